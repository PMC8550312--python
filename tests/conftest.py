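import numpy as np
import pandas as pd
import pytest

from gqsip.synthetic_sip import GradientConfig, SyntheticTaxon


@pytest.fixture
def toy_tables(tmp_path):
    """A minimal, hand-checkable TSV table set (3 fractions, 2 taxa)."""
    (tmp_path / "fractions.tsv").write_text(
        "sample_id\tfraction_id\tdensity_g_ml\tdna_conc_ng_ul\tvolume_ul\n"
        "s1\tf1\t1.70\t5.0\t144\n"
        "s1\tf2\t1.72\t8.0\t144\n"
        "s1\tf3\t1.74\t2.0\t144\n"
    )
    (tmp_path / "coverage.tsv").write_text(
        "library_id\tscaffold_id\tlength_bp\tmean_depth\n"
        "L1\tscA1\t1000\t10.0\n"
        "L1\tscA2\t3000\t20.0\n"
        "L1\tscB1\t2000\t4.0\n"
    )
    (tmp_path / "binmap.tsv").write_text(
        "scaffold_id\ttaxon_id\nscA1\tbinA\nscA2\tbinA\nscB1\tbinB\n"
    )
    (tmp_path / "design.tsv").write_text(
        "sample_id\thabitat\tweek\trole\treplicate\n"
        "s1\tbulk\t6\tunlabeled\t1\n"
    )
    (tmp_path / "libraries.tsv").write_text(
        "library_id\tsample_id\tfraction_or_bin_id\ttotal_reads\n"
        "L1\ts1\tf1\t2000000\n"
    )
    return tmp_path


@pytest.fixture
def small_community():
    """12 taxa spanning GC and enrichment, on a gradient wide enough to hold
    all of their density distributions."""
    rng = np.random.default_rng(11)
    gcs = rng.uniform(0.30, 0.75, 12)
    apes = np.linspace(0.0, 90.0, 12)
    taxa = [
        SyntheticTaxon(f"t{i:02d}", g, a, 10.0 + i)
        for i, (g, a) in enumerate(zip(gcs, apes))
    ]
    cfg = GradientConfig(density_min=1.62, density_max=1.82, n_fractions=32)
    return taxa, cfg


def hinge(x, psi=70.0, slope=0.5):
    return np.where(x > psi, slope * (x - psi), 0.0)
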