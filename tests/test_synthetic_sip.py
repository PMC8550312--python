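"""Forward simulator: conservation laws, determinism, preset shape."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from gqsip.qsip_core import estimate_enrichment
from gqsip.synthetic_sip import (
    GradientConfig,
    SyntheticTaxon,
    rhizosphere_preset,
    simulate_gradient,
    simulate_timepoints,
)
from gqsip.tables_io import aggregate_bin_coverage, relative_coverage_table


def _tables_bytes(sim):
    parts = []
    for name in ("fractions", "coverage", "binmap", "design", "libraries", "truth"):
        buf = io.StringIO()
        getattr(sim, name).to_csv(buf, sep="\t", index=False)
        parts.append(buf.getvalue())
    return "".join(parts)


class TestSimulateGradient:
    def test_null_taxon_gives_identical_profiles(self):
        taxa = [SyntheticTaxon("t0", 0.5, 0.0, 100.0)]
        cfg = GradientConfig(density_min=1.64, density_max=1.74, n_fractions=32)
        sim = simulate_gradient(taxa, cfg)
        bulk = sim.fractions[sim.fractions["sample_id"] == "bulk_w6"]
        rhizo = sim.fractions[sim.fractions["sample_id"] == "rhizo_w6"]
        np.testing.assert_allclose(
            bulk["dna_conc_ng_ul"].to_numpy(), rhizo["dna_conc_ng_ul"].to_numpy()
        )
        rel = relative_coverage_table(
            aggregate_bin_coverage(sim.coverage, sim.binmap), sim.libraries
        )
        enr, _ = estimate_enrichment(sim.design, sim.fractions, rel, 6)
        assert enr["APE_percent"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_mass_conservation(self, small_community):
        taxa, cfg = small_community
        sim = simulate_gradient(taxa, cfg)
        for sid, grp in sim.fractions.groupby("sample_id"):
            total = (grp["dna_conc_ng_ul"] * grp["volume_ul"]).sum()
            assert total == pytest.approx(sum(t.mass_ng for t in taxa), rel=1e-9)

    def test_deterministic_under_seed(self, small_community):
        taxa, cfg = small_community
        from dataclasses import replace

        cfg = replace(cfg, reads_per_library=100_000, seed=42)
        a = _tables_bytes(simulate_gradient(taxa, cfg))
        b = _tables_bytes(simulate_gradient(taxa, cfg))
        assert a == b

    def test_tail_truncation_warns_with_taxon_name(self):
        taxa = [SyntheticTaxon("edge_taxon", 0.05, 0.0, 10.0)]  # density ~1.65
        cfg = GradientConfig(density_min=1.692, density_max=1.765)
        with pytest.warns(UserWarning, match="edge_taxon"):
            simulate_gradient(taxa, cfg)

    def test_three_bins_mode_emits_three_pseudo_fractions(self, small_community):
        taxa, cfg = small_community
        from dataclasses import replace

        sim = simulate_gradient(taxa, replace(cfg, bin_mode="three_bins"))
        counts = sim.fractions.groupby("sample_id")["fraction_id"].count()
        assert (counts <= 3).all() and (counts >= 2).all()

    def test_multinomial_noise_roughly_unbiased(self):
        # estimated APE under read sampling stays near truth on average
        rng = np.random.default_rng(2)
        taxa = [
            SyntheticTaxon(f"t{i}", g, 30.0, 50.0)
            for i, g in enumerate(rng.uniform(0.4, 0.7, 8))
        ]
        biases = []
        for seed in range(5):
            cfg = GradientConfig(
                density_min=1.64, density_max=1.80, n_fractions=32,
                reads_per_library=1_000_000, seed=seed,
            )
            sim = simulate_gradient(taxa, cfg)
            rel = relative_coverage_table(
                aggregate_bin_coverage(sim.coverage, sim.binmap), sim.libraries
            )
            enr, _ = estimate_enrichment(sim.design, sim.fractions, rel, 6)
            biases.append((enr["APE_percent"] - 30.0).mean())
        assert abs(np.mean(biases)) < 1.0


class TestSimulateTimepoints:
    def test_zero_growth_constant_abundance(self):
        taxa = [SyntheticTaxon(f"t{i}", 0.5 + 0.05 * i, 20.0, 50.0, r_true=0.0) for i in range(3)]
        cfg = GradientConfig(density_min=1.66, density_max=1.78)
        sim = simulate_timepoints(taxa, cfg, weeks=(0, 6, 9))
        yields = sim.design.set_index("sample_id")["dna_yield_ng_per_g"]
        assert yields.nunique() == 1

    def test_requires_week_zero(self):
        taxa = [SyntheticTaxon("t", 0.5, 10.0, 50.0)]
        with pytest.raises(ValueError, match="include 0"):
            simulate_timepoints(taxa, GradientConfig(), weeks=(6, 9))

    def test_negative_mass_rejected(self):
        taxa = [SyntheticTaxon("t", 0.5, 10.0, 10.0, r_true=-1.0)]
        cfg = GradientConfig(density_min=1.66, density_max=1.78)
        with pytest.raises(ValueError, match="nonpositive mass"):
            simulate_timepoints(taxa, cfg, weeks=(0, 6))


class TestRhizospherePreset:
    def test_taxon_counts_match_study_shape(self):
        taxa, _ = rhizosphere_preset()
        classes = pd.Series([t.taxon_class for t in taxa]).value_counts()
        assert classes["bacterial_bin"] == 55
        assert classes["phage"] == 10
        assert classes["eukaryote_scaffold"] == 27

    def test_most_labeled_entities_are_phage(self):
        taxa, _ = rhizosphere_preset()
        top2 = sorted(taxa, key=lambda t: t.ape_true)[-2:]
        assert all(t.taxon_class == "phage" for t in top2)

    def test_constructed_bacterial_labeling_fraction(self):
        taxa, _ = rhizosphere_preset()
        bact = [t for t in taxa if t.taxon_class == "bacterial_bin"]
        frac = np.mean([t.ape_true > 2.5 for t in bact])
        assert frac == pytest.approx(43 / 55)

    def test_derived_boundaries_near_continuous_truth(self):
        # boundaries recovered from the 32-fraction discretization fall
        # within one fraction width of the continuous-profile values
        from scipy.stats import norm

        from gqsip.density_model import density_from_afe
        from gqsip.tables_io import derive_bin_boundaries

        taxa, cfg = rhizosphere_preset()
        sim = simulate_gradient(taxa, cfg)
        lab = sim.fractions[sim.fractions["sample_id"] == "rhizo_w6"]
        unl = sim.fractions[sim.fractions["sample_id"] == "bulk_w6"]
        derived = derive_bin_boundaries(lab, unl)

        width = (cfg.density_max - cfg.density_min) / cfg.n_fractions
        grid = np.linspace(cfg.density_min, cfg.density_max, 20001)

        def conc(apes):
            dens = np.zeros_like(grid)
            for t, a in zip(taxa, apes):
                dens += t.mass_ng * norm.pdf(grid, density_from_afe(t.g_true, a), cfg.sigma_density)
            return dens * width / cfg.volume_ul

        cu = conc([0.0] * len(taxa))
        cl = conc([t.ape_true / 100.0 for t in taxa])
        true_mm = grid[np.nonzero(cu > 0.05)[0][-1] + 1]
        diff = cl - cu
        idx = np.nonzero((diff[:-1] * diff[1:] <= 0) & (grid[:-1] < true_mm))[0]
        true_lm = grid[idx[-1]]
        assert abs(derived.middle_max - true_mm) <= width
        assert abs(derived.light_max - true_lm) <= width

    def test_three_bin_coarsening_preserves_rank_order(self):
        # rank order of true enrichment survives light/middle/heavy pooling
        taxa, cfg = rhizosphere_preset()
        from dataclasses import replace

        sim = simulate_gradient(taxa, replace(cfg, bin_mode="three_bins"))
        rel = relative_coverage_table(
            aggregate_bin_coverage(sim.coverage, sim.binmap), sim.libraries
        )
        enr, _ = estimate_enrichment(sim.design, sim.fractions, rel, 6)
        merged = enr.merge(sim.truth, on="taxon_id")
        rho = spearmanr(merged["APE_true"], merged["APE_percent"]).statistic
        assert rho >= 0.95
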