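"""Input tables: validation, bin-coverage aggregation, density bins."""

import numpy as np
import pandas as pd
import pytest

from gqsip.tables_io import (
    BinBoundaries,
    PAPER_BOUNDARIES,
    SchemaError,
    ValidationError,
    aggregate_bin_coverage,
    assign_density_bins,
    combine_fractions,
    derive_bin_boundaries,
    normalize_coverage,
    read_tables,
    relative_coverage_table,
)


class TestReadTables:
    def test_round_trip_toy_set(self, toy_tables):
        ts = read_tables(
            toy_tables / "fractions.tsv",
            toy_tables / "coverage.tsv",
            toy_tables / "binmap.tsv",
            toy_tables / "design.tsv",
            toy_tables / "libraries.tsv",
        )
        assert len(ts.fractions) == 3
        assert len(ts.coverage) == 3
        assert ts.fractions["density_g_ml"].tolist() == [1.70, 1.72, 1.74]

    def test_missing_column_names_it(self, toy_tables):
        (toy_tables / "fractions.tsv").write_text(
            "sample_id\tfraction_id\tdna_conc_ng_ul\ns1\tf1\t5.0\n"
        )
        with pytest.raises(SchemaError, match="density_g_ml"):
            read_tables(
                toy_tables / "fractions.tsv",
                toy_tables / "coverage.tsv",
                toy_tables / "binmap.tsv",
                toy_tables / "design.tsv",
            )

    def test_duplicate_key_rejected(self, toy_tables):
        path = toy_tables / "fractions.tsv"
        path.write_text(
            "sample_id\tfraction_id\tdensity_g_ml\tdna_conc_ng_ul\n"
            "s1\tf1\t1.70\t5.0\ns1\tf1\t1.71\t5.0\n"
        )
        with pytest.raises(ValidationError, match="duplicated key"):
            read_tables(
                path,
                toy_tables / "coverage.tsv",
                toy_tables / "binmap.tsv",
                toy_tables / "design.tsv",
            )

    def test_density_out_of_range_rejected(self, toy_tables):
        path = toy_tables / "fractions.tsv"
        path.write_text(
            "sample_id\tfraction_id\tdensity_g_ml\tdna_conc_ng_ul\ns1\tf1\t1.20\t5.0\n"
        )
        with pytest.raises(ValidationError, match="density"):
            read_tables(
                path,
                toy_tables / "coverage.tsv",
                toy_tables / "binmap.tsv",
                toy_tables / "design.tsv",
            )

    def test_unpaired_labeled_week_rejected(self, toy_tables):
        (toy_tables / "design.tsv").write_text(
            "sample_id\thabitat\tweek\trole\treplicate\ns1\trhizosphere\t6\tlabeled\t1\n"
        )
        with pytest.raises(ValidationError, match="unlabeled"):
            read_tables(
                toy_tables / "fractions.tsv",
                toy_tables / "coverage.tsv",
                toy_tables / "binmap.tsv",
                toy_tables / "design.tsv",
            )

    def test_short_scaffolds_dropped(self, toy_tables):
        (toy_tables / "coverage.tsv").write_text(
            "library_id\tscaffold_id\tlength_bp\tmean_depth\n"
            "L1\tscA1\t1000\t10.0\nL1\tscTiny\t500\t99.0\n"
        )
        ts = read_tables(
            toy_tables / "fractions.tsv",
            toy_tables / "coverage.tsv",
            toy_tables / "binmap.tsv",
            toy_tables / "design.tsv",
        )
        assert ts.coverage["scaffold_id"].tolist() == ["scA1"]


class TestAggregateBinCoverage:
    def test_length_weighted_mean(self):
        cov = pd.DataFrame(
            {
                "library_id": ["L1", "L1"],
                "scaffold_id": ["a", "b"],
                "length_bp": [1000, 3000],
                "mean_depth": [10.0, 20.0],
            }
        )
        binmap = pd.DataFrame({"scaffold_id": ["a", "b"], "taxon_id": ["bin1", "bin1"]})
        out = aggregate_bin_coverage(cov, binmap)
        # (10*1000 + 20*3000) / 4000
        assert out["mean_depth"].iloc[0] == pytest.approx(17.5)

    def test_single_scaffold_identity_and_zero(self):
        cov = pd.DataFrame(
            {
                "library_id": ["L1", "L1"],
                "scaffold_id": ["a", "b"],
                "length_bp": [1500, 2500],
                "mean_depth": [7.25, 0.0],
            }
        )
        binmap = pd.DataFrame({"scaffold_id": ["a", "b"], "taxon_id": ["x", "y"]})
        out = aggregate_bin_coverage(cov, binmap).set_index("taxon_id")
        assert out.at["x", "mean_depth"] == pytest.approx(7.25)
        assert out.at["y", "mean_depth"] == 0.0

    def test_invariant_under_scaffold_split(self):
        # splitting a scaffold into two contiguous pieces with the same depth
        whole = pd.DataFrame(
            {
                "library_id": ["L1", "L1"],
                "scaffold_id": ["a", "b"],
                "length_bp": [4000, 2000],
                "mean_depth": [10.0, 4.0],
            }
        )
        split = pd.DataFrame(
            {
                "library_id": ["L1"] * 3,
                "scaffold_id": ["a1", "a2", "b"],
                "length_bp": [1000, 3000, 2000],
                "mean_depth": [10.0, 10.0, 4.0],
            }
        )
        bm_whole = pd.DataFrame({"scaffold_id": ["a", "b"], "taxon_id": ["bin"] * 2})
        bm_split = pd.DataFrame(
            {"scaffold_id": ["a1", "a2", "b"], "taxon_id": ["bin"] * 3}
        )
        d1 = aggregate_bin_coverage(whole, bm_whole)["mean_depth"].iloc[0]
        d2 = aggregate_bin_coverage(split, bm_split)["mean_depth"].iloc[0]
        assert d1 == pytest.approx(d2, rel=1e-12)


@pytest.mark.parametrize(
    "depth, total, expected",
    [(10.0, 2_000_000, 5.0), (0.0, 123, 0.0), (7.0, 1_000_000, 7.0)],
)
def test_normalize_coverage(depth, total, expected):
    assert normalize_coverage(depth, total) == pytest.approx(expected)


def test_normalize_coverage_zero_reads_rejected():
    with pytest.raises(ValidationError):
        normalize_coverage(1.0, 0)


class TestBinBoundaries:
    def _profiles(self):
        # constructed so the unlabeled curve hits eps exactly at 1.747 and
        # the labeled-minus-unlabeled difference crosses zero at 1.738
        dens = [1.70, 1.71, 1.72, 1.73, 1.736, 1.740, 1.744, 1.747, 1.75]
        unl = [5.0, 6.0, 5.0, 3.0, 2.0, 1.0, 0.5, 0.05, 0.0]
        lab = [4.0, 5.0, 4.0, 2.0, 1.9, 1.1, 1.0, 0.8, 0.5]
        mk = lambda c, sid: pd.DataFrame(
            {
                "sample_id": sid,
                "fraction_id": [f"f{i}" for i in range(len(dens))],
                "density_g_ml": dens,
                "dna_conc_ng_ul": c,
                "volume_ul": 144.0,
            }
        )
        return mk(lab, "rhizo"), mk(unl, "bulk")

    def test_derived_boundaries_hit_constructed_points(self):
        lab, unl = self._profiles()
        b = derive_bin_boundaries(lab, unl, eps=0.05)
        assert b.source == "derived"
        assert b.light_max == pytest.approx(1.738, abs=1e-9)
        assert b.middle_max == pytest.approx(1.747, abs=1e-9)

    def test_identical_profiles_no_crossing(self):
        _, unl = self._profiles()
        lab = unl.copy()
        lab["sample_id"] = "rhizo"
        with pytest.raises(ValidationError, match="cross"):
            derive_bin_boundaries(lab, unl)

    def test_unlabeled_never_reaching_zero(self):
        lab, unl = self._profiles()
        unl["dna_conc_ng_ul"] = unl["dna_conc_ng_ul"] + 1.0
        with pytest.raises(ValidationError, match="fixed boundaries"):
            derive_bin_boundaries(lab, unl)

    def test_paper_fixed_boundaries(self):
        assert PAPER_BOUNDARIES.light_max == 1.737
        assert PAPER_BOUNDARIES.middle_max == 1.746
        assert PAPER_BOUNDARIES.source == "fixed"

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValidationError):
            BinBoundaries(1.75, 1.74)


class TestAssignBins:
    @pytest.mark.parametrize(
        "density, expected",
        [
            (1.70, "light"),  # inside the published light range
            (1.740, "middle"),  # inside the published middle range
            (1.737, "light"),  # boundary inclusive on the light side
            (1.75, "heavy"),
        ],
    )
    def test_paper_boundaries(self, density, expected):
        frac = pd.DataFrame({"density_g_ml": [density]})
        out = assign_density_bins(frac, PAPER_BOUNDARIES)
        assert out["density_bin"].iloc[0] == expected

    def test_partition_every_fraction_labeled(self):
        dens = np.linspace(1.69, 1.77, 33)
        out = assign_density_bins(pd.DataFrame({"density_g_ml": dens}), PAPER_BOUNDARIES)
        assert out["density_bin"].isin(["light", "middle", "heavy"]).all()


class TestCombineFractions:
    def _two_fractions(self):
        frac = pd.DataFrame(
            {
                "sample_id": ["s1", "s1"],
                "fraction_id": ["f1", "f2"],
                "density_g_ml": [1.740, 1.744],
                "dna_conc_ng_ul": [10.0, 30.0],
                "volume_ul": [144.0, 144.0],
            }
        )
        return assign_density_bins(frac, PAPER_BOUNDARIES)

    def test_mass_weighted_density(self):
        pseudo, _ = combine_fractions(self._two_fractions())
        # (1.740*10 + 1.744*30) / 40
        assert pseudo["density_g_ml"].iloc[0] == pytest.approx(1.743)

    def test_mass_conserved(self):
        frac = self._two_fractions()
        pseudo, _ = combine_fractions(frac)
        before = (frac["dna_conc_ng_ul"] * frac["volume_ul"]).sum()
        after = (pseudo["dna_conc_ng_ul"] * pseudo["volume_ul"]).sum()
        assert after == pytest.approx(before, rel=1e-12)

    def test_coverage_aggregated_mass_weighted(self):
        frac = self._two_fractions()
        cov = pd.DataFrame(
            {
                "taxon_id": ["t1", "t1"],
                "sample_id": ["s1", "s1"],
                "fraction_id": ["f1", "f2"],
                "relative_coverage": [0.2, 0.1],
            }
        )
        _, combined = combine_fractions(frac, cov)
        # weights are member DNA masses: (0.2*10 + 0.1*30) / 40
        assert combined["relative_coverage"].iloc[0] == pytest.approx(0.125)
        assert combined["fraction_id"].iloc[0] == "middle"

    def test_bin_keyed_coverage_passes_through(self):
        frac = self._two_fractions()
        cov = pd.DataFrame(
            {
                "taxon_id": ["t1"],
                "sample_id": ["s1"],
                "fraction_id": ["middle"],
                "relative_coverage": [0.5],
            }
        )
        _, combined = combine_fractions(frac, cov)
        assert combined["relative_coverage"].tolist() == [0.5]

    def test_zero_dna_bin_dropped(self):
        frac = pd.DataFrame(
            {
                "sample_id": ["s1", "s1"],
                "fraction_id": ["f1", "f2"],
                "density_g_ml": [1.70, 1.75],
                "dna_conc_ng_ul": [5.0, 0.0],
                "volume_ul": [144.0, 144.0],
            }
        )
        frac = assign_density_bins(frac, PAPER_BOUNDARIES)
        pseudo, _ = combine_fractions(frac)
        assert pseudo["density_bin"].tolist() == ["light"]
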