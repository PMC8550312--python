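"""Tabular input handling for the qSIP pipeline.

Reads and validates the five TSV inputs (gradient fraction metadata,
per-scaffold coverage, scaffold-to-bin membership, sample design, library
metadata), aggregates scaffold coverage into genome-bin coverage,
normalizes for sequencing depth, and derives/applies the density-bin
boundaries used to combine fractions into light/middle/heavy bins before
sequencing.

All tables are UTF-8, tab-delimited, with a header row and '.' decimal
separator.  Lines starting with '#' are treated as comments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger("gqsip")

__all__ = [
    "SchemaError",
    "ValidationError",
    "BinBoundaries",
    "PAPER_BOUNDARIES",
    "TableSet",
    "read_tables",
    "read_fractions",
    "read_coverage",
    "read_binmap",
    "read_design",
    "read_libraries",
    "aggregate_bin_coverage",
    "normalize_coverage",
    "relative_coverage_table",
    "derive_bin_boundaries",
    "assign_density_bins",
    "combine_fractions",
]

DENSITY_RANGE = (1.55, 1.85)
DEFAULT_FRACTION_VOLUME_UL = 144.0
DEFAULT_MIN_SCAFFOLD_BP = 1000
DEFAULT_CONC_EPS = 0.05  # ng/ul: "concentration reached 0" threshold

HABITATS = {"bulk", "rhizosphere"}
ROLES = {"labeled", "unlabeled"}
DENSITY_BINS = ("light", "middle", "heavy")


class SchemaError(ValueError):
    """A required column is missing or has the wrong dtype."""


class ValidationError(ValueError):
    """Table contents violate an invariant (range, duplication, pairing)."""


@dataclass(frozen=True)
class BinBoundaries:
    """Density-bin boundaries (g/ml): density <= light_max is light,
    light_max < density <= middle_max is middle, above is heavy."""

    light_max: float
    middle_max: float
    source: str = "fixed"  # {"fixed", "derived"}

    def __post_init__(self):
        if not self.light_max < self.middle_max:
            raise ValidationError(
                f"light_max ({self.light_max}) must be < middle_max ({self.middle_max})"
            )


#: the study's published boundaries (light 1.692-1.737, middle 1.738-1.746 g/ml)
PAPER_BOUNDARIES = BinBoundaries(light_max=1.737, middle_max=1.746, source="fixed")


@dataclass
class TableSet:
    """Validated input tables as pandas DataFrames."""

    fractions: pd.DataFrame
    coverage: pd.DataFrame
    binmap: pd.DataFrame
    design: pd.DataFrame
    libraries: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# reading & validation
# ---------------------------------------------------------------------------


def _read_tsv(path, required: dict, name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{name}: missing required column '{col}'")
    for col, dtype in required.items():
        if dtype is not None:
            try:
                df[col] = df[col].astype(dtype)
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"{name}: column '{col}' not parseable as {dtype}: {exc}")
    log.info("read %s: %d rows", name, len(df))
    return df


def _check_unique(df: pd.DataFrame, keys: list[str], name: str) -> None:
    dup = df.duplicated(subset=keys)
    if dup.any():
        first = df.loc[dup, keys].iloc[0].to_dict()
        raise ValidationError(f"{name}: duplicated key {first}")


def read_fractions(path) -> pd.DataFrame:
    df = _read_tsv(
        path,
        {
            "sample_id": str,
            "fraction_id": str,
            "density_g_ml": float,
            "dna_conc_ng_ul": float,
        },
        "fractions",
    )
    if "volume_ul" not in df.columns:
        df["volume_ul"] = DEFAULT_FRACTION_VOLUME_UL
    df["volume_ul"] = df["volume_ul"].fillna(DEFAULT_FRACTION_VOLUME_UL).astype(float)
    _check_unique(df, ["sample_id", "fraction_id"], "fractions")
    lo, hi = DENSITY_RANGE
    bad = (df["density_g_ml"] <= lo) | (df["density_g_ml"] >= hi)
    if bad.any():
        raise ValidationError(
            f"fractions: density outside ({lo}, {hi}) g/ml in rows "
            f"{df.loc[bad, 'fraction_id'].tolist()}"
        )
    if (df["dna_conc_ng_ul"] < 0).any():
        raise ValidationError("fractions: negative dna_conc_ng_ul")
    # strict monotonicity under collection order reduces to pairwise-distinct
    # densities within a sample (no order column is carried)
    for sid, grp in df.groupby("sample_id"):
        if grp["density_g_ml"].duplicated().any():
            raise ValidationError(f"fractions: duplicated density within sample {sid}")
    return df


def read_coverage(path, min_scaffold_bp: int = DEFAULT_MIN_SCAFFOLD_BP) -> pd.DataFrame:
    df = _read_tsv(
        path,
        {"library_id": str, "scaffold_id": str, "length_bp": int, "mean_depth": float},
        "coverage",
    )
    if not np.all(np.isfinite(df["mean_depth"])) or (df["mean_depth"] < 0).any():
        raise ValidationError("coverage: mean_depth must be finite and >= 0")
    short = df["length_bp"] < min_scaffold_bp
    if short.any():
        log.warning(
            "coverage: dropping %d rows with scaffolds < %d bp",
            int(short.sum()),
            min_scaffold_bp,
        )
        df = df.loc[~short].reset_index(drop=True)
    _check_unique(df, ["library_id", "scaffold_id"], "coverage")
    return df


def read_binmap(path, coverage: pd.DataFrame | None = None) -> pd.DataFrame:
    df = _read_tsv(path, {"scaffold_id": str, "taxon_id": str}, "binmap")
    _check_unique(df, ["scaffold_id"], "binmap")
    if coverage is not None:
        known = set(coverage["scaffold_id"])
        missing = ~df["scaffold_id"].isin(known)
        if missing.any():
            log.warning(
                "binmap: %d scaffolds not present in coverage table; rows dropped",
                int(missing.sum()),
            )
            df = df.loc[~missing].reset_index(drop=True)
    return df


def read_design(path) -> pd.DataFrame:
    df = _read_tsv(
        path,
        {"sample_id": str, "habitat": str, "week": int, "role": str, "replicate": int},
        "design",
    )
    _check_unique(df, ["sample_id"], "design")
    if not set(df["habitat"]).issubset(HABITATS):
        raise ValidationError(f"design: habitat must be one of {sorted(HABITATS)}")
    if not set(df["role"]).issubset(ROLES):
        raise ValidationError(f"design: role must be one of {sorted(ROLES)}")
    if (df["week"] < 0).any():
        raise ValidationError("design: week must be >= 0")
    if (df["replicate"] < 1).any():
        raise ValidationError("design: replicate must be >= 1")
    validate_design_pairing(df)
    return df


def validate_design_pairing(design: pd.DataFrame) -> None:
    """Every week with labeled samples must also have an unlabeled sample."""
    labeled_weeks = set(design.loc[design["role"] == "labeled", "week"])
    unlabeled_weeks = set(design.loc[design["role"] == "unlabeled", "week"])
    missing = labeled_weeks - unlabeled_weeks
    if missing:
        raise ValidationError(
            f"design: labeled weeks {sorted(missing)} lack a paired unlabeled sample"
        )


def read_libraries(path, design: pd.DataFrame | None = None) -> pd.DataFrame:
    df = _read_tsv(
        path,
        {
            "library_id": str,
            "sample_id": str,
            "fraction_or_bin_id": str,
            "total_reads": int,
        },
        "libraries",
    )
    _check_unique(df, ["library_id"], "libraries")
    if (df["total_reads"] <= 0).any():
        raise ValidationError("libraries: total_reads must be > 0")
    if design is not None:
        unknown = ~df["sample_id"].isin(set(design["sample_id"]))
        if unknown.any():
            raise ValidationError(
                f"libraries: sample_id not in design: "
                f"{sorted(df.loc[unknown, 'sample_id'].unique())}"
            )
    return df


def read_tables(
    fraction_path,
    coverage_path,
    binmap_path,
    design_path,
    libraries_path=None,
    min_scaffold_bp: int = DEFAULT_MIN_SCAFFOLD_BP,
) -> TableSet:
    """Read and cross-validate the full input table set."""
    fractions = read_fractions(fraction_path)
    coverage = read_coverage(coverage_path, min_scaffold_bp=min_scaffold_bp)
    binmap = read_binmap(binmap_path, coverage=coverage)
    design = read_design(design_path)
    libraries = read_libraries(libraries_path, design=design) if libraries_path else None
    unknown = ~fractions["sample_id"].isin(set(design["sample_id"]))
    if unknown.any():
        raise ValidationError(
            f"fractions: sample_id not in design: "
            f"{sorted(fractions.loc[unknown, 'sample_id'].unique())}"
        )
    return TableSet(fractions, coverage, binmap, design, libraries)


# ---------------------------------------------------------------------------
# coverage aggregation & normalization
# ---------------------------------------------------------------------------


def aggregate_bin_coverage(coverage: pd.DataFrame, binmap: pd.DataFrame) -> pd.DataFrame:
    """Length-weighted mean depth of each genome bin in each library.

    bin depth = sum(depth_s * len_s) / sum(len_s) over member scaffolds.
    Scaffolds of a bin missing from a library's rows count as depth 0 (their
    length still enters the denominator), so the result is invariant to
    whether zero-depth rows are written out.
    """
    lengths = (
        coverage[["scaffold_id", "length_bp"]]
        .drop_duplicates("scaffold_id")
        .merge(binmap, on="scaffold_id")
    )
    if lengths.empty:
        raise ValidationError("aggregate_bin_coverage: no binned scaffolds in coverage")
    bin_len = lengths.groupby("taxon_id")["length_bp"].sum()
    if (bin_len <= 0).any():
        bad = bin_len.index[bin_len <= 0].tolist()
        raise ValidationError(f"aggregate_bin_coverage: zero total length for bins {bad}")

    merged = coverage.merge(binmap, on="scaffold_id")
    merged["mass"] = merged["mean_depth"] * merged["length_bp"]
    num = merged.groupby(["library_id", "taxon_id"])["mass"].sum()
    out = num.reset_index()
    out["mean_depth"] = out["mass"] / out["taxon_id"].map(bin_len).to_numpy()
    return out[["library_id", "taxon_id", "mean_depth"]]


def normalize_coverage(depth, library_total_reads):
    """Depth per million mapped reads: p = depth / (total_reads / 1e6).

    Any per-library constant would do (qSIP uses p only in products and
    ratios); per-million is conventional and auditable.
    """
    total = np.asarray(library_total_reads, dtype=float)
    if np.any(total <= 0):
        raise ValidationError("normalize_coverage: library_total_reads must be > 0")
    return np.asarray(depth, dtype=float) / (total / 1e6)


def relative_coverage_table(
    bin_depths: pd.DataFrame, libraries: pd.DataFrame
) -> pd.DataFrame:
    """Join per-bin depths with library metadata and depth-normalize.

    Returns CoverageRecord rows: (taxon_id, sample_id, fraction_id,
    relative_coverage).
    """
    merged = bin_depths.merge(libraries, on="library_id", how="left")
    if merged["sample_id"].isna().any():
        bad = merged.loc[merged["sample_id"].isna(), "library_id"].unique().tolist()
        raise ValidationError(f"relative_coverage_table: unknown libraries {bad}")
    merged["relative_coverage"] = normalize_coverage(
        merged["mean_depth"].to_numpy(), merged["total_reads"].to_numpy()
    )
    out = merged.rename(columns={"fraction_or_bin_id": "fraction_id"})
    return out[["taxon_id", "sample_id", "fraction_id", "relative_coverage"]]


# ---------------------------------------------------------------------------
# density bins
# ---------------------------------------------------------------------------


def _interp_crossing(d0, c0, d1, c1, level):
    """Density at which a linearly interpolated concentration crosses level."""
    if c0 == c1:
        return 0.5 * (d0 + d1)
    return d0 + (c0 - level) / (c0 - c1) * (d1 - d0)


def derive_bin_boundaries(
    labeled_fractions: pd.DataFrame,
    unlabeled_fractions: pd.DataFrame,
    eps: float = DEFAULT_CONC_EPS,
) -> BinBoundaries:
    """Derive light/middle/heavy boundaries from a labeled vs unlabeled
    density-profile comparison.

    middle_max (start of heavy): the lowest density at and above which the
    unlabeled (bulk) DNA concentration stays at or below ``eps`` ("reached
    0"), linearly interpolated between the flanking fractions.  light_max:
    the highest density below middle_max at which the labeled and unlabeled
    concentration curves cross.
    """
    unl = unlabeled_fractions.sort_values("density_g_ml")
    lab = labeled_fractions.sort_values("density_g_ml")
    if len(unl) < 5 or len(lab) < 5:
        raise ValidationError("derive_bin_boundaries: need >= 5 fractions per profile")

    ud = unl["density_g_ml"].to_numpy()
    uc = unl["dna_conc_ng_ul"].to_numpy()
    above = uc > eps
    if not above.any():
        raise ValidationError(
            "derive_bin_boundaries: unlabeled profile never exceeds eps; "
            "check eps or supply fixed boundaries"
        )
    last_above = int(np.nonzero(above)[0][-1])
    if last_above == len(uc) - 1:
        raise ValidationError(
            "derive_bin_boundaries: unlabeled concentration never reaches "
            f"<= {eps} ng/ul at the heavy end; supply fixed boundaries instead"
        )
    middle_max = _interp_crossing(
        ud[last_above], uc[last_above], ud[last_above + 1], uc[last_above + 1], eps
    )

    # diff of the two curves on the labeled sample's density grid
    ld = lab["density_g_ml"].to_numpy()
    lc = lab["dna_conc_ng_ul"].to_numpy()
    uc_on_l = np.interp(ld, ud, uc)
    diff = lc - uc_on_l
    crossing = None
    for k in range(len(ld) - 1):
        if ld[k + 1] > middle_max:
            break
        if diff[k] == 0.0 and diff[k + 1] == 0.0:
            continue
        if diff[k] * diff[k + 1] <= 0.0 and (diff[k] != 0.0 or diff[k + 1] != 0.0):
            crossing = _interp_crossing(ld[k], diff[k], ld[k + 1], diff[k + 1], 0.0)
    if crossing is None or crossing >= middle_max:
        raise ValidationError(
            "derive_bin_boundaries: labeled and unlabeled profiles do not cross "
            "below the heavy boundary (identical or non-overlapping profiles?)"
        )
    return BinBoundaries(light_max=float(crossing), middle_max=float(middle_max), source="derived")


def assign_density_bins(fractions: pd.DataFrame, boundaries: BinBoundaries) -> pd.DataFrame:
    """Label each fraction light/middle/heavy (upper bounds inclusive)."""
    out = fractions.copy()
    d = out["density_g_ml"].to_numpy()
    out["density_bin"] = np.select(
        [d <= boundaries.light_max, d <= boundaries.middle_max],
        ["light", "middle"],
        default="heavy",
    )
    return out


def combine_fractions(
    fractions: pd.DataFrame, coverage: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Combine fractions into per-bin pseudo-fractions.

    Pseudo-fraction density is the DNA-mass-weighted mean density of the
    member fractions (the expected buoyant density of the DNA actually
    pooled for sequencing); concentration is total member DNA mass divided
    by total member volume, so DNA mass is conserved exactly.

    Coverage records keyed to member fraction_ids are aggregated with
    DNA-mass weights (the taxon's share of the pooled bin DNA); records
    already keyed to a bin name pass through unchanged, covering the case
    where sequencing was done per bin.
    """
    if "density_bin" not in fractions.columns:
        raise ValidationError("combine_fractions: assign_density_bins must run first")
    frac = fractions.copy()
    frac["mass_ng"] = frac["dna_conc_ng_ul"] * frac["volume_ul"]

    rows = []
    member_map: dict[tuple[str, str], str] = {}
    for (sid, dbin), grp in frac.groupby(["sample_id", "density_bin"], sort=False):
        if dbin not in DENSITY_BINS:
            continue
        total_mass = grp["mass_ng"].sum()
        total_vol = grp["volume_ul"].sum()
        if total_mass <= 0:
            log.warning("combine_fractions: empty %s bin in sample %s dropped", dbin, sid)
            continue
        density = float((grp["density_g_ml"] * grp["mass_ng"]).sum() / total_mass)
        rows.append(
            {
                "sample_id": sid,
                "fraction_id": dbin,
                "density_g_ml": density,
                "dna_conc_ng_ul": total_mass / total_vol,
                "volume_ul": total_vol,
                "density_bin": dbin,
            }
        )
        for fid in grp["fraction_id"]:
            member_map[(sid, fid)] = dbin
    pseudo = pd.DataFrame(rows)

    if coverage is None:
        return pseudo, None

    cov = coverage.copy()
    keys = list(zip(cov["sample_id"], cov["fraction_id"]))
    is_member = pd.Series([k in member_map for k in keys], index=cov.index)
    passthrough = cov.loc[~is_member & cov["fraction_id"].isin(DENSITY_BINS)]
    members = cov.loc[is_member].copy()
    if not members.empty:
        members["bin"] = [member_map[k] for k, m in zip(keys, is_member) if m]
        members = members.merge(
            frac[["sample_id", "fraction_id", "mass_ng"]],
            on=["sample_id", "fraction_id"],
        )
        members["w"] = members["relative_coverage"] * members["mass_ng"]
        agg = members.groupby(["taxon_id", "sample_id", "bin"], sort=False).agg(
            w=("w", "sum"), mass=("mass_ng", "sum")
        )
        agg = agg.reset_index()
        agg["relative_coverage"] = agg["w"] / agg["mass"]
        agg = agg.rename(columns={"bin": "fraction_id"})
        agg = agg[["taxon_id", "sample_id", "fraction_id", "relative_coverage"]]
    else:
        agg = members
    combined_cov = pd.concat(
        [agg, passthrough[["taxon_id", "sample_id", "fraction_id", "relative_coverage"]]],
        ignore_index=True,
    )
    return pseudo, combined_cov
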