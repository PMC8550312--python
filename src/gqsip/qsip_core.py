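"""Core qSIP calculation: weighted densities and atom percent excess.

For each taxon i, replicate j, fraction k the abundance metric is
y_ijk = p_ijk * f_jk (relative coverage times total DNA concentration of
the fraction).  The taxon's weighted mean buoyant density in a sample is
W = sum_k(x_k * y_k) / sum_k(y_k); the mean W over unlabeled replicates
(W_light) and labeled replicates (W_lab) feed the isotope substitution
model, yielding atom percent excess (APE) per taxon per timepoint.

Bacterial genome bins, phage genomes, and 18S-bearing eukaryote scaffolds
flow through identically; only the taxon_class metadata differs.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .density_model import (
    DEFAULT_CONSTANTS,
    IsotopeModelConstants,
    afe_from_densities,
    gc_from_light_density,
    gc_out_of_range,
)

log = logging.getLogger("gqsip")

__all__ = [
    "taxon_fraction_abundance",
    "weighted_mean_density",
    "estimate_enrichment",
    "rank_by_ape",
]

ENRICHMENT_COLUMNS = [
    "taxon_id",
    "taxon_class",
    "week",
    "W_light",
    "W_lab",
    "APE_percent",
    "rank",
    "labeled",
    "gc_out_of_range",
]


def taxon_fraction_abundance(p, f):
    """Abundance metric y = p * f (relative coverage x DNA concentration)."""
    p = np.asarray(p, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any(p < 0) or np.any(f < 0):
        raise ValueError("taxon_fraction_abundance: p and f must be >= 0")
    y = p * f
    return float(y) if y.ndim == 0 else y


def weighted_mean_density(y, x):
    """Abundance-weighted mean buoyant density W = sum(x*y)/sum(y).

    Returns NaN when the taxon carries no abundance in the sample
    (sum(y) == 0): an undetected taxon has no density, which is not an
    error — callers put it on the skip list.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.size == 0:
        raise ValueError("weighted_mean_density: x and y must be equal-length, nonempty")
    total = y.sum()
    if total <= 0:
        return float("nan")
    return float((x * y).sum() / total)


def _per_sample_w(fractions: pd.DataFrame, coverage: pd.DataFrame) -> pd.DataFrame:
    """Weighted mean density of every (taxon, sample) with any abundance.

    Relative coverages are renormalized to within-library proportions
    before use: the composition of a library is the signal, its absolute
    depth scale is a sequencing artifact, so any per-library constant in
    the normalization dialect cancels exactly.
    """
    merged = coverage.merge(
        fractions[["sample_id", "fraction_id", "density_g_ml", "dna_conc_ng_ul"]],
        on=["sample_id", "fraction_id"],
        how="inner",
    )
    lib_total = merged.groupby(["sample_id", "fraction_id"])["relative_coverage"].transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(lib_total > 0, merged["relative_coverage"] / lib_total, 0.0)
    merged["y"] = p * merged["dna_conc_ng_ul"]
    merged["xy"] = merged["y"] * merged["density_g_ml"]
    grp = merged.groupby(["taxon_id", "sample_id"], sort=False)[["y", "xy"]].sum()
    grp = grp.reset_index()
    with np.errstate(invalid="ignore", divide="ignore"):
        grp["W"] = np.where(grp["y"] > 0, grp["xy"] / grp["y"], np.nan)
    return grp[["taxon_id", "sample_id", "W", "y"]]


def estimate_enrichment(
    design: pd.DataFrame,
    fractions: pd.DataFrame,
    coverage: pd.DataFrame,
    week: int,
    constants: IsotopeModelConstants = DEFAULT_CONSTANTS,
    taxon_classes: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-taxon APE for one timepoint, using the same-week bulk samples
    as the unlabeled treatment.

    Returns ``(enrichment, skipped)``.  ``enrichment`` has one row per
    taxon detected in both treatments, ranked ascending by APE;
    ``skipped`` lists taxa undetected in one treatment with a reason —
    absence of evidence is never reported as zero enrichment.
    """
    wk = design.loc[design["week"] == week]
    labeled_ids = set(wk.loc[wk["role"] == "labeled", "sample_id"])
    unlabeled_ids = set(wk.loc[wk["role"] == "unlabeled", "sample_id"])
    if not labeled_ids or not unlabeled_ids:
        raise ValueError(
            f"week {week}: needs >= 1 labeled and >= 1 unlabeled sample "
            f"(got {len(labeled_ids)} labeled, {len(unlabeled_ids)} unlabeled)"
        )

    sample_ids = labeled_ids | unlabeled_ids
    frac = fractions.loc[fractions["sample_id"].isin(sample_ids)]
    cov = coverage.loc[coverage["sample_id"].isin(sample_ids)]
    per_sample = _per_sample_w(frac, cov)

    rows, skipped = [], []
    for taxon, grp in per_sample.groupby("taxon_id", sort=True):
        w_unl = grp.loc[grp["sample_id"].isin(unlabeled_ids), "W"].dropna()
        w_lab = grp.loc[grp["sample_id"].isin(labeled_ids), "W"].dropna()
        if w_unl.empty or w_lab.empty:
            reason = (
                "undetected_in_unlabeled" if w_unl.empty else "undetected_in_labeled"
            )
            skipped.append({"taxon_id": taxon, "week": week, "skip_reason": reason})
            continue
        w_light = float(w_unl.mean())  # mean over replicates (n=1 in this study)
        w_labeled = float(w_lab.mean())
        a = afe_from_densities(w_light, w_labeled, constants)
        g = gc_from_light_density(w_light, constants)
        rows.append(
            {
                "taxon_id": taxon,
                "taxon_class": (taxon_classes or {}).get(taxon, "bacterial_bin"),
                "week": week,
                "W_light": w_light,
                "W_lab": w_labeled,
                "APE_percent": 100.0 * a,
                "gc_out_of_range": bool(gc_out_of_range(g)),
            }
        )
    enrichment = pd.DataFrame(rows)
    skipped_df = pd.DataFrame(skipped, columns=["taxon_id", "week", "skip_reason"])
    if skipped:
        log.warning("week %d: %d taxa skipped (undetected in one treatment)", week, len(skipped))
    if not enrichment.empty:
        enrichment = rank_by_ape(enrichment)
        enrichment["labeled"] = pd.NA  # set by detect_threshold.ape_cutoff
    return enrichment, skipped_df


def rank_by_ape(enrichment: pd.DataFrame) -> pd.DataFrame:
    """Ascending stable sort by APE; ties broken by taxon_id; ranks 1..n."""
    out = enrichment.sort_values(
        ["APE_percent", "taxon_id"], kind="stable", ignore_index=True
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out
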