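"""Taxon-specific total abundances and growth rates on labeled carbon.

Under a linear growth model, N_total(t) = N_total(0) + r * t, the net
growth rate of a taxon is r_net = (N_t - N_0) / t in ng DNA per g dry soil
per day.  The gross growth rate attributable to labeled-substrate
assimilation partitions the standing DNA by its isotopic signature: with
new DNA built from a carbon pool at atom fraction excess A_source, a
fraction U of which comes from labeled substrates, the taxon's measured
APE implies a new-DNA fraction

    phi = (APE / 100) / (A_source * U)

and r_gross = N_t * min(phi, 1) / t.  Negative APE (measurement noise) is
clipped to zero growth on labeled carbon; negative net rates (population
decline) are reported as-is.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger("gqsip")

__all__ = [
    "GrowthConfig",
    "taxon_total_abundance",
    "net_growth_rate",
    "gross_growth_rate",
    "relative_abundance",
    "estimate_growth",
]

DAYS_PER_WEEK = 7.0


@dataclass(frozen=True)
class GrowthConfig:
    """Labeled-carbon bookkeeping for gross growth rates.

    u: fraction of carbon in newly synthesized DNA that comes from labeled
       substrates (1.0: all new DNA carbon is rhizosphere-derived).
    a_source: atom fraction excess of the assimilated carbon pool; results
       scale by 1/a_source, so it is exposed rather than guessed.
    t_days: elapsed time in days.
    """

    t_days: float
    u: float = 1.0
    a_source: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.u <= 1.0:
            raise ValueError("GrowthConfig: U must be in (0, 1]")
        if not 0.0 < self.a_source <= 1.0:
            raise ValueError("GrowthConfig: a_source must be in (0, 1]")
        if not self.t_days > 0:
            raise ValueError("GrowthConfig: t_days must be > 0")


def taxon_total_abundance(p, dna_yield):
    """N = P * dna_yield: whole-sample relative abundance scaled to
    ng DNA per g dry soil."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("taxon_total_abundance: P must be in [0, 1]")
    if not np.all(np.asarray(dna_yield, dtype=float) > 0):
        raise ValueError("taxon_total_abundance: dna_yield must be > 0")
    n = p * np.asarray(dna_yield, dtype=float)
    return float(n) if n.ndim == 0 else n


def net_growth_rate(n_t, n_0, t_days):
    """r_net = (N_t - N_0) / t; negative means population decline."""
    if not t_days > 0:
        raise ValueError("net_growth_rate: t_days must be > 0")
    r = (np.asarray(n_t, dtype=float) - np.asarray(n_0, dtype=float)) / t_days
    return float(r) if r.ndim == 0 else r


def gross_growth_rate(n_t, ape_percent, cfg: GrowthConfig):
    """Growth on labeled carbon: r_gross = N_t * min(phi, 1) / t.

    phi > 1 (measured enrichment exceeding the source pool) is capped at 1
    with a warning — all standing DNA is then new.
    """
    n_t = np.asarray(n_t, dtype=float)
    ape = np.asarray(ape_percent, dtype=float)
    if not np.all(np.isfinite(ape)):
        raise ValueError("gross_growth_rate: APE must be finite")
    phi = np.clip(ape, 0.0, None) / 100.0 / (cfg.a_source * cfg.u)
    if np.any(phi > 1.0):
        warnings.warn(
            "gross_growth_rate: new-DNA fraction > 1 capped (all DNA new); "
            "check a_source",
            stacklevel=2,
        )
        phi = np.minimum(phi, 1.0)
    r = n_t * phi / cfg.t_days
    return float(r) if r.ndim == 0 else r


def relative_abundance(
    fractions: pd.DataFrame, coverage: pd.DataFrame, sample_id: str
) -> pd.Series:
    """Whole-sample relative abundance P_i = sum_k y_ik / sum_i sum_k y_ik."""
    frac = fractions.loc[fractions["sample_id"] == sample_id]
    cov = coverage.loc[coverage["sample_id"] == sample_id]
    merged = cov.merge(
        frac[["sample_id", "fraction_id", "dna_conc_ng_ul"]],
        on=["sample_id", "fraction_id"],
    )
    merged["y"] = merged["relative_coverage"] * merged["dna_conc_ng_ul"]
    totals = merged.groupby("taxon_id")["y"].sum()
    grand = totals.sum()
    if grand <= 0:
        raise ValueError(f"relative_abundance: no abundance in sample {sample_id}")
    return totals / grand


def estimate_growth(
    enrichment: pd.DataFrame,
    design: pd.DataFrame,
    fractions: pd.DataFrame,
    coverage: pd.DataFrame,
    week: int,
    u: float = 1.0,
    a_source: float = 1.0,
) -> pd.DataFrame:
    """Per-taxon N_0, N_t, net and gross growth rates for one timepoint.

    N_0 comes from the week-0 bulk sample(s); N_t from the week's labeled
    (rhizosphere) sample(s); t = 7 * week days.  ``design`` must carry a
    ``dna_yield_ng_per_g`` column.  Taxa absent from the week-0 sample get
    N_0 = 0 (below detection initially).
    """
    if "dna_yield_ng_per_g" not in design.columns:
        raise ValueError("estimate_growth: design needs a dna_yield_ng_per_g column")
    if week <= 0:
        raise ValueError("estimate_growth: week must be > 0")
    cfg = GrowthConfig(t_days=DAYS_PER_WEEK * week, u=u, a_source=a_source)

    t0 = design.loc[(design["week"] == 0) & (design["role"] == "unlabeled")]
    if t0.empty:
        raise ValueError("estimate_growth: no week-0 unlabeled sample for N_0")
    tt = design.loc[(design["week"] == week) & (design["role"] == "labeled")]
    if tt.empty:
        raise ValueError(f"estimate_growth: no labeled sample at week {week}")

    def mean_abundance(samples: pd.DataFrame) -> pd.Series:
        per = []
        for _, row in samples.iterrows():
            p = relative_abundance(fractions, coverage, row["sample_id"])
            n = taxon_total_abundance(p.clip(upper=1.0).to_numpy(), row["dna_yield_ng_per_g"])
            per.append(pd.Series(n, index=p.index))
        return pd.concat(per, axis=1).mean(axis=1)

    n0 = mean_abundance(t0)
    nt = mean_abundance(tt)

    wk = enrichment.loc[enrichment["week"] == week].set_index("taxon_id")
    rows = []
    for taxon in wk.index:
        n_t = float(nt.get(taxon, 0.0))
        n_0 = float(n0.get(taxon, 0.0))
        ape = float(wk.at[taxon, "APE_percent"])
        rows.append(
            {
                "taxon_id": taxon,
                "taxon_class": wk.at[taxon, "taxon_class"],
                "week": week,
                "N_total_0": n_0,
                "N_total_t": n_t,
                "r_net": net_growth_rate(n_t, n_0, cfg.t_days),
                "r_gross": gross_growth_rate(n_t, ape, cfg),
                "APE_percent": ape,
            }
        )
    return pd.DataFrame(rows)
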