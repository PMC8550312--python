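"""End-to-end orchestration: simulate/load -> enrich -> threshold -> growth.

A run is fully described by a :class:`RunConfig`; the same config (including
the seed) always produces byte-identical outputs.  Every output TSV carries
a header comment with the package version, seed, and a hash of the config,
and a flat key-value run summary is written alongside.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .detect_threshold import ape_cutoff, davies_test, fit_segmented, restrict_window
from .growth_rates import estimate_growth
from .qsip_core import estimate_enrichment, rank_by_ape
from .synthetic_sip import GradientConfig, SimulatedTables, rhizosphere_preset, simulate_timepoints
from .tables_io import TableSet, aggregate_bin_coverage, read_tables, relative_coverage_table

log = logging.getLogger("gqsip")

__all__ = ["RunConfig", "run_pipeline", "config_hash"]

PRESETS = {"rhizosphere"}


@dataclass
class RunConfig:
    """Parameters of one pipeline run.

    Either ``preset`` names a simulation scenario, or the five table paths
    point at real inputs.  ``weeks=None`` selects every week that has a
    labeled sample.
    """

    preset: str | None = None
    fractions_path: str | None = None
    coverage_path: str | None = None
    binmap_path: str | None = None
    design_path: str | None = None
    libraries_path: str | None = None
    weeks: tuple[int, ...] | None = None
    rank_window: int = 90
    se_mult: float = 3.0
    u: float = 1.0
    a_source: float = 1.0
    bin_mode: str | None = None  # override the preset's granularity
    reads_per_library: int | None = None  # override the preset's noise model
    min_scaffold_bp: int = 1000
    seed: int = 0
    outdir: str = "qsip_out"

    def validate(self) -> None:
        if self.preset is not None:
            if self.preset not in PRESETS:
                raise ValueError(f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}")
        else:
            for name in ("fractions_path", "coverage_path", "binmap_path", "design_path", "libraries_path"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"RunConfig: {name} required when no preset is used")
                if not Path(path).exists():
                    raise FileNotFoundError(f"RunConfig: {name} = {path} does not exist")
        if self.rank_window < 1:
            raise ValueError("RunConfig: rank_window must be >= 1")
        if self.se_mult < 0:
            raise ValueError("RunConfig: se_mult must be >= 0")


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _load_inputs(cfg: RunConfig) -> tuple[TableSet, dict, pd.DataFrame | None]:
    """Return (tables, taxon_class mapping, truth-or-None)."""
    if cfg.preset == "rhizosphere":
        taxa, gcfg = rhizosphere_preset()
        overrides = {"seed": cfg.seed}
        if cfg.bin_mode is not None:
            overrides["bin_mode"] = cfg.bin_mode
        if cfg.reads_per_library is not None:
            overrides["reads_per_library"] = cfg.reads_per_library
        from dataclasses import replace

        gcfg = replace(gcfg, **overrides)
        sim = simulate_timepoints(taxa, gcfg, weeks=(0, 6, 9))
        tables = TableSet(
            fractions=sim.fractions,
            coverage=sim.coverage,
            binmap=sim.binmap,
            design=sim.design,
            libraries=sim.libraries,
        )
        classes = dict(zip(sim.truth["taxon_id"], sim.truth["taxon_class"]))
        return tables, classes, sim.truth
    tables = read_tables(
        cfg.fractions_path,
        cfg.coverage_path,
        cfg.binmap_path,
        cfg.design_path,
        cfg.libraries_path,
        min_scaffold_bp=cfg.min_scaffold_bp,
    )
    return tables, {}, None


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    header = (
        f"# gqsip {__version__} seed={cfg.seed} config={config_hash(cfg)}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns (and writes) a flat run summary."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log.info("stage: load/simulate inputs")
    tables, classes, truth = _load_inputs(cfg)

    bin_depth = aggregate_bin_coverage(tables.coverage, tables.binmap)
    rel_cov = relative_coverage_table(bin_depth, tables.libraries)

    weeks = cfg.weeks
    if weeks is None:
        weeks = tuple(
            sorted(tables.design.loc[tables.design["role"] == "labeled", "week"].unique())
        )
    if not weeks:
        raise ValueError("run_pipeline: no weeks with labeled samples")

    log.info("stage: enrichment (weeks %s)", list(weeks))
    enrich_parts, skip_parts = [], []
    for week in weeks:
        enr, skipped = estimate_enrichment(
            tables.design, tables.fractions, rel_cov, int(week), taxon_classes=classes
        )
        enrich_parts.append(enr)
        skip_parts.append(skipped)
    enrichment = pd.concat(enrich_parts, ignore_index=True)
    skipped = pd.concat(skip_parts, ignore_index=True)
    if enrichment.empty:
        raise ValueError("run_pipeline: no taxa detected in both treatments")

    # breakpoint: pooled over weeks (a single detection cutoff for the run)
    log.info("stage: detection threshold (rank window %d)", cfg.rank_window)
    pooled = rank_by_ape(enrichment.drop(columns=["rank"]))
    x, y = restrict_window(pooled, rank_hi=cfg.rank_window)
    fit = fit_segmented(x, y)
    fit.davies_p = davies_test(x, y)
    fit, pooled = ape_cutoff(pooled, fit, m=cfg.se_mult)
    enrichment = pooled  # pooled ranking + labeled flags

    threshold = pd.DataFrame(
        [
            {
                "weeks": ",".join(str(w) for w in weeks),
                "psi": fit.psi,
                "psi_se": fit.psi_se,
                "beta0": fit.beta0,
                "beta1": fit.beta1,
                "beta2": fit.beta2,
                "davies_p": fit.davies_p,
                "threshold_rank": fit.threshold_rank,
                "ape_cutoff": fit.ape_cutoff,
                "m": fit.m,
                "window_lo": fit.window[0],
                "window_hi": fit.window[1],
            }
        ]
    )

    growth_parts = []
    has_week0 = ((tables.design["week"] == 0) & (tables.design["role"] == "unlabeled")).any()
    if has_week0 and "dna_yield_ng_per_g" in tables.design.columns:
        log.info("stage: growth rates")
        for week in weeks:
            growth_parts.append(
                estimate_growth(
                    enrichment,
                    tables.design,
                    tables.fractions,
                    rel_cov,
                    int(week),
                    u=cfg.u,
                    a_source=cfg.a_source,
                )
            )
    else:
        log.warning("growth stage skipped: no week-0 sample or dna_yield column")
    growth = (
        pd.concat(growth_parts, ignore_index=True) if growth_parts else pd.DataFrame()
    )

    _write_tsv(enrichment, outdir / "enrichment.tsv", cfg)
    _write_tsv(skipped, outdir / "skipped.tsv", cfg)
    _write_tsv(threshold, outdir / "threshold.tsv", cfg)
    if not growth.empty:
        _write_tsv(growth, outdir / "growth.tsv", cfg)

    summary: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
        "weeks": ",".join(str(w) for w in weeks),
        "n_taxa": int(enrichment["taxon_id"].nunique()),
        "n_enrichment_rows": int(len(enrichment)),
        "n_skipped": int(len(skipped)),
        "psi": float(fit.psi),
        "psi_se": float(fit.psi_se),
        "davies_p": float(fit.davies_p),
        "threshold_rank": float(fit.threshold_rank),
        "ape_cutoff": float(fit.ape_cutoff),
        "n_labeled": int(enrichment["labeled"].sum()),
    }
    for cls, grp in enrichment.groupby("taxon_class"):
        summary[f"labeled_{cls}"] = int(grp["labeled"].sum())
        summary[f"n_{cls}"] = int(len(grp))
    if not growth.empty:
        for cls, grp in growth.groupby("taxon_class"):
            summary[f"mean_r_gross_{cls}"] = float(grp["r_gross"].mean())
            summary[f"mean_r_net_{cls}"] = float(grp["r_net"].mean())

    with open(outdir / "run_summary.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        for key, value in summary.items():
            fh.write(f"{key}\t{value}\n")
    log.info("run complete: %s", outdir)
    return summary
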