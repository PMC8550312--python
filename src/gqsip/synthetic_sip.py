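"""Forward simulation of a gradient-fractionation SIP experiment.

Taxa with known GC content, isotope enrichment, DNA mass, and growth rate
are pushed through CsCl gradient fractionation: each taxon's DNA spreads
as a Gaussian around its model-predicted buoyant density, is discretized
into equal-width fractions, optionally combined into light/middle/heavy
bins, and optionally resampled multinomially to emulate sequencing depth
noise.  The emitted tables use exactly the TSV schemas the pipeline
consumes, plus a ground-truth table, so every downstream stage can be
tested against known answers at desk scale.

Masses are interpreted as ng DNA per g dry soil; the community is assumed
to exhaust the extracted DNA, so a sample's DNA yield is the sum of its
taxon masses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .density_model import DEFAULT_CONSTANTS, IsotopeModelConstants, density_from_afe
from .tables_io import BinBoundaries, assign_density_bins, derive_bin_boundaries

log = logging.getLogger("gqsip")

__all__ = [
    "SyntheticTaxon",
    "GradientConfig",
    "SimulatedTables",
    "simulate_gradient",
    "simulate_timepoints",
    "rhizosphere_preset",
]

SCAFFOLD_LENGTHS = {"bacterial_bin": (60_000, 30_000, 10_000), "phage": (40_000,), "eukaryote_scaffold": (12_000,)}
NOISELESS_TOTAL_READS = 1_000_000  # per-library denominator when no read noise
DAYS_PER_WEEK = 7.0


@dataclass(frozen=True)
class SyntheticTaxon:
    """Ground truth for one simulated taxon."""

    taxon_id: str
    g_true: float  # GC fraction
    ape_true: float  # atom percent excess of the taxon's DNA-source pool
    mass_ng: float  # DNA mass (ng per g dry soil) at time zero
    taxon_class: str = "bacterial_bin"
    r_true: float = 0.0  # linear growth rate, ng DNA / g soil / day

    def __post_init__(self):
        if not 0.0 <= self.g_true <= 1.0:
            raise ValueError(f"{self.taxon_id}: GC fraction must be in [0, 1]")
        if not 0.0 <= self.ape_true <= 98.9:
            raise ValueError(f"{self.taxon_id}: APE_true must be in [0, 98.9]")
        if not self.mass_ng > 0:
            raise ValueError(f"{self.taxon_id}: mass_ng must be > 0")


@dataclass(frozen=True)
class GradientConfig:
    """Gradient geometry and noise model.

    Defaults mirror the study's setup: ~32 fractions spanning the published
    light-to-heavy density range, ~144 ul per fraction.  sigma_density is
    the Gaussian spread of one taxon's DNA about its buoyant density
    (diffusion + fragment-length effects, not modeled mechanistically);
    0.005 g/ml lets a 32-fraction gradient resolve labeled from unlabeled
    at APE around 20.  reads_per_library = 0 disables sequencing noise.
    """

    density_min: float = 1.692
    density_max: float = 1.765
    n_fractions: int = 32
    sigma_density: float = 0.005
    reads_per_library: int = 0
    seed: int = 0
    bin_mode: str = "per_fraction"  # or "three_bins"
    volume_ul: float = 144.0
    boundaries: BinBoundaries | None = None  # three_bins: derived if None
    constants: IsotopeModelConstants = DEFAULT_CONSTANTS

    def __post_init__(self):
        if not self.density_min < self.density_max:
            raise ValueError("GradientConfig: density_min must be < density_max")
        if self.n_fractions < 3:
            raise ValueError("GradientConfig: n_fractions must be >= 3")
        if not self.sigma_density > 0:
            raise ValueError("GradientConfig: sigma_density must be > 0")
        if self.bin_mode not in ("per_fraction", "three_bins"):
            raise ValueError("GradientConfig: bin_mode must be per_fraction|three_bins")

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.density_min, self.density_max, self.n_fractions + 1)


@dataclass
class SimulatedTables:
    """The pipeline's input tables plus ground truth, as DataFrames."""

    fractions: pd.DataFrame
    coverage: pd.DataFrame
    binmap: pd.DataFrame
    design: pd.DataFrame
    libraries: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        names = ["fractions", "coverage", "binmap", "design", "libraries", "truth"]
        for name in names:
            getattr(self, name).to_csv(outdir / f"{name}.tsv", sep="\t", index=False)


def _taxon_scaffolds(taxa: list[SyntheticTaxon]) -> pd.DataFrame:
    rows = []
    for t in taxa:
        lengths = SCAFFOLD_LENGTHS.get(t.taxon_class, (50_000,))
        for i, ln in enumerate(lengths):
            rows.append(
                {"scaffold_id": f"{t.taxon_id}|scf{i + 1}", "taxon_id": t.taxon_id, "length_bp": ln}
            )
    return pd.DataFrame(rows)


def _gaussian_mass(centers, masses, sigma, edges, taxon_ids):
    """Mass of each component landing in each fraction; warns on tail loss."""
    centers = np.asarray(centers, dtype=float)[:, None]
    cdf = norm.cdf((edges[None, :] - centers) / sigma)
    frac_share = np.diff(cdf, axis=1)  # (components, fractions)
    inside = frac_share.sum(axis=1)
    for tid, share in zip(taxon_ids, inside):
        if share < 0.99:
            warnings.warn(
                f"simulate_gradient: {100 * (1 - share):.1f}% of taxon {tid}'s DNA "
                "falls outside the gradient density range (tail truncation)",
                stacklevel=3,
            )
    return frac_share * np.asarray(masses, dtype=float)[:, None]


def _collapse_components(mass: np.ndarray, owner: np.ndarray, n_taxa: int) -> np.ndarray:
    """Sum component rows (e.g. old + new DNA) belonging to the same taxon."""
    out = np.zeros((n_taxa, mass.shape[1]))
    np.add.at(out, owner, mass)
    return out


def _sample_tables(
    sample_id: str,
    mass_tk: np.ndarray,
    taxa: list[SyntheticTaxon],
    scaffolds: pd.DataFrame,
    cfg: GradientConfig,
    rng: np.random.Generator,
):
    """Fraction, coverage, and library rows for one gradient (one sample)."""
    edges = cfg.edges
    mids = 0.5 * (edges[:-1] + edges[1:])
    frac_ids = [f"{sample_id}.F{k + 1:02d}" for k in range(cfg.n_fractions)]
    densities = mids
    volumes = np.full(cfg.n_fractions, cfg.volume_ul)

    if cfg.bin_mode == "three_bins":
        mass_tk, densities, frac_ids, volumes = _combine_to_bins(
            sample_id, mass_tk, mids, cfg
        )

    frac_mass = mass_tk.sum(axis=0)
    fractions = pd.DataFrame(
        {
            "sample_id": sample_id,
            "fraction_id": frac_ids,
            "density_g_ml": densities,
            "dna_conc_ng_ul": frac_mass / volumes,
            "volume_ul": volumes,
        }
    )

    taxon_index = {t.taxon_id: i for i, t in enumerate(taxa)}
    scf_owner = scaffolds["taxon_id"].map(taxon_index).to_numpy()

    cov_parts, lib_rows = [], []
    for k, fid in enumerate(frac_ids):
        lib_id = f"lib.{fid}"
        total = frac_mass[k]
        share = mass_tk[:, k] / total if total > 0 else np.zeros(len(taxa))
        if cfg.reads_per_library > 0 and total > 0:
            counts = rng.multinomial(cfg.reads_per_library, share)
            total_reads = int(counts.sum())
            depth_scale = counts.astype(float)
        else:
            total_reads = NOISELESS_TOTAL_READS
            depth_scale = share
        lib_rows.append(
            {
                "library_id": lib_id,
                "sample_id": sample_id,
                "fraction_or_bin_id": fid,
                "total_reads": max(total_reads, 1),
            }
        )
        cov_parts.append(
            pd.DataFrame(
                {
                    "library_id": lib_id,
                    "scaffold_id": scaffolds["scaffold_id"].to_numpy(),
                    "length_bp": scaffolds["length_bp"].to_numpy(),
                    # every scaffold of a bin sees the bin's depth
                    "mean_depth": depth_scale[scf_owner],
                }
            )
        )
    return fractions, pd.concat(cov_parts, ignore_index=True), pd.DataFrame(lib_rows)


def _combine_to_bins(sample_id, mass_tk, mids, cfg: GradientConfig):
    """Aggregate per-fraction masses into light/middle/heavy pseudo-fractions."""
    boundaries = cfg.boundaries
    if boundaries is None:
        raise ValueError("three_bins mode needs boundaries (derive or supply them)")
    frac_df = pd.DataFrame({"density_g_ml": mids})
    frac_df = assign_density_bins(frac_df, boundaries)
    bins, densities, vols, cols = [], [], [], []
    for dbin in ("light", "middle", "heavy"):
        member = (frac_df["density_bin"] == dbin).to_numpy()
        if not member.any():
            log.warning("simulate: %s bin empty in %s", dbin, sample_id)
            continue
        bin_mass = mass_tk[:, member].sum(axis=1)
        total = bin_mass.sum()
        if total <= 0:
            log.warning("simulate: %s bin has zero DNA in %s", dbin, sample_id)
            continue
        w = (mass_tk[:, member].sum(axis=0) * mids[member]).sum() / total
        bins.append(dbin)
        densities.append(w)
        vols.append(cfg.volume_ul * member.sum())
        cols.append(bin_mass)
    mass_bins = np.column_stack(cols)
    frac_ids = [f"{sample_id}.{b}" for b in bins]
    return mass_bins, np.asarray(densities), frac_ids, np.asarray(vols)


def _resolve_boundaries(taxa, cfg: GradientConfig, week: int = 6) -> BinBoundaries:
    """Derive three-bin boundaries from the noiseless per-fraction profiles,
    using the same rule applied to real gradients (bulk concentration
    reaching zero; labeled/unlabeled curve crossing)."""
    per_frac = replace(cfg, bin_mode="per_fraction", reads_per_library=0)
    sim = simulate_gradient(taxa, per_frac, week=week)
    lab = sim.fractions.loc[sim.fractions["sample_id"].str.startswith("rhizo")]
    unl = sim.fractions.loc[sim.fractions["sample_id"].str.startswith("bulk")]
    return derive_bin_boundaries(lab, unl)


def simulate_gradient(
    taxa: list[SyntheticTaxon], cfg: GradientConfig, week: int = 6
) -> SimulatedTables:
    """Simulate one labeled (rhizosphere) / unlabeled (bulk) sample pair.

    Each taxon's DNA centers on density_from_afe(G_true, APE_true) in the
    labeled sample and on its unlabeled buoyant density in the bulk sample.
    Deterministic under a fixed cfg.seed.
    """
    if not taxa:
        raise ValueError("simulate_gradient: taxa must be nonempty")
    cfg = _with_boundaries(taxa, cfg, week)
    rng = np.random.default_rng(cfg.seed)
    scaffolds = _taxon_scaffolds(taxa)
    ids = [t.taxon_id for t in taxa]
    masses = [t.mass_ng for t in taxa]

    centers_lab = [
        density_from_afe(t.g_true, t.ape_true / 100.0, constants=cfg.constants)
        for t in taxa
    ]
    centers_unl = [
        density_from_afe(t.g_true, 0.0, constants=cfg.constants) for t in taxa
    ]

    parts = []
    for sample_id, habitat, role, centers in [
        (f"bulk_w{week}", "bulk", "unlabeled", centers_unl),
        (f"rhizo_w{week}", "rhizosphere", "labeled", centers_lab),
    ]:
        mass_tk = _gaussian_mass(centers, masses, cfg.sigma_density, cfg.edges, ids)
        parts.append((sample_id, habitat, role, _sample_tables(sample_id, mass_tk, taxa, scaffolds, cfg, rng)))

    fractions = pd.concat([p[3][0] for p in parts], ignore_index=True)
    coverage = pd.concat([p[3][1] for p in parts], ignore_index=True)
    libraries = pd.concat([p[3][2] for p in parts], ignore_index=True)
    design = pd.DataFrame(
        [
            {
                "sample_id": sid,
                "habitat": hab,
                "week": week,
                "role": role,
                "replicate": 1,
                "dna_yield_ng_per_g": float(np.sum(masses)),
            }
            for sid, hab, role, _ in parts
        ]
    )
    truth = pd.DataFrame(
        {
            "taxon_id": ids,
            "taxon_class": [t.taxon_class for t in taxa],
            "G_true": [t.g_true for t in taxa],
            "APE_true": [t.ape_true for t in taxa],
            "mass_ng": masses,
            "r_true": [t.r_true for t in taxa],
        }
    )
    binmap = scaffolds[["scaffold_id", "taxon_id"]]
    return SimulatedTables(fractions, coverage, binmap, design, libraries, truth)


def _with_boundaries(taxa, cfg: GradientConfig, week: int) -> GradientConfig:
    if cfg.bin_mode == "three_bins" and cfg.boundaries is None:
        return replace(cfg, boundaries=_resolve_boundaries(taxa, cfg, week))
    return cfg


def simulate_timepoints(
    taxa: list[SyntheticTaxon],
    cfg: GradientConfig,
    weeks=(0, 6, 9),
) -> SimulatedTables:
    """Simulate a multi-week time course under linear growth.

    Each taxon's DNA mass evolves as mass(t) = mass(0) + r_true * t; the
    newly synthesized DNA carries the taxon's APE_true while the original
    DNA stays unlabeled, so the measured (mass-weighted) enrichment grows
    with the new-DNA fraction — exactly the signal the gross-growth model
    inverts.  Bulk samples see the same mass trajectory but fully
    unlabeled DNA.  Week 0 must be included (it anchors N_0).
    """
    if 0 not in weeks:
        raise ValueError("simulate_timepoints: weeks must include 0")
    cfg = _with_boundaries(taxa, cfg, week=max(weeks))
    rng = np.random.default_rng(cfg.seed)
    scaffolds = _taxon_scaffolds(taxa)
    ids = [t.taxon_id for t in taxa]
    n = len(taxa)
    centers_unl = np.array(
        [density_from_afe(t.g_true, 0.0, constants=cfg.constants) for t in taxa]
    )
    centers_lab = np.array(
        [
            density_from_afe(t.g_true, t.ape_true / 100.0, constants=cfg.constants)
            for t in taxa
        ]
    )

    frac_parts, cov_parts, lib_parts, design_rows = [], [], [], []
    for week in sorted(set(weeks)):
        t_days = DAYS_PER_WEEK * week
        mass0 = np.array([t.mass_ng for t in taxa])
        new = np.array([t.r_true for t in taxa]) * t_days
        if np.any(mass0 + new <= 0):
            bad = [ids[i] for i in np.nonzero(mass0 + new <= 0)[0]]
            raise ValueError(f"simulate_timepoints: nonpositive mass for {bad}")
        total = mass0 + new

        samples = [(f"bulk_w{week}", "bulk", "unlabeled")]
        if week > 0:
            samples.append((f"rhizo_w{week}", "rhizosphere", "labeled"))
        for sample_id, habitat, role in samples:
            if role == "labeled":
                # two components per taxon: original (unlabeled) + new DNA
                comp_centers = np.concatenate([centers_unl, centers_lab])
                comp_mass = np.concatenate([mass0, new])
                owner = np.concatenate([np.arange(n), np.arange(n)])
                keep = comp_mass > 0
                mass_ck = _gaussian_mass(
                    comp_centers[keep],
                    comp_mass[keep],
                    cfg.sigma_density,
                    cfg.edges,
                    [ids[i] for i in owner[keep]],
                )
                mass_tk = _collapse_components(mass_ck, owner[keep], n)
            else:
                mass_tk = _gaussian_mass(
                    centers_unl, total, cfg.sigma_density, cfg.edges, ids
                )
            f, c, l = _sample_tables(sample_id, mass_tk, taxa, scaffolds, cfg, rng)
            frac_parts.append(f)
            cov_parts.append(c)
            lib_parts.append(l)
            design_rows.append(
                {
                    "sample_id": sample_id,
                    "habitat": habitat,
                    "week": week,
                    "role": role,
                    "replicate": 1,
                    "dna_yield_ng_per_g": float(total.sum()),
                }
            )

    truth = pd.DataFrame(
        {
            "taxon_id": ids,
            "taxon_class": [t.taxon_class for t in taxa],
            "G_true": [t.g_true for t in taxa],
            "APE_true": [t.ape_true for t in taxa],
            "mass_ng": [t.mass_ng for t in taxa],
            "r_true": [t.r_true for t in taxa],
        }
    )
    return SimulatedTables(
        pd.concat(frac_parts, ignore_index=True),
        pd.concat(cov_parts, ignore_index=True),
        scaffolds[["scaffold_id", "taxon_id"]],
        pd.DataFrame(design_rows),
        pd.concat(lib_parts, ignore_index=True),
        truth,
    )


def rhizosphere_preset() -> tuple[list[SyntheticTaxon], GradientConfig]:
    """A rhizosphere-like community: 55 bacterial bins, 10 phage genomes,
    27 eukaryote 18S scaffolds.

    Constructed so the rank-APE curve has a flat low-rank segment (34
    effectively unlabeled taxa, APE < 2) followed by a rise — the shape the
    breakpoint stage needs — with ~78% of bacteria enriched above a 2.5-APE
    hinge, phage the most labeled entities, and eukaryotes barely enriched.
    Growth rates scale with enrichment (about 2%/day of standing DNA for a
    fully labeled taxon), so labeled-carbon growth is bacterial/phage
    dominated.  Fully deterministic.
    """
    taxa: list[SyntheticTaxon] = []

    def growth(mass, ape):
        return 0.02 * mass * ape / 100.0

    # 55 bacteria: 12 unlabeled, 43 labeled (78%)
    for i in range(55):
        g = 0.50 + 0.22 * i / 54.0
        mass = 50.0 + 2.0 * i
        if i < 12:
            ape = 0.10 + 0.12 * i
        else:
            ape = 2.6 + 1.45 * (i - 12)
        taxa.append(
            SyntheticTaxon(
                taxon_id=f"bact_{i + 1:02d}",
                taxon_class="bacterial_bin",
                g_true=g,
                ape_true=ape,
                mass_ng=mass,
                r_true=growth(mass, ape),
            )
        )
    # 10 phage, all strongly labeled; the most labeled entities are phage
    for i in range(10):
        ape = 60.0 + 3.1 * i
        mass = 5.0 + float(i)
        taxa.append(
            SyntheticTaxon(
                taxon_id=f"phage_{i + 1:02d}",
                taxon_class="phage",
                g_true=0.45 + 0.02 * i,
                ape_true=ape,
                mass_ng=mass,
                r_true=growth(mass, ape),
            )
        )
    # 27 eukaryote scaffolds: 22 unlabeled, 5 weakly labeled
    for i in range(27):
        g = 0.40 + 0.005 * i
        mass = 20.0 + float(i)
        if i < 22:
            ape = 0.05 + 0.05 * i
        else:
            ape = 2.8 + 0.8 * (i - 22)
        taxa.append(
            SyntheticTaxon(
                taxon_id=f"euk_{i + 1:02d}",
                taxon_class="eukaryote_scaffold",
                g_true=g,
                ape_true=ape,
                mass_ng=mass,
                r_true=growth(mass, ape),
            )
        )

    cfg = GradientConfig(
        density_min=1.66,
        density_max=1.80,
        n_fractions=32,
        sigma_density=0.005,
        reads_per_library=0,
        seed=0,
        bin_mode="per_fraction",
    )
    return taxa, cfg
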