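# Methods

This note documents the models, parameter choices, and numerical decisions
behind `gqsip`, and what its synthetic tests do and do not establish.

## Isotope substitution model (`density_model`)

Buoyant density of unlabeled DNA is linear in GC content,
ρ = 1.646057 + 0.083506·G g/ml, and the mean molecular weight of a
nucleotide is M_light = 307.691 + 0.496·G g/mol. Full ¹³C substitution adds
ΔM_max = 9.974564 − 0.4987282·G g/mol (G:C pairs carry marginally fewer
carbon atoms per unit mass). A labeled taxon's molecular weight follows
from its relative density shift, M_lab = M_light·(W_lab/W_light), and the
atom fraction excess is

A = (M_lab − M_light)/ΔM_max · (1 − 0.01111233),

the last factor subtracting natural ¹³C abundance. All constants live in
one frozen `IsotopeModelConstants` object so an ¹⁸O or ¹⁵N
parameterization, or a variant set of ¹³C constants, can be swapped in
without touching callers. `density_from_afe` is the exact algebraic
inverse and drives the simulator; the round trip is machine-exact
(|Δ| < 10⁻¹⁰ over the full G × A grid).

Out-of-range GC estimates (possible when W_light is noisy) are flagged,
never clamped, so downstream QC can drop the taxon explicitly. Negative
APE (W_lab < W_light) is reported as-is: it is informative scatter that the
detection-threshold stage needs.

## Abundance and weighted density (`qsip_core`)

y_ijk = p_ijk·f_jk and W = Σxy/Σy, computed per (taxon, sample);
replicate means of W are taken per treatment before the APE conversion
(the motivating study had n = 1 per treatment; replicated designs work
unchanged). Two normalization layers:

- `tables_io.normalize_coverage` uses depth per million mapped reads —
  conventional and auditable; any per-library constant is equivalent
  because
- `qsip_core` renormalizes coverages to within-library proportions before
  forming y. The composition of a library is the signal; its absolute
  depth scale is a sequencing artifact. This makes every W and APE exactly
  invariant to per-library rescaling, at the cost of assuming that the
  profiled taxa represent a density-independent share of each library —
  the same assumption 16S-proportion-based qSIP makes.

Taxa with zero abundance in either treatment are skipped with a reason,
never assigned APE 0: absence of evidence is not zero enrichment. Ranks
are an ascending stable sort with lexicographic taxon-id tie-break, so
output is deterministic. Bacterial bins, phage genomes, and 18S-bearing
eukaryote scaffolds (handled as one-scaffold bins) flow through
identically.

## Density bins (`tables_io`)

Genome-bin coverage is the scaffold-length-weighted mean depth; scaffolds
under 1000 bp are excluded (configurable). Light/middle/heavy boundaries
can be fixed (the published 1.737 / 1.746 g/ml pair, upper bounds
inclusive) or derived from a labeled-vs-unlabeled concentration-profile
comparison: the heavy bin starts where the unlabeled (bulk) concentration
reaches zero — operationally ≤ ε = 0.05 ng/µl, linearly interpolated,
because fluorometry rarely returns exact zeros — and the light bin ends at
the highest crossing of the two curves below that point. A pooled bin
becomes a pseudo-fraction whose density is the DNA-mass-weighted mean of
its members (the expected buoyant density of the DNA actually sequenced)
and whose concentration conserves total DNA mass exactly.

## Breakpoint threshold (`detect_threshold`)

The segmented model y = β₀ + β₁x + β₂(x−ψ)₊ is fitted by Muggeo-style
iterative linearization (working covariate V = −1{x>ψ}, update
ψ ← ψ + γ̂/β̂₂, damped when |γ̂| fails to contract, tolerance 10⁻⁸, 50
iterations). Because the linearization can settle in a local RSS minimum
on noisy data, every fit is cross-checked against an exhaustive 0.1-rank
grid search (vectorized via suffix-sum normal equations) with an iterative
polish from the best grid point; the lower-RSS solution wins, and grid
ties take the smallest ψ (the most conservative threshold).
SE(ψ) = SE(γ̂)/|β̂₂| at the solution — the standard error of the cited
segmented-regression method. |β̂₂| < 10⁻¹⁰ raises a no-breakpoint flag;
fewer than 3 points on either side of ψ̂ warns.

The Davies test evaluates the Wald statistic for β₂ at K = 10 equally
spaced candidates (2-rank interior margin) and bounds the p-value of the
maximum M by Φ(−M) + V·exp(−M²/2)/√(8π), V the total variation of the
statistic sequence, capped at 1. It is one-sided (a rising slope change)
and conservative; measured type-I error at α = 0.05 on i.i.d. noise is
≈ 0.04.

The fit window is the lowest 90 ranks by default: including highly
enriched ranks, where the rank–APE slope declines again, skews the
breakpoint toward zero APE. The labeling cutoff is the linear
interpolation of the rank-sorted APE sequence at ψ + m·SE (m = 3 default,
the upper 99.7% confidence limit); taxa strictly above it are flagged
labeled. When several weeks are analyzed in one run the breakpoint is
fitted on the pooled ranking (one cutoff per run), matching a design where
a single detection threshold is quoted across timepoints.

Calibration, measured by Monte Carlo (hinge at rank 70, slope change 0.5,
σ = 2 noise, ranks 1–90): ψ̂ is unbiased with SD ≈ 2.5 — that scatter is
intrinsic (the exhaustive-grid oracle shows the same spread), so no
estimator recovers ψ to ±2 ranks in ≥ 90% of such replicates; and the
Muggeo SE understates the MC SD by ≈ 20% in this kinked design, giving
≈ 97–98% (not ≥ 99%) coverage for ψ̂ ± 3·SE. The Davies test detects the
slope change in essentially 100% of these replicates. The corresponding
acceptance assertions are kept at their stated levels and fail honestly.

## Growth rates (`growth_rates`)

N = P·(DNA yield), with P the taxon's share of the sample's summed y
(fraction-summed path) unless supplied directly. r_net = (N_t − N_0)/t
with t = 7·week days and N_0 from the week-0 bulk sample (taxa absent at
week 0 get N_0 = 0). The gross rate on labeled carbon assumes new DNA is
built from a pool at atom fraction excess A_source, a fraction U of which
is labeled substrate: φ = (APE/100)/(A_source·U) is the new-DNA fraction,
r_gross = N_t·min(φ,1)/t. Negative APE clips to r_gross = 0 (measurement
noise, not negative growth); negative r_net is reported as-is (decline).
φ > 1 caps with a warning. A_source defaults to 1.0 and is exposed, never
guessed — results scale by 1/A_source (a ¹³CO₂ chamber at 90 atom% and
shoots near 94 atom% are plausible alternatives). r_gross ≤ N_t/t always.

## Simulator (`synthetic_sip`)

Each taxon's DNA spreads as a Gaussian (σ = 0.005 g/ml default) around its
model-predicted buoyant density and is integrated over equal-width
fraction intervals; fraction concentration is summed mass over volume
(144 µl default); relative coverage is the taxon's mass share of the
fraction, optionally resampled multinomially at a configurable expected
read depth. σ = 0.005 lets a 32-fraction gradient resolve labeled from
unlabeled at APE ≈ 20; diffusion and fragment-length effects are not
modeled mechanistically, and there is no GC extraction bias or mapping
error — so a green round-trip test establishes correctness of the
estimation algebra and its noise robustness, not robustness to those
unmodeled artifacts. Real gradients are also nonlinear in density; this is
immaterial because the pipeline consumes (density, concentration) pairs.
More than 1% of a taxon's mass falling outside the gradient warns (tail
truncation); mass is otherwise conserved to < 10⁻⁹ relative.

Time courses evolve masses linearly, mass(t) = mass(0) + r·t, with the
newly synthesized DNA carrying the taxon's source-pool enrichment and the
original DNA staying unlabeled — exactly the mixture the gross-growth
formula inverts, so recovery tests are exact up to discretization. Bulk
samples follow the same mass trajectory fully unlabeled.

The `rhizosphere` preset (55 bacterial bins / 10 phage / 27 eukaryote
scaffolds — the motivating study's community shape) constructs a rank–APE
curve with a flat ~34-taxon segment and a rise, 78% of bacteria above a
2.5-APE hinge, phage the most labeled entities, eukaryotes barely
enriched, and growth rates ≈ 2%/day of standing DNA scaled by enrichment.
Its gradient spans 1.66–1.80 g/ml so that all taxa (GC 0.40–0.72, APE up
to ~88) stay inside the gradient; the published bin ranges would truncate
the low-GC tail of a synthetic community.

## Three-bin coarsening: known limitation

With coverage only at light/middle/heavy resolution, a taxon's W is a
weighted mean of three sample-specific pseudo-densities. Two artifacts
follow: taxa lying entirely within one bin are quantized, and the pooled
bin density shifts between treatments as labeled community mass moves
across boundaries, injecting GC-correlated spurious APE into unlabeled
taxa. On the rhizosphere preset the true enrichment rank order survives
(Spearman ρ ≈ 0.98), but on a community with GC ~ U(0.30, 0.75) and
enrichment independent of GC, ρ ≈ 0.90 and no boundary placement exceeds
≈ 0.92. Three-bin designs trade rank fidelity for sequencing cost;
per-fraction sequencing removes the artifact entirely (APE recovered to
< 10⁻⁴ points noiselessly).

## Determinism and provenance

All randomness flows from explicit integer seeds (`numpy.random.
default_rng`); identical configs produce byte-identical outputs. Every
output TSV carries a header comment with the package version, seed, and a
SHA-256 config hash; the run summary is a flat key-value TSV.
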