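# Methods

`syntronet` re-implements, as a tested library, the statistical pipeline by
which syntrophic partnerships between anaerobic methanotrophic archaea (ANME)
and seep-associated sulfate-reducing bacteria (SRB) are inferred from 16S
amplicon surveys and validated with sorted-consortium statistics, single-cell
stable-isotope imaging, and a reaction-diffusion model of ammonium supply.
Every stage can be exercised end-to-end on synthetic data with known ground
truth; nothing requires downloading the original sequencing runs or images.

## Compositional correlation inference (SparCC)

Amplicon counts are compositional: per-library totals are arbitrary, so only
relative abundances are observed and naive correlations between OTU columns
are confounded by the closure constraint. The SparCC estimator works from
log-ratio variances, which are closure-invariant:

    t_ij = Var_samples[ log(f_i / f_j) ]

where f are component fractions. Under a sparsity assumption (most OTU pairs
uncorrelated in the latent "basis" abundances), the basis log-variances
w_i = ω_i² satisfy the linear system Σ_{j∈N(i)} t_ij = |N(i)| w_i + Σ_{j∈N(i)} w_j,
whose full-pair form has matrix (D−2)I + J. Correlations follow as

    ρ_ij = (w_i + w_j − t_ij) / (2 ω_i ω_j),  clamped to [−1, 1].

Pairs that violate sparsity are handled by iterated exclusion: the single pair
with the largest |ρ| above a threshold (default 0.1) is removed from the row
sums, the system re-solved, up to 10 times. Fractions come from one posterior
Dirichlet(counts + 1) draw per inner iteration; 20 inner iterations are
aggregated by the element-wise median. These defaults follow the reference
implementation of the estimator; the survey this package models does not print
them. Negative basis-variance solutions (a known pathology at small D) are
clamped to 1e−12 and the affected pairs reported as undefined (NaN) rather
than silently propagated.

Numerical error note: the basis solve is verified against the closed-form
inverse ((D−2)I + J)⁻¹ = (1/(D−2))(I − J/(2D−2)) to 1e−10.

## Permutation significance (pseudo-p)

Significance follows the survey's criterion: a pair is significant at
pseudo-p < 0.01 with B = 100 null datasets exactly when its observed
coefficient exceeds that pair's coefficient in every null dataset. We use the
add-one permutation p-value p = (1 + #{b : ρ_b ≥ ρ_obs}) / (B + 1), which
reproduces that criterion (1/101 < 0.01) and never returns p = 0. Null
datasets permute each OTU's counts independently across samples — all pairwise
dependence is destroyed while every marginal count distribution is preserved.
The tail is one-sided positive by default (co-occurrence, not exclusion, is
the partnership signal); a two-sided |ρ| option exists. Sample resampling with
replacement is available behind a flag as an alternative null.

Calibration, measured by the suite: on independent synthetic tables the
fraction of pairs reaching p < 0.01 stays near the nominal 1% (≤ 3% asserted),
and the pseudo-p distribution is not anti-conservative at the 5% level.

## Network, cohesive blocks, partnership counts

Significant positive edges form an undirected graph weighted by ρ. At survey
scale the graph is thinned to the 99th percentile of coefficients; the filter
keeps the ⌈(1−q)·N⌉ strongest edges plus any edges tied with the weakest kept
weight, a count-based rule that is exactly testable (the percentile phrasing
does not fix an interpolation scheme). Cohesive blocks follow the Moody–White
structural-cohesion recursion: per component, compute vertex connectivity k,
remove one minimum vertex cut, recurse on each remaining component together
with the cut, and emit a block whenever a subgraph's connectivity exceeds its
parent block's. Emitted blocks contained in another block of equal or higher
cohesion are pruned and the hierarchy is rebuilt by node-set containment,
which makes the output independent of which minimum cut was found — verified
by exact agreement with a brute-force oracle that explores every minimum cut
on hundreds of random graphs. Partnerships are then summarized by counting,
per (ANME subtype × SRB clade) cell, the edges whose endpoints span the two
clade groups and lie inside at least one nested (non-root) block; each edge
counts once. Root blocks are the connected components themselves; both views
(roots and nested blocks) are exported because a component that is already
cohesive carries no nesting.

The force-directed layout is a seeded stress minimisation with target
inter-node distances equal to weighted shortest-path lengths under per-edge
length 1/weight, so stronger correlations draw nodes closer. It is
visualization-only; the standard library layouts rescale coordinates to a
unit box, which would destroy the weight→distance relationship the figure
convention requires, hence the small in-package implementation.

## Sorted-consortium specificity

Flow-sorted single consortia give one (ANME clade, SRB clade) observation per
sort. The chi-squared test of independence uses the plain Pearson statistic
Σ(O−E)²/E with E = (row total × column total)/n and df = (r−1)(c−1) — no
continuity correction, matching the reported convention (a Yates option exists
for 2×2). Categories with zero marginal are dropped before testing, so df
reflects the reduced table. Expected counts below 5 raise a warning, not an
exact-test substitution. Partner fractions are conditional distributions given
a focal clade, reported as counts and percentages (e.g. 8/9 → 88.9%).
`specificity_power` wraps generator + test into a calibration harness: with
uniform conditionals the rejection rate matches the nominal level (checked at
α = 0.05 within ±0.01 using 200-sort tables, where the χ² approximation is
accurate); with identity conditionals power at n = 30 sorts exceeds 0.99.

## Isotope imaging and colocalization

The ¹⁵N atom fraction of a region of interest is the ratio of summed counts
f = Σc15 / (Σc15 + Σc14) (ratio-of-sums), the Poisson-optimal weighting; a
mean-of-ratios alternative is provided behind a flag. Atom percent is 100·f;
natural abundance is 0.36%. Cells are classified interior/exterior by the
Euclidean distance from the ROI centroid to the nearest pixel outside the
consortium mask, with a 10 µm default threshold (the scale at which interior
enrichment gradients were described). Group summaries report both the standard
deviation across ROIs and the standard error, since the "±" convention of the
figures being emulated is not fixed. Dead-time, quasi-simultaneous-arrival and
drift corrections are assumed applied upstream. Colocalization uses Pearson's
coefficient over paired pixel intensities and Manders' M1/M2 with
zero thresholds by default (any positive signal), both standard in the JaCoP
tool family.

## Reaction-diffusion model of within-consortium diazotrophy

Ammonium at boundary concentration C0 diffuses into a consortium and is
assimilated with first-order kinetics: D∇²C = kC at steady state. The
depletion length λ = √(D/k) sets the gradient scale. Closed forms:
C(x) = C0·e^(−x/λ) for a planar semi-infinite domain, and
C(r) = C0·(R/r)·sinh(r/λ)/sinh(R/λ) for a sphere of radius R (centre value
C0·(R/λ)/sinh(R/λ)). The finite-difference solver uses second-order central
differences (the spherical case via the substitution u = rC), an exact
radiation condition C' = −C/λ at the truncated planar far boundary (12λ), and
grid doubling until successive solutions agree to a relative tolerance
(default 1e−7 — tolerances much below that hit the ε/h² roundoff floor of
second differences in double precision). Numeric and analytic profiles agree
to ≤ 1e−6 relative error across λ/R ∈ {0.1, 1, 10} in both geometries.

Defaults: D = 1980 µm²/s (free-solution ammonium near 25 °C, a stated
assumption), C* = 25 µM (the lowest literature threshold below which
diazotrophy is induced); k is user-supplied since the source rate constant is
not printed in accessible text. The regime claim the model supports is treated
as an existence property: with C0 ≈ 30 µM and C* = 25 µM there are depletion
lengths in a physically plausible sweep (≈2.5–55 µm) for which the induction
threshold is crossed 1–10 µm below the surface — e.g. λ = 10 µm gives
x* = 10·ln(30/25) ≈ 1.823 µm. Kinetics are first-order only; Michaelis–Menten
saturation, transient dynamics and coupled solute fields are out of scope.

## Synthetic data: what it emulates, and what it does not

`gen_otu_table` draws per-sample log basis abundances from a multivariate
normal whose correlation is the identity except at planted pairs (the
generative model the estimator assumes, which makes parameter recovery a
meaningful test), exponentiates, normalizes, draws a negative-binomial library
depth (mean 30,000, a typical amplicon depth; per-library depths of the real
survey are unpublished) and samples counts multinomially. Contaminant OTUs
carry a recognizable reagent-genus lineage (Ralstonia); rare OTUs get tiny
basis fractions and a hard cap of 9 reads per library, with the capped excess
moved to the sample's most abundant OTU so depths are conserved exactly.
Desk-scale defaults are 60 samples × 300 OTUs; the full-survey design
(310 × 3052) is available via `SimOtuConfig.survey_scale()`. One integer seed
is split deterministically per random source, so regenerating with a different
depth setting reuses the identical basis draw (used by the
depth-robustness test). Not simulated: chimeras, sequencing error, primer
bias, taxonomic mis-assignment — so passing tests demonstrate estimator
correctness under the assumed generative model, not robustness to those
artifacts.

`partnership_demo_config` is the end-to-end scenario: one ANME-2b OTU and five
SEEP-SRB1g OTUs fully co-occurring at ρ_basis = 0.9 (exactly five planted
ANME–SRB partner pairs), plus three ρ = 0.3 background correlations attaching
the module to unrelated OTUs. The weak attachments matter: a fully isolated
module is its own connected component and hence a root block, and five
disjoint planted pairs would yield only connectivity-1 dyads, which can never
be nested blocks — neither would exercise the partnership count. At this
scale all significant edges are kept (q = 0); the top-1% rule is meaningful
only on hundreds of thousands of edges, and is tested exactly on its own
examples instead.

`gen_sorted_consortia` draws (ANME, SRB) labels from a marginal and a
conditional P(SRB | ANME) row-stochastic matrix. `gen_nanosims_scene` builds a
disk-shaped consortium at a chosen pixel pitch, evaluates a true
atom-fraction profile as a function of distance from the disk boundary, and
draws ¹⁵N¹²C⁻ / ¹²C¹⁴N⁻ counts as independent Poissons whose expected ratio
equals the local truth; circular single-cell ROIs must be disjoint and inside
the disk. `gen_two_channel_image` constructs channel B to cover an exact
fraction α of channel A's signal mass, so Manders M1 recovers α by
construction.

## Problem sizes used by the default suite

The shipped tests and the acceptance script run at desk scale: SparCC null
calibration on a 100 × 50 table with B = 100 permutations; planted-partnership
recovery on ten replicate 300 × 60 tables with B = 100; cohesive-block oracle
agreement on 200 random graphs of ≤ 8 nodes; isotope scenes with ≥ 10⁵ counts
per ROI; reaction-diffusion grids up to ~65k points. Statistical assertions
use Monte-Carlo-calibrated bounds (3-sigma z-tests for unbiasedness checks) so
they are reproducible across seeds.
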