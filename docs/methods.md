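# Methods

## Model and procedure

The package treats a local community as a sample from a meta-community whose
phylogeny evolved under a generalized birth–death process with speciation
rate λ, extinction rate μ (both per unit relative tree time) and species
sampling proportion ρ. For an s-species community with ordered divergence
times t₁ > … > t₍ₛ₋₁₎ > 0 taken from the node ages of its induced subtree,
the likelihood conditional on t₁ is

    L = (s−2)! ∏_{j=2}^{s−1} λ p₁(tⱼ) / v_{t₁},

with P(0,t), p₁(t) and v_t as defined in the README. Two identities pin the
implementation down and are enforced by tests: dv_t/dt = λ p₁(t), and
∫₀^{t₁} λ p₁(t)/v_{t₁} dt = 1 — i.e. v is the unnormalized CDF of a node
age, so v_{t₁} belongs in the denominator of every one of the s−2 density
terms. The log (s−2)! constant is included in reported log-likelihoods
(it never moves the maximizer). For s = 2 the product is empty and the
log-likelihood is exactly 0. At μ = 0, ρ = 1 the functions collapse to the
Yule forms p₁ = e^{−λt}, v = 1 − e^{−λt}, which the implementation matches
to machine precision.

Estimation is two-step. Step one (`SpeciationExtinctionModel`): maximize
over (λ, μ) with ρ fixed (ρ = 1 for a fully known species pool), applied to
the meta-tree's s−1 divergence times. Step two (`SamplingProportionModel`):
hold (λ̂, μ̂) fixed and maximize over ρ per community, using the community's
own induced-subtree ages and conditioning on the community's own oldest
divergence — not the meta-tree root, since the density is explicitly
conditional on the sample's t₁. The effective proportion ρ̂_E is compared
with the actual fraction ρ₀ = s/S: PS = ρ̂_E/ρ₀ and PE = ρ₀/ρ̂_E, computed
as PE = 1/PS so the reciprocity is exact to the last bit.

Why this measures skew: thinning a birth–death tree by binomial sampling at
rate ρ produces exactly the ρ-thinned node-age density, so a random
community estimates ρ̂_E ≈ ρ₀ and PS ≈ 1. A clade-restricted community's
subtree is instead (approximately) a complete subtree of the pool — its ages
look fully sampled, ρ̂_E → 1, and PS ≈ 1/ρ₀ ≫ 1. The upper bound at the
minimum mapped community size (11 of 236 species) is 236/11 ≈ 21.5.

## Diversity indices

Faith's PD is the branch-length sum of the *unrooted* minimum spanning path:
an edge is counted exactly when members lie on both of its sides, so the
stem above the members' MRCA is never included. (The rooted variant differs
for nested subsets; the unrooted one matches the minimum-spanning-path
definition and makes PD of the full tip set equal the total branch length.)
AvTD is the mean patristic distance over unordered member pairs — on an
ultrametric tree, twice the mean pairwise MRCA age, accumulated per internal
node in O(n). Dividing by pairs (not by species) is the convention here; the
alternative rescales each community by a constant factor in its size. Both
indices are checked exhaustively against brute-force oracles (pairwise
path-edge unions; explicit distance matrices) on all subsets of random
8-tip trees.

## Numerical choices

- Ultrametricity: relative tolerance 1e-6 on tip depths; tips within
  tolerance are snapped to age 0; violations name the offending tip.
- Tied node ages (common in files rounded to few digits): broken by
  subtracting multiples of 1e-9 × root age so the ordering is strict, as the
  likelihood's ordered-times form assumes.
- Polytomies are rejected by default; an explicit option resolves them
  deterministically with zero-length branches (the tie-breaker then orders
  the resulting equal ages).
- Optimization: Nelder–Mead in unconstrained transforms — (log λ,
  logit(μ/λ)) for step one, a logit over [1e-6, 1] for step two — from 10
  fixed-seed Latin-hypercube starts; the best log-likelihood wins and
  `n_starts_agreeing` counts starts within 1e-4 of it. Boundary hits
  (μ → 0, μ → λ, ρ → 1e-6 or 1) are flagged in the results, never hidden.
- Standard errors: square roots of the diagonal of the inverse numerical
  observed information (central differences, relative step 1e-5) in the
  original parameterization; NaN where the curvature is unusable (e.g. at a
  boundary).
- Likelihood evaluation is done in log space throughout; the closed form
  v_t = ρλ(1−E)/(ρλ + (λ(1−ρ)−μ)E) with E = e^{(μ−λ)t} (expm1 for 1−E) is
  exact at t = 0 and stable for small t.

## Gridding and prioritization

Cell (i, j) covers [i, i+1) × [j, j+1) degrees; coordinates are floored, and
there is no wraparound merging at ±180°. Occurrences are point records;
rasterizing range polygons is upstream of this package. Cells need more than
10 species (≥ 11) for the skew indices and the maps, because the
effective-sampling estimate is biased in very small samples; PD/AvTD only
need 2. Percentile ranks use the mid-rank rule, 100·(rank − 0.5)/n.
"Top 5%" selection takes the empirical 95th-percentile threshold with the
'higher' quantile rule and flags values ≥ threshold, ties included — with
100 distinct values exactly 5 cells are flagged, and raising the quantile
can only remove cells. A constant index column degenerates to flagging all
cells and emits a warning. Latitude profiles report 10-degree-band means and
LOWESS smooths (span 2/3, tricube weights) against signed and absolute
latitude.

## Synthetic data: what it emulates and what it does not

The tree simulator is ages-first: given the root age, the other node ages
are i.i.d. inverse-CDF draws from λ p₁(t)/v_{t₁} (the CDF v_t/v_{t₁} inverts
in closed form), and the topology is built backward by uniform pairing of
lineages at successive ages — matching the likelihood's exchangeable density
exactly, so simulator and likelihood validate each other. The root age is
drawn by rejection from a forward Gillespie birth–death (first passage of
the lineage count from 2 to ⌈n/ρ⌉, rejecting extinctions), or fixed by
option; tests and the acceptance runs fix it at 1 for unit-scale
calibration.

The default grid scenario fixes the study conditions at the scale of the
shark analysis the pipeline is designed for: a 236-species meta-community at
(λ, μ, ρ) = (17, 6, 1) on a unit-root-age tree — the magnitude of rates
estimated for that pool — 100 cells split between a tropical band
(|lat| ≤ 23.5°) and temperate bands (40–60°), and an expected per-cell
sampling fraction of 0.15 (≈ 35 species per cell, comfortably above the
≥ 11 filter and inside the 1–58 per-cell range such databases show).
Tropical cells mix clade-biased inclusion (favored clades covering ~20% of
tips, p_in calibrated so the expected community size equals the random
regime's; p_out = 0.02) with uniform inclusion at weight `skew_strength`;
temperate cells are uniform. A truth sidecar records each cell's regime.

What passing tests therefore show: the estimator chain is internally
consistent and recovers planted compositional structure at realistic sizes.
What they do not show: robustness to the features of real occurrence
databases the generator omits — spatially autocorrelated ranges, heterogeneous
survey effort, imperfect trees (single-locus saturation, polytomies from
rounding), or ecological mechanisms behind clade concentration. The biased-
inclusion model is a test harness, not a biogeographic claim.

## Problem sizes

Default test and acceptance runs use 8-tip trees for exhaustive-subset
oracle checks, 200-age datasets × 50 replicates for rate recovery, a
236-tip tree with 100 subsamples per regime for skew calibration, and one
100-cell grid for the end-to-end check — sizes chosen so the full suite
exercises every stage at the study's own scale while remaining quick to run
on one CPU.

## Known limitations

- Rates are constant in time and across lineages; no diversified-sampling
  or time-varying-ρ variants.
- The two-step procedure ignores step-one uncertainty when fitting per-cell
  ρ̂_E (as in the original design); PS carries no confidence interval.
- A single fixed input tree is used; averaging over a posterior sample of
  trees is out of scope.
- ρ̂_E for communities near the ≥ 11-species filter is noisy and its
  boundary flags should be inspected before interpreting extreme PS values.
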