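# Methods

## The model

`gmaptad` calls topologically associating domains (TADs) and nested
subTADs from a single chromosome's normalized Hi-C contact matrix
**H** (n×n, symmetric, nonnegative). The procedure has three stages.

**1. Mixture binarization.** Contacts are modeled as a two-component
Gaussian mixture: an intra-domain component Y₁ ~ N(μ₁, σ₁²) (high
frequency) and an inter-domain component Y₂ ~ N(μ₂, σ₂²), with mixing
weight α on the intra-domain component. Parameters are estimated by EM
with a deterministic initialization (sample split at the median,
component 1 from the upper half; no random restarts by default).
The state matrix is h_ij = 1 iff the intra-domain posterior
r̂_ij = αφ₁(H_ij) / [αφ₁(H_ij) + (1−α)φ₂(H_ij)] exceeds 0.5 (strictly).

Two departures from the bare formula, both visible in the API:

* the mixture is fit on log₂(1 + H_ij) by default
  (`log_transform=False` fits raw values): normalized Hi-C counts are
  strongly right-skewed and a Gaussian on raw counts puts the decision
  boundary far into the upper tail;
* the posterior is clamped to 0 below μ₂ (the inter-domain mean). With
  unequal fitted variances the wider intra-domain component also wins in
  the far *low* tail, so near-zero contacts would be labeled
  intra-domain; the clamp makes the state rule monotone in the contact
  value, which is what "intra-domain = high-frequency" means.

Only upper-triangle pairs with 1 ≤ j−i ≤ D bins enter the fit, where
D = 2 Mb / resolution is the background distance cap; more distant pairs
never influence domain calls. The diagonal is excluded; zeros are kept.

**2. Block-boundary statistic.** For each bin i and window size d, four
proportions of intra-domain states are computed over d×d index boxes of
h: within the upstream box [i−d+1, i]², within the downstream box
[i, i+d−1]², pooled (p_w), and between them over the cross box (p_b).
The boundary statistic is the two-proportion form

    Z_i = (p_w − p_b) / sqrt(p₀(1 − p₀)/d²),  p₀ = (p_w + p_b)/2,

with d² as the effective sample size (as defined; the cells of a box are
not independent, so Z is a score, not a calibrated normal deviate).
At the chromosome ends the boxes are clipped and their actual areas are
used as denominators. Boundaries are *local peaks* of Z: interior bins
with Z > t₁ that are strict local maxima (leftmost bin of a plateau)
and rise with topographic prominence ≥ 5 above their surrounding
valleys. The prominence requirement is part of the peak definition
because Z has a high structural baseline inside gaps and large domains
(the boxes always straddle the dense diagonal band), and wiggles on that
baseline are not boundaries. Peaks closer than d_p bins are merged
left-to-right, keeping the larger (the right one on ties), repeated to
stability.

**3. Orientation and assembly.** The directionality statistic
D_i = (p_u − p_d)/sqrt(p(1−p)/d²) (upstream vs downstream box
proportions) labels each peak upstream-biased (D > t₂),
downstream-biased (D < −t₂) or unbiased. A TAD opens at a
downstream-biased peak, extends through consecutive downstream-biased
peaks, and closes at the next upstream- or unbiased peak; an unbiased
peak is shared by two consecutive TADs (closing one and opening the
next); the stretch from an upstream-biased peak to the next
downstream-biased peak is a gap. Unbiased peaks inside an explicitly
opened gap do not open TADs. Bins before the first and after the last
peak are gaps, so a domain flush against a chromosome end has no
callable outer boundary — a structural property of the peak-based rule.

Two post-processing steps follow assembly: domains smaller than the
minimal domain size (200 kb by default) are dropped, and each called
domain must individually beat the background in intra-domain proportion
at z > 2 (same two-proportion form as the tuning objective, with
background = all band pairs outside the called domains). The second
step exists because both edges of a contact desert often read
"unbiased" (the D boxes saturate), which would otherwise convert gaps
into called domains.

## Parameter tuning

The four free parameters are tuned by maximizing the separation between
the intra-domain contact proportion inside called TADs and in the
background, as a pooled two-proportion z statistic over band pairs.
The printed variance factor (1/n_TAD − 1/n_bg) and the signed pooled
proportion make the expression undefined for many calls; the default
`corrected` mode uses the classical pooled form (1/n_TAD + 1/n_bg), and
`objective="literal"` reproduces the printed signs with a zero guard.

The default grid is d ∈ {10, 12, 15, 18} bins, d_p ∈ {5, 7},
t₂ ∈ {3, 4, 5}, with t₁ coupled to the window as t₁ = d. The coupling
is a half-maximum rule — a saturated block boundary scores Z = 2d — and
is deliberate: when t₁ is searched freely at small values, the density
objective is maximized by degenerate over-segmentation (chains of tiny
domains hugging the dense diagonal band), because any single-threshold
binarization of a 1/distance-decaying matrix produces a state matrix
whose density is dominated by distance, not domain membership. The
narrow grid keeps the search inside the regime where the objective
ranks genuinely different segmentations. Ties prefer smaller d, then
smaller t₁.

## SubTAD recursion

Each called TAD at least twice the minimal domain size is re-processed
on its own submatrix: a fresh mixture fit on the submatrix band, fresh
Z/D tracks, and a fresh grid search with the TAD itself as background.
The sub-level default grid differs from the top level
(d ∈ {15, 20, 25, 30}, t₁ ∈ {2, 3, 5}, t₂ ∈ {2, 3}, prominence 2):
within a TAD the intra/inter contrast is roughly one log₂ unit instead
of the full foreground/background contrast, so windows must reach past
the in-TAD contact band and thresholds sit much lower. Recursion stops
when no peak survives, when candidates fall below the minimal domain
size, or at the level cap (2 by default). Children spanning their whole
parent are discarded (not a subdivision).

## The simulator

`simulate_hic` draws the upper triangle independently with mean
u / max(1, |i−j|) (background, u = 200 at distance 1), t·u / |i−j|
inside embedded TADs (t = 2) and s·t·u / |i−j| inside nested subTADs
(s = 2), then mirrors to symmetry. Counts are Poisson, or negative
binomial with variance 1.25× the mean (size r = μ/0.25). Ten TAD sizes
are drawn uniformly on [40, 175] bins and the TADs tile the diagonal in
adjacent runs; two gap regions, with sizes drawn from the same
distribution, are inserted at random interior slots; leftover bins are
background at the chromosome ends. The whole size vector is redrawn
until it fits in the 1000-bin chromosome — the printed size range is
kept per TAD, at the cost of conditioning the total. When subTADs are
enabled, each sufficiently large TAD is split at a random interior
point and each side hosts one subTAD covering 50–90% of it.

What the simulator does *not* emulate: mappability/GC bias, unmappable
bins, translocations or copy-number effects, distance-decay exponents
other than −1, and cross-TAD looping. Tests passing on these matrices
show that the statistics and the assembly logic behave as specified
under the idealized generative model, not that calls on real Hi-C data
will have the same accuracy.

## Evaluation utilities

Variation of Information between two partitions of the bin set is
computed in nats from the contingency table; zero-mass cells contribute
0; domain sets are converted level by level with gaps as their own
subsets (VI cannot compare hierarchies directly). The Jaccard index
between interval sets is the symmetrized mean of best-match interval
Jaccards. Boundary feature enrichment uses the single bin at each
domain edge, flanked by ±25 kb for feature counting; the permutation
null re-places the same number of regions with the same sizes uniformly
and without overlap, and the p-value uses the add-one estimator
(1 + #{null ≥ observed}) / (1 + n_perm), which makes it conservative
(never zero, type-I at or below nominal).

## Known limitations

* Domains flush against a chromosome end cannot be called (no peak may
  sit on an endpoint). On densely packed simulated chromosomes this
  costs one to two domains per matrix.
* The orientation statistic saturates at junctions between adjacent
  domains and separates gap edges only moderately (|D| ≈ 3–9 vs ≈ 2–3),
  so a single t₂ occasionally mislabels a peak; the per-domain pruning
  recovers most but not all of these cases.
* The tuning objective discriminates poorly outside the narrow default
  grid (see above); users supplying custom grids with small free t₁
  should expect over-segmented optima.
* On the default simulation the end-to-end tuned pipeline typically
  recovers 8–10 of 10 embedded TADs with matched boundaries within
  ±1 bin and VI ≈ 0.2–0.5 against the truth; exact recovery of all ten
  is not achieved on every matrix, for the structural reasons above.

## Problem sizes used in tests

The test suite runs simulations at 250–1000 bins, oracle comparisons on
30–50-bin state matrices, 10⁶ draws for the negative-binomial
dispersion check, and 500 trials × 99 permutations for the
permutation-test calibration; the full suite completes in well under a
minute on one core.
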