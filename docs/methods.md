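# Methods

`t3brain` implements a data-driven pipeline for discriminating two brain
states (rest vs. focused-attention meditation) from region-level BOLD
time series.  This note documents the models, the tunable parameters, the
synthetic-data generators, and the numerical choices — including the
places where the design was genuinely open and a decision had to be made.

## Pipeline overview

Per subject and condition, a block of T ROI time courses (J regions) is
turned into a J x J functional connectivity matrix of Fisher-z
transformed Pearson correlations.  Each matrix is binarized by *cost*
thresholding: the m = round(cost * J(J-1)/2) strongest connections are
kept, so every network has the same density regardless of overall
correlation level.  Three nodal graph metrics (degree centrality,
normalized betweenness centrality, Watts–Strogatz clustering coefficient)
plus fractional ALFF give a J x 4 feature matrix per observation.
Stacking observations yields a three-way array **X** (I x J x K,
I = 2 x subjects, K = 4), which is classified by supervised Tucker3
clustering; discriminating regions and metrics are identified by a
permutation test on the first-component loadings.

## Supervised Tucker3 clustering

The Tucker3 model for the matricized array is

    X_(I x JK) = U Y_(G x QR) (C ⊗ B)ᵀ + E

with U the I x G binary class indicator, B (J x Q) and C (K x R)
column-orthonormal loading matrices, and Y the class-centroid core.
T3Clus minimizes ‖X − U Y (C ⊗ B)ᵀ‖².  Here U is *fixed* by the known
condition labels (supervised variant); the unsupervised alternating
k-means step is out of scope.

With U fixed, the optimal core is Y = (UᵀU)⁻¹Uᵀ X (C ⊗ B) and the loss
separates into an irreducible within-class part plus the residual of the
weighted class-mean tensor W = (UᵀU)^(−1/2) Uᵀ X (reshaped G x J x K).
Minimizing over (B, C) is therefore a Tucker2-type problem on W, solved
by higher-order orthogonal iteration (HOOI) with an HOSVD
initialization.  At these sizes (G=2, J=116, K=4) the iteration is
deterministic, converges in a handful of steps, and needs no random
restarts.  The loss is asserted non-increasing at every iteration.

Identifiability: with Q=2 the individual columns of B are only defined up
to rotation within their span.  Determinism is imposed by ordering B's
columns by decreasing explained core norm and flipping signs so each
column's largest-magnitude element is positive; all inference uses
absolute loadings, so these conventions cannot change conclusions.

Component scores are provided in two forms: *centroid* scores
U(UᵀU)⁻¹Uᵀ X (C ⊗ B), which are constant within class, and *raw*
per-observation scores X (C ⊗ B).  Raw scores are the default for
plotting and for the score condition test, since only they vary across
participants.

Defaults: G=2, Q=2, R=1; convergence at relative loss change < 1e-9,
at most 500 iterations.

## Standardization of the feature array

The four metrics live on incommensurate scales (degree is a count up to
J−1, clustering and betweenness live in [0,1], fALFF in [0,1]).  Without
scaling, the decomposition would be dominated by degree.  Each
(region, metric) column is therefore z-scored across observations by
default (zero-variance columns are set to zero with a warning).  This is
the single most consequential free choice in the pipeline and is exposed
as a flag (`standardize`); the raw mode is retained.  Standardization
also removes any class-independent mean structure, which matters for the
permutation test (below).

## Cost-threshold selection

Candidate costs span 0.050–0.500 in steps of 0.025 (19 settings).  Three
criteria pick a single cost:

1. **Small-world feasibility** — group-mean global efficiency must lie
   strictly between an edge-matched deterministic ring lattice and the
   mean of degree-preserving random rewirings (default 20 realizations,
   double-edge swaps with 10 x edge-count attempts).  Group means are
   taken over all subject-condition networks (per-subject comparison is
   configurable in principle but not default).
2. **Similarity** — per network, the degree vector at each feasible cost
   is correlated with the cost-averaged degree vector; the mean
   correlation per cost is the score (higher better).
3. **Stability** — the sample standard deviation (ddof=1) of the number
   of communities (greedy resolution-modularity maximization, γ = 1)
   across participants, computed within each condition and averaged
   (lower better).

No canonical rule combines criteria 2 and 3; the default is the minimal
sum of the two competition ranks with ties resolved toward the smaller
cost, with `similarity_first` and `stability_first` as alternatives.
Similarity and stability are evaluated within the feasible range only.

Edge-count rounding is nearest-integer, half away from zero.  Ties at
the threshold cutoff break by ascending lexicographic pair order, which
makes edge sets nested across costs and the whole report deterministic
given a seed.

## fALFF

fALFF is the in-band share of the DFT amplitude (modulus) spectrum:
amplitudes at the discrete frequencies k/(T·TR), DC excluded, summed over
low ≤ f ≤ high (inclusive endpoints) and divided by the sum over all
positive frequencies.  Default band 0.008–0.09 Hz.

The series is demeaned first; linear detrending is available
(`detrend="linear"`) but is **not** the default.  Over a short window a
discrete on-grid sinusoid is not orthogonal to a ramp
(Σₙ n·sin(2πkn/N) = −(N/2)·cot(πk/N)), so subtracting a least-squares
line injects broadband amplitude leakage — at T=120 it moves the fALFF of
a pure in-band tone from ~1.0 down to ~0.91.  Since the analysis band
already excludes the two lowest frequency bins where residual drift
concentrates, mean removal is the lesser distortion.  fALFF is computed
directly on the region-level time course (voxelwise computation followed
by within-region averaging would require voxel data).

## Permutation inference

Condition labels are permuted (default: each subject's two labels are
swapped independently with probability 1/2, respecting the paired
design; a `free` relabeling preserving class sizes is available), the
supervised model is refitted, and absolute first-component loadings are
recorded.  p = (1 + #{|λ*| ≥ |λ_obs|}) / (n_perm + 1), so the smallest
attainable p-value is 1/(n_perm+1) and p is never zero.  Regions and
metrics are tested separately, uncorrected at α = 0.05 by default (an
optional BH mode exists).  Default n_perm = 10,000.

A regime worth knowing about: under within-subject swaps a residual
fraction |1 − 2f| of the class separation survives a permutation
(f = fraction of subjects swapped), so the test has power only when the
column noise exceeds the typical permuted residual signal while the
observed full signal still dominates it.  With I = 58 and J = 116 this
corresponds to noise-to-separation ratios of roughly 0.03–0.2 on the
standardized scale.  This is a property of permutation tests on loading
vectors generally, not of this implementation.

Baselines: a paired t-test per (region, metric) cell with
Benjamini–Hochberg correction across all J·K tests, and per-component
paired t-tests on raw component scores.  Cross-cost stability is
summarized by overlap ratios — the fraction of grid costs at which each
region is selected, with sub-range ratios splitting the grid at 0.225
(8 lower, 11 higher costs for the default grid).

## Synthetic data

Both generators exist to provide known ground truth; neither is
calibrated to any real recording.

**Tensor generator** (`generate_feature_tensor`) inverts the Tucker3
model: B's first column is the unit-normalized indicator of the planted
region set, the second the indicator of the complement; C is the unit
vector on the planted metric; noise is i.i.d. Gaussian (σ).  The core is

    Y = [[δ/2, δ/4], [−δ/2, δ/4]]

i.e. class separation δ along the first component only, plus a
class-common second component scaled with δ.  This satisfies four
constraints at once: the core has rank 2 with orthogonal columns of
distinct norms, so the planted two-dimensional region subspace (and the
first component's alignment with the planted set) is identified exactly
in the noiseless case; δ = 0 makes the labels fully exchangeable, so
null permutation p-values are exactly uniform; the second component is
non-discriminative, so its score test is null; and column
standardization removes the common component, so permutation power on
the metric loadings is restored.  Defaults mirror the study layout:
29 subjects (I = 58), J = 116, K = 4, 8 planted regions on the
clustering coefficient; δ = 1, σ = 0.1.

**Time-series generator** (`generate_timeseries_dataset`) draws, per
subject and condition, T x J Gaussian signals with a block correlation
structure: contiguous blocks of `block_size` regions (default 8) with
within-block correlation ρ₀, a small between-block level ε = 0.01, and —
in the meditation condition only — pairwise correlation ρ₁ among the
effect regions.  Correlation matrices are checked for positive
semi-definiteness and rejected otherwise.  Spectra are shaped by
frequency-domain filtering of white noise: in-band bins get gain 1,
out-of-band bins a gain chosen so the expected in-band amplitude
fraction equals `band_power_fraction` (default 0.85), giving exact
control of the fALFF ground truth.  The same filter is applied to every
region before Cholesky mixing, which preserves the cross-region
correlation structure.  Condition blocks are generated independently per
subject (no temporal carryover).  Defaults: 29 subjects, J = 116,
T = 120 volumes at TR = 2.5 s (a 5-minute block), band 0.008–0.09 Hz,
ρ₀ = 0.1, ρ₁ = 0.9, 8 effect regions.

What the generators do *not* emulate: hemodynamic response dynamics,
physiological and motion noise, spatial autocorrelation of real
parcellations, inter-subject variability in connectivity topology, and
temporal autocorrelation beyond the band-limiting filter.  Passing tests
therefore demonstrate correctness of the computational machinery and the
statistical calibration of the inference under the assumed model — not
that the pipeline would detect meditation effects in real recordings.

## Problem sizes used in validation

The test suite exercises the solver at the full study dimensions
(I = 58, J = 116, K = 4).  Null calibration of the permutation test uses
500 datasets x 999 permutations at J = 20 — under exchangeability the
p-value distribution is uniform for any J, and the smaller region count
keeps half a million refits cheap.  End-to-end recovery uses 50 seeded
full-size datasets at the fixed cost 0.225 with 999 permutations; the
three-criteria grid search is validated separately at reduced size
(its reference-graph resampling across 19 costs x 58 networks is by far
the most expensive stage of the pipeline).

## Known limitations

- Only binarized (unweighted) networks; no weighted-graph metrics.
- Greedy modularity maximization is a heuristic; it is deterministic and
  matches exhaustive search on small cases but carries no optimality
  guarantee at J = 116.
- HOOI converges to a stationary point; for the reduced G x J x K
  problems used here the HOSVD start has always reached the brute-force
  optimum in testing, but global optimality is not guaranteed in general.
- The permutation scheme treats subjects as exchangeable units; nothing
  corrects for multiple testing across regions by default (by design,
  with an optional BH mode).
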