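# Methods

This note documents the models implemented in `hyperbundle`, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and the
numerical conventions that pin down otherwise ambiguous steps.

## Signal model

All simulated sources are complex analytic narrowband series: white Gaussian
noise convolved ("valid" mode, so no edge transients) with a complex Morlet
wavelet w(t) = exp(−t²/2σ_t²)·exp(2πi f₀ t), σ_t = m/(2π f₀), then
standardised to zero mean and unit variance per column. Defaults f₀ = 10 Hz,
m = 5, f_s = 100 Hz. Phase is the complex argument; no separate Hilbert
transform is needed, and decimated phases are uniform on [−π, π) (checked by
Rayleigh test).

A coupled target is built as y(t) = c·x(t−lag) + √(1−c²)·η(t), with η an
independent Morlet-noise series of matched spectrum and variance, so the
lagged Pearson correlation equals c by construction. Default coupling 0.9 at
a 3-sample lag. At f₀ = 10 Hz and f_s = 100 Hz a 3-sample delay corresponds
to a 108° phase lag (sometimes loosely called a quarter cycle); the literal
sample delay is implemented and the phase lag is reported as a derived
quantity. The lag is applied circularly; for 3 samples on ≥10⁴-sample series
the wrap-around is negligible.

**Decimation.** Narrowband neighbours are strongly autocorrelated, so series
are decimated before synchrony estimation. The default step is 0.6 of the
wavelet envelope width, ceil(0.6·(m/f₀)·f_s) = 30 samples at the default
band, where the theoretical lag-1 autocorrelation
exp(−τ²/4σ_t²) ≈ 0.03. Independence is asserted, not assumed: decimation
fails if the modulus of the *column-averaged* complex lag-1 autocorrelation
is ≥ 0.1. Averaging across columns before taking the modulus is deliberate —
the true autocorrelation is common to all columns while the estimation noise
(≈ 1/√2n per component) is not, so the pooled check does not misfire on wide
arrays; for one- or two-column series the check retains ~0.03 of headroom.
The standard run decimates to m = 1000 independent samples.

## Mixing models

**Grid kernel.** On an open (non-periodic) n×n grid with spacing d_g, the
mixing weight between sources at distance d is exp(−d²/2d_g²) for d ≤ 3·d_g
and exactly 0 beyond; self-mixing is maximal (weight 1). Measurement is
linear, X′_v = X_v + Σ_{i≠v} w(v,i)·X_i: the sum excludes the self term,
which enters once through the leading X_v (including it again would double-
count the source's own signal).

**Synthetic cortical operator.** Stands in for a forward-plus-inverse MEG
modeling chain when grid geometry is too idealised. Parcels get uniform
random centroids in the unit cube and a modeling quality q ~ Beta(4, 2).
Leakage into parcel v from parcel i is proportional to
h_vi·exp(−d_vi/λ) with heavy-tailed h ~ LogNormal(0, 1) and λ = 0.15 (about
a quarter of the median inter-centroid distance), rescaled per row so total
leakage power is (0.6·(1−q_v))²; parcel-specific measurement noise has SD
0.6·(1−q_v). Poorly modeled parcels therefore have simultaneously low
fidelity and high residual spread, which reproduces the qualitative
structure of real source spaces: heavy-tailed mixing-weight distributions,
mixing decaying with distance, and a strong negative rank correlation
between parcel fidelity and residual spread (measured ρ ≈ −0.84 on the
default operator). What it does **not** emulate: cortical folding and the
gyrus/sulcus geometry of real leakage, 1/f sensor noise, inter-subject
operator variability, or any anatomical labeling — so passing tests show
the *mechanisms* (bias of synchrony estimates by modeling accuracy, ghost
halos around true edges), not quantitative agreement with any real operator.

## Synchrony estimation and thresholding

cPLV is averaged over unit phasors of independent samples; PLV = |cPLV| and
iPLV = |Im cPLV| (absolute value, so iPLV is lag-sign invariant). Estimation
refuses non-decimated input unless explicitly overridden, and requires ≥100
samples. The chance level for a null PLV with n samples is √(π/4n) ≈ 0.028
at n = 1000.

Null thresholds: the cutoff for a significance level L = −log₁₀(p) ∈
{1.3, 2, 3, 4, 5} is the (1 − 10⁻ᴸ) quantile of iPLV values pooled across
all provided null graphs (one pooled set, not per-graph thresholds). A
warning is issued when the pooled count cannot resolve the strictest tail.

Percentile thresholding uses **Hazen plotting positions** ((i−½)/N midpoint
interpolation, the Matlab `prctile` convention) over the unique upper-
triangle values, with a strictly-greater comparison. This convention is what
makes the 99.7th-percentile rule on a 400-source graph (79,800 unique pairs)
yield exactly 239 suprathreshold edges on tie-free data; numpy's default
linear interpolation would yield 240.

## Mixing properties

Per iteration (default 10), fresh null series are decimated, measured
through the model, and compared: f_mix[i,j] = PLV(X_i, X̂_j),
PLV₀[i,j] = PLV(X̂_i, X̂_j), f_p[i] = Re cPLV(X_i, X̂_i). Iteration means are
reported; f_mix is directional per iteration and symmetrised on output.
Edge fidelity is the product of non-negative-clipped endpoint fidelities,
f_e[i,j] = max(f_p[i],0)·max(f_p[j],0) — a configurable default; its
diagonal is f_p². Group-level properties are arithmetic means across models.

The intractable-edge-mask deletes pairs with f_e < 0.1 (default) OR
PLV₀ above a cutoff; the two criteria are combined by OR. When a target
deleted fraction is requested instead of a PLV₀ cutoff, the cutoff is placed
between order statistics of the remaining pairs so the total deleted
fraction matches the target to within one edge; it is an error to request a
target below what the f_e criterion alone already deletes.

## Hyperedge bundling

Edge-to-edge similarity: for edges (a,b), (c,d),
S = max(√(m[a,c]·m[b,d]), √(m[a,d]·m[b,c])) with m the residual-spread
matrix PLV₀ by default (configurable to f_mix); m's diagonal is set to 1 so
edges sharing an endpoint score high. Distance D = 1 − S.

UPGMA is implemented directly (not delegated) so that tie-breaking is
deterministic: at each step the globally nearest active cluster pair merges
at its average-linkage distance, ties going to the lexicographically
smallest pair of cluster ids (leaves first, then merges in creation order).
Cluster distances use the exact weighted-average update, equivalent to
averaging all leaf-pair distances; the tests verify exact agreement in
merge order and heights with a from-scratch brute-force recomputation, and
cross-check against scipy's average linkage.

Inconsistency κ_θ = (δ − μ_δ)/σ_δ uses the merge heights within depth θ
below and including the merge (depth 1 = the merge itself, depth 2 adds its
direct merge children, …), with sample SD (ddof = 1); a neighbourhood with
fewer than two heights or zero spread (bottom ties) gets κ = 0. Default
θ = 2.

The cut threshold is the (1−CL)·100 linear-interpolation percentile of κ
over all merges of the tree being cut (per-tree, not a fixed reference);
merges strictly above it split, and every maximal subtree containing no
split merge becomes one hyperedge; uncovered leaves become singletons.
Default CL = 0.15. CL = 1 is the degenerate boundary (every merge split,
all singletons). Hyperedge count is non-decreasing in CL.

**Known limitation.** Because the κ threshold is a per-tree percentile, a
fraction ≈ CL of merges always splits, which puts a floor on partition
granularity: on the six-interaction grid run, CL = 0.15 yields ≈ 99
hyperedges over 239 edges rather than the ideal 6 (the count falls toward
~17 at CL = 0.01). The qualitative goal is still met — each planted
interaction lands in its own hyperedge and spatially distant interactions
never share one.

## Stability test

n_perturb (default 40) independently perturbed copies of S — a random 15%
of off-diagonal entry pairs zeroed, symmetry preserved, element set intact —
are bundled, and likewise for one value-rewired surrogate of S. Partition
differences are measured by variation of information in nats (normalised
variant VI/ln n available). The one-sided Mann–Whitney U test asks whether
VI within the perturbed family is smaller than within the surrogate family.

VI samples are taken over **disjoint** perturbation pairs (2k vs 2k+1),
giving n_perturb/2 conditionally independent values per family. Using all
partition pairs instead (available as `pairing="all"`) makes the VI samples
share partitions, violates the rank test's independence assumption, and
demonstrably miscalibrates the null (p-values U-shaped rather than
uniform); with disjoint pairs the p-value distribution under an
unstructured S is uniform to KS precision, which the acceptance suite
checks over 100 runs.

## Evaluation conventions

The planted truth is a perfect matching (every node degree exactly 1;
n/2 edges for n parcels). "Other" edges are all remaining unique pairs —
exactly 79,600 for 400 parcels, which the false-positive arithmetic keeps
distinct from the conventional rounded population of 8×10⁴. Gamma coupling
patterns use shape 2 with scale level/2 (mean = level), clipped to [0, 1];
uniform patterns use the level itself. Hyperedge scores: a hyperedge is a
true positive if it contains ≥1 true edge; sensitivity = fraction of true
edges inside true-positive hyperedges; specificity = 1 − false-positive
hyperedge fraction; separability = fraction of true-positive hyperedges
holding exactly one true edge. These hyperedge-level definitions are this
package's own, and are deliberately simple.

## Problem sizes

The reference experiments run at the full study conditions — 400
sources/parcels, 1000 independent samples, six or 200 planted couplings —
which complete in seconds on one CPU. Mixing-property estimation in the
test fixtures uses 3–5 null iterations rather than the default 10, and
stability calibration uses 15-edge matrices with 20–60 perturbations;
estimator-variance margins in the corresponding assertions account for
those sizes.
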