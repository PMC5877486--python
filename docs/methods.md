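# Methods note

This note records the model implemented by `somnograph`, the default
parameters and the reasons behind them, the scope of the bundled synthetic-EEG
generator, and the numerical choices that affect results. Nothing here is an
empirical claim about clinical data; every number quoted below is either a
definition, a package default, or a quantity the test suite computes.

## Pipeline model

The package stages sleep from multichannel EEG in five steps:

1. **Preprocessing.** Per-channel mean removal, then a zero-phase Butterworth
   cascade (3rd order, applied forward and backward with `sosfiltfilt`):
   high-pass 0.5 Hz, low-pass 50 Hz, band-stop 47–53 Hz, band-stop 97–103 Hz.
   The second band-stop targets the mains harmonic and is skipped with a
   warning when the sampling rate cannot represent it (fs ≤ 206 Hz). The
   recording is then cut into non-overlapping 30-s epochs; a trailing partial
   epoch is dropped. An optional step removes artifact components given an
   externally computed unmixing matrix: the data are transformed to component
   space, the selected rows are zeroed, and the mixing (inverse unmixing)
   matrix maps back to channel space.

2. **Synchronization likelihood (SL).** Each channel is z-scored per epoch and
   time-delay embedded (lag `l`, dimension `m`). For each channel and each
   reference time `i` (every `stride`-th embedded vector), a critical distance
   ε is set to the smallest distance such that a fraction `p_ref` of the
   vectors in the window `w1 < |i − j| < w2` lie within ε (ties included, so
   the achieved fraction is ≥ `p_ref`). The SL of a channel pair is the
   probability, averaged over reference times and over the two channels, that
   a recurrence of one channel coincides with a recurrence of the other —
   i.e. `|own ∩ other| / |own|`. Identical channels give exactly 1;
   independent channels give approximately `p_ref`. The matrix is symmetric
   with zero diagonal.

3. **Relative wavelet entropy (RWE).** Each channel is decomposed with an
   orthogonal discrete wavelet transform (Daubechies-4 by default) to a depth
   whose final approximation band lies inside the delta range (depth 5 at
   128 Hz). The relative energy distribution over levels is compared between
   channels with the Kullback–Leibler form `Σ p_j ln(p_j / q_j)`; the result
   is asymmetric, zero iff the distributions match, and non-negative. The RWE
   matrix is therefore directed. Channel-averaged relative energies mapped to
   the five canonical bands (delta, theta, alpha, beta, gamma) give five
   band-energy ratios per epoch.

4. **Graph metrics.** Each connectivity matrix is a weighted graph over
   electrodes: SL values are similarities directly; RWE divergences `v` map to
   `1/(1+v)`. Shortest-path metrics use edge lengths `1/similarity`. Per
   epoch the package computes: mean binarized degree and density (strongest
   30% of edges kept, ties kept — undirected graphs only, since the directed
   RWE graph is complete and these would be constant), mean weighted
   clustering (Onnela geometric-mean form; Fagiolo form for directed graphs),
   characteristic path length, global efficiency, mean normalized betweenness
   centrality, and the small-world index σ = (C/C_rand)/(L/L_rand) against
   surrogates that permute the weights over the existing edges (preserving
   every node's degree and the weight multiset).

5. **Staging.** The SL feature vector concatenates the strictly-lower
   triangle of the matrix (M(M−1)/2 values; 171 at 19 channels) with the 7
   graph features: 178 dimensions. The RWE vector concatenates all
   off-diagonal entries (M(M−1); 342), the 5 directed graph features, and the
   5 band ratios: 352 dimensions. Features are min-max scaled to [0, 1] with
   the scaler fitted on the training split only (test values clipped). The
   split is stratified at epoch level, 70/30 by default. The comparison grid
   holds 31 classifiers: 9 kNN (k ∈ {1,3,5} × {euclidean, cityblock,
   cosine}), 15 SVM (C ∈ {0.1, 10, 100} × {linear, polynomial degree 3,
   degree 5, gaussian with two method-matched widths: σ ∈ {1.95, 1.45} for
   SL features, {0.25, 0.75} for RWE}), and 7 feed-forward networks (hidden
   layouts (10,), (30,), (50,), (100,), (50,50), (100,50), (100,100)).
   Accuracy is reported overall and per stage; confusion matrices index rows
   by predicted and columns by true stage.

## Default parameters and rationale

| Parameter | Default | Rationale |
|---|---|---|
| Epoch length | 30 s | The standard staging unit; an 8-h night gives 960 epochs. |
| SL lag `l` | 1 | Finest temporal resolution at typical EEG rates. |
| SL dimension `m` | 10 | Large enough to unfold broadband EEG dynamics. |
| SL `w1` | 18 | Theiler window excluding autocorrelated neighbours (≈ (m−1)·l·2). |
| SL `w2` | w1 + 1000 | Window wide enough for a stable recurrence quantile. |
| SL `p_ref` | 0.01 | Sets the baseline: independent channels score ≈ 0.01. |
| SL stride | 4 | Reference-time subsampling; the estimate is an average, so subsampling trades variance for time. |
| Wavelet | db4, depth to ≤ 2 Hz approx | Orthogonal (energy-preserving) and standard for EEG. |
| Binarization fraction | 0.3 | Keeps the strongest edges while leaving a non-trivial degree distribution. |
| Surrogates `n_rand` | 20 | Stable null means for C_rand, L_rand. |
| Train fraction | 0.7 | Stratified 70/30 epoch-level split. |

## Synthetic generator: scope and limits

Each stage is a `StageProfile`: relative power in the five bands, a coupling
coefficient `c`, and a white-noise floor. A channel is the convex mixture
`x_k = c·s + (1−c)·u_k` of a shared band-limited drive `s` and an independent
process `u_k`, both built from unit-variance Butterworth-filtered Gaussian
noise scaled by the square root of the band weight, with the rhythmic part
scaled to 30 µV RMS. This gives analytic handles for testing: `c = 1` makes
channels identical (SL → 1), `c = 0` makes them independent (SL → p_ref),
spectra follow the band weights, and coupling is monotone in `c`.

The default profiles follow the qualitative stage descriptions (N1
alpha/theta, N2 theta-dominant, N3 delta-dominant, REM mixed with elevated
fast activity); the numbers themselves are this package's own choices — no
standard fixes them. `overlapping_profiles()` deliberately pushes N1 between
its neighbours to reproduce the well-known difficulty of scoring N1: N2, N3
and REM become nearby fixed profiles, and N1 becomes a `ProfileMixture` —
each N1 epoch draws a mixing coefficient λ ~ U[0, 1] and interpolates the N2
and REM profiles, so epochs near the extremes are distributed exactly like a
neighbour stage. (A first design that merely placed a fixed N1 profile
between its neighbours produced no confusion at all: per-epoch band-ratio
estimates are precise enough that even nearby fixed spectra separate
perfectly. Ambiguity has to be built into the N1 distribution itself.)

Limits: no sleep grapho-elements (spindles, K-complexes, slow-wave
morphology), no non-stationarity within an epoch, no volume-conduction model,
no electrode geometry, and a single global coupling per stage. Accuracies
measured on this generator characterize the pipeline, not clinical
performance; published clinical accuracies are not reproducible from it and
are not targets anywhere in the test suite.

## Numerical choices

- **DWT boundary mode = periodization.** The orthogonality of the transform
  (exact Parseval energy conservation, verified to 1e-6 relative) holds only
  with periodized boundaries in PyWavelets; symmetric extension leaves ~1e-3
  relative energy error. RWE needs a true energy distribution, so
  periodization is used.
- **SL normalization.** Pair values are normalized by each reference's actual
  recurrence count (`|own|`), not by the nominal window size, so identical
  channels give exactly 1.0 regardless of quantile ties.
- **Recurrence tie rule.** Distances equal to ε count as recurrences
  (θ(0) = 1); with ties the achieved recurrence fraction is ≥ p_ref.
- **Critical distance.** ε is the k-th smallest window distance with
  k = max(1, ⌈p_ref·|window|⌉), found by partial sort.
- **Shortest paths** use Dijkstra on `1/similarity` lengths; unreachable
  pairs are excluded from the path-length mean (with a warning) and
  contribute zero to efficiency.
- **Degenerate guards.** Flat (zero-variance) channels are rejected by name;
  relative energies are floored at 1e-12 and renormalized before the
  logarithm, and the KL sum is clamped at 0 against rounding.
- **Determinism.** All randomness flows from explicit seeds; per-stage seeds
  are derived from a root seed with a CRC-based, process-independent hash.
  Seeds stay below 2^31.

## Study conditions for the end-to-end evaluation

`synthetic_staging_study` (used by the acceptance test, the acceptance script
and the README example) runs the full pipeline at a desk-scale configuration
fixed before any full run: 8 channels at 128 Hz, 200 epochs per stage, SL at
`p_ref = 0.02` with reference stride 32, 10 graph surrogates, and a compact
5-spec grid spanning all three classifier families (1-NN euclidean, 5-NN
cosine, linear SVM C=10, gaussian SVM C=10 with the method-matched width, and
a (30,)-unit network). These reduce runtime (≈ 4–5 minutes per profile set on
one CPU) relative to the 19-channel, 31-spec defaults; they are this
package's own study conditions, not values taken from any external source.
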