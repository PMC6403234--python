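# Methods

This note documents the models, algorithms and design choices behind
`gmmsort`, the way the synthetic data generator works, and the numerical
conventions the tests rely on.

## Mixture fitting (gmmsort.gmm)

All stages use finite Gaussian mixtures
p(x) = Σᵢ αᵢ·N(x | μᵢ, Σᵢ) fitted by expectation-maximization.

**Defaults** (`FitOptions`): 10 replicate restarts keeping the
highest-likelihood fit; convergence when the percentage change of log p(x)
between iterations falls below 1e-6 (i.e., a relative change of 1e-8), capped
at 10⁴ full E+M cycles; covariance ridge of 1e-6 × per-dimension data
variance added each M-step.

**Initialization** (unstated in most formulations; fixed here for
reproducibility): component means are k distinct observations drawn without
replacement, covariances start at the data covariance, weights uniform.
Replicate r runs on a deterministically spawned child stream of the root
seed, so every fit is exactly repeatable.

**Fixed-mean variant**: means are supplied and never updated; only weights
and covariances adapt. The returned means are bit-identical to the input.
A component that captures no posterior mass is clamped (weight 1e-12,
covariance at the ridge) rather than deleted, because downstream cluster
identity depends on component indices; a warning is emitted. Since this
initialization is deterministic, a single EM run suffices.

**Numerics**: the univariate path runs a fused single-pass kernel
(E-step and M-step sufficient statistics in one loop, data centered first so
the moment subtraction is well-conditioned); the multivariate path uses
per-component Cholesky factorizations, retrying with a 10³-fold stronger
ridge if a factorization fails. The per-iteration log-likelihood trace is
stored on the model; EM guarantees it non-decreasing up to the ridge
perturbation (tests allow a 1e-8 relative slack). Degenerate inputs
(constant data) yield a ridge-variance single-point model, not a crash.

## Feature extraction (gmmsort.features)

*PCA* is computed by eigendecomposition of the covariance of centered
waveforms; components are ordered by decreasing eigenvalue and each
loading's largest-magnitude entry is made positive for run-to-run
determinism. Trailing zero-variance components are kept and flagged.

*Wavelets*: a 4-level multiresolution Haar decomposition per channel
(channels concatenated afterwards), in the orthonormal convention (1/√2 per
level), computed with PyWavelets in periodization mode. The transform is an
orthogonal map — coefficient energy equals sample energy and reconstruction
is exact — which the tests assert on random waveforms. All n coefficients
are kept as candidate features, including the level-4 approximation (it
carries low-frequency shape). Channel lengths not divisible by 2⁴ are padded
at the end by symmetric reflection; coefficients whose support touches
padding are kept but flagged.

*Weighted PCA*: zero-variance coefficient columns are dropped (logged), the
rest are z-scored, multiplied by a mixture-based separability score, and PCA
is applied. Variance is never used as the weight — it would undo the
z-scoring.

## Separability metrics (gmmsort.selection)

Each feature column gets an 8-component univariate mixture fitted to its
empirical distribution. The density is discretized on 100 equally spaced
points over the data range; peaks are +→− sign changes of the first forward
difference and inflections any sign change of the second difference, a zero
run counting once at its left edge. I_peak and I_inf sum the density at
those points and divide by the maximum density on the grid; I_dist is the
median over all 28 component pairs of
D_ij = |μᵢ−μⱼ|·√(αᵢαⱼ)/(σᵢσⱼ). Components keep their weight in the pairs —
the √(αᵢαⱼ) factor already suppresses empty ones. Degenerate columns or
failed fits score 0 and are never selected; ties in the top-5 selection
break to the lower column index.

Two practical notes established while validating the metrics:

- I_dist is not scale-free (it scales as 1/σ²), so its monotone growth with
  true mode separation holds for *standardized* samples — which is how the
  pipeline applies it (weights on z-scored coefficients). The sweep tests
  standardize first.
- A fitted 8-component model of a single Gaussian never yields exactly
  I_dist = 0 (components retain finite spread); near-zero (≈0.2 against ≈2
  at 8σ separation) is the attainable statement.

**Scoring budget**: the scoring fits are ranking statistics, not final
models; they run with an iteration cap of 200 (`scoring_max_iterations`) and
on at most 2 000 subsampled values per feature (`scoring_max_points`).
Rankings and weights are stable under this budget while full-tolerance
scoring is ~30× slower; both caps are configurable, and the clustering-stage
fits always run at the full tolerance.

## Clustering (gmmsort.clustering)

A full-covariance mixture with 12 components (single wire; 20 for tetrodes)
is fitted to the 5 selected features. From each component center a
Nelder-Mead simplex search maximizes the mixture log-density in
range-normalized coordinates (xatol 1e-4 of each dimension's range, fatol
1e-10, 2 000 evaluations; non-converged searches are dropped with a
warning). Endpoints are merged greedily by decreasing density when their
range-normalized Euclidean distance falls below 1% (a per-axis merge mode is
available); each merged group is represented by its highest-density
endpoint, the actual mode estimate. The retained modes become fixed means of
a final mixture refit, and each spike is assigned to the maximum-posterior
component (ties to the lower index; labels are 1-based).

**Overclustering is real, not transient.** A maximum-likelihood
over-parameterized mixture tiles each physical cluster with several
components, and the fitted density genuinely carries micro-modes more than
1% of the data range apart — the same behavior appears in an independent
reference implementation (scikit-learn) at tight tolerance. Consequently the
mode count exceeds the true unit count (typically 7–10 modes for 3 clean
units with 12 components). This does not cost information: splits are
within-unit, so MI_norm stays high and clusters can be merged explicitly
afterwards (`merge_clusters`, `gmmsort merge`). The idealization that extra
components only smooth the density without adding modes holds for mode
*positions* (modes sit inside true clusters; every true center is covered),
not for the count.

**Outlier handling** (optional): spikes whose k-NN distance (k=20) exceeds
twice the 95th percentile are held out of all mixture fits and classified
afterwards under the final model. A cutoff excluding more than half the
spikes is treated as a misconfiguration.

## Preprocessing (gmmsort.preprocess)

Band-pass 300–3000 Hz, zero-phase (forward-backward 3rd-order Butterworth).
Detection thresholds at 5 robust SD (median absolute deviation × 1.4826;
plain SD by flag) per channel, negative-going by default; snippets of 64
samples per channel are centered on the extremum of the largest-deflection
channel, with a 1 ms lockout; channels are concatenated in fixed order.
Ground truth matches each true event to the nearest detection within 2 ms;
truth events with more than one candidate in the window are discarded as
ambiguous, and unmatched detections are labeled background (0).

## Synthetic recordings (gmmsort.simulate)

The generator emulates the structure of classic simulated benchmark
recordings: 3 target neurons superimposed on ~60 s of background activity at
controllable SNR.

- **Templates** are parametric triphasic shapes (positive pre-hump, Gaussian
  trough of width 0.1–0.3 ms, slower after-wave), Hann-tapered, normalized
  to unit trough. The three target templates are chosen by greedy
  farthest-point selection from a candidate pool under a pairwise L2 floor
  (default 2.0 for unit-trough 64-sample shapes) — the targets model
  *different* cells; without the floor, two random shapes can nearly
  coincide and no feature set separates them.
- **Background** is dense low-amplitude spike hash (5 kHz of non-target
  templates at amplitudes 0.02–0.08) plus Gaussian noise at half the hash
  SD, demeaned. By superposition it is quasi-Gaussian, so single background
  events stay below a 5-SD detection threshold.
- **Targets** fire as Poisson trains (default 5 Hz each, 2 ms refractory);
  amplitudes are set so trough/background-SD equals the requested SNR
  (default 10). Truth times point at each spike's trough sample. An optional
  outlier fraction adds coincident companion spikes within 0.5 ms.
- `synthesize_waveforms` bypasses the trace entirely (template + white noise
  of SD 1/snr per sample), isolating classification difficulty from
  detection effects.

What the generator does *not* model: electrode drift and waveform
nonstationarity, bursting amplitude attenuation, spatially overlapping
high-density-array spikes, and correlated (non-Poisson) firing. Passing
tests therefore demonstrate the pipeline's behavior under stationary,
well-isolated conditions, not robustness to drift or overlap.

## Evaluation (gmmsort.evaluate)

MI is the plug-in estimator in bits (0·log terms are 0), with an optional
Miller–Madow correction; MI_norm = 100·MI/H(truth), clipped to [0, 100]; a
single true class is an explicit error. The error rate maps each cluster to
its predominant true class (ties to the lower class index). `consistency`
re-sorts the same waveforms R times (default 25) on spawned seeds and
reports mean/variance of MI_norm and mean cluster count. `symmetry_sweep`
equalizes class counts, subsamples one class to each symmetry index,
re-runs the full pipeline, and reports overall MI_norm plus the binary
MI_norm of the subsampled class against the rest (truth binarized); indexes
leaving fewer than 10 spikes are skipped.

## Problem sizes used in tests and the acceptance script

Chosen as this package's scaled-down operating sizes: 60 s recordings at
5 Hz per neuron (≈900 detected spikes), 25 re-sorts for the consistency
analysis, 20 seeds for metric sweeps, 10–20 seeds for clustering checks,
noise sweep over SNR ∈ {1, 2, 3, 5, 8} on a fixed neuron set, symmetry
sweep at indexes {1, 10, 100}% on a 200 s set at SNR 5 (≈1 000 spikes per
class after equalization, so the 1% index keeps ≥10 spikes; moderate noise,
because at SNR 10 even a 10-spike class remains perfectly separable and the
smallest-cluster degradation cannot be observed).

## Known limitations

- Single- and multi-channel recordings are supported, but there is no
  spatial masking for high-density arrays.
- No noise whitening or sampling-jitter correction; alignment is at sample
  resolution.
- Cluster merging is explicit (user-driven), never automatic.
- The plug-in MI estimator is biased upward at very small counts; the
  Miller–Madow flag mitigates but does not remove this.
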