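# Methods

`spdstates` detects brain-state changes in multichannel (BOLD-like) time
series by working directly on the Riemannian manifold of symmetric
positive-definite (SPD) matrices, and then characterizes the recovered
states through their eigen-spectra. This note records the model, the
numerical choices, and what the synthetic benchmark does and does not
establish.

## The model

**Windowed connectivity.** A series of T time points over N regions is
converted to a trajectory of Pearson-correlation matrices over sliding
windows of width w (stride 1), indexed by window centers. Each matrix is
eigenvalue-floored at 1e-6 so that short windows (w < N) still yield SPD
matrices; the floor preserves eigenvectors. Windows are centered,
inclusive `[t - floor(w/2), t + ceil(w/2) - 1]`, 0-based, producing
exactly T − w + 1 matrices — the boundary rule is a convention we fix, as
any centering scheme only shifts indices.

**Geometry.** The default metric is log-Euclidean,
`g(A, B) = ||log A − log B||_F`, which makes Sym⁺ flat in the log chart
and gives the Fréchet mean the closed form `exp(mean(log S_i))`. The
affine-invariant metric (Karcher iteration, step size 1, tolerance 1e-8,
at most 100 sweeps) is available behind a flag. Near-singular inputs are
ridge-lifted by `1e-10·trace/N·I` with a logged warning before any matrix
function.

**Alignment.** Subject-to-subject offsets are removed by parallel
transport: per trajectory, the subject Fréchet mean X̄_m is computed, then
the population mean X̄ of the subject means, and every matrix is moved by
the congruence `E X Eᵀ` with `E = (X̄ · X̄_m⁻¹)^{1/2}`. The principal
square root is evaluated through the symmetrized similar form
`X̄_m^{1/2} (X̄_m^{-1/2} X̄ X̄_m^{-1/2})^{1/2} X̄_m^{-1/2}` and verified by
`E·E = X̄·X̄_m⁻¹`. The congruence is an exact isometry of the
affine-invariant metric; under the log-Euclidean default it is
approximately geometry-preserving, so transported subject means coincide
with X̄ exactly only in the affine-invariant case. One alignment pass is
performed by default (after one pass the subject means already coincide
with the population mean up to the metric discrepancy above); the pass
count is configurable.

**Feature learning.** The network alternates BiMap layers
`X ↦ W X Wᵀ` (row semi-orthogonal W, dimension N_k < N_{k−1}) and ReEig
layers `U max(εI, Λ) Uᵀ` with ε = 1e-4, ending in a P×P representation.
Defaults: 268→64→32→16 is the intended real-data schedule; the synthetic
benchmark uses 10→8→6→4. Weights are initialized as seeded random
semi-orthogonal matrices (QR of a Gaussian draw with sign-fixed R
diagonal, so initialization is unique per seed).

**Mean-shift recurrence.** The low-dimensional trajectory is collapsed
toward modes by E = 5 synchronous mean-shift layers with Gaussian kernels
of trainable bandwidths σ_e (initialized at 0.5), computed in the
log-Euclidean chart. Because consecutive exp/log maps cancel in that
chart, one layer reduces to a kernel-weighted average of log-matrices:
`L_t ← Σ_s k(g_ts) L_s / Σ_s k(g_ts)` with `k(g) = exp(−g²/2σ²)`. All
shift vectors are computed before any point moves (synchronous update).
This is the *blurring* form of mean shift — the density is re-estimated
from the moved points at each layer — which contracts clusters quickly but
also contracts the whole configuration; the trainable bandwidths exist
precisely to keep between-state gaps wide relative to σ.

**Grouping.** Stratified representations are grouped by single linkage
under the geodesic distance with threshold `tol = 0.1 × median pairwise
distance` of the stratified set (scale-free; no absolute threshold is
meaningful after contraction). Labels are renumbered by first appearance;
each mode is the Fréchet mean of its members.

**Reported state count.** Windows that straddle a state transition carry
mixtures of two covariance regimes; their representations fall between
clusters and form transient modes that can persist for up to a window's
worth of consecutive windows. The pipeline therefore distinguishes the
raw mode count (`Q_detected`, every single-linkage group) from the state
count it reports (`n_states`): the number of distinct states in the
segmentation that survives the minimum-duration rule (short segments are
merged into their predecessor, then same-label neighbours are fused).
Change points are the first window-center times of the surviving segments
after the first. The pipeline's duration floor is `max(5, w//2)` windows:
the transients it must suppress arise from the half-window ambiguity
corridor around each transition, so the floor scales with the window
rather than sitting at a fixed count. A "state" is by definition
sustained activity; the boundary modes are a property of windowing, not
of the underlying state sequence.

**Objective and training.** With stratified representations V̂_t and
geodesic distances g_tt′, the similarity is `d = 1/(1+g)` and the loss
sums over ordered pairs: same-state pairs contribute `1 − d`,
different-state pairs `max(d − α, 0)` with margin α = 0.5 (the midpoint of
d's range; configurable). Labels come either from the mode grouping itself
(self-supervised; gradients are stopped at the discrete labels, which are
recomputed every epoch) or from a known task schedule — the pretext used
when a schedule exists, as in the synthetic benchmark. Optimization is
joint over the BiMap weights (Riemannian: Euclidean gradients are
projected onto the Stiefel tangent space `G − W Gᵀ W` and the update is
retracted by QR row re-orthogonalization) and the bandwidths (softplus
reparameterized to stay positive), at learning rate 0.01.

All gradients are analytic: the loss differentiates through the pairwise
distances, the mean-shift layers (through both the averaging weights and
the kernel, including ∂/∂σ), the matrix logarithm, and the ReEig/BiMap
layers. Eigendecomposition gradients use the Daleckii–Krein / Loewner
divided-difference form; duplicate eigenvalues are perturbed by 1e-12
before the divided differences. Every piece, and the composed end-to-end
chain, matches central finite differences to ~1e-8 in the test suite.

**Gradient scale.** The pair-sum objective grows like T² in the number of
windows, so raw gradient steps at the nominal learning rate leave the
region where eigendecompositions are well conditioned. Gradients are
therefore norm-clipped per parameter block (default clip 1.0) before the
step — the update direction is exact, only its magnitude is bounded. With
more than 400 windows the pair sum is subsampled to 50,000 seeded pairs
per epoch (an unbiased estimate of the loss).

## Synthetic benchmark

The generator emulates a standard simulated-fMRI design: 10 regions, four
states, each a binary block template (three modules on the diagonal;
within-module connectivity 1, cross-module 0), 100 time points per state,
hence true change points at t = 100, 200, 300; windows of 25. Segments are
drawn i.i.d. from a zero-mean Gaussian with covariance
`λ·template_SPD + (1−λ)·I` (λ = 0.7), so the observed within-module
correlation is λ; `noise_sd` only scales amplitudes and cancels in
correlations. The four module partitions rotate block boundaries —
(3,3,4), (4,3,3), (2,5,3), (5,2,3) — so all templates are pairwise
distinct. The default bundle of 2000 series splits 900/100/1000
(train/validation/test) with per-series child seeds.

What this emulates: state-conditional second-order structure, the only
property the pipeline consumes. What it does not: haemodynamic response,
autocorrelation, events, drift, motion, spatial maps. Passing tests
therefore certify the geometry and learning machinery under clean
covariance switching, not robustness to fMRI artifacts.

Benchmark runs train on 5 series with the known schedule and evaluate on
20 held-out series — sizes chosen so a full run completes in minutes on
one CPU while leaving the training effect clearly measurable; the
protocol (train split → fit once → evaluate on held-out series) mirrors
the full-scale design. The reproduction script trains for 600 epochs,
where the recovered state count is already stable; the change-point
analysis in the test suite uses a longer 1000-epoch regime, which
sharpens transition localization.

## Spectral signatures

Per state, the Fréchet mean (not the arithmetic mean) of its
representations is eigendecomposed in descending order with a
deterministic sign convention (first nonzero eigenvector component
positive). The system energy is Σλ_i² = ‖S‖_F². The resampling
distribution of a state's energy draws 70% of its representations without
replacement, 1000 times, recomputing the mean and energy each time.
Eigenmode perturbation isolates mode i (all other modes nulled) and moves
its eigenvalue by ±δ, where δ is the per-index standard deviation of
eigenvalues across subjects; a perturbation that would cross zero is
floored at 1e-8. Perturbing the eigen*value* is our reading — a scalar δ
applied to an eigen*vector* is not well defined. Perturbed representations
are lifted back to region space by the Moore–Penrose pseudoinverse of the
composite BiMap chain (rectification layers skipped), which is exact on
the row space: re-projecting the lift returns the representation to
machine precision. Circuits keep the top 5% of off-diagonal |entries| as
edges (the thresholding rule is a convention; Table-style subnetwork
shares depend on it) and subnetwork degree shares are percentages of total
incident-edge count.

## Degenerate inputs and tie-breaks

- Zero-variance region in a window: error naming the window and region.
- Rank-deficient correlations: eigenvalue floor 1e-6 (preserves
  eigenvectors).
- Duplicate eigenvalues in backward passes: 1e-12 perturbation before the
  Loewner matrix.
- Coincident points in the loss: the pair's distance gradient is zero (the
  pair sits at its minimum), avoiding the 0/0 in the distance derivative.
- Grouping of a single window: one mode, label 0.
- Karcher non-convergence: warning, last iterate returned.

## Known limitations

- The blurring mean shift contracts the whole configuration; with
  bandwidths far above the between-state gap the recurrence merges states
  (the failure mode the trainable σ mitigates). Detection quality is
  sensitive to the bandwidth-to-separation ratio.
- Windows straddling transitions are genuinely ambiguous over a half-window
  (±w/2) corridor; change-point precision is bounded by that corridor, and
  occasional transient modes longer than the minimum duration survive as
  spurious transitions. At the benchmark's small training size (a handful
  of series) a minority of held-out series retain one such spurious
  transition; the rate falls as training series and epochs grow.
- Purity rewards over-segmentation; it is reported against the designed
  schedule and should be read together with the recovered state count.
- The self-supervised label source can reinforce a degenerate grouping if
  the initial grouping is already collapsed; with a known schedule the
  pretext is stable. This mirrors the method's reliance on task timing to
  steer resting-state learning.
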