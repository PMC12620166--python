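# Methods

This note documents the models, numerical choices and limitations behind
the package: a self-supervised, physics-informed pipeline for detecting
motion-corrupted phase-encode (PE) lines in multi-echo gradient-echo (GRE)
k-space and reconstructing T2* maps from the down-weighted data. All
empirical statements below are properties the test suite or the acceptance
script computes; none are quoted from external measurements.

## Signal model and physics-informed loss

Per voxel, the magnitude of a multi-echo GRE acquisition decays
mono-exponentially,

    s_n = s0 · exp(−TE_n / T2*),   n = 1 … N,

with `s0` the extrapolated magnitude at TE = 0. Fitting is **log-linear**:
ordinary least squares of `log(max(s_n, ε))` on TE, with
`ε = 1e-6 × (volume maximum)` flooring the logarithm. The choice of
log-linear over nonlinear least squares is deliberate: the solution is a
fixed linear map (a hat matrix) applied to the log-signal, so the fit is
closed-form, fast, and differentiable with respect to the input
magnitudes — a requirement, because the fit sits *inside* the detection
loss. T2* maps are clamped to [1, 1000] ms only on export; the fit itself
is unclamped so gradients never die. Degenerate voxels (all-zero signal,
non-negative slope) are flagged invalid and set to the clamp maximum
rather than raising.

Motion changes the head's position relative to the B0 field; the induced
field change perturbs the echo-wise decay away from mono-exponentiality.
The **physics-informed loss** measures this voxelwise as

    L_phys = 1 − corr(s_rec, s_fit),

the empirical correlation across echoes between the reconstructed
magnitudes and their own mono-exponential fit, averaged over brain-mask
voxels. The fit is recomputed at every optimization step (it is part of
the differentiable graph). Voxels with zero variance across echoes are
*excluded from the average* rather than assigned zero loss — assigning
zero would reward reconstructions that wipe out signal. The loss is
scale-free (correlation is invariant to positive rescaling) and bounded in
[0, 2].

## Forward model and motion simulation

The multicoil forward model is `y = Σ_t S_t F C U_t x`: per acquisition
time, a rigid in-plane transform plus off-resonance phase
`U_t = exp(−i·κ·ω_t·TE_n) T_t R_t`, coil weighting `C`, a centered unitary
FFT and sampling of one PE line. Conventions:

* **FFT**: centered, "ortho" normalization; DC at index `N/2` for even `N`.
  This makes the adjoint equal the inverse and gives the KeepCenter
  2×2 block a well-defined location `{N/2−1, N/2}` on both axes.
* **2D multi-slice**: only in-plane rotation and translation are applied to
  slices (bilinear resampling, zero outside the FOV); through-plane
  components still count toward the displacement metric. A 2D acquisition
  cannot represent through-plane resampling without a 3D model.
* **Off-resonance phase factor** `κ`: default 2, configurable
  (`b0_phase_factor`). The conventional off-resonance phase would use
  `κ = 2π` with ω as a frequency in Hz; since ω here is in rad/s the
  package treats κ as part of the corruption model's parametrization and
  exposes it rather than fixing the convention.
* **Slice packages**: the interleaved acquisition is modeled as two
  packages; line `k` (linear ordering) of the first ('odd') package is
  acquired at `k·TR`, of the second at `(k+0.5)·TR`. The half-TR offset is
  a modeling choice — the exact intra-TR slice timing is not part of the
  model. Which 0-based slice parity belongs to which package is a flag.

Motion severity of a rigid state is the **average displacement** of a
fixed low-discrepancy set of 4096 points inside a 64-mm-radius sphere (a
head-sized ball): `mean ‖R p + t − p‖`. A pure translation evaluates to
its norm exactly; the point set is shared across calls so the metric is
deterministic. Simulation corrupts only lines whose state exceeds a
displacement threshold (default 2 mm, one voxel). The motion-coupled B0
perturbation is a Gaussian-smoothed white-noise field rescaled to a peak
amplitude (default 100 rad/s, i.e. ~16 Hz — a realistic order for
motion-induced field changes in the brain) and scaled **linearly** by
`displacement / threshold`. An earlier design capped this scaling at 1×;
the cap made every event beyond twice the threshold produce the same field
perturbation, so the physics loss saturated with amplitude and the
loss-vs-motion relationship inverted between 3 mm and 6 mm events. The
uncapped linear coupling preserves the qualitative motion–field link and
restores strict monotonicity of the loss across {1, 3, 6} mm, which the
acceptance suite checks.

Motion curves are centered on their **median-displacement state** (the
state whose average displacement is the median is composed out of all
states), so full-reference image metrics need no registration. PCA
augmentation fits principal components to a set of training curves on a
common time grid and draws `α_i ~ N(0, (scale·σ_i)²)` for the top
`ceil(0.2·N)` components (ceil resolves the ambiguity for fractional
counts); `σ_i` is the training score standard deviation.

## Unrolled reconstruction

Reconstruction starts from the zero-filled adjoint and alternates a
denoiser with a gradient-descent data-consistency (DC) step

    x ← x − η · A^H W (A x − y),

five times by default. `W` is the per-line exclusion mask expanded to a
k-space plane (soft weights allowed) — the same weights multiply the
measured k-space and the DC residual, keeping the operator consistent with
how the data were down-weighted. With unit root-sum-of-squares coil maps
the operator norm of `A^H W A` is at most one, so `η = 1` is stable; with
a full mask and identity denoiser the zero-filled adjoint is already the
fixed point.

Denoisers: `identity` (default — the whole detection loop then runs
without any training), `gaussian_smooth` (circular Gaussian applied in
k-space, exactly self-adjoint), and `cnn`, a compact trainable
convolutional denoiser (2 conv layers, 16 features, ReLU, residual
connection, real/imaginary parts of all echoes stacked as channels,
independent weights per unrolled iteration). Training minimizes the MSE
between the reconstruction of randomly variable-density-undersampled clean
data and the fully sampled image, with Adam; masks can be generated with
or without KeepCenter, and the flag used in training should match the one
used at inference.

Everything — the unrolled loop, the denoisers, the magnitude, the
log-linear fit and the correlation loss — carries hand-written
vector-Jacobian products, so the pipeline is differentiable end-to-end in
plain numpy. The test suite validates every VJP against central finite
differences on small random instances; the mask gradient agrees to ~1e-10
relative.

## Self-supervised line detection

One continuous exclusion mask per slice package ("Even/Odd") is optimized
through the frozen reconstruction by minimizing `L_phys + L_reg`, where

    L_reg = λ_reg [ (1 − mean(Ω)) + λ_center (1 − mean(Ω_central 10)) ],

with λ_reg = 0.005, λ_center = 2 and the central window `[Y/2−5, Y/2+5)`
(half-open, exactly ten lines). Optimization runs Adam at lr 0.01 for 100
epochs on batches of 20 slices drawn with replacement from the selected
subset: slices with more than 20% brain voxels and mean susceptibility
gradient below 80 μT/m (mean of the gradient map over the slice's brain
voxels), keeping the most inferior eight survivors. The batch physics loss
is the joint brain-voxel average across the batch. KeepCenter forces the
central 2×2 k-space block to weight 1 (its gradient is masked
accordingly), and the continuous masks are applied to all slices of the
matching parity at inference, without binarization.

**Parametrization.** The masks are optimized *directly* as weight vectors
projected onto the open unit interval after every Adam step (length 2Y =
184 for Y = 92). A logistic squashing of an unconstrained vector was
considered and rejected on arithmetic grounds: Adam's per-step update is
bounded by roughly the learning rate, so 100 epochs at lr 0.01 move a
parameter by at most ~1 — in squashed coordinates a weight initialized at
0.95 (θ ≈ 2.94) can only reach σ(1.94) ≈ 0.87 and can never cross the 0.5
decision threshold. In direct coordinates the same budget spans the whole
interval. Weights start at 0.95 (near keep-all).

The susceptibility-gradient map of the phantom is the in-plane gradient
magnitude of the B0 map (central finite differences, converted to μT/m
with the gyromagnetic ratio and the voxel size).

## Baselines and metrics

* **ORBA** reconstructs the same k-space under 15 independent
  variable-density masks at exclusion rate 0.5 (KeepCenter on) and averages
  the results. The variable-density law excludes line `k` with probability
  proportional to `|k − Y/2| / (Y/2)` (α = 1), renormalized to hit the
  exact exclusion count `round(rate·Y)`; the DC line is never excluded.
* **HR/QR** averages full-, half- and quarter-resolution acquisitions over
  the central half/quarter of PE lines (uniform weights by default — the
  reference weighting scheme is not specified here) and copies the full
  acquisition on peripheral lines, which is exactly why peripheral motion
  events pass through it unchanged.
* **Line-detection metrics** treat "motion-corrupted" (weight below the 0.5
  threshold, reference label 0) as the positive class: MAE on the
  continuous weights, accuracy/precision/recall at the threshold, and a
  precision-recall curve over 101 equally spaced thresholds.
* **Map metrics** are per-slice MAE (ms) and SSIM over brain voxels with
  susceptibility gradients below 100 μT/m; SSIM uses a fixed 200-ms dynamic
  range, a 7-pixel window, maps clamped to [0, 200] ms and background
  zeroed in both images.

## The digital phantom and what it does not show

The phantom is a piecewise-elliptical multi-slice "brain": a cortical
gray-matter ring (T2* 50–70 ms), white-matter interior (40–55 ms) and two
ventricular CSF regions (150–500 ms), with smooth within-compartment
variation; smooth synthetic coil maps normalized to unit RSS; a smooth B0
field whose per-slice gradient strength grows along the slice axis so the
80 μT/m selection threshold separates moderate from strong slices; and
exactly mono-exponential echoes (12 echoes, TE1 = ΔTE = 5 ms, TR =
2300 ms) under a TE-independent smooth phase. The default geometry is 92
PE lines × 64 readout samples × 8 slices × 4 coils — chosen so a full
100-epoch mask optimization runs in about 1–2 CPU minutes; the acquisition
scale (224 readout, 36 slices, 32 coils) is reachable through parameters.

What passing tests on this phantom demonstrate: the operators are correct
(adjointness, Parseval, fixed points), the gradients are exact, the loss
responds monotonically to motion amplitude, the detector recovers a known
corrupted-line set with high accuracy and improves the T2* map, and the
KeepCenter/Even-Odd mechanisms act as designed. What they do not
demonstrate: performance on real scanner data — the phantom has no
physiological noise, no partial-volume effects at 2-mm resolution, exactly
mono-exponential ground truth (so the physics loss is zero at optimum by
construction), simplified coil geometry, and motion events that are
piecewise constant rather than continuous drifts. Claims about real
acquisitions require real k-space data.

## Reduced problem sizes used by the automated checks

The acceptance suite runs entirely on the default phantom geometry. The
standard corrupted scenario is a single sustained 6-mm event covering PE
lines 15–26 of both packages (12 lines each). The objective-decrease
property is checked at 30 epochs per seed and the determinism property at
3 epochs; all other detection runs use the full 100-epoch configuration.
Denoiser-training checks run on a 32×32 phantom. These sizes are the
package's test-bed choices and are set in the test fixtures.

## Known limitations

* Through-plane motion is scored by the displacement metric but not
  resampled; strong through-plane events are therefore under-corrupted in
  simulation.
* The B0 perturbation is a single smooth in-plane field shared across
  slices and scaled per line; real motion-induced field changes are
  position-dependent in 3D and correlate with pose.
* The trainable denoiser is deliberately compact (it must train on a CPU
  in seconds); it is a stand-in architecture, not a tuned reconstruction
  network, and the detection loop does not depend on it.
* Nearest-neighbor lookup of the motion state at a line's acquisition time
  assumes the curve is sampled finely relative to TR; event boundaries can
  shift by up to half a grid step.
* HR/QR weighting is uniform; reference implementations may weight
  acquisitions by consistency, which would change its scores but not the
  peripheral-line mechanism.
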