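"""Rigid-motion curves, PCA augmentation, displacement metric and k-space corruption.

A motion curve is a time series of 6-DOF rigid states (translations in mm,
rotations in degrees about the volume center).  Severity of a single state
is summarized by the average displacement of points inside a 64-mm-radius
sphere modeling the head.  Corruption of k-space applies the motion forward
model only to phase-encode lines whose state exceeds a displacement
threshold (default 2 mm, one voxel), and couples a smooth random B0
perturbation field to the motion amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial.transform import Rotation
from scipy.stats import qmc

from .forward import (
    AcquisitionScheme,
    CoilSensitivityMaps,
    KSpaceVolume,
    RigidState,
    apply_motion_operator,
    fft2c,
    slice_indices_for_package,
    static_multicoil_kspace,
    PACKAGES,
)

__all__ = [
    "MotionCurve",
    "PCAMotionModel",
    "ReferenceMask",
    "average_displacement",
    "center_on_median_state",
    "fit_pca_motion_model",
    "pca_augment",
    "mark_corrupted_lines",
    "sample_b0_perturbation",
    "simulate_corrupted_kspace",
    "synthetic_motion_curve",
    "reference_mask_from_timings",
]

HEAD_SPHERE_RADIUS_MM = 64.0
DISPLACEMENT_THRESHOLD_MM = 2.0
_N_SPHERE_POINTS = 4096


@dataclass
class MotionCurve:
    """Strictly increasing time grid with one :class:`RigidState` per time."""

    times_s: np.ndarray
    states: list[RigidState]

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.ndim != 1 or self.times_s.size == 0:
            raise ValueError("times_s must be a non-empty vector")
        if not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times must be strictly increasing")
        if len(self.states) != self.times_s.size:
            raise ValueError("one state per time point required")

    @property
    def n_times(self) -> int:
        return self.times_s.size

    def params_matrix(self) -> np.ndarray:
        """[n_times, 6] array (tx, ty, tz, rx, ry, rz)."""
        return np.stack([s.params for s in self.states])

    def state_at(self, t: float) -> RigidState:
        """Nearest-neighbor lookup of the state at time ``t``."""
        idx = int(np.argmin(np.abs(self.times_s - t)))
        return self.states[idx]


@dataclass
class PCAMotionModel:
    """Mean curve, principal components and per-component score spread."""

    mean: np.ndarray  # [n_times * 6]
    components: np.ndarray  # [n_components, n_times * 6]
    score_std: np.ndarray  # [n_components]
    times_s: np.ndarray


@dataclass
class ReferenceMask:
    """Binary per-package line labels: 1 = motion-free, 0 = corrupted."""

    line_labels: np.ndarray
    package: str = "odd"

    def __post_init__(self) -> None:
        self.line_labels = np.asarray(self.line_labels)
        if not np.isin(self.line_labels, (0, 1)).all():
            raise ValueError("reference mask must be binary")
        self.line_labels = self.line_labels.astype(int)


# ---------------------------------------------------------------------------
# displacement metric
# ---------------------------------------------------------------------------

_SPHERE_CACHE: dict[tuple[float, int], np.ndarray] = {}


def _sphere_points(radius_mm: float, n_points: int) -> np.ndarray:
    """Fixed low-discrepancy point set inside the sphere (shared across calls)."""
    key = (radius_mm, n_points)
    if key not in _SPHERE_CACHE:
        halton = qmc.Halton(d=3, scramble=False, seed=0)
        pts = []
        while sum(len(p) for p in pts) < n_points:
            cube = halton.random(2 * n_points) * 2.0 - 1.0
            inside = cube[np.sum(cube**2, axis=1) <= 1.0]
            pts.append(inside)
        _SPHERE_CACHE[key] = np.concatenate(pts)[:n_points] * radius_mm
    return _SPHERE_CACHE[key]


def _rotation(state: RigidState) -> Rotation:
    return Rotation.from_euler("xyz", state.r, degrees=True)


def average_displacement(
    state: RigidState,
    radius_mm: float = HEAD_SPHERE_RADIUS_MM,
    n_points: int = _N_SPHERE_POINTS,
) -> float:
    """Mean displacement ``|R p + t - p|`` over points in a head-sized sphere.

    Uses a fixed quasi-uniform interior point set, so the value is
    deterministic.  A pure translation returns its Euclidean norm exactly.
    """
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    if not np.any(state.params):
        return 0.0
    if not np.any(state.r):
        return float(np.linalg.norm(state.t))
    p = _sphere_points(radius_mm, n_points)
    moved = _rotation(state).apply(p) + state.t
    return float(np.mean(np.linalg.norm(moved - p, axis=1)))


def _compose_with_inverse(state: RigidState, ref: RigidState) -> RigidState:
    """State of the relative transform ``U ∘ M^{-1}`` (ref becomes identity)."""
    R = _rotation(state)
    M = _rotation(ref)
    rel = R * M.inv()
    t_rel = state.t - rel.apply(ref.t)
    return RigidState(t=t_rel, r=rel.as_euler("xyz", degrees=True), omega=state.omega)


def center_on_median_state(curve: MotionCurve) -> MotionCurve:
    """Re-express the curve relative to its median-displacement state.

    The state whose average displacement is the median over the curve is
    composed out of every state, so that the median motion state becomes the
    identity; full-reference image metrics then need no registration.
    """
    disp = np.array([average_displacement(s) for s in curve.states])
    median_idx = int(np.argsort(disp, kind="stable")[disp.size // 2])
    ref = curve.states[median_idx]
    states = [_compose_with_inverse(s, ref) for s in curve.states]
    return MotionCurve(curve.times_s.copy(), states)


# ---------------------------------------------------------------------------
# PCA augmentation of motion curves
# ---------------------------------------------------------------------------


def _curves_matrix(curves: list[MotionCurve]) -> np.ndarray:
    t0 = curves[0].times_s
    for c in curves[1:]:
        if c.n_times != t0.size or not np.allclose(c.times_s, t0):
            raise ValueError("curves must share a common time grid")
    return np.stack([c.params_matrix().ravel() for c in curves])


def fit_pca_motion_model(curves: list[MotionCurve]) -> PCAMotionModel:
    """PCA of rigid-parameter trajectories over a set of training curves."""
    if len(curves) < 2:
        raise ValueError("at least 2 curves required")
    X = _curves_matrix(curves)
    mean = X.mean(axis=0)
    Xc = X - mean
    _, svals, vt = np.linalg.svd(Xc, full_matrices=False)
    score_std = svals / np.sqrt(max(len(curves) - 1, 1))
    return PCAMotionModel(mean=mean, components=vt, score_std=score_std,
                          times_s=curves[0].times_s.copy())


def _curve_from_vector(vec: np.ndarray, times_s: np.ndarray) -> MotionCurve:
    params = vec.reshape(times_s.size, 6)
    states = [RigidState(t=p[:3], r=p[3:]) for p in params]
    return MotionCurve(times_s.copy(), states)


def pca_augment(
    curves: list[MotionCurve],
    component_fraction: float = 0.2,
    n_out: int = 90,
    seed: int = 0,
    alpha_scale: float = 1.0,
) -> list[MotionCurve]:
    """Generate augmented motion curves from the top PCA modes.

    The largest ``ceil(component_fraction * N)`` principal components of the
    training curves are combined with random weights
    ``alpha_i ~ Normal(0, (alpha_scale * sigma_i)^2)`` and added to the mean
    curve.  Deterministic for a given seed.
    """
    model = fit_pca_motion_model(curves)
    n_comp = int(np.ceil(component_fraction * len(curves)))
    n_comp = min(n_comp, model.components.shape[0])
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_out):
        alpha = rng.normal(0.0, alpha_scale * model.score_std[:n_comp])
        vec = model.mean + alpha @ model.components[:n_comp]
        out.append(_curve_from_vector(vec, model.times_s))
    return out


# ---------------------------------------------------------------------------
# corruption bookkeeping and simulation
# ---------------------------------------------------------------------------


def mark_corrupted_lines(
    curve: MotionCurve,
    scheme: AcquisitionScheme,
    threshold_mm: float = DISPLACEMENT_THRESHOLD_MM,
) -> dict[str, ReferenceMask]:
    """Label each (line, package) as corrupted if its state moves too far.

    A line is corrupted iff the average displacement of the motion state at
    its acquisition time (nearest-neighbor lookup on the curve grid) exceeds
    ``threshold_mm``.  Returns one binary mask per package.
    """
    y = int(scheme.pe_index.max()) + 1
    masks = {}
    for pkg in PACKAGES:
        labels = np.ones(y, dtype=int)
        for i in scheme.entries_for_package(pkg):
            state = curve.state_at(scheme.time_s[i])
            if average_displacement(state) > threshold_mm:
                labels[scheme.pe_index[i]] = 0
        masks[pkg] = ReferenceMask(labels, package=pkg)
    return masks


def sample_b0_perturbation(
    shape: tuple[int, int],
    amplitude_rad_s: float,
    smoothness_vox: float = 4.0,
    seed: int = 0,
) -> np.ndarray:
    """Smooth random in-plane off-resonance field with max |omega| = amplitude.

    White noise is low-pass filtered with a Gaussian kernel of width
    ``smoothness_vox`` and rescaled; an amplitude of zero yields the zero
    field.  Deterministic for a given seed.
    """
    if amplitude_rad_s < 0:
        raise ValueError("amplitude must be non-negative")
    if amplitude_rad_s == 0:
        return np.zeros(shape)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    smooth = ndi.gaussian_filter(noise, sigma=smoothness_vox, mode="wrap")
    peak = np.abs(smooth).max()
    if peak == 0:
        return np.zeros(shape)
    return smooth * (amplitude_rad_s / peak)


@dataclass
class B0Config:
    """Motion-coupled B0 perturbation settings for the simulator."""

    amplitude_rad_s: float = 100.0
    smoothness_vox: float = 4.0
    seed: int = 0


def simulate_corrupted_kspace(
    clean_images: np.ndarray,
    csm: CoilSensitivityMaps,
    curve: MotionCurve,
    scheme: AcquisitionScheme,
    te_ms: np.ndarray,
    b0_cfg: B0Config | None = None,
    threshold_mm: float = DISPLACEMENT_THRESHOLD_MM,
    voxel_mm: float = 2.0,
    b0_phase_factor: float = 2.0,
    odd_first: bool = True,
) -> tuple[KSpaceVolume, dict[str, ReferenceMask]]:
    """Corrupt the motion-free k-space on lines whose state exceeds the threshold.

    Below-threshold lines copy the static forward model; above-threshold
    lines are re-acquired under the line's rigid state, with the B0
    perturbation field scaled linearly by ``displacement / threshold`` so
    that stronger motion also means stronger field change.  Returns the
    corrupted volume and the per-package reference masks.
    """
    x = np.asarray(clean_images, dtype=np.complex128)
    if x.ndim != 4:
        raise ValueError("clean_images must be [echo, slice, pe, ro]")
    te_ms = np.asarray(te_ms, dtype=float)
    if x.shape[0] != te_ms.size:
        raise ValueError("echo axis must match te_ms")
    if csm.csm.shape[1:] != x.shape[1:]:
        raise ValueError("csm shape does not match the image stack")
    n_echo, n_slices, pe, ro = x.shape
    y = int(scheme.pe_index.max()) + 1
    if y != pe:
        raise ValueError("scheme PE extent does not match the image stack")

    omega_field = None
    if b0_cfg is not None and b0_cfg.amplitude_rad_s > 0:
        omega_field = sample_b0_perturbation(
            (pe, ro), b0_cfg.amplitude_rad_s, b0_cfg.smoothness_vox, b0_cfg.seed
        )

    out = static_multicoil_kspace(x, csm)
    masks = {pkg: np.ones(y, dtype=int) for pkg in PACKAGES}
    for i in range(scheme.n_entries):
        state = curve.state_at(scheme.time_s[i])
        disp = average_displacement(state)
        if disp <= threshold_mm:
            continue
        pkg = str(scheme.package[i])
        line = int(scheme.pe_index[i])
        masks[pkg][line] = 0
        omega = None
        if omega_field is not None:
            omega = omega_field * (disp / threshold_mm)
        moved_state = RigidState(t=state.t, r=state.r, omega=omega)
        for s in slice_indices_for_package(n_slices, pkg, odd_first=odd_first):
            moved = np.stack(
                [
                    apply_motion_operator(
                        x[e, s], moved_state, te_ms[e], voxel_mm=voxel_mm,
                        b0_phase_factor=b0_phase_factor,
                    )
                    for e in range(n_echo)
                ]
            )
            k = fft2c(csm.csm[None, :, s] * moved[:, None])
            out[:, :, s, line, :] = k[:, :, line, :]

    volume = KSpaceVolume(out, te_ms, scheme.tr_ms)
    ref = {pkg: ReferenceMask(masks[pkg], package=pkg) for pkg in PACKAGES}
    return volume, ref


def synthetic_motion_curve(
    scan_duration_s: float,
    n_events: int,
    event_duration_s_range: tuple[float, float] = (5.0, 10.0),
    amplitude_mm: float = 3.0,
    seed: int = 0,
    dt_s: float = 0.5,
    event_times_s: list[tuple[float, float]] | None = None,
) -> MotionCurve:
    """Still baseline with short rigid motion events of a given severity.

    Events are constant rigid offsets (a random 6-DOF direction scaled so the
    peak average displacement equals ``amplitude_mm``) over non-overlapping
    intervals with random onsets and durations in the requested range.
    Passing ``event_times_s`` pins the event intervals explicitly (useful for
    constructing scenarios with known corrupted lines).  Deterministic for a
    given seed.
    """
    if n_events < 0:
        raise ValueError("n_events must be non-negative")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, scan_duration_s + dt_s / 2, dt_s)
    states: list[RigidState] = [RigidState() for _ in times]
    if n_events == 0:
        return MotionCurve(times, states)

    if event_times_s is not None:
        if len(event_times_s) != n_events:
            raise ValueError("event_times_s must match n_events")
        intervals = [tuple(map(float, iv)) for iv in event_times_s]
    else:
        intervals = []
        for _ in range(n_events):
            placed = False
            for _attempt in range(200):
                dur = rng.uniform(*event_duration_s_range)
                onset = rng.uniform(0.0, scan_duration_s - dur)
                cand = (onset, onset + dur)
                if all(cand[1] <= a or cand[0] >= b for a, b in intervals):
                    intervals.append(cand)
                    placed = True
                    break
            if not placed:
                raise ValueError("events cannot fit without overlap")
    for a, b in intervals:
        if a < 0 or b > scan_duration_s:
            raise ValueError("event interval outside the scan")

    for a, b in sorted(intervals):
        # random 6-DOF direction, rescaled to the target average displacement
        direction = rng.standard_normal(6)
        direction[3:] *= 0.5  # keep rotations moderate relative to translations
        probe = RigidState(t=direction[:3], r=direction[3:])
        d0 = average_displacement(probe)
        scale = amplitude_mm / d0 if d0 > 0 else 0.0
        state_params = direction * scale
        # displacement is not exactly linear in the rotation angle; one
        # correction step lands the peak displacement on the target
        trial = RigidState(t=state_params[:3], r=state_params[3:])
        d1 = average_displacement(trial)
        if d1 > 0:
            state_params = state_params * (amplitude_mm / d1)
        inside = (times >= a) & (times < b)
        for idx in np.flatnonzero(inside):
            states[idx] = RigidState(t=state_params[:3], r=state_params[3:])
    return MotionCurve(times, states)


def reference_mask_from_timings(
    intervals_s: list[tuple[float, float]],
    scheme: AcquisitionScheme,
) -> dict[str, ReferenceMask]:
    """Convert motion-event time intervals into per-package line masks.

    A line is corrupted iff its acquisition time falls inside any interval
    (half-open ``[start, end)``).
    """
    for a, b in intervals_s:
        if a < 0 or b > scheme.scan_duration_s:
            raise ValueError("interval outside the scan duration")
    y = int(scheme.pe_index.max()) + 1
    masks = {}
    for pkg in PACKAGES:
        labels = np.ones(y, dtype=int)
        for i in scheme.entries_for_package(pkg):
            t = scheme.time_s[i]
            if any(a <= t < b for a, b in intervals_s):
                labels[scheme.pe_index[i]] = 0
        masks[pkg] = ReferenceMask(labels, package=pkg)
    return masks
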