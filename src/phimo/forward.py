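"""Data model and motion-aware multicoil MRI forward/adjoint operators.

Conventions
-----------
* k-space arrays are indexed ``[echo, coil, slice, pe, ro]``.
* Fourier transforms are centered and unitary ("ortho"): the DC sample of an
  even-sized plane sits at index ``N//2`` along each axis, and the adjoint of
  the forward FFT equals its inverse.
* 2D multi-slice data only support in-plane rigid motion (rotation about the
  slice center plus in-plane translation); through-plane components enter the
  displacement metric but not the image transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "KSpaceVolume",
    "CoilSensitivityMaps",
    "RigidState",
    "AcquisitionScheme",
    "ExclusionMask",
    "fft2c",
    "ifft2c",
    "apply_motion_operator",
    "static_multicoil_kspace",
    "forward_acquire",
    "adjoint_reconstruct",
    "expand_mask_keepcenter",
    "variable_density_line_mask",
    "acquisition_times",
    "slice_indices_for_package",
]

PACKAGES = ("odd", "even")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class KSpaceVolume:
    """Complex multi-echo multicoil k-space with acquisition metadata.

    Parameters
    ----------
    data:
        Complex samples, shape ``[echo, coil, slice, pe, ro]``.
    te_ms:
        Echo times in milliseconds, strictly increasing, one per echo.
    tr_ms:
        Repetition time in milliseconds.
    """

    data: np.ndarray
    te_ms: np.ndarray
    tr_ms: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        self.te_ms = np.asarray(self.te_ms, dtype=float)
        if self.data.ndim != 5:
            raise ValueError("k-space data must be [echo, coil, slice, pe, ro]")
        if self.data.shape[0] != self.te_ms.size:
            raise ValueError("number of echoes must equal length of te_ms")
        if self.te_ms.size > 1 and not np.all(np.diff(self.te_ms) > 0):
            raise ValueError("te_ms must be strictly increasing")
        if not np.all(np.isfinite(self.data.view(float))):
            raise ValueError("k-space contains non-finite values")
        if self.pe_size % 2 or self.ro_size % 2:
            raise ValueError("pe and ro sizes must be even")

    @property
    def n_echoes(self) -> int:
        return self.data.shape[0]

    @property
    def n_coils(self) -> int:
        return self.data.shape[1]

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    @property
    def pe_size(self) -> int:
        return self.data.shape[3]

    @property
    def ro_size(self) -> int:
        return self.data.shape[4]


@dataclass
class CoilSensitivityMaps:
    """Complex coil sensitivity maps ``[coil, slice, pe, ro]``.

    Normalized on construction so the voxelwise root-sum-of-squares over
    coils equals one wherever any coil has signal.
    """

    csm: np.ndarray

    def __post_init__(self) -> None:
        csm = np.asarray(self.csm, dtype=np.complex128)
        if csm.ndim != 4:
            raise ValueError("csm must be [coil, slice, pe, ro]")
        rss = np.sqrt(np.sum(np.abs(csm) ** 2, axis=0, keepdims=True))
        safe = np.where(rss > 0, rss, 1.0)
        self.csm = csm / safe

    @property
    def n_coils(self) -> int:
        return self.csm.shape[0]


@dataclass
class RigidState:
    """One 6-DOF rigid motion state, optionally with a B0 perturbation.

    ``t`` is the translation (tx, ty, tz) in mm; ``r`` the rotation
    (rx, ry, rz) in degrees about the volume center.  ``omega`` is an
    optional in-plane off-resonance field in rad/s, applied as the phase
    ``exp(-i * b0_phase_factor * omega * TE)`` after the rigid resampling.
    """

    t: np.ndarray = field(default_factory=lambda: np.zeros(3))
    r: np.ndarray = field(default_factory=lambda: np.zeros(3))
    omega: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.t.shape != (3,) or self.r.shape != (3,):
            raise ValueError("t and r must be length-3 vectors")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.r))):
            raise ValueError("rigid parameters must be finite")
        if self.omega is not None:
            self.omega = np.asarray(self.omega, dtype=float)
            if self.omega.ndim != 2:
                raise ValueError("omega must be an in-plane 2D field")

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.t, self.r])

    def is_identity(self, tol: float = 0.0) -> bool:
        rigid = np.all(np.abs(self.params) <= tol)
        return bool(rigid and (self.omega is None or not np.any(self.omega)))


@dataclass
class AcquisitionScheme:
    """Ordered PE-line acquisition entries for the two slice packages.

    Each entry is one phase-encode line of one package, acquired at
    ``time_s``.  Within a TR all echoes of that line are read out; the odd
    and even slice packages are interleaved with a fixed intra-TR offset.
    """

    pe_index: np.ndarray
    package: np.ndarray  # array of 'odd'/'even' strings, aligned with pe_index
    time_s: np.ndarray
    tr_ms: float
    scan_duration_s: float

    def __post_init__(self) -> None:
        self.pe_index = np.asarray(self.pe_index, dtype=int)
        self.package = np.asarray(self.package, dtype=object)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if not (self.pe_index.size == self.package.size == self.time_s.size):
            raise ValueError("scheme arrays must be aligned")
        pairs = list(zip(self.pe_index.tolist(), self.package.tolist()))
        if len(set(pairs)) != len(pairs):
            raise ValueError("each (pe_index, package) pair must appear exactly once")
        for pkg in PACKAGES:
            t = self.time_s[self.package == pkg]
            if t.size and not np.all(np.diff(t[np.argsort(t)]) > 0):
                raise ValueError(f"times must be strictly increasing within package {pkg!r}")
        if np.any(self.time_s < 0) or np.any(self.time_s > self.scan_duration_s):
            raise ValueError("times must lie in [0, scan_duration_s]")

    @property
    def n_entries(self) -> int:
        return self.pe_index.size

    def entries_for_package(self, package: str) -> np.ndarray:
        """Indices of entries belonging to ``package``."""
        return np.flatnonzero(self.package == package)


@dataclass
class ExclusionMask:
    """Per-PE-line weights in [0, 1]; 1 keeps the line, 0 excludes it."""

    line_weights: np.ndarray
    package: str = "odd"

    def __post_init__(self) -> None:
        self.line_weights = np.asarray(self.line_weights, dtype=float)
        if self.line_weights.ndim != 1:
            raise ValueError("line_weights must be a vector")
        if np.any(self.line_weights < 0) or np.any(self.line_weights > 1):
            raise ValueError("line weights must lie in [0, 1]")

    @property
    def n_lines(self) -> int:
        return self.line_weights.size


# ---------------------------------------------------------------------------
# centered unitary FFT
# ---------------------------------------------------------------------------


def fft2c(image_plane: np.ndarray) -> np.ndarray:
    """Centered unitary 2D FFT over the last two axes (DC at ``N//2``)."""
    x = np.asarray(image_plane)
    if not np.all(np.isfinite(x.view(float) if np.iscomplexobj(x) else x)):
        raise ValueError("non-finite input to fft2c")
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def ifft2c(kspace_plane: np.ndarray) -> np.ndarray:
    """Inverse (and adjoint) of :func:`fft2c`."""
    y = np.asarray(kspace_plane)
    if not np.all(np.isfinite(y.view(float) if np.iscomplexobj(y) else y)):
        raise ValueError("non-finite input to ifft2c")
    return np.fft.ifftshift(
        np.fft.ifft2(np.fft.fftshift(y, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


# ---------------------------------------------------------------------------
# in-plane rigid motion operator
# ---------------------------------------------------------------------------

_INTERP_ORDERS = {"bilinear": 1, "nearest": 0}


def _inplane_affine(shape: tuple[int, int], state: RigidState, voxel_mm: float):
    """Matrix/offset mapping output to input coordinates for (T R x)."""
    pe, ro = shape
    center = np.array([(pe - 1) / 2.0, (ro - 1) / 2.0])
    theta = np.deg2rad(state.r[2])
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])  # rotation in the (pe, ro) plane
    # translation in pixels: ty moves along pe (rows), tx along ro (cols)
    t_pix = np.array([state.t[1], state.t[0]]) / voxel_mm
    inv = rot.T
    offset = center - inv @ (center + t_pix)
    return inv, offset


def apply_motion_operator(
    image_plane: np.ndarray,
    state: RigidState,
    te_ms: float,
    voxel_mm: float = 2.0,
    interp: str = "bilinear",
    b0_phase_factor: float = 2.0,
) -> np.ndarray:
    """Apply the per-state motion transform U to one image plane.

    Performs the in-plane rigid resampling ``T R x`` followed by the
    off-resonance phase ``exp(-i * b0_phase_factor * omega * TE)``.  The
    default ``b0_phase_factor`` of 2 follows the forward-model convention of
    the motion-corruption formulation; set it to ``2 * np.pi`` to interpret
    ``omega`` as a frequency offset in Hz scaled by 2π.
    """
    if interp not in _INTERP_ORDERS:
        raise ValueError(f"unsupported interpolation scheme {interp!r}")
    x = np.asarray(image_plane, dtype=np.complex128)
    if x.ndim != 2:
        raise ValueError("image plane must be 2D")
    if state.is_identity():
        return x.copy()
    if np.any(state.t[:2]) or state.r[2] != 0.0:
        matrix, offset = _inplane_affine(x.shape, state, voxel_mm)
        order = _INTERP_ORDERS[interp]
        re = ndimage.affine_transform(x.real, matrix, offset=offset, order=order, cval=0.0)
        im = ndimage.affine_transform(x.imag, matrix, offset=offset, order=order, cval=0.0)
        x = re + 1j * im
    if state.omega is not None and np.any(state.omega):
        if state.omega.shape != x.shape:
            raise ValueError("omega shape must match the image plane")
        te_s = float(te_ms) * 1e-3
        x = np.exp(-1j * b0_phase_factor * state.omega * te_s) * x
    return x


# ---------------------------------------------------------------------------
# multicoil forward / adjoint
# ---------------------------------------------------------------------------


def static_multicoil_kspace(image_stack: np.ndarray, csm: CoilSensitivityMaps) -> np.ndarray:
    """Motion-free multicoil k-space ``F(C x)``, shape [echo, coil, slice, pe, ro]."""
    x = np.asarray(image_stack, dtype=np.complex128)
    return fft2c(csm.csm[None] * x[:, None])


def adjoint_reconstruct(kspace: np.ndarray, csm: CoilSensitivityMaps) -> np.ndarray:
    """Adjoint ``C^H F^H y``: coil-combined zero-filled reconstruction."""
    return np.sum(np.conj(csm.csm)[None] * ifft2c(kspace), axis=1)


def slice_indices_for_package(n_slices: int, package: str, odd_first: bool = True) -> np.ndarray:
    """Slice indices belonging to one interleaved package (0-based parity).

    With ``odd_first`` (default) the 'odd' package holds slices 0, 2, 4, …
    (first package acquired), matching a two-package interleaved multi-slice
    acquisition; flip the flag to invert the labeling.
    """
    if package not in PACKAGES:
        raise ValueError(f"unknown package {package!r}")
    first = "odd" if odd_first else "even"
    start = 0 if package == first else 1
    return np.arange(start, n_slices, 2)


def forward_acquire(
    image_stack: np.ndarray,
    csm: CoilSensitivityMaps,
    scheme: AcquisitionScheme,
    states_per_time: list[RigidState],
    te_ms: np.ndarray,
    voxel_mm: float = 2.0,
    b0_phase_factor: float = 2.0,
    odd_first: bool = True,
) -> KSpaceVolume:
    """Motion-aware acquisition: sum over time of ``S_t F C U_t x``.

    Each scheme entry contributes one PE line of every slice in its package,
    transformed by that entry's rigid state (with the echo-time-dependent
    off-resonance phase), coil-weighted and Fourier transformed.  Summing
    over entries covers every (line, package) pair exactly once.
    """
    x = np.asarray(image_stack, dtype=np.complex128)
    if x.ndim != 4:
        raise ValueError("image_stack must be [echo, slice, pe, ro]")
    if len(states_per_time) != scheme.n_entries:
        raise ValueError("one RigidState required per scheme entry")
    te_ms = np.asarray(te_ms, dtype=float)
    n_echo, n_slices, pe, ro = x.shape
    n_coil = csm.n_coils
    out = np.zeros((n_echo, n_coil, n_slices, pe, ro), dtype=np.complex128)

    static_k = static_multicoil_kspace(x, csm)
    for i in range(scheme.n_entries):
        line = int(scheme.pe_index[i])
        pkg = str(scheme.package[i])
        state = states_per_time[i]
        slices = slice_indices_for_package(n_slices, pkg, odd_first=odd_first)
        if state.is_identity():
            out[:, :, slices, line, :] = static_k[:, :, slices, line, :]
            continue
        for s in slices:
            moved = np.stack(
                [
                    apply_motion_operator(
                        x[e, s], state, te_ms[e], voxel_mm=voxel_mm,
                        b0_phase_factor=b0_phase_factor,
                    )
                    for e in range(n_echo)
                ]
            )
            k = fft2c(csm.csm[None, :, s] * moved[:, None])
            out[:, :, s, line, :] = k[:, :, line, :]
    tr_ms = scheme.tr_ms
    return KSpaceVolume(out, te_ms, tr_ms)


# ---------------------------------------------------------------------------
# masks and timing
# ---------------------------------------------------------------------------


def expand_mask_keepcenter(
    mask: ExclusionMask, ro_size: int, keepcenter: bool = True
) -> np.ndarray:
    """Broadcast line weights along readout; optionally force the 2x2 DC block.

    With KeepCenter, the four samples around the k-space center (indices
    ``{Y/2-1, Y/2} x {ro/2-1, ro/2}``) are set to 1 regardless of the line
    weights, preserving the mean image intensity when central lines are
    excluded.
    """
    y = mask.n_lines
    if y % 2 or ro_size % 2:
        raise ValueError("pe and ro sizes must be even")
    plane = np.repeat(mask.line_weights[:, None], ro_size, axis=1)
    if keepcenter:
        plane[y // 2 - 1 : y // 2 + 1, ro_size // 2 - 1 : ro_size // 2 + 1] = 1.0
    return plane


def variable_density_line_mask(
    Y: int,
    exclusion_rate: float,
    seed: int | np.random.Generator = 0,
    keepcenter: bool = True,
    alpha: float = 1.0,
) -> ExclusionMask:
    """Random binary line mask excluding ``round(rate * Y)`` lines.

    The probability of excluding a line grows from the k-space center to the
    periphery as ``(|k_pe| / (Y/2)) ** alpha``, so central (contrast-bearing)
    lines are rarely dropped.  Exactly the requested count is excluded;
    deterministic for a given seed.  The ``keepcenter`` flag is metadata used
    when the mask is expanded to a 2D weight plane.
    """
    if not 0 <= exclusion_rate < 1:
        raise ValueError("exclusion_rate must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_excl = int(round(exclusion_rate * Y))
    weights = np.ones(Y)
    if n_excl:
        k_offset = np.abs(np.arange(Y) - Y // 2) / (Y / 2)
        p = k_offset**alpha
        p = p / p.sum()
        excl = rng.choice(Y, size=n_excl, replace=False, p=p)
        weights[excl] = 0.0
    mask = ExclusionMask(weights)
    mask.keepcenter = keepcenter
    return mask


def acquisition_times(
    Y: int,
    tr_ms: float,
    ordering: str = "linear",
    package_offset_fraction: float = 0.5,
) -> AcquisitionScheme:
    """Acquisition schedule for an interleaved two-package 2D GRE sequence.

    Line ``k`` (in acquisition order) of package ``p`` is acquired at
    ``(k + offset_p) * TR`` with ``offset_odd = 0`` and
    ``offset_even = package_offset_fraction`` (the even slice package is
    excited half a TR after the odd one under the default).  The scan lasts
    ``Y * TR``.
    """
    if Y <= 0:
        raise ValueError("Y must be positive")
    if ordering != "linear":
        raise ValueError(f"unknown ordering {ordering!r}")
    tr_s = tr_ms * 1e-3
    order = np.arange(Y)
    pe = np.concatenate([order, order])
    pkg = np.array(["odd"] * Y + ["even"] * Y, dtype=object)
    times = np.concatenate([order * tr_s, (order + package_offset_fraction) * tr_s])
    return AcquisitionScheme(pe, pkg, times, tr_ms, scan_duration_s=Y * tr_s)
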