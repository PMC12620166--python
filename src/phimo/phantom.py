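"""Digital multi-echo brain phantom.

Generates a piecewise-elliptical multi-slice "brain" with white-matter,
cortical gray-matter and ventricular CSF compartments, per-voxel s0 and T2*
maps, smooth synthetic coil sensitivities (unit root-sum-of-squares), a
smooth B0 field whose in-plane gradient magnitude gives the susceptibility
gradient map, exactly mono-exponential multi-echo images and the matching
static multicoil k-space.  All structures are deterministic for a given
seed.

The default geometry (92 phase-encode lines, 64 readout samples, 8 slices,
12 echoes with TE1 = ΔTE = 5 ms, TR = 2300 ms, 4 coils) keeps the full
detection loop in CPU minutes while preserving the acquisition's echo train
and PE extent; larger geometries are reachable through the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .forward import (
    AcquisitionScheme,
    CoilSensitivityMaps,
    KSpaceVolume,
    acquisition_times,
    static_multicoil_kspace,
)
from .relaxometry import predict_signal

__all__ = ["PhantomDataset", "make_digital_phantom", "GAMMA_RAD_PER_S_PER_T"]

GAMMA_RAD_PER_S_PER_T = 2.675e8  # proton gyromagnetic ratio

# design tissue values (ms / a.u.); ranges are plausible for 3T brain
_TISSUE = {
    "wm": {"t2star": (40.0, 55.0), "s0": 100.0},
    "gm": {"t2star": (50.0, 70.0), "s0": 120.0},
    "csf": {"t2star": (150.0, 500.0), "s0": 160.0},
}


@dataclass
class PhantomDataset:
    """Ground-truth maps, coil maps, clean images and clean k-space."""

    s0_map: np.ndarray  # [slice, pe, ro], a.u.
    t2star_map: np.ndarray  # [slice, pe, ro], ms
    b0_map: np.ndarray  # [slice, pe, ro], rad/s
    csm: CoilSensitivityMaps
    brain_mask: np.ndarray  # [slice, pe, ro], bool
    sg_map: np.ndarray  # [slice, pe, ro], μT/m
    clean_images: np.ndarray  # [echo, slice, pe, ro], complex
    clean_kspace: KSpaceVolume
    te_ms: np.ndarray
    tr_ms: float
    voxel_mm: float
    seed: int

    @property
    def n_slices(self) -> int:
        return self.s0_map.shape[0]

    @property
    def pe_size(self) -> int:
        return self.s0_map.shape[1]

    @property
    def ro_size(self) -> int:
        return self.s0_map.shape[2]

    def scheme(self, **kwargs) -> AcquisitionScheme:
        """Acquisition schedule matching this phantom's PE extent and TR."""
        return acquisition_times(self.pe_size, self.tr_ms, **kwargs)


def _ellipse(pe: int, ro: int, cy: float, cx: float, ay: float, ax: float,
             tilt_deg: float = 0.0) -> np.ndarray:
    yy, xx = np.mgrid[0:pe, 0:ro]
    y = yy - cy
    x = xx - cx
    th = np.deg2rad(tilt_deg)
    yr = np.cos(th) * y + np.sin(th) * x
    xr = -np.sin(th) * y + np.cos(th) * x
    return (yr / ay) ** 2 + (xr / ax) ** 2 <= 1.0


def _smooth_field(shape, rng, sigma) -> np.ndarray:
    f = ndi.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def make_digital_phantom(
    pe: int = 92,
    ro: int = 64,
    n_slices: int = 8,
    n_echoes: int = 12,
    te1_ms: float = 5.0,
    dte_ms: float = 5.0,
    tr_ms: float = 2300.0,
    n_coils: int = 4,
    voxel_mm: float = 2.0,
    seed: int = 0,
) -> PhantomDataset:
    """Build the deterministic digital brain phantom.

    Tissue T2* values are drawn per slice inside the compartment ranges
    (WM 40-55 ms, GM 50-70 ms, CSF 150-500 ms) with smooth within-compartment
    variation; the clean echo images follow the mono-exponential decay
    exactly, modulated by a TE-independent smooth phase, and the clean
    k-space is the static multicoil forward model of those images.
    """
    if pe % 2 or ro % 2:
        raise ValueError("pe and ro must be even")
    if n_echoes < 3:
        raise ValueError("need at least 3 echoes")
    if min(n_slices, n_coils) < 1 or te1_ms <= 0 or dte_ms <= 0 or tr_ms <= 0:
        raise ValueError("invalid phantom geometry")
    rng = np.random.default_rng(seed)
    te_ms = te1_ms + dte_ms * np.arange(n_echoes)

    s0 = np.zeros((n_slices, pe, ro))
    t2 = np.zeros((n_slices, pe, ro))
    brain = np.zeros((n_slices, pe, ro), dtype=bool)
    b0 = np.zeros((n_slices, pe, ro))

    cy, cx = (pe - 1) / 2, (ro - 1) / 2
    for s in range(n_slices):
        # brain extent varies along the slice direction (small at both ends)
        frac = 0.55 + 0.25 * np.sin(np.pi * (s + 1) / (n_slices + 1))
        ay, ax = frac * (pe / 2 - 2), frac * (ro / 2 - 2)
        outer = _ellipse(pe, ro, cy, cx, ay, ax)
        inner = _ellipse(pe, ro, cy, cx, 0.78 * ay, 0.78 * ax)
        vent_l = _ellipse(pe, ro, cy - 0.15 * ay, cx - 0.22 * ax, 0.22 * ay, 0.12 * ax, 15)
        vent_r = _ellipse(pe, ro, cy - 0.15 * ay, cx + 0.22 * ax, 0.22 * ay, 0.12 * ax, -15)
        csf = (vent_l | vent_r) & inner
        gm = outer & ~inner
        wm = inner & ~csf

        def _draw(lo_hi):
            return rng.uniform(*lo_hi)

        t2_slice = np.zeros((pe, ro))
        s0_slice = np.zeros((pe, ro))
        for region, name in ((wm, "wm"), (gm, "gm"), (csf, "csf")):
            base_t2 = _draw(_TISSUE[name]["t2star"])
            lo, hi = _TISSUE[name]["t2star"]
            wiggle = 0.15 * (hi - lo) * _smooth_field((pe, ro), rng, sigma=6)
            t2_slice[region] = np.clip(base_t2 + wiggle[region], lo, hi)
            s0_slice[region] = _TISSUE[name]["s0"] * (1.0 + 0.05 * wiggle[region] / max(hi - lo, 1))
        t2[s] = t2_slice
        s0[s] = s0_slice
        brain[s] = outer

        # smooth B0 with gradients growing along the slice direction; the
        # resulting mean susceptibility gradients span roughly 10-100 μT/m
        # so the slice-selection threshold separates moderate from strong
        amp = 180.0 * (1.0 + 1.0 * s)  # rad/s variation scale
        low = _smooth_field((pe, ro), rng, sigma=5)
        ramp = 0.5 * ((np.arange(pe)[:, None] - cy) / pe + (np.arange(ro)[None, :] - cx) / ro)
        b0[s] = amp * (low + ramp)

    # susceptibility-gradient map: in-plane |∇B| in μT/m
    voxel_m = voxel_mm * 1e-3
    sg = np.zeros_like(b0)
    for s in range(n_slices):
        gy, gx = np.gradient(b0[s] / GAMMA_RAD_PER_S_PER_T, voxel_m)
        sg[s] = np.hypot(gy, gx) * 1e6

    # smooth synthetic coil sensitivities, unit RSS after normalization
    yy, xx = np.mgrid[0:pe, 0:ro]
    centers = [
        (0.2 * pe, 0.2 * ro), (0.2 * pe, 0.8 * ro),
        (0.8 * pe, 0.2 * ro), (0.8 * pe, 0.8 * ro),
        (0.5 * pe, 0.1 * ro), (0.5 * pe, 0.9 * ro),
        (0.1 * pe, 0.5 * ro), (0.9 * pe, 0.5 * ro),
    ]
    csm = np.zeros((n_coils, n_slices, pe, ro), dtype=complex)
    for c in range(n_coils):
        my, mx = centers[c % len(centers)]
        mag = np.exp(-(((yy - my) / (0.7 * pe)) ** 2 + ((xx - mx) / (0.7 * ro)) ** 2))
        phase = 2 * np.pi * (0.1 * (c + 1) * (xx / ro) + 0.07 * (c + 1) * (yy / pe))
        for s in range(n_slices):
            csm[c, s] = (mag + 0.05) * np.exp(1j * phase)
    coil_maps = CoilSensitivityMaps(csm)

    # mono-exponential echoes with a TE-independent smooth phase
    safe_t2 = np.where(brain, t2, 1.0)
    mags = predict_signal(np.where(brain, s0, 0.0), safe_t2, te_ms)
    static_phase = np.stack([0.3 * _smooth_field((pe, ro), rng, sigma=10) for _ in range(n_slices)])
    images = mags * np.exp(1j * static_phase)[None]

    kspace = KSpaceVolume(static_multicoil_kspace(images, coil_maps), te_ms, tr_ms)
    return PhantomDataset(
        s0_map=np.where(brain, s0, 0.0),
        t2star_map=np.where(brain, t2, 0.0),
        b0_map=b0,
        csm=coil_maps,
        brain_mask=brain,
        sg_map=sg,
        clean_images=images,
        clean_kspace=kspace,
        te_ms=te_ms,
        tr_ms=tr_ms,
        voxel_mm=voxel_mm,
        seed=seed,
    )
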