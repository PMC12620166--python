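"""Canonical synthetic study conditions used by tests, scripts and the CLI.

The standard corrupted-phantom scenario holds the motion timing fixed — a
single sustained event covering twelve consecutive mid-frequency PE lines in
both slice packages — while the event amplitude (average displacement in mm)
and the motion-coupled B0 perturbation are parameters.  Because the timing
is pinned, the set of corrupted lines is known exactly and line-detection
metrics are well defined.
"""

from __future__ import annotations

from .forward import AcquisitionScheme, KSpaceVolume
from .motion import (
    B0Config,
    MotionCurve,
    ReferenceMask,
    simulate_corrupted_kspace,
    synthetic_motion_curve,
)
from .phantom import PhantomDataset, make_digital_phantom

__all__ = ["standard_corruption_scenario", "corrupt_phantom"]

DEFAULT_EVENT_LINES = (15, 27)  # half-open PE-line range of the standard event
DEFAULT_B0_AMPLITUDE_RAD_S = 100.0


def corrupt_phantom(
    phantom: PhantomDataset,
    curve: MotionCurve,
    scheme: AcquisitionScheme | None = None,
    b0_amplitude_rad_s: float = DEFAULT_B0_AMPLITUDE_RAD_S,
    b0_seed: int = 0,
) -> tuple[KSpaceVolume, dict[str, ReferenceMask]]:
    """Apply a motion curve to a phantom's clean data."""
    scheme = scheme or phantom.scheme()
    b0_cfg = B0Config(amplitude_rad_s=b0_amplitude_rad_s, seed=b0_seed)
    return simulate_corrupted_kspace(
        phantom.clean_images, phantom.csm, curve, scheme, phantom.te_ms,
        b0_cfg=b0_cfg, voxel_mm=phantom.voxel_mm,
    )


def standard_corruption_scenario(
    seed: int = 0,
    amplitude_mm: float = 6.0,
    event_lines: tuple[int, int] = DEFAULT_EVENT_LINES,
    b0_amplitude_rad_s: float = DEFAULT_B0_AMPLITUDE_RAD_S,
    phantom: PhantomDataset | None = None,
):
    """Phantom + single-event corruption with a known set of corrupted lines.

    The event interval is aligned with the acquisition schedule so that the
    PE lines ``event_lines[0] .. event_lines[1]-1`` of both packages (and no
    others) are corrupted.  Returns ``(phantom, scheme, curve, corrupted
    k-space, reference masks)``.
    """
    ph = phantom if phantom is not None else make_digital_phantom(seed=seed)
    scheme = ph.scheme()
    tr_s = ph.tr_ms * 1e-3
    lo, hi = event_lines
    # cover the odd package times [lo*TR, (hi-1)*TR] and the even package
    # times offset by TR/2, with margins clear of the curve's grid points
    t0 = lo * tr_s - 0.01
    t1 = (hi - 1 + 0.5) * tr_s + 0.1
    curve = synthetic_motion_curve(
        scheme.scan_duration_s, 1, amplitude_mm=amplitude_mm, seed=seed + 3,
        event_times_s=[(t0, t1)],
    )
    kspace, ref = corrupt_phantom(ph, curve, scheme, b0_amplitude_rad_s, b0_seed=seed)
    return ph, scheme, curve, kspace, ref
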