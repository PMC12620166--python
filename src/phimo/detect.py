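"""Self-supervised optimization of Even/Odd k-space exclusion masks.

One continuous exclusion mask per interleaved slice package is optimized by
minimizing the physics-informed loss (one minus the echo-wise correlation
between the reconstruction and its own mono-exponential fit) plus a
regularizer that discourages excluding lines, with a stronger penalty on the
ten central lines.  The reconstruction weights stay frozen; gradients flow
through the k-space multiplication, the data-consistency weights, the
unrolled reconstruction, the magnitude and the differentiable log-linear
fit, all via hand-written vector-Jacobian products.

Masks are parametrized directly as a vector of length ``2Y`` holding the
line weights themselves, initialized near keep-all and projected onto the
open unit interval after every update; they are returned without
binarization.  With Adam's per-step update bounded by the learning rate,
this direct parametrization lets a weight traverse the whole unit interval
within ``lr * epochs = 0.01 * 100``, which a saturating squashing would not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import (
    CoilSensitivityMaps,
    ExclusionMask,
    KSpaceVolume,
    expand_mask_keepcenter,
    slice_indices_for_package,
)
from .recon import (
    AdamOptimizer,
    UnrolledConfig,
    make_denoisers,
    normalize_volume,
    _unrolled_forward,
    _unrolled_vjp,
)
from .relaxometry import DecayStack, physics_loss_and_grad

__all__ = [
    "MaskParameters",
    "DetectConfig",
    "exclusion_regularizer",
    "select_optimization_slices",
    "selected_slices_for_volume",
    "optimize_exclusion_masks",
    "masks_for_all_slices",
]


_WEIGHT_EPS = 1e-4  # projection margin keeping weights in the open interval


@dataclass
class MaskParameters:
    """Directly optimized parameters for the two per-package line masks.

    The vector has length ``2Y`` (one mask of ``Y`` lines per slice
    package) and holds the mask weights themselves; :meth:`project` clips
    them back into the open unit interval after a gradient update.  The
    default initialization puts every weight at 0.95 (near keep-all).
    """

    theta: np.ndarray

    @classmethod
    def init(cls, Y: int, initial_weight: float = 0.95) -> "MaskParameters":
        if not 0 < initial_weight < 1:
            raise ValueError("initial_weight must lie in (0, 1)")
        return cls(np.full(2 * Y, float(initial_weight)))

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 1 or self.theta.size % 2:
            raise ValueError("theta must be a vector of length 2Y")

    @property
    def n_lines(self) -> int:
        return self.theta.size // 2

    def project(self) -> None:
        np.clip(self.theta, _WEIGHT_EPS, 1.0 - _WEIGHT_EPS, out=self.theta)

    def weights(self) -> np.ndarray:
        """Mask weights in (0, 1), shape [2, Y] (row 0: even slices' package)."""
        return self.theta.reshape(2, self.n_lines).copy()


@dataclass
class DetectConfig:
    """Hyperparameters of the mask optimization."""

    lr: float = 0.01
    epochs: int = 100
    batch_slices: int = 20
    lambda_reg: float = 0.005
    lambda_center: float = 2.0
    sg_threshold: float = 80.0  # μT/m
    brain_fraction_min: float = 0.20
    n_select_slices: int = 8
    keepcenter: bool = True
    initial_weight: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lr, self.epochs, self.batch_slices, self.lambda_reg,
               self.sg_threshold, self.n_select_slices) <= 0:
            raise ValueError("config values must be positive")
        if self.lambda_center < 0:
            raise ValueError("lambda_center must be non-negative")


def _central_window(Y: int) -> slice:
    # ten central lines, half-open [Y/2 - 5, Y/2 + 5)
    return slice(Y // 2 - 5, Y // 2 + 5)


def exclusion_regularizer(
    mask_weights: np.ndarray,
    lambda_reg: float = 0.005,
    lambda_center: float = 2.0,
    Y: int | None = None,
) -> float:
    """Penalty against excluding lines, stronger on the ten central lines.

    ``L = lambda_reg * [(1 - mean(all lines)) + lambda_center * (1 - mean(central 10))]``
    """
    w = np.asarray(mask_weights, dtype=float)
    Y = w.size if Y is None else Y
    if w.size != Y:
        raise ValueError("mask length must equal Y")
    if Y < 10 or Y % 2:
        raise ValueError("Y must be even and at least 10")
    center = w[_central_window(Y)]
    return float(lambda_reg * ((1.0 - w.mean()) + lambda_center * (1.0 - center.mean())))


def _regularizer_grad(w: np.ndarray, lambda_reg: float, lambda_center: float) -> np.ndarray:
    Y = w.size
    g = np.full(Y, -lambda_reg / Y)
    g[_central_window(Y)] += -lambda_reg * lambda_center / 10.0
    return g


def select_optimization_slices(
    per_slice_mean_sg: np.ndarray,
    brain_fraction_per_slice: np.ndarray,
    cfg: DetectConfig,
) -> np.ndarray:
    """Most inferior slices with enough brain and moderate susceptibility gradients.

    Keeps slices with brain fraction above ``brain_fraction_min`` and mean
    susceptibility gradient below ``sg_threshold`` (μT/m), and returns the
    first (most inferior) ``min(n_select_slices, count)`` of them.  Slices
    are assumed ordered inferior to superior.
    """
    sg = np.asarray(per_slice_mean_sg, dtype=float)
    bf = np.asarray(brain_fraction_per_slice, dtype=float)
    ok = np.flatnonzero((bf > cfg.brain_fraction_min) & (sg < cfg.sg_threshold))
    if ok.size == 0:
        raise ValueError(
            "no slice passes the selection "
            f"(brain fraction > {cfg.brain_fraction_min}, sg < {cfg.sg_threshold} μT/m)"
        )
    return ok[: cfg.n_select_slices]


def selected_slices_for_volume(
    brain_mask: np.ndarray,
    sg_map: np.ndarray,
    cfg: DetectConfig,
) -> np.ndarray:
    """Slice selection from a volume's brain mask and susceptibility map.

    Computes per-slice brain fraction and the mean susceptibility gradient
    over brain voxels, then applies :func:`select_optimization_slices`.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    n_slices = brain_mask.shape[0]
    bf = brain_mask.reshape(n_slices, -1).mean(axis=1)
    sg = np.asarray(sg_map, dtype=float).reshape(n_slices, -1)
    flat_brain = brain_mask.reshape(n_slices, -1)
    mean_sg = np.array(
        [sg[s][flat_brain[s]].mean() if flat_brain[s].any() else np.inf
         for s in range(n_slices)]
    )
    return select_optimization_slices(mean_sg, bf, cfg)


def masks_for_all_slices(
    mask_even: ExclusionMask,
    mask_odd: ExclusionMask,
    n_slices: int,
    even_slices_first: bool = True,
) -> list[ExclusionMask]:
    """Assign the package masks to every slice by 0-based parity.

    Slice ``s`` receives ``mask_even`` if ``s`` is even, else ``mask_odd``;
    flipping ``even_slices_first`` inverts the assignment.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be at least 1")
    pair = (mask_even, mask_odd) if even_slices_first else (mask_odd, mask_even)
    return [pair[s % 2] for s in range(n_slices)]


def optimize_exclusion_masks(
    y_corrupt: KSpaceVolume,
    csm: CoilSensitivityMaps,
    recon_cfg: UnrolledConfig,
    brain_mask: np.ndarray,
    sg_map: np.ndarray,
    cfg: DetectConfig | None = None,
    denoiser_weights: list | None = None,
    odd_first: bool = True,
):
    """Optimize one exclusion mask per slice package on the corrupted volume.

    Each epoch samples ``batch_slices`` slices (with replacement) from the
    selected subset, applies the parity-appropriate continuous mask to their
    k-space (KeepCenter override active), reconstructs with the frozen
    unrolled network, and evaluates the physics loss over brain voxels of
    the batch jointly plus the per-package exclusion regularizer.  The mask
    parameters are updated with Adam; the result is the pair of continuous
    masks (not binarized) together with the loss history.

    Returns ``(mask_even, mask_odd, history)`` where ``mask_even`` belongs
    to the package containing the 0-based even slice indices.
    """
    cfg = cfg or DetectConfig()
    vol, _ = normalize_volume(y_corrupt, csm)
    data = vol.data
    n_echo, _, n_slices, Y, ro = data.shape
    brain_mask = np.asarray(brain_mask, dtype=bool)
    selected = selected_slices_for_volume(brain_mask, sg_map, cfg)

    # package membership of each slice (row 0 of theta = even-index slices)
    pkg_even = "odd" if odd_first else "even"  # package holding slices 0, 2, 4, …
    pkg_odd = "even" if odd_first else "odd"
    even_set = set(slice_indices_for_package(n_slices, pkg_even, odd_first=odd_first).tolist())
    row_of_slice = np.array([0 if s in even_set else 1 for s in range(n_slices)])

    if recon_cfg.denoiser == "cnn":
        if denoiser_weights is None:
            raise ValueError("cnn denoiser requested without trained weights")
        denoisers = denoiser_weights
    else:
        denoisers = make_denoisers(recon_cfg, n_echo)

    params = MaskParameters.init(Y, cfg.initial_weight)
    opt = AdamOptimizer(lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    cy, cx = Y // 2 - 1, ro // 2 - 1  # upper-left corner of the KeepCenter block
    history: list[float] = []

    for _epoch in range(cfg.epochs):
        batch = rng.choice(selected, size=cfg.batch_slices, replace=True)
        uniq, counts = np.unique(batch, return_counts=True)
        w = params.weights()  # [2, Y]
        w_bar = np.zeros_like(w)
        phys_num = 0.0
        phys_den = 0.0
        slice_grads = []
        for s, mult in zip(uniq.tolist(), counts.tolist()):
            row = row_of_slice[s]
            mask = ExclusionMask(w[row])
            plane = expand_mask_keepcenter(mask, ro, keepcenter=cfg.keepcenter)
            y_raw = data[:, :, s]
            y_w = plane * y_raw
            x, tape = _unrolled_forward(y_w, plane, csm.csm[:, s], denoisers, recon_cfg.eta)
            mags = np.abs(x)
            stack = DecayStack(mags[:, None], vol.te_ms)
            bm = brain_mask[s][None]
            n_vox = int(bm.sum())
            if n_vox == 0:
                continue
            loss_s, grad_mag = physics_loss_and_grad(stack, bm)
            weight = mult * n_vox
            phys_num += weight * loss_s
            phys_den += weight
            slice_grads.append((s, row, weight, x, mags, grad_mag[:, 0], tape,
                               y_w, y_raw, plane))
        if phys_den == 0:
            raise ValueError("no brain voxels in the sampled batch")
        phys = phys_num / phys_den

        for s, row, weight, x, mags, gmag, tape, y_w, y_raw, plane in slice_grads:
            scale = weight / phys_den
            safe = np.where(mags > 0, mags, 1.0)
            x_bar = scale * gmag * x / safe
            W_bar, _, _ = _unrolled_vjp(
                x_bar, tape, y_w, y_raw, plane, csm.csm[:, s], recon_cfg.eta,
                need_mask_grad=True,
            )
            if cfg.keepcenter:
                W_bar[cy : cy + 2, cx : cx + 2] = 0.0
            w_bar[row] += W_bar.sum(axis=1)

        reg = 0.0
        for row in range(2):
            reg += exclusion_regularizer(w[row], cfg.lambda_reg, cfg.lambda_center)
            w_bar[row] += _regularizer_grad(w[row], cfg.lambda_reg, cfg.lambda_center)

        total = phys + reg
        history.append(total)
        if not np.isfinite(total):
            break
        opt.step([params.theta], [w_bar.ravel()])
        params.project()

    w = params.weights()
    mask_even = ExclusionMask(w[0], package=pkg_even)
    mask_odd = ExclusionMask(w[1], package=pkg_odd)
    return mask_even, mask_odd, history
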