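"""Mono-exponential T2* signal model, least-squares fitting and physics loss.

The signal magnitude of a multi-echo gradient-echo acquisition decays as
``s_n = s0 * exp(-TE_n / T2*)`` per voxel.  Motion-induced B0 changes break
this mono-exponential evolution, which the physics-informed loss measures as
one minus the echo-wise empirical correlation between a reconstruction and
its own mono-exponential fit.

Fitting is log-linear (ordinary least squares of ``log s`` on TE), which has
a closed form and is differentiable with respect to the input magnitudes;
the reverse-mode gradient of the loss is provided for the self-supervised
mask optimization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DecayStack",
    "RelaxometryMaps",
    "predict_signal",
    "fit_monoexp",
    "physics_loss",
    "physics_loss_and_grad",
]

T2STAR_CLAMP_MS = (1.0, 1000.0)
_EPS_FRACTION = 1e-6  # log floor relative to the volume maximum


@dataclass
class DecayStack:
    """Non-negative magnitude images ``[echo, slice, pe, ro]`` with echo times."""

    magnitudes: np.ndarray
    te_ms: np.ndarray

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        self.te_ms = np.asarray(self.te_ms, dtype=float)
        if self.magnitudes.ndim != 4:
            raise ValueError("magnitudes must be [echo, slice, pe, ro]")
        if self.magnitudes.shape[0] != self.te_ms.size:
            raise ValueError("echo axis must match te_ms")
        if self.te_ms.size < 3:
            raise ValueError("at least 3 echoes are required")
        if np.any(self.magnitudes < 0):
            raise ValueError("magnitudes must be non-negative")

    @property
    def n_echoes(self) -> int:
        return self.te_ms.size


@dataclass
class RelaxometryMaps:
    """Per-voxel T2* (ms), s0 (a.u.) and a fit-validity mask."""

    t2star_ms: np.ndarray
    s0: np.ndarray
    valid: np.ndarray


def predict_signal(s0, t2star_ms, te_ms) -> np.ndarray:
    """Evaluate ``s_n = s0 * exp(-TE_n / T2*)`` for each echo time.

    Scalars broadcast; ``t2star_ms`` must be strictly positive.
    """
    s0 = np.asarray(s0, dtype=float)
    t2 = np.asarray(t2star_ms, dtype=float)
    te = np.asarray(te_ms, dtype=float)
    if np.any(s0 < 0):
        raise ValueError("s0 must be non-negative")
    if np.any(t2 <= 0):
        raise ValueError("t2star_ms must be positive")
    shape = (te.size,) + np.broadcast_shapes(s0.shape, t2.shape)
    te = te.reshape((te.size,) + (1,) * (len(shape) - 1))
    return np.broadcast_to(s0 * np.exp(-te / t2), shape).copy()


def _design(te_ms: np.ndarray):
    """Hat matrix and solver matrix for OLS of log-signal on TE."""
    te = np.asarray(te_ms, dtype=float)
    X = np.stack([np.ones_like(te), te], axis=1)  # intercept ln s0, slope -1/T2*
    M = np.linalg.solve(X.T @ X, X.T)  # (2, n): coefficients = M @ logs
    H = X @ M  # (n, n): predictions = H @ logs
    return X, M, H


def fit_monoexp(stack: DecayStack, mask: np.ndarray | None = None):
    """Voxel-wise log-linear least-squares fit of the mono-exponential decay.

    Returns the T2*/s0 maps (T2* clamped to ``T2STAR_CLAMP_MS`` on export)
    and the fitted magnitudes ``exp(prediction)``.  Degenerate voxels
    (all-zero signal, non-decaying or out-of-range slope) are flagged
    invalid with T2* at the clamp maximum; no exception is raised.
    """
    s = stack.magnitudes
    if mask is None:
        mask = np.ones(s.shape[1:], dtype=bool)
    eps = _EPS_FRACTION * max(float(s.max()), np.finfo(float).tiny)
    logs = np.log(np.maximum(s, eps))
    _, M, H = _design(stack.te_ms)

    n = stack.n_echoes
    flat = logs.reshape(n, -1)
    coef = M @ flat  # [2, V]
    pred = H @ flat
    fitted = np.exp(pred).reshape(s.shape)

    intercept = coef[0].reshape(s.shape[1:])
    slope = coef[1].reshape(s.shape[1:])
    lo, hi = T2STAR_CLAMP_MS
    with np.errstate(divide="ignore", over="ignore"):
        t2_raw = np.where(slope < 0, -1.0 / np.where(slope < 0, slope, -1.0), np.inf)
    nonzero = s.max(axis=0) > eps
    valid = mask & nonzero & (slope < 0) & (t2_raw >= lo) & (t2_raw <= hi)
    t2map = np.clip(np.where(np.isfinite(t2_raw), t2_raw, hi), lo, hi)
    t2map = np.where(valid, t2map, np.where(slope >= 0, hi, t2map))
    s0map = np.exp(intercept)
    s0map = np.where(nonzero, s0map, 0.0)
    maps = RelaxometryMaps(t2star_ms=t2map, s0=s0map, valid=valid)
    return maps, DecayStack(fitted, stack.te_ms)


def _corr_terms(s: np.ndarray, f: np.ndarray):
    sc = s - s.mean(axis=0)
    fc = f - f.mean(axis=0)
    a = np.sum(sc * fc, axis=0)
    b = np.sqrt(np.sum(sc**2, axis=0))
    c = np.sqrt(np.sum(fc**2, axis=0))
    return sc, fc, a, b, c


def physics_loss(recon_stack: DecayStack, brain_mask: np.ndarray) -> float:
    """Mean of ``1 - corr(s, s_fit)`` over brain voxels.

    The correlation is computed across echoes between the reconstructed
    magnitudes and their own mono-exponential fit; voxels with zero variance
    across echoes are excluded from the average.  The value lies in [0, 2]
    and is invariant to global positive rescaling of the stack.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    loss, _ = physics_loss_and_grad(recon_stack, brain_mask, need_grad=False)
    return loss


def physics_loss_and_grad(
    recon_stack: DecayStack, brain_mask: np.ndarray, need_grad: bool = True
):
    """Physics loss and its gradient with respect to the input magnitudes.

    The fit is recomputed inside the loss (it is part of the differentiable
    graph), so the gradient has two paths per voxel: directly through the
    reconstructed magnitudes in the correlation, and through the fitted
    magnitudes ``exp(H log s)`` with the constant hat matrix ``H``.
    """
    s_full = recon_stack.magnitudes
    brain_mask = np.asarray(brain_mask, dtype=bool)
    n = recon_stack.n_echoes
    eps = _EPS_FRACTION * max(float(s_full.max()), np.finfo(float).tiny)
    _, _, H = _design(recon_stack.te_ms)

    s = s_full.reshape(n, -1)[:, brain_mask.ravel()]  # [n, V]
    logs = np.log(np.maximum(s, eps))
    f = np.exp(H @ logs)
    sc, fc, a, b, c = _corr_terms(s, f)
    tol = 1e-12 * max(float(s.max()), 1.0)
    ok = (b > tol) & (c > tol)
    n_ok = int(ok.sum())
    if n_ok == 0:
        loss = 0.0
        grad = np.zeros_like(s_full) if need_grad else None
        return loss, grad
    corr = np.zeros_like(a)
    corr[ok] = a[ok] / (b[ok] * c[ok])
    loss = float(np.mean(1.0 - corr[ok]))
    if not need_grad:
        return loss, None

    # d corr / d s (direct) and d corr / d f, only on valid voxels
    dL_ds = np.zeros_like(s)
    dcorr_ds = np.zeros_like(s)
    dcorr_df = np.zeros_like(s)
    bc = b[ok] * c[ok]
    dcorr_ds[:, ok] = fc[:, ok] / bc - corr[ok] * sc[:, ok] / (b[ok] ** 2)
    dcorr_df[:, ok] = sc[:, ok] / bc - corr[ok] * fc[:, ok] / (c[ok] ** 2)
    # chain through f = exp(H log s)
    lbar = H.T @ (f * dcorr_df)
    with np.errstate(divide="ignore"):
        dlog = np.where(s > eps, 1.0 / np.maximum(s, eps), 0.0)
    dL_ds = -(dcorr_ds + lbar * dlog) / n_ok
    dL_ds[:, ~ok] = 0.0

    grad = np.zeros((n, s_full[0].size))
    grad[:, brain_mask.ravel()] = dL_ds
    return loss, grad.reshape(s_full.shape)
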