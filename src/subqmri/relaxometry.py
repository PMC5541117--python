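"""Voxelwise mono-exponential T2* estimation from multi-echo magnitude data.

The signal model is the single-component decay S(TE) = S0 * exp(-TE/T2*).
Each voxel is fitted by nonlinear least squares: the closed-form log-linear
solution initializes a damped Gauss-Newton iteration on (S0, R2*) with
R2* = 1/T2*, vectorized across all masked voxels. T2* is constrained to
[0.1, 500] ms; voxels pinned at a bound or failing the tolerance are
flagged rather than silently filled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["T2StarFitResult", "fit_t2star", "T2S_BOUNDS_MS"]

#: Admissible T2* range (ms).
T2S_BOUNDS_MS = (0.1, 500.0)


@dataclass
class T2StarFitResult:
    """Per-voxel fit output; maps are zero (and unflagged) outside the mask."""

    t2star_ms: np.ndarray
    s0: np.ndarray
    rss: np.ndarray  # residual sum of squares
    converged: np.ndarray  # bool; False where pinned, degenerate, or not converged
    mask: np.ndarray


def _loglinear_init(signal: np.ndarray, te: np.ndarray, eps_frac: float = 1e-9):
    """Weighted log-linear closed form; uses only echoes above eps * max."""
    n, _ = signal.shape
    smax = signal.max(axis=1, keepdims=True)
    ok = signal > eps_frac * np.maximum(smax, 1e-300)
    # need >= 2 usable echoes; degenerate voxels fall back to mid-range
    usable = ok.sum(axis=1) >= 2
    logs = np.where(ok, np.log(np.where(ok, signal, 1.0)), 0.0)
    w = ok.astype(float)
    sw = w.sum(axis=1)
    sx = (w * te).sum(axis=1)
    sy = (w * logs).sum(axis=1)
    sxx = (w * te * te).sum(axis=1)
    sxy = (w * te * logs).sum(axis=1)
    denom = sw * sxx - sx * sx
    good = usable & (np.abs(denom) > 1e-12)
    slope = np.where(good, (sw * sxy - sx * sy) / np.where(good, denom, 1.0), 0.0)
    intercept = np.where(good, (sy - slope * sx) / np.maximum(sw, 1.0), 0.0)
    r2 = np.clip(-slope, 1.0 / T2S_BOUNDS_MS[1], 1.0 / T2S_BOUNDS_MS[0])
    s0 = np.where(good, np.exp(intercept), smax[:, 0])
    return s0, r2, usable


def fit_t2star(
    series,
    mask: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> T2StarFitResult:
    """Fit S(TE) = S0 * exp(-TE/T2*) per voxel inside ``mask``.

    Parameters
    ----------
    series
        A :class:`~subqmri.phantom.MultiEchoSeries` (or any object with
        ``echo_times_ms`` and ``magnitude``). At least two echoes.
    mask
        Boolean volume restricting the fit; defaults to all voxels.
    tol
        Convergence tolerance on the relative parameter change.
    max_iter
        Gauss-Newton iteration cap.
    """
    te = np.asarray(series.echo_times_ms, dtype=float)
    if te.size < 2:
        raise ValueError("T2* fitting requires at least 2 echoes")
    mag4d = np.asarray(series.magnitude, dtype=float)
    shape = mag4d.shape[:-1]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if np.any(mag4d[mask] < 0):
        raise ValueError("magnitudes must be non-negative inside the mask")

    sig = mag4d[mask]  # (n_vox, n_echo)
    n = sig.shape[0]
    s0, r2, usable = _loglinear_init(sig, te)
    active = usable.copy()

    lo, hi = 1.0 / T2S_BOUNDS_MS[1], 1.0 / T2S_BOUNDS_MS[0]

    def cost(s0v, r2v):
        resid = sig - s0v[:, None] * np.exp(-te[None, :] * r2v[:, None])
        return (resid * resid).sum(axis=1)

    converged = np.zeros(n, dtype=bool)
    prev_cost = cost(s0, r2)
    for _ in range(max_iter):
        if not active.any():
            break
        e = np.exp(-te[None, :] * r2[:, None])
        model = s0[:, None] * e
        resid = sig - model
        # Jacobian columns: d/dS0 = e, d/dR2 = -S0 * te * e
        j2 = -model * te[None, :]
        a11 = (e * e).sum(axis=1)
        a12 = (e * j2).sum(axis=1)
        a22 = (j2 * j2).sum(axis=1)
        b1 = (e * resid).sum(axis=1)
        b2 = (j2 * resid).sum(axis=1)
        det = a11 * a22 - a12 * a12
        ok = np.abs(det) > 1e-300
        ds0 = np.where(ok, (a22 * b1 - a12 * b2) / np.where(ok, det, 1.0), 0.0)
        dr2 = np.where(ok, (a11 * b2 - a12 * b1) / np.where(ok, det, 1.0), 0.0)

        # damped update: halve the step where the cost does not decrease
        step = np.where(active, 1.0, 0.0)
        new_s0, new_r2 = s0, r2
        for _half in range(12):
            cand_s0 = s0 + step * ds0
            cand_r2 = np.clip(r2 + step * dr2, lo, hi)
            cand_cost = cost(cand_s0, cand_r2)
            better = cand_cost <= prev_cost + 1e-15
            if _half == 0:
                new_s0 = np.where(better, cand_s0, new_s0)
                new_r2 = np.where(better, cand_r2, new_r2)
                new_cost = np.where(better, cand_cost, prev_cost)
                need = active & ~better
            else:
                take = need & better
                new_s0 = np.where(take, cand_s0, new_s0)
                new_r2 = np.where(take, cand_r2, new_r2)
                new_cost = np.where(take, cand_cost, new_cost)
                need = need & ~better
            if not need.any():
                break
            step = np.where(need, step * 0.5, step)

        rel = np.maximum(
            np.abs(new_s0 - s0) / np.maximum(np.abs(s0), 1e-30),
            np.abs(new_r2 - r2) / np.maximum(np.abs(r2), 1e-30),
        )
        done = active & (rel < tol)
        converged |= done
        active &= ~done
        s0, r2, prev_cost = new_s0, new_r2, new_cost

    t2s = 1.0 / r2
    pinned = (t2s <= T2S_BOUNDS_MS[0] * (1 + 1e-9)) | (
        t2s >= T2S_BOUNDS_MS[1] * (1 - 1e-9)
    )
    flag = converged & usable & ~pinned

    out_t2s = np.zeros(shape)
    out_s0 = np.zeros(shape)
    out_rss = np.zeros(shape)
    out_flag = np.zeros(shape, dtype=bool)
    out_t2s[mask] = t2s
    out_s0[mask] = s0
    out_rss[mask] = prev_cost
    out_flag[mask] = flag
    return T2StarFitResult(
        t2star_ms=out_t2s, s0=out_s0, rss=out_rss, converged=out_flag, mask=mask
    )
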