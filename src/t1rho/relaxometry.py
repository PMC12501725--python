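"""Mono-exponential T1rho relaxometry: the signal model and its inversion.

The spin-lock prepared signal decays as

    I(TSL) = I0 * exp(-TSL / T1rho)

per voxel. This module provides the forward model, the closed-form two-point
inversion, a vectorized Levenberg-Marquardt nonlinear least-squares (NLLS)
fitter for >= 2 spin-lock times, and volume-level application over an ROI.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AcquisitionProtocol, FitResult, ROIMask, T1rhoMap, WeightedVolume

__all__ = [
    "FitBounds",
    "signal_intensity",
    "two_point_fit",
    "nlls_fit",
    "nlls_fit_batch",
    "fit_volume",
]


@dataclass(frozen=True)
class FitBounds:
    """Box constraints for the (I0, T1rho) fit.

    Cartilage T1rho sits around 20-80 ms; the default T1rho box [1, 500] ms is
    generous but finite so that non-decaying voxels clamp at the upper bound
    instead of diverging. I0 is bounded by ``i0_max_factor`` times the largest
    observed intensity.
    """

    t1rho_min: float = 1.0
    t1rho_max: float = 500.0
    i0_max_factor: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.t1rho_min < self.t1rho_max:
            raise ValueError("need 0 < t1rho_min < t1rho_max")
        if self.i0_max_factor <= 0:
            raise ValueError("i0_max_factor must be positive")


DEFAULT_BOUNDS = FitBounds()

_STEP_TOL = 1e-8
_MAX_ITER = 200


def signal_intensity(i0, t1rho, tsl):
    """Forward mono-exponential model ``I0 * exp(-TSL / T1rho)``.

    Broadcasts over array arguments. ``t1rho`` must be strictly positive.
    """
    i0 = np.asarray(i0, dtype=np.float64)
    t1rho = np.asarray(t1rho, dtype=np.float64)
    tsl = np.asarray(tsl, dtype=np.float64)
    if np.any(t1rho <= 0):
        raise ValueError("t1rho must be > 0")
    if np.any(i0 < 0):
        raise ValueError("i0 must be >= 0")
    if np.any(tsl < 0):
        raise ValueError("tsl must be >= 0")
    out = i0 * np.exp(-tsl / t1rho)
    return out if out.ndim else float(out)


def two_point_fit(
    i0: float,
    ik: float,
    tsl0: float,
    tslk: float,
    bounds: FitBounds = DEFAULT_BOUNDS,
) -> FitResult:
    """Closed-form inversion of the signal model from two samples.

    With samples ``i0`` at ``tsl0`` and ``ik`` at ``tslk > tsl0``,

        T1rho = (tslk - tsl0) / ln(i0 / ik)

    Exact inverse of :func:`signal_intensity` on noise-free data. Non-decaying
    pairs (``ik >= i0``) or non-positive ``ik`` cannot satisfy the model: the
    result is clamped to the upper T1rho bound and flagged unconverged.
    """
    if not tslk > tsl0 >= 0:
        raise ValueError("need tslk > tsl0 >= 0")
    if i0 < 0 or ik < 0:
        raise ValueError("intensities must be >= 0")
    if ik <= 0 or ik >= i0:
        return FitResult(
            i0_hat=float(i0),
            t1rho_hat=bounds.t1rho_max,
            residual_norm=0.0,
            converged=False,
            clamped=True,
        )
    t1rho = (tslk - tsl0) / np.log(i0 / ik)
    clamped = not (bounds.t1rho_min <= t1rho <= bounds.t1rho_max)
    t1rho = float(np.clip(t1rho, bounds.t1rho_min, bounds.t1rho_max))
    # back-extrapolate I0 to TSL = 0
    i0_hat = float(i0 * np.exp(tsl0 / t1rho)) if not clamped else float(i0)
    if clamped:
        return FitResult(i0_hat, t1rho, 0.0, converged=False, clamped=True)
    return FitResult(i0_hat, t1rho, 0.0, converged=True, clamped=False)


def _loglinear_init(y: np.ndarray, tsls: np.ndarray, bounds: FitBounds):
    """Log-linear regression of ln(y) on TSL as the LM starting point.

    Operates row-wise on strictly positive samples (callers guarantee this).
    Returns (i0_init, t1rho_init), clipped into the bounds.
    """
    ly = np.log(y)
    t_mean = tsls.mean()
    ly_mean = ly.mean(axis=1, keepdims=True)
    denom = np.sum((tsls - t_mean) ** 2)
    slope = np.sum((tsls - t_mean) * (ly - ly_mean), axis=1) / denom
    intercept = ly_mean[:, 0] - slope * t_mean
    with np.errstate(divide="ignore", over="ignore"):
        t1rho0 = np.where(slope < 0, -1.0 / np.where(slope < 0, slope, -1.0), bounds.t1rho_max)
    t1rho0 = np.clip(t1rho0, bounds.t1rho_min, bounds.t1rho_max)
    i0_cap = bounds.i0_max_factor * max(float(y.max()), 1e-30)
    i00 = np.clip(np.exp(np.clip(intercept, -700, 700)), 1e-30, i0_cap)
    return i00, t1rho0


def nlls_fit_batch(
    intensities: np.ndarray,
    tsls,
    bounds: FitBounds = DEFAULT_BOUNDS,
    step_tol: float = _STEP_TOL,
    max_iter: int = _MAX_ITER,
):
    """Vectorized Levenberg-Marquardt fit of (I0, T1rho) over many voxels.

    Parameters
    ----------
    intensities
        Array (V, K) of magnitude samples, one row per voxel.
    tsls
        K strictly increasing spin-lock times in ms.

    Returns
    -------
    dict of arrays: ``i0``, ``t1rho``, ``residual_norm``, ``converged``,
    ``clamped``, ``fitted`` (False where a voxel was excluded because some
    sample was non-positive or non-finite).

    Initialization is the log-linear regression of ln(I) on TSL; each LM step
    solves the damped 2x2 normal equations in closed form, parameters are
    projected into the bounds, and a voxel stops when its parameter step falls
    below ``step_tol`` (relative). Voxels ending on a T1rho bound are flagged
    ``clamped`` and not ``converged``.
    """
    Y = np.asarray(intensities, dtype=np.float64)
    if Y.ndim != 2:
        raise ValueError("intensities must be (V, K)")
    tsls = np.asarray(tsls, dtype=np.float64)
    if tsls.ndim != 1 or tsls.size != Y.shape[1] or tsls.size < 2:
        raise ValueError("need K >= 2 TSLs matching intensity columns")
    if np.any(np.diff(tsls) <= 0):
        raise ValueError("TSLs must be strictly increasing")
    if not np.all(np.isfinite(Y)):
        raise ValueError("non-finite intensities")

    V = Y.shape[0]
    out = {
        "i0": np.zeros(V),
        "t1rho": np.full(V, bounds.t1rho_max),
        "residual_norm": np.zeros(V),
        "converged": np.zeros(V, dtype=bool),
        "clamped": np.zeros(V, dtype=bool),
        "fitted": np.zeros(V, dtype=bool),
    }
    ok = np.all(Y > 0, axis=1)  # log-space init needs positive samples
    if not np.any(ok):
        return out
    y = Y[ok]
    i0_cap = bounds.i0_max_factor * max(float(y.max()), 1e-30)

    i0, t1 = _loglinear_init(y, tsls, bounds)
    lam = np.full(y.shape[0], 1e-3)

    def sse(i0v, t1v):
        r = y - i0v[:, None] * np.exp(-tsls[None, :] / t1v[:, None])
        return np.einsum("ij,ij->i", r, r), r

    cur_sse, _ = sse(i0, t1)
    active = np.ones(y.shape[0], dtype=bool)
    conv = np.zeros(y.shape[0], dtype=bool)
    for _ in range(max_iter):
        if not np.any(active):
            break
        ia, ta, la = i0[active], t1[active], lam[active]
        E = np.exp(-tsls[None, :] / ta[:, None])
        r = y[active] - ia[:, None] * E
        # Jacobian of the model wrt (i0, t1rho)
        J0 = E
        J1 = ia[:, None] * E * (tsls[None, :] / ta[:, None] ** 2)
        a00 = np.einsum("ij,ij->i", J0, J0)
        a01 = np.einsum("ij,ij->i", J0, J1)
        a11 = np.einsum("ij,ij->i", J1, J1)
        g0 = np.einsum("ij,ij->i", J0, r)
        g1 = np.einsum("ij,ij->i", J1, r)
        d00 = a00 * (1 + la)
        d11 = a11 * (1 + la)
        det = d00 * d11 - a01 * a01
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        s0 = (d11 * g0 - a01 * g1) / det
        s1 = (d00 * g1 - a01 * g0) / det
        i0_new = np.clip(ia + s0, 0.0, i0_cap)
        t1_new = np.clip(ta + s1, bounds.t1rho_min, bounds.t1rho_max)
        r_new = y[active] - i0_new[:, None] * np.exp(-tsls[None, :] / t1_new[:, None])
        sse_new = np.einsum("ij,ij->i", r_new, r_new)
        better = sse_new <= cur_sse[active]
        # accept improving steps, raise damping otherwise
        step = np.maximum(
            np.abs(i0_new - ia) / (np.abs(ia) + 1e-12),
            np.abs(t1_new - ta) / (np.abs(ta) + 1e-12),
        )
        idx = np.flatnonzero(active)
        acc = idx[better]
        i0[acc] = i0_new[better]
        t1[acc] = t1_new[better]
        cur_sse[acc] = sse_new[better]
        lam[acc] = np.maximum(la[better] / 3.0, 1e-12)
        rej = idx[~better]
        lam[rej] = np.minimum(lam[rej] * 5.0, 1e12)
        done = np.zeros_like(better)
        done[better] = step[better] < step_tol
        conv[idx[done]] = True
        done |= lam[idx] >= 1e10  # damping exhausted: stop without convergence
        active[idx[done]] = False

    at_bound = (t1 <= bounds.t1rho_min * (1 + 1e-9)) | (t1 >= bounds.t1rho_max * (1 - 1e-9))
    out["i0"][ok] = i0
    out["t1rho"][ok] = t1
    out["residual_norm"][ok] = np.sqrt(cur_sse)
    out["clamped"][ok] = at_bound
    out["converged"][ok] = conv & ~at_bound
    out["fitted"][ok] = True
    return out


def nlls_fit(
    intensities,
    tsls,
    bounds: FitBounds = DEFAULT_BOUNDS,
) -> FitResult:
    """NLLS fit of a single voxel's multi-TSL samples; see :func:`nlls_fit_batch`."""
    y = np.asarray(intensities, dtype=np.float64)
    if y.ndim != 1:
        raise ValueError("intensities must be 1-D for a single-voxel fit")
    res = nlls_fit_batch(y[None, :], tsls, bounds=bounds)
    return FitResult(
        i0_hat=float(res["i0"][0]),
        t1rho_hat=float(res["t1rho"][0]),
        residual_norm=float(res["residual_norm"][0]),
        converged=bool(res["converged"][0]),
        clamped=bool(res["clamped"][0]),
    )


def fit_volume(
    volumes: list[WeightedVolume],
    protocol: AcquisitionProtocol,
    roi: ROIMask | None = None,
    method: str = "nlls",
    bounds: FitBounds = DEFAULT_BOUNDS,
) -> T1rhoMap:
    """Voxelwise fit of the signal model over a multi-TSL volume stack.

    ``volumes`` must carry TSL contrasts matching ``protocol.tsls`` in order.
    With an ROI, only ``roi > 0`` voxels are fitted; others are invalid (0).
    ``method`` is ``"nlls"`` (any K >= 2) or ``"two_point"`` (exactly 2).
    """
    if method not in ("nlls", "two_point"):
        raise ValueError("method must be 'nlls' or 'two_point'")
    if len(volumes) != len(protocol.tsls):
        raise ValueError("one volume per protocol TSL required")
    shape = volumes[0].shape
    for v in volumes:
        if v.shape != shape:
            raise ValueError("all volumes must share one grid shape")
        if v.is_pd:
            raise ValueError("fit_volume needs TSL-tagged volumes, not a PD volume")
    got = tuple(float(v.contrast) for v in volumes)
    if got != protocol.tsls:
        raise ValueError(f"volume contrasts {got} do not match protocol TSLs {protocol.tsls}")
    if method == "two_point" and len(volumes) != 2:
        raise ValueError("two_point fitting needs exactly 2 volumes")
    if roi is not None and roi.shape != shape:
        raise ValueError("ROI shape mismatch")

    sel = roi.mask if roi is not None else np.ones(shape, dtype=bool)
    values = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)
    if not np.any(sel):
        return T1rhoMap(values, valid)

    Y = np.stack([v.data[sel] for v in volumes], axis=1)
    tsls = np.asarray(protocol.tsls)
    if method == "two_point":
        i0s, iks = Y[:, 0], Y[:, 1]
        t = np.full(Y.shape[0], bounds.t1rho_max)
        okp = (iks > 0) & (iks < i0s)
        with np.errstate(divide="ignore"):
            t[okp] = (tsls[1] - tsls[0]) / np.log(i0s[okp] / iks[okp])
        inb = okp & (t >= bounds.t1rho_min) & (t <= bounds.t1rho_max)
        t = np.clip(t, bounds.t1rho_min, bounds.t1rho_max)
        values[sel] = t
        valid[sel] = inb
    else:
        res = nlls_fit_batch(Y, tsls, bounds=bounds)
        values[sel] = res["t1rho"]
        valid[sel] = res["converged"]
    return T1rhoMap(values, valid)
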