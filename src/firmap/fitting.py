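"""Two-step pixel-wise fitting of the IR-LL relaxation model.

Step 1 fits the three-parameter signed recovery

    M(t) = M0* - (M0 + M0*) exp(-t / T1*)

to the coil-combined curve of every pixel by damped (Levenberg-Marquardt)
least squares with an analytic Jacobian, vectorised over pixels: all pixels
advance together, each carrying its own damping factor, so a whole slice is
fitted in a handful of matrix operations per LM step.  The true relaxation
time follows as T1 = T1* * M0 / M0* = T1* * k.

Step 2 re-fits only a complex amplitude per coil: with k and T1* fixed from
step 1 the model is linear in M0*, and the least-squares solution against the
basis b(t) = 1 - (k + 1) exp(-t / T1*) is the closed form

    M0*_c = sum_t d_c(t) b(t) / sum_t b(t)^2,

applied to the complex coil data (equivalently to real and imaginary parts
separately).  Rebuilding the model from (M0*_c, k, T1*) closes the loop.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .data_model_io import InversionTimeAxis, ModelSeries

__all__ = [
    "ThreeParamFit",
    "fit_three_param",
    "fit_three_param_batch",
    "compute_t1",
    "fit_coil_scale",
    "fit_coil_scale_batch",
    "rebuild_model",
]

T1_STAR_BOUNDS_MS = (1e-2, 1e4)


class ThreeParamFit(NamedTuple):
    m0: float
    m0_star: float
    t1_star_ms: float
    converged: bool


def _default_init(curves: np.ndarray, t1_star_init_ms: float) -> np.ndarray:
    """First-iteration guess: curve max for M0*, negated minimum for M0.

    The recovery curve starts near -M0 and saturates at M0*, so the signed
    extrema of the measured curve estimate both amplitudes directly.
    """
    scale = np.maximum(np.abs(curves).max(axis=1), 1e-30)
    m0s0 = np.maximum(curves.max(axis=1), 1e-3 * scale)
    m00 = np.maximum(-curves.min(axis=1), 1e-3 * scale)
    t1s0 = np.full(curves.shape[0], t1_star_init_ms)
    return np.stack([m00, m0s0, t1s0], axis=1)


def _clip_params(params: np.ndarray, scale: np.ndarray) -> np.ndarray:
    params[:, 1] = np.maximum(params[:, 1], 1e-12 * scale)  # M0* > 0
    params[:, 2] = np.clip(params[:, 2], *T1_STAR_BOUNDS_MS)
    return params


def fit_three_param_batch(
    curves: np.ndarray,
    times: InversionTimeAxis,
    init: np.ndarray | None = None,
    t1_star_init_ms: float = 1000.0,
    max_iter: int = 200,
    rtol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit M(t) = M0* - (M0+M0*) e^{-t/T1*} to many curves at once.

    Parameters
    ----------
    curves : (B, T) signed real curves.
    times : inversion time axis (length T, strictly increasing).
    init : optional (B, 3) warm start [M0, M0*, T1*]; when omitted the
        extremum rule above is used with ``t1_star_init_ms``.
    rtol : relative parameter-step size below which a pixel counts as
        converged.

    Returns
    -------
    params : (B, 3) array of [M0, M0*, T1*_ms] (best found per pixel).
    converged : (B,) boolean flags; all-zero curves are flagged unconverged
        and keep zero parameters.
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=np.float64))
    t = times.t_ms
    if curves.shape[1] != t.size:
        raise ValueError("curves and time axis length disagree")
    if t.size < 3:
        raise ValueError("need at least 3 time points for a 3-parameter fit")
    n_pix = curves.shape[0]

    scale = np.abs(curves).max(axis=1)
    fittable = scale > 0

    params = np.zeros((n_pix, 3))
    converged = np.zeros(n_pix, dtype=bool)
    if not np.any(fittable):
        return params, converged

    d = curves[fittable]
    sc = scale[fittable]
    if init is None:
        p = _default_init(d, t1_star_init_ms)
    else:
        init = np.atleast_2d(np.asarray(init, dtype=np.float64))
        p = init[fittable].copy()
        # repair degenerate warm starts (non-finite, collapsed amplitude or a
        # relaxation time stuck at the lower bound) so the fit can recover
        bad = (
            ~np.all(np.isfinite(p), axis=1)
            | (p[:, 1] <= 1e-10 * np.maximum(np.abs(d).max(axis=1), 1e-30))
            | (p[:, 2] <= 2.0 * T1_STAR_BOUNDS_MS[0])
        )
        if np.any(bad):
            p[bad] = _default_init(d[bad], t1_star_init_ms)
    p = _clip_params(p, sc)

    nb = p.shape[0]
    lam = np.full(nb, 1e-3)
    conv = np.zeros(nb, dtype=bool)
    done = np.zeros(nb, dtype=bool)

    # cached per-pixel state: exponential, residual and cost at the current p
    e_cur = np.exp(-t[None] / p[:, 2:3])
    r_cur = p[:, 1:2] - (p[:, 0:1] + p[:, 1:2]) * e_cur - d
    cost = np.einsum("bt,bt->b", r_cur, r_cur)

    eye = np.eye(3)
    n_t = float(t.size)
    for _ in range(max_iter):
        act = ~done
        if not np.any(act):
            break
        idx = np.nonzero(act)[0]
        pa = p[idx]
        e = e_cur[idx]
        r = r_cur[idx]

        # Gauss-Newton normal equations from moments of the exponential.
        # With J = [-e, 1-e, c*t*e], c = -(M0+M0*)/T1*^2, all entries of
        # J^T J and J^T r reduce to sums of e, e^2, t e, t e^2, t^2 e^2.
        te = t[None] * e
        s1 = np.einsum("bt->b", e)
        s2 = np.einsum("bt,bt->b", e, e)
        s3 = np.einsum("bt->b", te)
        s4 = np.einsum("bt,bt->b", te, e)
        s5 = np.einsum("bt,bt->b", te, te)
        sr = np.einsum("bt->b", r)
        ser = np.einsum("bt,bt->b", e, r)
        ster = np.einsum("bt,bt->b", te, r)
        c = -(pa[:, 0] + pa[:, 1]) / pa[:, 2] ** 2

        h = np.empty((idx.size, 3, 3))
        h[:, 0, 0] = s2
        h[:, 0, 1] = h[:, 1, 0] = s2 - s1
        h[:, 0, 2] = h[:, 2, 0] = -c * s4
        h[:, 1, 1] = n_t - 2.0 * s1 + s2
        h[:, 1, 2] = h[:, 2, 1] = c * (s3 - s4)
        h[:, 2, 2] = c**2 * s5
        g = np.stack([-ser, sr - ser, c * ster], axis=1)

        diag = np.einsum("bkk->bk", h)
        a = h + lam[idx][:, None, None] * (diag[:, None, :] * eye[None]) + 1e-30 * eye[None]
        try:
            delta = np.linalg.solve(a, -g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(a.reshape(-1, 3, 3), -g[..., None], rcond=None)[0][..., 0]

        p_new = _clip_params(pa + delta, sc[idx])
        e_new = np.exp(-t[None] / p_new[:, 2:3])
        r_new = p_new[:, 1:2] - (p_new[:, 0:1] + p_new[:, 1:2]) * e_new - d[idx]
        cost_new = np.einsum("bt,bt->b", r_new, r_new)

        # a step is accepted when it does not worsen the cost beyond rounding;
        # pixels already at the optimum produce a negligible step and must
        # still be recognised as converged
        improved = cost_new <= cost[idx] * (1.0 + 1e-12)
        imp_idx = idx[improved]
        p[imp_idx] = p_new[improved]
        e_cur[imp_idx] = e_new[improved]
        r_cur[imp_idx] = r_new[improved]
        cost[imp_idx] = cost_new[improved]
        lam[imp_idx] = np.maximum(lam[imp_idx] * 0.25, 1e-12)
        lam[idx[~improved]] *= 4.0

        rel_step = np.max(np.abs(delta) / (np.abs(pa) + 1e-30), axis=1)
        small = improved & (rel_step < rtol)
        flat = cost[idx] <= (1e-28 * sc[idx] ** 2 * t.size)
        conv[idx[small]] = True
        conv[idx] |= flat
        done[idx] = conv[idx] | (lam[idx] > 1e12)

    params[fittable] = p
    converged[fittable] = conv
    return params, converged


def fit_three_param(
    curve: np.ndarray,
    times: InversionTimeAxis,
    init: tuple[float, float, float] | None = None,
    **kwargs,
) -> ThreeParamFit:
    """Fit a single signed recovery curve; see :func:`fit_three_param_batch`."""
    init_arr = None if init is None else np.asarray(init, dtype=np.float64)[None]
    params, conv = fit_three_param_batch(
        np.asarray(curve, dtype=np.float64)[None], times, init=init_arr, **kwargs
    )
    return ThreeParamFit(params[0, 0], params[0, 1], params[0, 2], bool(conv[0]))


def compute_t1(
    m0: np.ndarray | float, m0_star: np.ndarray | float, t1_star_ms: np.ndarray | float
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """True relaxation time T1 = T1* M0/M0* and the ratio k = M0/M0*.

    Pixels with M0* = 0 are undefined and return NaN.
    """
    m0 = np.asarray(m0, dtype=np.float64)
    m0s = np.asarray(m0_star, dtype=np.float64)
    t1s = np.asarray(t1_star_ms, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(m0s != 0, m0 / np.where(m0s != 0, m0s, 1.0), np.nan)
        t1 = t1s * k
    if np.ndim(k) == 0:
        return float(t1), float(k)
    return t1, k


def _basis(t: np.ndarray, k: np.ndarray, t1s: np.ndarray) -> np.ndarray:
    """b(t) = 1 - (k+1) exp(-t/T1*); zero where k or T1* is undefined."""
    k = np.asarray(k, dtype=np.float64)
    t1s = np.asarray(t1s, dtype=np.float64)
    valid = np.isfinite(k) & np.isfinite(t1s) & (t1s > 0)
    t1s_safe = np.where(valid, t1s, 1.0)
    b = 1.0 - (k + 1.0) * np.exp(-t[(...,) + (None,) * k.ndim] / t1s_safe)
    return np.where(valid, b, 0.0)


def fit_coil_scale_batch(
    coil_curves: np.ndarray,
    k: np.ndarray,
    t1_star_ms: np.ndarray,
    times: InversionTimeAxis,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form complex amplitude per coil and pixel.

    ``coil_curves`` is (T, C, B) complex, ``k`` and ``t1_star_ms`` are (B,)
    from the first fitting step.  Returns ``(scales (C, B) complex, valid
    (B,) bool)``; pixels whose basis has zero energy are invalid (scale 0).
    """
    t = times.t_ms
    b = _basis(t, k, t1_star_ms)  # (T, B)
    denom = np.einsum("tb,tb->b", b, b)
    valid = denom > 0
    num = np.einsum("tcb,tb->cb", coil_curves, b)
    scales = np.zeros_like(num)
    scales[:, valid] = num[:, valid] / denom[valid]
    return scales, valid


def fit_coil_scale(
    coil_curve: np.ndarray, k: float, t1_star_ms: float, times: InversionTimeAxis
) -> complex:
    """Single-pixel, single-coil convenience wrapper (complex amplitude)."""
    curve = np.asarray(coil_curve, dtype=np.complex128)[:, None, None]
    scales, valid = fit_coil_scale_batch(
        curve, np.asarray([k]), np.asarray([t1_star_ms]), times
    )
    if not valid[0]:
        raise ZeroDivisionError("basis has zero energy; coil scale undefined")
    return complex(scales[0, 0])


def rebuild_model(
    coil_scales: np.ndarray,
    k: np.ndarray,
    t1_star_ms: np.ndarray,
    times: InversionTimeAxis,
    dtype: np.dtype | type = np.complex128,
) -> ModelSeries:
    """Regenerate the complex model series from second-step parameters.

    ``coil_scales`` is (C, ...map shape...) complex; ``k`` and ``t1_star_ms``
    are the map-shaped step-1 results.  Pixels with undefined parameters (or
    zero scale) yield zero model signal.
    """
    k = np.asarray(k, dtype=np.float64)
    t1s = np.asarray(t1_star_ms, dtype=np.float64)
    n_coil = coil_scales.shape[0]
    n_t = times.t_ms.size
    map_shape = k.shape
    kf = k.reshape(-1)
    t1f = t1s.reshape(-1)
    live = np.isfinite(kf) & np.isfinite(t1f) & (t1f > 0)
    images = np.zeros((n_t, n_coil) + (kf.size,), dtype=dtype)
    if np.any(live):
        b = _basis(times.t_ms, kf[live], t1f[live])  # (T, B)
        images[:, :, live] = coil_scales.reshape(n_coil, -1)[None, :, live] * b[:, None]
    return ModelSeries(images=images.reshape((n_t, n_coil) + map_shape))
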