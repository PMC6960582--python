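"""The full model-based reconstruction loop.

Starting from one of the three initial models, each iteration (i) Fourier
transforms the current image-series model, (ii) evaluates the termination
metric against the measured spokes, (iii) reinserts the measured k-space
nodes, (iv) inverse transforms and phase-sensitively combines the coils,
(v) runs the two-step pixel-wise fit (warm-started from the previous
iteration) and (vi) rebuilds the model from the fitted parameters.  The loop
stops when the relative change of the metric falls below a tolerance or at a
fixed iteration cap.

Projection reduction is supported independently for the initial model
(``nth_init``) and for the iteration loop (``nth_iter``): every n-th
projection is kept with its original inversion time.  Reducing only the
iteration loop trades accuracy for speed; reducing both emulates acquiring
fewer spokes altogether (the time freed could acquire other slices).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .coil_combine import combine, composite_kspace, mean_phase_maps
from .consistency import consistency_metric, model_to_kspace, reinsert, sparsity_select
from .data_model_io import (
    ConvergenceLog,
    GriddedProjections,
    InversionTimeAxis,
    ModelSeries,
    ParameterMaps,
)
from .fitting import (
    T1_STAR_BOUNDS_MS,
    _default_init,
    compute_t1,
    fit_coil_scale_batch,
    fit_three_param_batch,
    rebuild_model,
)
from .fourier import ifft2c
from .initial_models import build_ifm, build_mfm, build_ofm

__all__ = ["ReconConfig", "reconstruct", "subset_projections", "roi_stats"]

log = logging.getLogger(__name__)

_DEFAULT_ITERS = {"mfm": 150, "ifm": 30, "ofm": 150}


@dataclass(frozen=True)
class ReconConfig:
    """Knobs of the reconstruction loop.

    ``max_iters=None`` resolves to 150 for MFM/OFM and 30 for IFM (the
    interpolated start converges in far fewer iterations).  ``tol`` is the
    relative change of the consistency metric between successive iterations
    below which the loop stops early.  ``background_threshold`` skips pixels
    whose combined-curve peak magnitude stays below that fraction of the
    image-wide peak — they carry no tissue signal.
    """

    initial_model: str = "mfm"
    max_iters: int | None = None
    tol: float = 1e-4
    nth_iter: int = 1
    nth_init: int = 1
    circular_mask: bool = True
    mask_radius: float | None = None
    sparsity_reinsertion: bool = False
    sparsity_fraction: float = 0.05
    t1_star_init_ms: float = 1000.0
    background_threshold: float = 0.01
    fit_max_iter: int = 30  # LM steps per pixel per outer iteration (warm-started)
    fit_rtol: float = 1e-9
    single_precision: bool = True  # complex64 for the per-iteration k-space/series arrays
    phase_last_n: int = 200
    amplitude_root: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_model not in _DEFAULT_ITERS:
            raise ValueError(f"unknown initial model {self.initial_model!r}")
        if self.nth_iter < 1 or self.nth_init < 1:
            raise ValueError("projection strides must be >= 1")
        if self.max_iters is not None and self.max_iters < 0:
            raise ValueError("max_iters must be >= 0")

    @property
    def iterations(self) -> int:
        return _DEFAULT_ITERS[self.initial_model] if self.max_iters is None else self.max_iters


def subset_projections(
    gridded: GriddedProjections, n: int
) -> tuple[GriddedProjections, np.ndarray]:
    """Keep every n-th projection (indices 0, n, 2n, ...) with its own data.

    Returns the reduced container and the retained original indices, so the
    caller can subset the inversion-time axis consistently (times are never
    re-assigned).
    """
    if n < 1:
        raise ValueError("stride must be >= 1")
    if n == 1:
        return gridded, np.arange(gridded.meta.n_proj)
    idx = np.arange(0, gridded.meta.n_proj, n)
    meta = replace(gridded.meta, n_proj=int(idx.size))
    return (
        GriddedProjections(values=gridded.values[idx], mask=gridded.mask[idx], meta=meta),
        idx,
    )


class _FitState:
    """Per-pixel parameter store carried across iterations (warm starts)."""

    def __init__(self, n_pix: int, n_coil: int):
        self.params = np.zeros((n_pix, 3))  # [M0, M0*, T1*]
        self.fitted = np.zeros(n_pix, dtype=bool)
        self.scales = np.zeros((n_coil, n_pix), dtype=np.complex128)
        self.k = np.full(n_pix, np.nan)
        self.t1 = np.full(n_pix, np.nan)


def reconstruct(
    gridded: GriddedProjections,
    times: InversionTimeAxis,
    config: ReconConfig = ReconConfig(),
) -> tuple[ParameterMaps, ConvergenceLog]:
    """Run the full iterative reconstruction; returns maps and the metric log.

    With ``max_iters=0`` the initial model is fitted once and returned
    without any data-consistency iteration.
    """
    meta = gridded.meta
    n = meta.matrix
    if times.t_ms.size != meta.n_proj:
        raise ValueError("time axis length must equal the projection count")

    init_gridded, init_idx = subset_projections(gridded, config.nth_init)
    init_times = InversionTimeAxis(times.t_ms[init_idx])
    iter_gridded, iter_idx = subset_projections(gridded, config.nth_iter)
    iter_times = InversionTimeAxis(times.t_ms[iter_idx])

    phi = mean_phase_maps(gridded, last_n=min(config.phase_last_n, meta.n_proj))

    if config.initial_model == "mfm":
        model = build_mfm(
            init_gridded, init_times, config.t1_star_init_ms, eval_times=iter_times
        )
    elif config.initial_model == "ifm":
        model = build_ifm(init_gridded, init_times, eval_times=iter_times)
    else:  # ofm: every frame is its own projection's zero-filled image
        model = build_ofm(iter_gridded)

    sample_mask = None
    if config.sparsity_reinsertion:
        ref_k = composite_kspace(gridded, last_n=min(config.phase_last_n, meta.n_proj))
        sample_mask = sparsity_select(iter_gridded, ref_k, config.sparsity_fraction)

    # single precision halves the traffic on the (n_proj, n_coil, N, N)
    # arrays that dominate each iteration; parameter fits stay in float64
    work_dtype = np.complex64 if config.single_precision else np.complex128
    if config.single_precision:
        iter_gridded = GriddedProjections(
            values=iter_gridded.values.astype(work_dtype),
            mask=iter_gridded.mask,
            meta=iter_gridded.meta,
        )
        model = ModelSeries(images=model.images.astype(work_dtype))

    state = _FitState(n * n, meta.n_coil)
    conv = ConvergenceLog()
    fitted_once = False

    def fit_pass(images: np.ndarray) -> None:
        nonlocal fitted_once
        comb = combine(ModelSeries(images), phi, amplitude_root=config.amplitude_root)
        curves = comb.values.reshape(len(iter_times), -1).T  # (B, T)
        peak = np.abs(curves).max(axis=1)
        fg = peak >= config.background_threshold * peak.max()
        d = curves[fg]
        init = _default_init(d, config.t1_star_init_ms)
        warm = state.fitted[fg]
        init[warm] = state.params[fg][warm]
        params, converged = fit_three_param_batch(
            d, iter_times, init=init, max_iter=config.fit_max_iter, rtol=config.fit_rtol
        )
        t1, kk = compute_t1(params[:, 0], params[:, 1], params[:, 2])
        # a fit collapsed onto the parameter floor has effectively M0* = 0,
        # and a non-positive M0 implies T1 <= 0: both leave T1 undefined
        # (masked) for that pixel, like any zero steady state
        degenerate = (
            (params[:, 1] <= 1e-10 * np.abs(d).max(axis=1))
            | (params[:, 2] <= 2.0 * T1_STAR_BOUNDS_MS[0])
            | (params[:, 0] <= 0.0)
        )
        t1 = np.where(degenerate, np.nan, t1)
        kk = np.where(degenerate, np.nan, kk)
        coil_curves = images.reshape(len(iter_times), meta.n_coil, -1)[:, :, fg]
        scales, valid = fit_coil_scale_batch(coil_curves, kk, params[:, 2], iter_times)
        state.params[fg] = params
        state.fitted[fg] = True
        state.k[fg] = kk
        state.t1[fg] = t1
        state.scales[:, fg] = scales
        fitted_once = True
        if not np.all(converged):
            log.debug("%d of %d pixels not fully converged", int(np.sum(~converged)), d.shape[0])

    for it in range(1, config.iterations + 1):
        model_k = model_to_kspace(model)
        metric = consistency_metric(model_k, iter_gridded)
        conv.append(it, metric, time.time())
        log.info("iteration %d: consistency metric %.6g", it, metric)
        if fitted_once and len(conv) >= 2:
            prev = conv.metric[-2]
            if prev > 0 and abs(metric - prev) / prev < config.tol:
                log.info("terminated: relative metric change below %.2g", config.tol)
                break
        consistent_k = reinsert(
            model_k,
            iter_gridded,
            circular_mask=config.circular_mask,
            radius=config.mask_radius,
            sample_mask=sample_mask,
        )
        images = ifft2c(consistent_k)
        fit_pass(images)
        model = rebuild_model(
            state.scales.reshape(meta.n_coil, n, n),
            state.k.reshape(n, n),
            state.params[:, 2].reshape(n, n),
            iter_times,
            dtype=work_dtype,
        )

    if not fitted_once:  # max_iters == 0: fit the initial model itself
        fit_pass(model.images)

    t1s_map = np.where(state.fitted, state.params[:, 2], np.nan)
    maps = ParameterMaps(
        m0=state.params[:, 0].reshape(n, n),
        m0_star=state.params[:, 1].reshape(n, n),
        t1_star_ms=t1s_map.reshape(n, n),
        k=state.k.reshape(n, n),
        t1_ms=state.t1.reshape(n, n),
        coil_scale=state.scales.reshape(meta.n_coil, n, n),
        fitted=state.fitted.reshape(n, n),
    )
    return maps, conv


def roi_stats(
    t1_map: np.ndarray, masks: Mapping[str, np.ndarray]
) -> pd.DataFrame:
    """Mean, sample standard deviation and their ratio of T1 inside each ROI.

    NaN pixels are excluded; an empty (or all-NaN) ROI yields a NaN row, and
    a zero-std ROI reports an infinite ratio.
    """
    rows = []
    for name, mask in masks.items():
        vals = np.asarray(t1_map)[np.asarray(mask, dtype=bool)]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            rows.append({"roi": name, "mean": np.nan, "std": np.nan, "mean_over_std": np.nan})
            continue
        mean = float(np.mean(vals))
        std = float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan
        if std == 0.0:
            ratio = np.inf
        elif np.isnan(std):
            ratio = np.nan
        else:
            ratio = mean / std
        rows.append({"roi": name, "mean": mean, "std": std, "mean_over_std": ratio})
    return pd.DataFrame(rows, columns=["roi", "mean", "std", "mean_over_std"])
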