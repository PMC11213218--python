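"""Conventional nested model selection (NMS).

Each voxel's dR1 trace is fit with the three nested tracer-kinetic models
(see :mod:`dcepnms.pk_models`) by least squares on the retained frames, and
the simplest statistically adequate model is chosen by sequential partial
F-tests at a stated confidence level (default 95%): Model 1 vs 2, then --
only if Model 2 wins -- Model 2 vs 3.  Each comparison adds one parameter,
so the F statistic is

    F = (RSS_simple - RSS_complex) / (RSS_complex / (n_obs - p_complex))

with (1, n_obs - p_complex) degrees of freedom.

Two deliberate numerical choices:

* ``ModelFit.rss`` is the *unconstrained* ordinary-least-squares residual,
  which makes the nested RSS ordering exact and the F statistic follow its
  classical null distribution; the *reported parameters* are projected onto
  the non-negative orthant (clip-and-refit), since negative vp/Ktrans are
  unphysical.
* the Model-3 kep search always includes the degenerate kep = 0 candidate
  (identically Model 2), so RSS(M3) <= RSS(M2) holds unconditionally.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import f as f_dist

from .exceptions import ContractViolation, DegenerateInputError, DomainError
from .pk_models import (
    SECONDS_PER_MINUTE,
    AIFCurve,
    PKParams,
    TimeGrid,
    cumulative_integral,
    exp_convolution,
)

__all__ = [
    "ModelFit",
    "NMSVoxelResult",
    "NMSVolumeResult",
    "Model3Workspace",
    "fit_model1",
    "fit_model2",
    "fit_model3",
    "fit_voxel",
    "select_model",
    "fit_volume",
    "DEFAULT_KEP_BOUNDS",
]

DEFAULT_KEP_BOUNDS = (1e-3, 5.0)  # 1/min, physiological search range
_N_KEP_COARSE = 60
_GOLDEN_TOL = 1e-5  # absolute kep interval tolerance, 1/min
_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class ModelFit:
    """Least-squares fit of one nested model to one voxel trace.

    ``rss`` is the unconstrained OLS residual sum of squares used for model
    comparison; ``params`` holds the non-negativity-projected estimates.
    """

    model_order: int
    params: PKParams
    rss: float
    n_free: int
    n_obs: int
    #: total sum of squares of the retained trace; sets the numerical
    #: floor below which RSS differences count as rounding noise
    tss: float = 0.0


@dataclass(frozen=True)
class NMSVoxelResult:
    """Selected label plus all three fits for one voxel.

    All three fits are retained regardless of the label because the
    model-averaging stage needs vp from every model, Ktrans from Models 2-3
    and kep from Model 3.
    """

    label: int
    fits: tuple[ModelFit, ModelFit, ModelFit]
    confidence_level: float


@dataclass
class NMSVolumeResult:
    """Per-voxel labels and per-model parameter maps over a volume.

    Maps are NaN outside ``brain_mask``; ktrans/kep are in 1/min.
    """

    label_map: np.ndarray
    vp_m1: np.ndarray
    vp_m2: np.ndarray
    vp_m3: np.ndarray
    ktrans_m2: np.ndarray
    ktrans_m3: np.ndarray
    kep_m3: np.ndarray
    brain_mask: np.ndarray
    confidence_level: float

    def selected_vp(self) -> np.ndarray:
        """vp of the selected model at each voxel."""
        out = np.where(self.label_map == 1, self.vp_m1,
                       np.where(self.label_map == 2, self.vp_m2, self.vp_m3))
        return np.where(self.brain_mask, out, np.nan)

    def selected_ktrans(self) -> np.ndarray:
        """Ktrans of the selected model; 0 where Model 1 was selected."""
        out = np.where(self.label_map == 2, self.ktrans_m2,
                       np.where(self.label_map == 3, self.ktrans_m3, 0.0))
        return np.where(self.brain_mask, out, np.nan)

    def to_dataframe(self):
        """Per-voxel fit table: one row per masked voxel with coordinates,
        the selected label and every per-model parameter estimate."""
        import pandas as pd

        coords = np.argwhere(self.brain_mask)
        idx = tuple(coords.T)
        return pd.DataFrame({
            "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
            "label": self.label_map[idx],
            "vp_m1": self.vp_m1[idx], "vp_m2": self.vp_m2[idx],
            "vp_m3": self.vp_m3[idx], "ktrans_m2": self.ktrans_m2[idx],
            "ktrans_m3": self.ktrans_m3[idx], "kep_m3": self.kep_m3[idx],
        })


def _retained(trace, aif: AIFCurve, grid: TimeGrid) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(trace, dtype=float)
    if y.ndim != 1 or y.size != grid.n_frames:
        raise DomainError("trace length does not match grid")
    if not np.all(np.isfinite(y)):
        raise DomainError("trace must be finite")
    return y[grid.retained], aif.values[grid.retained]


def fit_model1(trace, aif: AIFCurve, grid: TimeGrid) -> ModelFit:
    """Model 1: no-intercept regression of the trace on the AIF.

    Closed form vp = sum(C_t * C_a) / sum(C_a^2), clipped at 0 for the
    reported estimate.
    """
    y, a = _retained(trace, aif, grid)
    saa = float(a @ a)
    if saa <= 0:
        raise DegenerateInputError("AIF is zero over the retained frames")
    yy = float(y @ y)
    vp_ols = float(a @ y) / saa
    rss = yy - (float(a @ y) ** 2) / saa
    return ModelFit(
        model_order=1,
        params=PKParams(vp=max(vp_ols, 0.0), model_order=1),
        rss=max(rss, 0.0),
        n_free=1,
        n_obs=y.size,
        tss=yy,
    )


def _ols2(y: np.ndarray, a: np.ndarray, g: np.ndarray) -> tuple[float, float, float]:
    """Unconstrained 2-column OLS of y on [a, g] via the normal equations.

    Returns ``(coef_a, coef_g, rss)``; raises on a rank-deficient design.
    """
    saa = float(a @ a)
    sgg = float(g @ g)
    sag = float(a @ g)
    det = saa * sgg - sag * sag
    if det <= 1e-12 * max(saa * sgg, 1e-300):
        raise DegenerateInputError("design columns are (near) collinear")
    say = float(a @ y)
    sgy = float(g @ y)
    ca = (sgg * say - sag * sgy) / det
    cg = (saa * sgy - sag * say) / det
    rss = float(y @ y) - (ca * say + cg * sgy)
    return ca, cg, max(rss, 0.0)


def _clip_refit2(y, a, g, ca, cg) -> tuple[float, float]:
    """Project a 2-parameter fit onto the non-negative orthant.

    If the OLS solution is infeasible, the constrained optimum lies on a
    boundary: refit the remaining free column alone and keep the better of
    the two single-column candidates.
    """
    if ca >= 0 and cg >= 0:
        return ca, cg
    # candidate 1: cg = 0, fit a alone
    ca1 = max(float(a @ y) / float(a @ a), 0.0)
    rss1 = float(y @ y) - 2 * ca1 * float(a @ y) + ca1 * ca1 * float(a @ a)
    # candidate 2: ca = 0, fit g alone
    cg2 = max(float(g @ y) / float(g @ g), 0.0)
    rss2 = float(y @ y) - 2 * cg2 * float(g @ y) + cg2 * cg2 * float(g @ g)
    if rss1 <= rss2:
        return ca1, 0.0
    return 0.0, cg2


def fit_model2(trace, aif: AIFCurve, grid: TimeGrid) -> ModelFit:
    """Model 2 (Patlak): linear least squares on [AIF, int AIF]."""
    y, a = _retained(trace, aif, grid)
    g = cumulative_integral(aif.values, grid)[grid.retained]
    ca, cg, rss = _ols2(y, a, g)
    vp, kt_per_s = _clip_refit2(y, a, g, ca, cg)
    return ModelFit(
        model_order=2,
        params=PKParams(vp=vp, ktrans=kt_per_s * SECONDS_PER_MINUTE, model_order=2),
        rss=rss,
        n_free=2,
        n_obs=y.size,
        tss=float(y @ y),
    )


class Model3Workspace:
    """Shared precomputation for Model-3 fits against one (AIF, grid).

    Holds the retained AIF column, the kep-convolution columns for the
    coarse log-spaced kep grid and their Gram quantities, so a volume fit
    pays the convolution cost once rather than per voxel.
    """

    def __init__(self, aif: AIFCurve, grid: TimeGrid,
                 kep_bounds: tuple[float, float] = DEFAULT_KEP_BOUNDS,
                 n_coarse: int = _N_KEP_COARSE):
        lo, hi = kep_bounds
        if not 0 < lo < hi:
            raise DomainError(f"invalid kep bounds {kep_bounds}")
        self.grid = grid
        self.aif = aif
        self.kep_bounds = (float(lo), float(hi))
        self.kep_candidates = np.concatenate(
            [[0.0], np.geomspace(lo, hi, n_coarse)]
        )
        self.a = aif.values[grid.retained]
        self.columns = np.stack(
            [exp_convolution(aif.values, k, grid)[grid.retained]
             for k in self.kep_candidates]
        )
        self.saa = float(self.a @ self.a)
        self.sag = self.columns @ self.a
        self.sgg = (self.columns * self.columns).sum(axis=1)
        self.det = self.saa * self.sgg - self.sag**2

    def conv_column(self, kep: float) -> np.ndarray:
        return exp_convolution(self.aif.values, kep, self.grid)[self.grid.retained]


def fit_model3(
    trace,
    aif: AIFCurve,
    grid: TimeGrid,
    kep_bounds: tuple[float, float] = DEFAULT_KEP_BOUNDS,
    workspace: Model3Workspace | None = None,
) -> ModelFit:
    """Model 3 (extended Patlak) by separable least squares.

    For fixed kep the model is linear in (vp, Ktrans); kep is located by a
    coarse log-spaced scan over ``kep_bounds`` (plus the degenerate kep = 0
    candidate, which reproduces Model 2 exactly) followed by golden-section
    refinement of the profiled RSS around the best coarse candidate.  Ties
    resolve to the smallest kep.
    """
    if workspace is None:
        workspace = Model3Workspace(aif, grid, kep_bounds)
    elif workspace.kep_bounds != (float(kep_bounds[0]), float(kep_bounds[1])):
        raise DomainError("workspace kep bounds differ from requested bounds")
    y, a = _retained(trace, aif, grid)
    yy = float(y @ y)
    say = float(a @ y)
    saa = workspace.saa
    if saa <= 0:
        raise DegenerateInputError("AIF is zero over the retained frames")

    # vectorized profiled RSS over the coarse kep candidates
    sgy = workspace.columns @ y
    with np.errstate(divide="ignore", invalid="ignore"):
        ca_all = (workspace.sgg * say - workspace.sag * sgy) / workspace.det
        cg_all = (saa * sgy - workspace.sag * say) / workspace.det
        rss_all = yy - (ca_all * say + cg_all * sgy)
    bad = workspace.det <= 1e-12 * np.maximum(saa * workspace.sgg, 1e-300)
    rss_all = np.where(bad | ~np.isfinite(rss_all), np.inf, np.maximum(rss_all, 0.0))
    if not np.isfinite(rss_all).any():
        raise DegenerateInputError("Model-3 design degenerate at every kep")
    best = int(np.argmin(rss_all))  # first minimum -> smallest kep on ties
    best_kep = float(workspace.kep_candidates[best])
    best_sol = (float(ca_all[best]), float(cg_all[best]), float(rss_all[best]))

    def profiled(kep: float) -> tuple[float, float, float]:
        g = workspace.conv_column(kep)
        sgg = float(g @ g)
        sag = float(a @ g)
        det = saa * sgg - sag * sag
        if det <= 1e-12 * max(saa * sgg, 1e-300):
            return 0.0, 0.0, np.inf
        sgy_ = float(g @ y)
        ca = (sgg * say - sag * sgy_) / det
        cg = (saa * sgy_ - sag * say) / det
        return ca, cg, max(yy - (ca * say + cg * sgy_), 0.0)

    if best > 0:  # refine inside the positive bracket around the best candidate
        lo_idx = max(best - 1, 1)
        hi_idx = min(best + 1, len(workspace.kep_candidates) - 1)
        x0 = float(workspace.kep_candidates[lo_idx])
        x1 = float(workspace.kep_candidates[hi_idx])
        xa = x1 - _INVPHI * (x1 - x0)
        xb = x0 + _INVPHI * (x1 - x0)
        fa = profiled(xa)
        fb = profiled(xb)
        while (x1 - x0) > _GOLDEN_TOL:
            if fa[2] <= fb[2]:
                x1, xb, fb = xb, xa, fa
                xa = x1 - _INVPHI * (x1 - x0)
                fa = profiled(xa)
            else:
                x0, xa, fa = xa, xb, fb
                xb = x0 + _INVPHI * (x1 - x0)
                fb = profiled(xb)
        refined_kep, refined = (xa, fa) if fa[2] <= fb[2] else (xb, fb)
        if refined[2] < best_sol[2]:
            best_kep, best_sol = float(refined_kep), refined

    ca, cg, rss = best_sol
    col = workspace.columns[0] if best_kep == 0.0 else workspace.conv_column(best_kep)
    vp, kt_per_s = _clip_refit2(y, a, col, ca, cg)
    return ModelFit(
        model_order=3,
        params=PKParams(vp=vp, ktrans=kt_per_s * SECONDS_PER_MINUTE,
                        kep=best_kep, model_order=3),
        rss=rss,
        n_free=3,
        n_obs=y.size,
        tss=yy,
    )


@lru_cache(maxsize=64)
def _f_critical(confidence_level: float, dfd: int) -> float:
    return float(f_dist.ppf(confidence_level, 1, dfd))


def _partial_f(rss_simple: float, rss_complex: float, dfd: int, floor: float) -> float:
    """Partial F with 1 numerator dof.

    Improvements below ``floor`` (rounding noise on an exactly-representable
    fit) count as zero, so noiseless data never triggers spurious
    rejections; at realistic noise levels true improvements are orders of
    magnitude above the floor.
    """
    if rss_simple - rss_complex <= floor:
        return 0.0
    if rss_complex <= floor:
        return np.inf
    return (rss_simple - rss_complex) / (rss_complex / dfd)


def select_model(
    fits: tuple[ModelFit, ModelFit, ModelFit],
    confidence_level: float = 0.95,
) -> NMSVoxelResult:
    """Sequential partial F-tests over the nested fits.

    Model 2 is accepted over Model 1 only if its extra parameter is
    significant at ``1 - confidence_level``; Model 3 is tested only after
    Model 2 wins.  The label is the most complex model whose addition was
    significant.
    """
    if not 0 < confidence_level < 1:
        raise DomainError("confidence_level must be in (0, 1)")
    f1, f2, f3 = fits
    if (f1.model_order, f2.model_order, f3.model_order) != (1, 2, 3):
        raise DomainError("fits must be ordered (model 1, model 2, model 3)")
    tol = 1e-12 * f1.tss + 1e-9 * f1.rss + 1e-300
    if f2.rss > f1.rss + tol or f3.rss > f2.rss + tol:
        raise ContractViolation(
            f"nested RSS not monotone: {f1.rss}, {f2.rss}, {f3.rss}"
        )
    label = 1
    floor = 1e-12 * max(f1.tss, 1e-300)
    F12 = _partial_f(f1.rss, f2.rss, f2.n_obs - f2.n_free, floor)
    if F12 > _f_critical(confidence_level, f2.n_obs - f2.n_free):
        label = 2
        F23 = _partial_f(f2.rss, f3.rss, f3.n_obs - f3.n_free, floor)
        if F23 > _f_critical(confidence_level, f3.n_obs - f3.n_free):
            label = 3
    return NMSVoxelResult(label=label, fits=(f1, f2, f3),
                          confidence_level=confidence_level)


def fit_voxel(
    trace,
    aif: AIFCurve,
    grid: TimeGrid,
    confidence_level: float = 0.95,
    kep_bounds: tuple[float, float] = DEFAULT_KEP_BOUNDS,
    workspace: Model3Workspace | None = None,
) -> NMSVoxelResult:
    """Fit all three models to one trace and select the label."""
    fits = (
        fit_model1(trace, aif, grid),
        fit_model2(trace, aif, grid),
        fit_model3(trace, aif, grid, kep_bounds, workspace),
    )
    return select_model(fits, confidence_level)


def fit_volume(
    delta_r1: np.ndarray,
    brain_mask: np.ndarray,
    aif: AIFCurve,
    grid: TimeGrid,
    confidence_level: float = 0.95,
    kep_bounds: tuple[float, float] = DEFAULT_KEP_BOUNDS,
) -> NMSVolumeResult:
    """Run the per-voxel NMS pipeline over every voxel in ``brain_mask``.

    All per-model parameter maps are stored (not just the selected model's)
    because the probabilistic stage averages across models.
    """
    data = np.asarray(delta_r1, dtype=float)
    mask = np.asarray(brain_mask, dtype=bool)
    if data.ndim != 4:
        raise DomainError("delta_r1 must be 4-D (x, y, z, t)")
    if mask.shape != data.shape[:3]:
        raise DomainError("brain_mask shape must match spatial dimensions")
    if not mask.any():
        raise DegenerateInputError("brain mask is empty")

    workspace = Model3Workspace(aif, grid, kep_bounds)
    shape = mask.shape
    label_map = np.zeros(shape, dtype=np.int8)
    maps = {name: np.full(shape, np.nan) for name in
            ("vp_m1", "vp_m2", "vp_m3", "ktrans_m2", "ktrans_m3", "kep_m3")}
    for ix, iy, iz in np.argwhere(mask):
        res = fit_voxel(data[ix, iy, iz], aif, grid, confidence_level,
                        kep_bounds, workspace)
        f1, f2, f3 = res.fits
        label_map[ix, iy, iz] = res.label
        maps["vp_m1"][ix, iy, iz] = f1.params.vp
        maps["vp_m2"][ix, iy, iz] = f2.params.vp
        maps["vp_m3"][ix, iy, iz] = f3.params.vp
        maps["ktrans_m2"][ix, iy, iz] = f2.params.ktrans
        maps["ktrans_m3"][ix, iy, iz] = f3.params.ktrans
        maps["kep_m3"][ix, iy, iz] = f3.params.kep
    return NMSVolumeResult(
        label_map=label_map,
        brain_mask=mask,
        confidence_level=confidence_level,
        **maps,
    )
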