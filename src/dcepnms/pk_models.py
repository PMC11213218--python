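"""Forward evaluation of the three nested pharmacokinetic models.

The tissue contrast-agent concentration (proportional to the change in the
longitudinal relaxation rate, dR1) is described by one of three nested
tracer-kinetic models of increasing physiological complexity:

* Model 1 -- intact vasculature, no leakage::

      C_t(t) = vp * C_a(t)

* Model 2 -- leakage without measurable back-flux (Patlak)::

      C_t(t) = vp * C_a(t) + Ktrans * int_0^t C_a(u) du

* Model 3 -- leakage with back-flux (extended Patlak / extended Tofts)::

      C_t(t) = vp * C_a(t) + Ktrans * int_0^t C_a(u) exp(-kep (t-u)) du

where ``C_a`` is the arterial input function (AIF), ``vp`` the fractional
plasma volume, ``Ktrans`` the forward volumetric transfer constant and
``kep`` the reverse transfer constant.  ``ve = Ktrans / kep`` is the
extravascular-extracellular volume fraction.

Internally all time is in seconds.  ``Ktrans`` and ``kep`` are accepted and
reported in 1/min (the unit the field uses) and converted at the operation
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import lfilter

from .exceptions import DomainError

__all__ = [
    "SECONDS_PER_MINUTE",
    "TimeGrid",
    "AIFCurve",
    "PKParams",
    "cumulative_integral",
    "exp_convolution",
    "eval_model",
]

SECONDS_PER_MINUTE = 60.0

#: default acquisition: 400 frames, 1.55 s apart, bolus ~60 s after start
DEFAULT_N_FRAMES = 400
DEFAULT_FRAME_SPACING_S = 1.55
DEFAULT_INJECTION_INDEX = int(np.ceil(60.0 / DEFAULT_FRAME_SPACING_S))  # 39
DEFAULT_RETAINED_START = 20


@dataclass(frozen=True)
class TimeGrid:
    """Uniform acquisition time grid.

    Parameters
    ----------
    n_frames : int
        Number of acquired frames.
    dt : float
        Frame spacing in seconds (strictly positive).
    injection_index : int
        Frame index of bolus arrival.
    retained_start : int
        Index of the first frame kept for analysis; earlier frames are
        discarded to let the spin system reach saturation equilibrium.
    t0 : float
        Time of the first frame, seconds.
    """

    n_frames: int = DEFAULT_N_FRAMES
    dt: float = DEFAULT_FRAME_SPACING_S
    injection_index: int = DEFAULT_INJECTION_INDEX
    retained_start: int = DEFAULT_RETAINED_START
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise DomainError("TimeGrid needs at least 2 frames")
        if not self.dt > 0:
            raise DomainError("frame spacing must be strictly positive")
        if not (0 <= self.retained_start <= self.injection_index < self.n_frames):
            raise DomainError(
                "require 0 <= retained_start <= injection_index < n_frames, got "
                f"retained_start={self.retained_start}, "
                f"injection_index={self.injection_index}, n_frames={self.n_frames}"
            )

    @classmethod
    def from_timepoints(
        cls,
        timepoints: np.ndarray,
        injection_index: int,
        retained_start: int = DEFAULT_RETAINED_START,
    ) -> "TimeGrid":
        """Build a grid from an explicit time vector, verifying uniformity
        to 1e-9 relative."""
        t = np.asarray(timepoints, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise DomainError("timepoints must be a 1-D array of length >= 2")
        steps = np.diff(t)
        dt = float(steps[0])
        if dt <= 0 or np.any(np.abs(steps - dt) > 1e-9 * max(abs(dt), 1.0)):
            raise DomainError("timepoints must be uniformly increasing")
        return cls(
            n_frames=t.size,
            dt=dt,
            injection_index=injection_index,
            retained_start=retained_start,
            t0=float(t[0]),
        )

    @property
    def timepoints(self) -> np.ndarray:
        """Frame times in seconds."""
        return self.t0 + self.dt * np.arange(self.n_frames)

    @property
    def injection_time(self) -> float:
        return self.t0 + self.dt * self.injection_index

    @property
    def retained(self) -> slice:
        """Slice selecting the frames kept for analysis."""
        return slice(self.retained_start, self.n_frames)

    @property
    def n_retained(self) -> int:
        return self.n_frames - self.retained_start


@dataclass(frozen=True)
class AIFCurve:
    """Arterial input function sampled on a :class:`TimeGrid`.

    Values are relaxation-rate changes (1/s), proportional to the plasma
    contrast-agent concentration. The curve is zero (to within the noise
    floor) before ``grid.injection_index``.
    """

    values: np.ndarray
    grid: TimeGrid

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size != self.grid.n_frames:
            raise DomainError(
                f"AIF length {v.size} does not match grid length {self.grid.n_frames}"
            )
        if not np.all(np.isfinite(v)):
            raise DomainError("AIF values must be finite")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class PKParams:
    """Pharmacokinetic parameters of one nested model.

    ``vp`` is dimensionless (fraction), ``ktrans`` and ``kep`` are in 1/min.
    ``model_order`` selects which terms are active: order 1 uses only
    ``vp``; order 2 adds ``ktrans``; order 3 adds ``kep``.
    """

    vp: float
    ktrans: float = 0.0
    kep: float = 0.0
    model_order: int = 1

    def __post_init__(self) -> None:
        if self.model_order not in (1, 2, 3):
            raise DomainError(f"model_order must be 1, 2 or 3, got {self.model_order}")
        if self.vp < 0 or self.ktrans < 0 or self.kep < 0:
            raise DomainError("vp, ktrans and kep must be non-negative")

    @property
    def ve(self) -> float:
        """Extravascular-extracellular volume fraction Ktrans/kep
        (defined only for kep > 0)."""
        if self.kep <= 0:
            raise DomainError("ve undefined for kep <= 0")
        return self.ktrans / self.kep


def _curve_values(curve, grid: TimeGrid) -> np.ndarray:
    if isinstance(curve, AIFCurve):
        if curve.grid.n_frames != grid.n_frames:
            raise DomainError("curve grid and evaluation grid lengths differ")
        return curve.values
    v = np.asarray(curve, dtype=float)
    if v.ndim != 1 or v.size != grid.n_frames:
        raise DomainError(
            f"curve length {v.size} does not match grid length {grid.n_frames}"
        )
    return v


def cumulative_integral(curve, grid: TimeGrid) -> np.ndarray:
    """Running trapezoidal integral of ``curve`` from the first frame.

    Element ``k`` approximates ``int_{t0}^{t_k} curve(u) du``; the first
    element is exactly 0.  Units: (1/s) * s.
    """
    v = _curve_values(curve, grid)
    return cumulative_trapezoid(v, dx=grid.dt, initial=0.0)


def _conv_segment_coefficients(k: float, dt: float) -> tuple[float, float, float]:
    """Exact update coefficients for the exponential convolution of a
    piecewise-linear curve on a uniform grid.

    Returns ``(E, A, B)`` such that ``y[i] = E*y[i-1] + A*c[i-1] + B*c[i]``
    where ``E = exp(-k*dt)``.  Derived by integrating the linear segment
    against the exponential kernel; formulated with expm1 to stay accurate
    for k*dt << 1.
    """
    kdt = k * dt
    E = float(np.exp(-kdt))
    u = -float(np.expm1(-kdt))  # 1 - E, accurate for small kdt
    # int_0^dt e^{-k(dt-s)} ds = u / k
    # int_0^dt s e^{-k(dt-s)} ds = dt*u/k - (u - kdt*E)/k^2
    B = u / k - (u - kdt * E) / (k * k * dt)  # weight of c[i]
    A = u / k - B                             # weight of c[i-1]
    return E, A, B


def exp_convolution(curve, kep: float, grid: TimeGrid) -> np.ndarray:
    """``int_0^t curve(u) exp(-kep (t-u)) du`` at every frame.

    ``kep`` is in 1/min and converted to 1/s internally.  ``kep = 0``
    reduces exactly to :func:`cumulative_integral`.  The integral is exact
    for a piecewise-linear interpolation of ``curve`` between frames,
    evaluated by a stable O(n) first-order recursion.
    """
    if kep < 0:
        raise DomainError(f"kep must be non-negative, got {kep}")
    v = _curve_values(curve, grid)
    k = kep / SECONDS_PER_MINUTE
    if k * grid.dt < 1e-12:
        return cumulative_integral(v, grid)
    E, A, B = _conv_segment_coefficients(k, grid.dt)
    drive = np.empty_like(v)
    drive[0] = 0.0
    drive[1:] = A * v[:-1] + B * v[1:]
    # y[i] = E*y[i-1] + drive[i]  <=>  first-order IIR filter
    return lfilter([1.0], [1.0, -E], drive)


def eval_model(params: PKParams, aif: AIFCurve, grid: TimeGrid | None = None) -> np.ndarray:
    """Noiseless tissue dR1 trace for one voxel under ``params``.

    Dispatches on ``params.model_order``; the models nest, so order 2 with
    ``ktrans = 0`` equals order 1 and order 3 with ``kep = 0`` equals
    order 2.
    """
    if grid is None:
        grid = aif.grid
    v = _curve_values(aif, grid)
    trace = params.vp * v
    if params.model_order == 1:
        return trace
    ktrans_per_s = params.ktrans / SECONDS_PER_MINUTE
    if params.model_order == 2:
        return trace + ktrans_per_s * cumulative_integral(v, grid)
    return trace + ktrans_per_s * exp_convolution(v, params.kep, grid)
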