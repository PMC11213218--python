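"""Synthetic DCE-MRI phantom studies.

The real data this pipeline targets (rat brains with orthotopic gliomas,
~230k voxel time-courses) is not publicly available, so this module
generates phantoms with the statistical structure the analysis assumes:

* a population arterial input function (gamma-variate bolus plus a slower
  recirculation/washout component) shared by all voxels;
* three concentric tissue regions obeying the three nested models --
  background = Model 1 (normal vasculature), tumor core = Model 2
  (leakage, no back-flux), tumor rim = Model 3 (leakage with back-flux);
* per-voxel parameters drawn from physiologically plausible ranges
  (vp ~ U[0.01, 0.04], Ktrans ~ U[0.05, 0.3] /min, kep ~ U[0.5, 2.5] /min);
* additive Gaussian noise on dR1 (dR1 is a derived relaxivity change, not
  a magnitude image, so Rician noise is not appropriate);
* the acquisition protocol: 400 frames 1.55 s apart, injection ~60 s after
  the start, with the first 20 frames excluded from analysis.

A "cohort" is a list of such studies with per-animal geometry jitter,
standing in for a multi-animal dataset in cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import DomainError
from .pk_models import AIFCurve, PKParams, TimeGrid, eval_model, cumulative_integral, exp_convolution, SECONDS_PER_MINUTE

__all__ = [
    "PhantomSpec",
    "SyntheticStudy",
    "make_aif",
    "make_geometry",
    "simulate_study",
    "exclude_and_normalize",
    "normalize_profiles",
    "make_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, parameter distributions and noise level of one phantom.

    The tumor is a disc (per slice) of radius ``tumor_radius`` centered at
    ``tumor_center`` (defaults to the slice center); voxels within
    ``core_radius`` are Model 2, the annulus out to ``tumor_radius`` is
    Model 3, everything else is Model 1. ``noise_sd`` is the Gaussian noise
    standard deviation relative to the peak of the noiseless phantom
    (0.05 = SNR 20 at the enhancing peak).
    """

    shape: tuple[int, int, int] = (32, 32, 3)
    tumor_center: tuple[float, float] | None = None
    tumor_radius: float = 9.0
    core_radius: float = 5.5
    vp_range: tuple[float, float] = (0.01, 0.04)
    ktrans_range: tuple[float, float] = (0.05, 0.3)
    kep_range: tuple[float, float] = (0.5, 2.5)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise DomainError("shape must be three positive dimensions")
        if not 0 < self.core_radius < self.tumor_radius:
            raise DomainError("require 0 < core_radius < tumor_radius")
        for lo, hi in (self.vp_range, self.ktrans_range, self.kep_range):
            if lo < 0 or hi < lo:
                raise DomainError("parameter ranges must be non-negative intervals")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")


@dataclass
class SyntheticStudy:
    """One phantom acquisition with full ground truth."""

    delta_r1: np.ndarray          # 4-D (x, y, z, t)
    labels: np.ndarray            # 3-D ground-truth model labels (1/2/3)
    vp_true: np.ndarray
    ktrans_true: np.ndarray       # 1/min, 0 in Model-1 voxels
    kep_true: np.ndarray          # 1/min, 0 outside Model-3 voxels
    aif: AIFCurve
    grid: TimeGrid
    brain_mask: np.ndarray        # 3-D boolean
    animal_id: str = "animal_00"
    noise_sd: float = 0.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


def make_aif(
    grid: TimeGrid,
    peak_amplitude: float = 2.5,
    alpha: float = 3.0,
    t_peak: float = 8.0,
    recirc_fraction: float = 0.25,
    recirc_rise: float = 25.0,
    recirc_decay: float = 300.0,
) -> AIFCurve:
    """Population AIF: gamma-variate first pass plus recirculation tail.

    The bolus is ``(s/t_peak)**alpha * exp(alpha*(1 - s/t_peak))`` (unit
    peak at ``s = t_peak`` after injection); the recirculation term is
    ``recirc_fraction * (1 - exp(-s/recirc_rise)) * exp(-s/recirc_decay)``.
    The sum is rescaled so its maximum equals ``peak_amplitude`` (1/s) and
    is exactly zero before the injection frame.
    """
    if alpha <= 0 or t_peak <= 0 or recirc_rise <= 0 or recirc_decay <= 0:
        raise DomainError("AIF shape parameters must be strictly positive")
    if peak_amplitude <= 0:
        raise DomainError("peak_amplitude must be strictly positive")
    t = grid.timepoints
    s = t - grid.injection_time
    post = s > 0
    values = np.zeros(grid.n_frames)
    sp = s[post]
    bolus = (sp / t_peak) ** alpha * np.exp(alpha * (1.0 - sp / t_peak))
    recirc = recirc_fraction * (1.0 - np.exp(-sp / recirc_rise)) * np.exp(-sp / recirc_decay)
    values[post] = bolus + recirc
    peak = values.max()
    if peak <= 0:
        raise DomainError("AIF is identically zero on this grid")
    values *= peak_amplitude / peak
    return AIFCurve(values=values, grid=grid)


def make_geometry(spec: PhantomSpec) -> np.ndarray:
    """Ground-truth label volume: 1 = background, 2 = core, 3 = rim."""
    nx, ny, nz = spec.shape
    cx, cy = spec.tumor_center if spec.tumor_center is not None else ((nx - 1) / 2.0, (ny - 1) / 2.0)
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    r = np.hypot(x - cx, y - cy)
    slice_labels = np.ones((nx, ny), dtype=np.int8)
    slice_labels[r <= spec.tumor_radius] = 3
    slice_labels[r <= spec.core_radius] = 2
    return np.repeat(slice_labels[:, :, None], nz, axis=2)


def simulate_study(
    spec: PhantomSpec,
    grid: TimeGrid | None = None,
    aif: AIFCurve | None = None,
    animal_id: str = "animal_00",
) -> SyntheticStudy:
    """Draw per-voxel parameters, evaluate the forward models, add noise.

    With ``spec.noise_sd == 0`` every voxel trace equals its
    :func:`~dcepnms.pk_models.eval_model` output exactly.
    """
    if grid is None:
        grid = TimeGrid()
    if aif is None:
        aif = make_aif(grid)
    rng = np.random.default_rng(spec.seed)
    labels = make_geometry(spec)
    shape = spec.shape
    vp = rng.uniform(*spec.vp_range, size=shape)
    ktrans = np.where(labels >= 2, rng.uniform(*spec.ktrans_range, size=shape), 0.0)
    kep = np.where(labels == 3, rng.uniform(*spec.kep_range, size=shape), 0.0)

    a = aif.values
    cum = cumulative_integral(a, grid)
    clean = vp[..., None] * a  # Model-1 term everywhere
    m2 = labels >= 2
    clean[m2] += (ktrans[m2, None] / SECONDS_PER_MINUTE) * cum
    # Model-3 voxels replace the Patlak integral with the kep convolution
    idx3 = np.argwhere(labels == 3)
    for ix, iy, iz in idx3:
        conv = exp_convolution(a, float(kep[ix, iy, iz]), grid)
        clean[ix, iy, iz] = (
            vp[ix, iy, iz] * a + ktrans[ix, iy, iz] / SECONDS_PER_MINUTE * conv
        )

    if spec.noise_sd > 0:
        sd = spec.noise_sd * float(np.abs(clean).max())
        data = clean + rng.normal(0.0, sd, size=clean.shape)
    else:
        sd = 0.0
        data = clean
    return SyntheticStudy(
        delta_r1=data,
        labels=labels,
        vp_true=vp,
        ktrans_true=ktrans,
        kep_true=kep,
        aif=aif,
        grid=grid,
        brain_mask=np.ones(shape, dtype=bool),
        animal_id=animal_id,
        noise_sd=sd,
    )


def exclude_and_normalize(
    trace: np.ndarray,
    grid: TimeGrid,
    method: str = "peak",
) -> tuple[np.ndarray, bool]:
    """Drop excluded frames and normalize a trace to a pure-shape profile.

    Frames before ``grid.retained_start`` are discarded; the mean of the
    remaining pre-injection frames is subtracted as baseline; the result is
    scaled to unit peak absolute value (``method="peak"``, default) or unit
    L2 norm (``method="l2"``).  Scaling by any positive factor leaves the
    output unchanged, so the SOM clusters by kinetic shape, not amplitude.

    Returns ``(profile, included)``; an (effectively) all-zero trace comes
    back all-zero with ``included = False``.
    """
    v = np.asarray(trace, dtype=float)[grid.retained]
    n_pre = grid.injection_index - grid.retained_start
    if n_pre > 0:
        v = v - v[:n_pre].mean()
    else:
        v = v.copy()
    if method == "peak":
        scale = np.abs(v).max()
    elif method == "l2":
        scale = float(np.linalg.norm(v))
    else:
        raise DomainError(f"unknown normalization method {method!r}")
    if scale <= 0:
        return np.zeros_like(v), False
    return v / scale, True


def normalize_profiles(
    traces: np.ndarray,
    grid: TimeGrid,
    method: str = "peak",
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`exclude_and_normalize` over rows of ``traces``.

    Returns ``(profiles, included)`` with ``profiles`` of shape
    ``(n, grid.n_retained)``.
    """
    v = np.asarray(traces, dtype=float)[..., grid.retained]
    n_pre = grid.injection_index - grid.retained_start
    if n_pre > 0:
        v = v - v[..., :n_pre].mean(axis=-1, keepdims=True)
    if method == "peak":
        scale = np.abs(v).max(axis=-1, keepdims=True)
    elif method == "l2":
        scale = np.linalg.norm(v, axis=-1, keepdims=True)
    else:
        raise DomainError(f"unknown normalization method {method!r}")
    included = scale[..., 0] > 0
    out = np.divide(v, scale, out=np.zeros_like(v), where=scale > 0)
    return out, included


def make_cohort(
    n_animals: int,
    spec: PhantomSpec | None = None,
    seed: int = 0,
    grid: TimeGrid | None = None,
    aif: AIFCurve | None = None,
) -> list[SyntheticStudy]:
    """Generate ``n_animals`` studies with per-animal geometry jitter.

    Each animal gets its own parameter draws and a tumor center/radius
    perturbation (center +-2 voxels, radii +-1 voxel), mimicking anatomical
    variability across subjects; seeds are derived deterministically from
    ``seed``.
    """
    if n_animals < 1:
        raise DomainError("n_animals must be >= 1")
    if spec is None:
        spec = PhantomSpec()
    if grid is None:
        grid = TimeGrid()
    if aif is None:
        aif = make_aif(grid)
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_animals)
    nx, ny, _ = spec.shape
    base_center = spec.tumor_center if spec.tumor_center is not None else ((nx - 1) / 2.0, (ny - 1) / 2.0)
    cohort = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        center = (
            base_center[0] + rng.uniform(-2.0, 2.0),
            base_center[1] + rng.uniform(-2.0, 2.0),
        )
        dr = rng.uniform(-1.0, 1.0)
        dc = rng.uniform(-1.0, 1.0)
        animal_spec = replace(
            spec,
            tumor_center=center,
            tumor_radius=spec.tumor_radius + dr,
            core_radius=max(1.0, spec.core_radius + dc),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cohort.append(
            simulate_study(animal_spec, grid=grid, aif=aif, animal_id=f"animal_{i:02d}")
        )
    return cohort
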