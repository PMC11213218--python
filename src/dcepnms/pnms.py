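"""Probabilistic nested model selection (PNMS).

The trained SOM's labeled hit map gives each neuron an empirical
probability over the three nested models; every voxel inherits the
probabilities of its BMU.  Permeability parameters are then
probability-weighted averages of the per-model least-squares estimates:

    vp     = (P1 vp_M1 + P2 vp_M2 + P3 vp_M3) / (P1 + P2 + P3)
    Ktrans = (P2 Ktrans_M2 + P3 Ktrans_M3) / (P2 + P3)
    ve     = Ktrans / kep_M3

Region masks are obtained by thresholding the probability maps (default
50%): the Model-1 region masks out the intact-vasculature tissue first,
and the Model-2/3 regions live in the remainder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ContractViolation, DegenerateInputError, DomainError
from .ksom import HitMap, SOMGrid, SOMWeights, bmu_indices
from .nms import NMSVolumeResult
from .pk_models import TimeGrid
from .synthetic import normalize_profiles

__all__ = [
    "NeuronProbabilityTable",
    "ProbabilityVolume",
    "AveragedParameterMaps",
    "KEP_FLOOR",
    "neuron_probabilities",
    "profile_probabilities",
    "voxel_probabilities",
    "averaged_vp",
    "averaged_ktrans",
    "averaged_ve",
    "averaged_parameter_maps",
]

#: kep (1/min) below which ve = Ktrans/kep is considered undefined
KEP_FLOOR = 1e-3


@dataclass(frozen=True)
class NeuronProbabilityTable:
    """Per-neuron probabilities of the three nested models.

    ``provenance[i]`` is -1 for a neuron whose probabilities come from its
    own hits, otherwise the index of the hit-bearing neuron it borrowed
    from (interpolating units that never won a BMU competition).
    """

    probs: np.ndarray       # (n_neurons, 3), rows sum to 1
    n_hits: np.ndarray      # (n_neurons,)
    provenance: np.ndarray  # (n_neurons,) int, -1 = direct


@dataclass
class ProbabilityVolume:
    """Voxel-wise model probabilities and thresholded region masks."""

    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    brain_mask: np.ndarray
    threshold: float

    def region_mask(self, model: int) -> np.ndarray:
        """Voxels whose probability of ``model`` exceeds the threshold.

        With threshold >= 0.5 the three masks are automatically pairwise
        disjoint; a voxel with all probabilities <= threshold belongs to no
        region.
        """
        p = {1: self.p1, 2: self.p2, 3: self.p3}[model]
        return (p > self.threshold) & self.brain_mask


@dataclass
class AveragedParameterMaps:
    """Model-averaged permeability maps.

    ``vp`` and ``ve`` are fractions, ``ktrans`` is 1/min.  ``ve`` is NaN
    where the Model-3 kep estimate is below :data:`KEP_FLOOR` (no
    measurable back-flux, so the ratio is undefined); all maps are NaN
    outside the brain mask.
    """

    vp: np.ndarray
    ktrans: np.ndarray
    ve: np.ndarray


def neuron_probabilities(hitmap: HitMap, grid: SOMGrid) -> NeuronProbabilityTable:
    """Empirical model probabilities per neuron from the labeled hit map.

    Neurons with no hits borrow the probabilities of the nearest
    hit-bearing neuron in lattice distance (ties to the lowest index).
    """
    total = hitmap.total
    if total.shape[0] != grid.n_neurons:
        raise DomainError("hit map size does not match grid")
    hit_idx = np.flatnonzero(total > 0)
    if hit_idx.size == 0:
        raise DegenerateInputError("every neuron is empty")
    probs = np.zeros((grid.n_neurons, 3))
    provenance = np.full(grid.n_neurons, -1, dtype=np.int64)
    probs[hit_idx] = hitmap.per_label[hit_idx] / total[hit_idx, None]
    for i in np.flatnonzero(total == 0):
        # argmin over hit-bearing neurons returns the first (lowest-index) tie
        donor = int(hit_idx[np.argmin(grid.distances[i, hit_idx])])
        probs[i] = probs[donor]
        provenance[i] = donor
    return NeuronProbabilityTable(probs=probs, n_hits=total.copy(),
                                  provenance=provenance)


def profile_probabilities(
    profiles: np.ndarray,
    weights: SOMWeights,
    table: NeuronProbabilityTable,
) -> np.ndarray:
    """(P1, P2, P3) for each normalized profile via its BMU.

    Profiles must be normalized exactly as the training data was; a
    max-absolute value far above 1 indicates raw (unnormalized) input.
    """
    x = np.atleast_2d(np.asarray(profiles, dtype=float))
    if x.size and np.abs(x).max() > 1.0 + 1e-6:
        raise ContractViolation(
            "profiles exceed unit peak; pass normalized profiles"
        )
    return table.probs[bmu_indices(weights, x)]


def voxel_probabilities(
    delta_r1: np.ndarray,
    grid: TimeGrid,
    weights: SOMWeights,
    table: NeuronProbabilityTable,
    brain_mask: np.ndarray,
    threshold: float = 0.5,
    normalization: str = "peak",
) -> ProbabilityVolume:
    """Project neuron probabilities to a voxel-wise probability volume.

    The 4-D study is normalized internally with the same transform used
    for SOM training, guaranteeing train/apply consistency.  Voxels whose
    trace is all-zero (excluded by normalization) get zero probabilities.
    """
    data = np.asarray(delta_r1, dtype=float)
    mask = np.asarray(brain_mask, dtype=bool)
    if data.ndim != 4 or mask.shape != data.shape[:3]:
        raise DomainError("need a 4-D study and a matching 3-D mask")
    if not 0 < threshold <= 1:
        raise DomainError(f"threshold must be in (0, 1], got {threshold}")
    traces = data[mask]
    profiles, included = normalize_profiles(traces, grid, normalization)
    p = np.zeros((traces.shape[0], 3))
    if included.any():
        p[included] = profile_probabilities(profiles[included], weights, table)
    maps = np.zeros(mask.shape + (3,))
    maps[mask] = p
    return ProbabilityVolume(
        p1=maps[..., 0], p2=maps[..., 1], p3=maps[..., 2],
        brain_mask=mask, threshold=threshold,
    )


def averaged_vp(p1, p2, p3, vp_m1, vp_m2, vp_m3):
    """Probability-weighted plasma volume across all three models.

    Voxels with a zero probability total are undefined (NaN).
    """
    p1, p2, p3 = np.asarray(p1, float), np.asarray(p2, float), np.asarray(p3, float)
    denom = p1 + p2 + p3
    numer = p1 * vp_m1 + p2 * vp_m2 + p3 * vp_m3
    return np.divide(numer, denom, out=np.full(np.broadcast(numer, denom).shape, np.nan),
                     where=denom > 0)


def averaged_ktrans(p2, p3, ktrans_m2, ktrans_m3):
    """Probability-weighted Ktrans over the two leaky models.

    A voxel with P2 + P3 = 0 is certainly non-leaky: Ktrans = 0 there.
    """
    p2, p3 = np.asarray(p2, float), np.asarray(p3, float)
    k2, k3 = np.asarray(ktrans_m2, float), np.asarray(ktrans_m3, float)
    if np.any(k2[np.isfinite(k2)] < 0) or np.any(k3[np.isfinite(k3)] < 0):
        raise DomainError("ktrans inputs must be non-negative")
    denom = p2 + p3
    numer = p2 * k2 + p3 * k3
    return np.divide(numer, denom, out=np.zeros(np.broadcast(numer, denom).shape),
                     where=denom > 0)


def averaged_ve(ktrans_avg, kep_m3, kep_floor: float = KEP_FLOOR):
    """ve = averaged Ktrans over the Model-3 kep estimate.

    Zero averaged Ktrans gives ve = 0; otherwise kep below ``kep_floor``
    (1/min) means no measurable back-flux and ve is undefined (NaN).
    """
    kt = np.asarray(ktrans_avg, float)
    kep = np.asarray(kep_m3, float)
    shape = np.broadcast(kt, kep).shape
    out = np.full(shape, np.nan)
    zero = np.broadcast_to(kt == 0, shape)
    out[zero] = 0.0
    ok = np.broadcast_to(kep >= kep_floor, shape) & ~zero
    out[ok] = np.broadcast_to(kt, shape)[ok] / np.broadcast_to(kep, shape)[ok]
    return out


def averaged_parameter_maps(
    prob: ProbabilityVolume,
    nms_result: NMSVolumeResult,
    kep_floor: float = KEP_FLOOR,
) -> AveragedParameterMaps:
    """Model-averaged vp / Ktrans / ve maps from probabilities plus the
    per-model NMS parameter maps."""
    mask = prob.brain_mask & nms_result.brain_mask
    vp = averaged_vp(prob.p1, prob.p2, prob.p3,
                     nms_result.vp_m1, nms_result.vp_m2, nms_result.vp_m3)
    kt = averaged_ktrans(prob.p2, prob.p3,
                         np.nan_to_num(nms_result.ktrans_m2),
                         np.nan_to_num(nms_result.ktrans_m3))
    ve = averaged_ve(kt, np.nan_to_num(nms_result.kep_m3), kep_floor)
    nanmask = ~mask
    vp = np.where(nanmask, np.nan, vp)
    kt = np.where(nanmask, np.nan, kt)
    ve = np.where(nanmask, np.nan, ve)
    return AveragedParameterMaps(vp=vp, ktrans=kt, ve=ve)
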