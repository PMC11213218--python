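"""Cross-validated comparison of probabilistic vs conventional NMS.

The harness mirrors a subject-level k-fold nested cross-validation: the
cohort of (synthetic) animals is randomly permuted and split into k
non-overlapping test folds; for each fold a SOM plus neuron-probability
table is built from the *training* animals' labeled profiles and applied
to the *test* animals.  Agreement is measured by

* Dice similarity coefficients between the PNMS 50%-threshold regions and
  the NMS label regions for the two leaky models (the Model-1 region is
  used to mask out intact tissue first);
* mean percent differences MPD = 100 * (PNMS - NMS) / NMS of the
  cohort-averaged permeability parameters;
* percentile-bootstrap confidence intervals across folds.

Splits are always at animal level, never voxel level, so within-animal
correlation cannot leak between train and test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, DomainError
from .ksom import SOMConfig, batch_train, compute_hitmap
from .nms import NMSVolumeResult, fit_volume
from .pnms import (
    KEP_FLOOR,
    averaged_parameter_maps,
    neuron_probabilities,
    voxel_probabilities,
)
from .synthetic import SyntheticStudy, normalize_profiles

logger = logging.getLogger(__name__)

__all__ = [
    "FoldSplit",
    "EvaluationReport",
    "dice",
    "mean_percent_difference",
    "make_folds",
    "confidence_interval",
    "nms_parameter_means",
    "pnms_parameter_means",
    "run_nested_cv",
]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|) of two boolean
    masks on the same lattice; two empty sets count as perfect agreement."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise DomainError("masks must share a voxel lattice")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def mean_percent_difference(nms_value: float, pnms_value: float) -> float:
    """100 * (PNMS - NMS) / NMS; NaN (with a warning) for a zero baseline."""
    if nms_value == 0:
        warnings.warn("zero NMS baseline: percent difference undefined")
        return float("nan")
    return 100.0 * (pnms_value - nms_value) / nms_value


@dataclass(frozen=True)
class FoldSplit:
    """Animal-level train/test assignment for each fold."""

    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]  # (train, test)
    k: int
    train_fraction: float

    def __iter__(self):
        return iter(self.folds)


def make_folds(
    animal_ids,
    k: int = 10,
    train_fraction: float = 0.66,
    seed: int = 0,
) -> FoldSplit:
    """Random-permutation k-fold split at animal level.

    One random permutation; the k (near-)equal contiguous blocks are the
    test folds; each fold's training set is drawn from the remaining
    animals so that the train fraction is honored (0.66/0.34 = 44/22 on a
    66-animal cohort at k=10).
    """
    ids = list(animal_ids)
    if k < 2:
        raise DomainError("k must be >= 2")
    if k > len(ids):
        raise DomainError(f"k={k} exceeds the number of animals ({len(ids)})")
    if not 0 < train_fraction < 1:
        raise DomainError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    blocks = np.array_split(np.arange(len(ids)), k)
    n_train = int(round(train_fraction * len(ids)))
    folds = []
    for block in blocks:
        test = tuple(perm[i] for i in block)
        remainder = [a for a in perm if a not in test]
        train = tuple(remainder[: min(n_train, len(remainder))])
        folds.append((train, test))
    return FoldSplit(folds=tuple(folds), k=k, train_fraction=train_fraction)


def confidence_interval(
    values,
    level: float = 0.95,
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile-bootstrap CI of the mean of per-fold values."""
    v = np.asarray(list(values), dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise DegenerateInputError("no finite values for the CI")
    if v.size == 1:
        return float(v[0]), float(v[0])
    rng = np.random.default_rng(seed)
    means = rng.choice(v, size=(n_boot, v.size), replace=True).mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass
class EvaluationReport:
    """Per-fold metrics plus a pooled summary.

    ``per_fold`` has one row per fold: Dice for Models 2/3 and the NMS /
    PNMS cohort means of vp, Ktrans and ve on the test animals (vp and ve
    in percent, Ktrans in 1/min).  ``summary`` holds fold-averaged values,
    bootstrap CIs and the MPD of each parameter.
    """

    per_fold: pd.DataFrame
    summary: dict

    def to_json_dict(self) -> dict:
        return {
            "per_fold": self.per_fold.to_dict(orient="records"),
            "summary": self.summary,
        }


def nms_parameter_means(res: NMSVolumeResult) -> dict[str, float]:
    """Cohort means of the conventional-NMS parameters for one study.

    vp is averaged over the whole brain (selected-model estimate), Ktrans
    over the leaky (label 2/3) voxels, ve over label-3 voxels with kep
    above the floor.  ve estimates above 1 are non-physical (a volume
    fraction) and excluded.  vp and ve are reported in percent.
    """
    mask = res.brain_mask
    vp = res.selected_vp()[mask]
    leaky = mask & (res.label_map >= 2)
    kt = res.selected_ktrans()[leaky]
    m3 = mask & (res.label_map == 3) & (res.kep_m3 >= KEP_FLOOR)
    ve = res.ktrans_m3[m3] / res.kep_m3[m3]
    ve = ve[ve <= 1.0]
    return {
        "vp_pct": 100.0 * float(np.nanmean(vp)) if vp.size else float("nan"),
        "ktrans": float(np.nanmean(kt)) if kt.size else float("nan"),
        "ve_pct": 100.0 * float(np.nanmean(ve)) if ve.size else float("nan"),
    }


def pnms_parameter_means(prob, avg) -> dict[str, float]:
    """Cohort means of the PNMS model-averaged parameters for one study.

    vp over the whole brain, Ktrans over the PNMS leaky regions (Models
    2/3 at the probability threshold), ve where it is defined within the
    Model-3 region; non-physical ve > 1 excluded as in the NMS means."""
    mask = prob.brain_mask
    vp = avg.vp[mask]
    leaky = prob.region_mask(2) | prob.region_mask(3)
    kt = avg.ktrans[leaky]
    r3 = prob.region_mask(3) & np.isfinite(avg.ve)
    ve = avg.ve[r3]
    ve = ve[ve <= 1.0]
    return {
        "vp_pct": 100.0 * float(np.nanmean(vp)) if vp.size else float("nan"),
        "ktrans": float(np.nanmean(kt)) if kt.size else float("nan"),
        "ve_pct": 100.0 * float(np.nanmean(ve)) if ve.size else float("nan"),
    }


def _study_profiles(study: SyntheticStudy, nms_res: NMSVolumeResult,
                    normalization: str):
    traces = study.delta_r1[study.brain_mask]
    profiles, included = normalize_profiles(traces, study.grid, normalization)
    labels = nms_res.label_map[study.brain_mask]
    return profiles[included], labels[included]


def run_nested_cv(
    cohort: list[SyntheticStudy],
    k: int = 10,
    train_fraction: float = 0.66,
    confidence_level: float = 0.95,
    threshold: float = 0.5,
    som_config: SOMConfig | None = None,
    normalization: str = "peak",
    seed: int = 0,
    nms_results: dict[str, NMSVolumeResult] | None = None,
) -> EvaluationReport:
    """Animal-level k-fold cross-validation of PNMS against NMS.

    For each fold a SOM and neuron-probability table are built from the
    training animals' NMS-labeled profiles and applied, unchanged, to the
    held-out animals.  Conventional NMS results can be passed in
    (``nms_results``) to avoid recomputation; otherwise they are fit here.
    Folds where a Dice value is undefined (no voxels in either region) are
    excluded from that model's average with a logged warning.
    """
    if som_config is None:
        som_config = SOMConfig()
    ids = [s.animal_id for s in cohort]
    if len(set(ids)) != len(ids):
        raise DomainError("animal_ids must be unique")
    by_id = {s.animal_id: s for s in cohort}

    if nms_results is None:
        nms_results = {}
    for aid, study in by_id.items():
        if aid not in nms_results:
            logger.info("fitting NMS for %s", aid)
            nms_results[aid] = fit_volume(
                study.delta_r1, study.brain_mask, study.aif, study.grid,
                confidence_level,
            )

    split = make_folds(ids, k=k, train_fraction=train_fraction, seed=seed)
    rows = []
    for fold_idx, (train_ids, test_ids) in enumerate(split):
        xs, ls = [], []
        for aid in train_ids:
            p, l = _study_profiles(by_id[aid], nms_results[aid], normalization)
            xs.append(p)
            ls.append(l)
        x_train = np.concatenate(xs)
        l_train = np.concatenate(ls)
        logger.info("fold %d: training SOM on %d profiles", fold_idx, len(x_train))
        weights = batch_train(x_train, som_config)
        table = neuron_probabilities(
            compute_hitmap(weights, x_train, l_train), weights.grid
        )

        # pooled test-voxel region masks and parameter means
        masks_pnms = {2: [], 3: []}
        masks_nms = {2: [], 3: []}
        fold_nms_means, fold_pnms_means = [], []
        for aid in test_ids:
            study = by_id[aid]
            res = nms_results[aid]
            prob = voxel_probabilities(
                study.delta_r1, study.grid, weights, table,
                study.brain_mask, threshold, normalization,
            )
            model1_out = ~prob.region_mask(1)  # mask out intact vasculature
            for m in (2, 3):
                masks_pnms[m].append(prob.region_mask(m) & model1_out)
                masks_nms[m].append(res.brain_mask & (res.label_map == m))
            avg = averaged_parameter_maps(prob, res)
            fold_nms_means.append(nms_parameter_means(res))
            fold_pnms_means.append(pnms_parameter_means(prob, avg))

        row = {"fold": fold_idx}
        for m in (2, 3):
            a = np.concatenate([x.ravel() for x in masks_pnms[m]])
            b = np.concatenate([x.ravel() for x in masks_nms[m]])
            if a.sum() + b.sum() == 0:
                logger.warning(
                    "fold %d: Model-%d region empty under both methods; "
                    "DSC excluded", fold_idx, m,
                )
                row[f"dsc_m{m}"] = float("nan")
            else:
                row[f"dsc_m{m}"] = dice(a, b)
        for key in ("vp_pct", "ktrans", "ve_pct"):
            row[f"nms_{key}"] = float(np.nanmean([d[key] for d in fold_nms_means]))
            row[f"pnms_{key}"] = float(np.nanmean([d[key] for d in fold_pnms_means]))
        rows.append(row)

    per_fold = pd.DataFrame(rows)
    summary: dict = {"k": k, "threshold": threshold,
                     "confidence_level": confidence_level}
    for m in (2, 3):
        vals = per_fold[f"dsc_m{m}"]
        summary[f"dsc_m{m}_mean"] = float(vals.mean(skipna=True))
        lo, hi = confidence_interval(vals.dropna(), seed=seed)
        summary[f"dsc_m{m}_ci"] = [lo, hi]
    for key in ("vp_pct", "ktrans", "ve_pct"):
        nms_mean = float(per_fold[f"nms_{key}"].mean(skipna=True))
        pnms_mean = float(per_fold[f"pnms_{key}"].mean(skipna=True))
        summary[f"nms_{key}_mean"] = nms_mean
        summary[f"pnms_{key}_mean"] = pnms_mean
        summary[f"nms_{key}_ci"] = list(
            confidence_interval(per_fold[f"nms_{key}"].dropna(), seed=seed))
        summary[f"pnms_{key}_ci"] = list(
            confidence_interval(per_fold[f"pnms_{key}"].dropna(), seed=seed))
        summary[f"mpd_{key}"] = mean_percent_difference(nms_mean, pnms_mean)
    return EvaluationReport(per_fold=per_fold, summary=summary)
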