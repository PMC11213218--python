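"""End-to-end pipeline: simulate -> NMS -> SOM -> PNMS -> validate.

`run_pipeline` drives the whole analysis from a single `RunConfig`
(loadable from YAML) and writes every artifact plus a provenance manifest
under an output directory.  One global seed deterministically derives the
seed of every stochastic stage, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import io as dio
from .exceptions import DomainError
from .ksom import SOMConfig, batch_train, compute_hitmap
from .nms import fit_volume
from .pk_models import TimeGrid
from .pnms import averaged_parameter_maps, neuron_probabilities, voxel_probabilities
from .synthetic import PhantomSpec, make_aif, make_cohort, normalize_profiles
from .validation import run_nested_cv

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "fit-nms", "train-som", "pnms", "validate")


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration of one pipeline run."""

    # phantom cohort
    n_animals: int = 6
    shape: tuple[int, int, int] = (24, 24, 2)
    tumor_radius: float = 7.0
    core_radius: float = 4.0
    noise_sd: float = 0.05
    # acquisition
    n_frames: int = 400
    dt: float = 1.55
    injection_index: int = 39
    retained_start: int = 20
    # analysis
    confidence_level: float = 0.95
    threshold: float = 0.5
    normalization: str = "peak"
    som: SOMConfig = field(default_factory=SOMConfig)
    # cross-validation
    k_folds: int = 3
    train_fraction: float = 0.66
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise DomainError(
                f"threshold must be in (0, 1], got {self.threshold}"
            )
        if not 0 < self.confidence_level < 1:
            raise DomainError("confidence_level must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        som = SOMConfig(**raw.pop("som", {}))
        if "shape" in raw:
            raw["shape"] = tuple(raw["shape"])
        return cls(som=som, **raw)

    def to_yaml(self, path) -> Path:
        payload = asdict(self)
        payload["shape"] = list(self.shape)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
        return Path(path)

    def grid(self) -> TimeGrid:
        return TimeGrid(self.n_frames, self.dt, self.injection_index,
                        self.retained_start)

    def phantom_spec(self, seed: int) -> PhantomSpec:
        return PhantomSpec(shape=self.shape, tumor_radius=self.tumor_radius,
                           core_radius=self.core_radius,
                           noise_sd=self.noise_sd, seed=seed)


def _derive_seeds(seed: int) -> dict[str, int]:
    """Per-stage integer seeds (< 2^31) derived from the global seed."""
    names = ("cohort", "som", "cv")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(config: RunConfig, outdir, stages=("all",)) -> dict:
    """Run the requested stages, writing artifacts under ``outdir``.

    Stage names follow :data:`STAGES`; ``"all"`` expands to every stage.
    Returns a dict of the in-memory results keyed by stage.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    wanted = list(STAGES) if "all" in stages else list(stages)
    unknown = set(wanted) - set(STAGES)
    if unknown:
        raise DomainError(f"unknown stages: {sorted(unknown)}")

    seeds = _derive_seeds(config.seed)
    grid = config.grid()
    aif = make_aif(grid)
    results: dict = {}
    t_start = time.perf_counter()

    cohort = make_cohort(config.n_animals, config.phantom_spec(seeds["cohort"]),
                         seed=seeds["cohort"], grid=grid, aif=aif)
    if "simulate" in wanted:
        sim_dir = out / "cohort"
        sim_dir.mkdir(exist_ok=True)
        dio.save_aif_csv(sim_dir / "aif.csv", aif)
        dio.save_aif_json(sim_dir / "aif.json", aif)
        for study in cohort:
            base = sim_dir / study.animal_id
            dio.save_volume(f"{base}_delta_r1.nii",
                            study.delta_r1.astype(np.float32))
            dio.save_volume(f"{base}_labels.nii", study.labels.astype(np.int16))
            dio.save_volume(f"{base}_vp_true.nii", study.vp_true.astype(np.float32))
            dio.save_volume(f"{base}_ktrans_true.nii",
                            study.ktrans_true.astype(np.float32))
            dio.save_volume(f"{base}_kep_true.nii", study.kep_true.astype(np.float32))
        logger.info("simulate: %d animals, %d voxels each",
                    len(cohort), int(cohort[0].brain_mask.sum()))
        results["simulate"] = cohort

    nms_results = {}
    if {"fit-nms", "train-som", "pnms", "validate"} & set(wanted):
        nms_dir = out / "nms"
        nms_dir.mkdir(exist_ok=True)
        for study in cohort:
            res = fit_volume(study.delta_r1, study.brain_mask, study.aif,
                             study.grid, config.confidence_level)
            nms_results[study.animal_id] = res
            if "fit-nms" in wanted:
                base = nms_dir / study.animal_id
                dio.save_volume(f"{base}_labels.nii",
                                res.label_map.astype(np.int16))
                for name in ("vp_m1", "vp_m2", "vp_m3", "ktrans_m2",
                             "ktrans_m3", "kep_m3"):
                    dio.save_volume(f"{base}_{name}.nii",
                                    getattr(res, name).astype(np.float32))
                res.to_dataframe().to_csv(f"{base}_fits.csv", index=False)
        logger.info("fit-nms: %d studies fit", len(nms_results))
        results["fit-nms"] = nms_results

    weights = table = None
    if {"train-som", "pnms"} & set(wanted):
        xs, ls = [], []
        for study in cohort:
            profiles, included = normalize_profiles(
                study.delta_r1[study.brain_mask], grid, config.normalization)
            labels = nms_results[study.animal_id].label_map[study.brain_mask]
            xs.append(profiles[included])
            ls.append(labels[included])
        x_all, l_all = np.concatenate(xs), np.concatenate(ls)
        som_config = replace(config.som, seed=seeds["som"])
        weights = batch_train(x_all, som_config)
        hitmap = compute_hitmap(weights, x_all, l_all)
        table = neuron_probabilities(hitmap, weights.grid)
        if "train-som" in wanted:
            som_dir = out / "som"
            som_dir.mkdir(exist_ok=True)
            dio.save_som(som_dir / "som", weights)
            dio.hitmap_to_csv(som_dir / "hitmap.csv", hitmap, som_config)
            np.save(som_dir / "neuron_probs.npy", table.probs)
        logger.info("train-som: %d profiles, %d neurons hit",
                    len(x_all), int((hitmap.total > 0).sum()))
        results["train-som"] = (weights, table)

    if "pnms" in wanted:
        pnms_dir = out / "pnms"
        pnms_dir.mkdir(exist_ok=True)
        pnms_maps = {}
        for study in cohort:
            prob = voxel_probabilities(
                study.delta_r1, grid, weights, table, study.brain_mask,
                config.threshold, config.normalization)
            avg = averaged_parameter_maps(prob, nms_results[study.animal_id])
            pnms_maps[study.animal_id] = (prob, avg)
            base = pnms_dir / study.animal_id
            for name, arr in (("p1", prob.p1), ("p2", prob.p2), ("p3", prob.p3),
                              ("vp", avg.vp), ("ktrans", avg.ktrans),
                              ("ve", avg.ve)):
                dio.save_volume(f"{base}_{name}.nii", arr.astype(np.float32))
            dio.save_rgb_probability_png(f"{base}_rgb_z0.png", prob, 0)
        logger.info("pnms: probability and averaged maps for %d animals",
                    len(pnms_maps))
        results["pnms"] = pnms_maps

    if "validate" in wanted:
        report = run_nested_cv(
            cohort, k=config.k_folds, train_fraction=config.train_fraction,
            confidence_level=config.confidence_level,
            threshold=config.threshold,
            som_config=replace(config.som, seed=seeds["som"]),
            normalization=config.normalization,
            seed=seeds["cv"], nms_results=nms_results,
        )
        val_dir = out / "validation"
        val_dir.mkdir(exist_ok=True)
        report.per_fold.to_csv(val_dir / "per_fold.csv", index=False)
        dio.save_manifest(val_dir / "summary.json", report.summary)
        logger.info("validate: DSC m2=%.3f m3=%.3f",
                    report.summary["dsc_m2_mean"], report.summary["dsc_m3_mean"])
        results["validate"] = report

    manifest = {
        "config": {**asdict(config), "shape": list(config.shape)},
        "derived_seeds": seeds,
        "stages": wanted,
    }
    dio.save_manifest(out / "manifest.json", manifest)
    logger.info("pipeline finished in %.1f s", time.perf_counter() - t_start)
    return results
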