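"""End-to-end workflow: synthesize/ingest -> split -> train -> predict ->
segment -> evaluate -> cohort analysis.

``run_pipeline`` executes the enabled stages in order into a run directory
and writes a manifest (config hash, seed, package versions, per-file
checksums).  Stages communicate through files, so each can also be run
independently from the CLI; deterministic stages reproduce bit-identical
outputs under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, fixtures
from .cohort import stratify_cohort
from .evalmetrics import evaluate_patches, threshold_sweep
from .nn import LossSpec
from .patches import split_dataset
from .postproc import PostprocParams
from .segnet import TrainConfig, UNetConfig, build_model, predict, train

__all__ = ["PipelineConfig", "run_pipeline", "StageError"]

STAGES = ("synth", "split", "train", "predict", "segment", "eval", "cohort")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of one run; nested configs use the stage modules'
    dataclasses.  ``stages`` selects which stages run, in canonical order."""

    out_dir: str = "runs/demo"
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    # synthetic data
    n_patches: int = 60
    patch_size: int = 64
    n_cohort_patients: int = 200
    cohort_effect: float = 1.0
    # nested stage configs
    split_ratios: tuple[float, float, float] = (0.6, 0.1, 0.3)
    unet: UNetConfig | None = None
    train_cfg: TrainConfig | None = None
    loss: str = "bce"
    postproc: PostprocParams = field(default_factory=PostprocParams)
    iou_threshold: float = 0.5
    sweep_thresholds: tuple[float, ...] = (0.30, 0.35, 0.40, 0.45, 0.50)
    microns_per_pixel: float = 0.25
    horizon: float = 5.0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(s for s in STAGES if s in self.stages)
        if self.unet is None:
            self.unet = UNetConfig(
                input_size=(self.patch_size, self.patch_size, 3),
                depth=2, base_channels=8)
        if self.train_cfg is None:
            self.train_cfg = TrainConfig(epochs=25, batch_size=4,
                                         seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        nested = {}
        if "unet" in raw:
            u = raw.pop("unet")
            if "input_size" in u:
                u["input_size"] = tuple(u["input_size"])
            nested["unet"] = UNetConfig(**u)
        if "train_cfg" in raw:
            nested["train_cfg"] = TrainConfig(**raw.pop("train_cfg"))
        if "postproc" in raw:
            nested["postproc"] = PostprocParams(**raw.pop("postproc"))
        for key in ("stages", "split_ratios", "sweep_thresholds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw, **nested)

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        blob = json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the enabled stages; returns the run directory.

    Any stage failure raises :class:`StageError` naming the stage; outputs
    of completed stages stay on disk.  Stages that need upstream artifacts
    raise a stage-order error when those are missing.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_root = np.random.default_rng(config.seed)
    seeds = {s: int(rng_root.integers(2**31)) for s in STAGES}

    state: dict = {}

    def _load_patches():
        if "patches" in state:
            return state["patches"]
        raise RuntimeError("no patches in run state; run the 'synth' stage first")

    for stage in config.stages:
        try:
            if stage == "synth":
                pats = []
                for i in range(config.n_patches):
                    cfg = fixtures.SynthPatchConfig(
                        patch_size=config.patch_size,
                        n_nuclei=(3, 7),
                        radius=(4.0, 7.0),
                        seed=seeds["synth"] + i,
                    )
                    rgb, labels = fixtures.generate_patch(cfg)
                    pats.append((f"patch{i:04d}", rgb, labels))
                state["patches"] = pats
                cohort = fixtures.generate_cohort(fixtures.SynthCohortConfig(
                    n_patients=config.n_cohort_patients,
                    log_hazard_ratio_per_unit_density=config.cohort_effect,
                    seed=seeds["synth"],
                ))
                state["cohort"] = cohort
                fixtures.write_cohort(cohort, out / "cohort.csv")
            elif stage == "split":
                pats = _load_patches()
                spec = split_dataset([p[0] for p in pats],
                                     ratios=config.split_ratios,
                                     seed=seeds["split"])
                state["split"] = spec
                spec.to_frame().to_csv(out / "split.csv", index=False)
            elif stage == "train":
                pats = _load_patches()
                if "split" not in state:
                    raise RuntimeError("run the 'split' stage first")
                spec = state["split"]
                by_id = {p[0]: p for p in pats}
                tr = [(by_id[i][1], by_id[i][2] > 0) for i in spec.ids("train")]
                va = [(by_id[i][1], by_id[i][2] > 0)
                      for i in spec.ids("train_val")]
                model = build_model(config.unet, seed=seeds["train"])
                model, history = train(model, tr, va, config.train_cfg,
                                       LossSpec.parse(config.loss))
                state["model"] = model
                pd.DataFrame(history).to_csv(out / "training_log.csv",
                                             index=False)
            elif stage == "predict":
                pats = _load_patches()
                if "model" not in state:
                    raise RuntimeError("no trained model; run 'train' first")
                spec = state.get("split")
                test_ids = spec.ids("test") if spec else [p[0] for p in pats]
                by_id = {p[0]: p for p in pats}
                probs = {i: predict(state["model"], by_id[i][1])
                         for i in test_ids}
                state["probs"] = probs
            elif stage == "segment":
                if "probs" not in state:
                    raise RuntimeError("no predictions; run 'predict' first")
                from .postproc import segment as _segment

                state["instances"] = {
                    i: _segment(p, config.postproc)
                    for i, p in state["probs"].items()
                }
            elif stage == "eval":
                if "probs" not in state:
                    raise RuntimeError("no predictions; run 'predict' first")
                pats = _load_patches()
                by_id = {p[0]: p for p in pats}
                ids = sorted(state["probs"])
                probs = [state["probs"][i] for i in ids]
                gtb = [by_id[i][2] > 0 for i in ids]
                gti = [by_id[i][2] for i in ids]
                report = evaluate_patches(probs, gtb, gti,
                                          params=config.postproc,
                                          iou_threshold=config.iou_threshold)
                with open(out / "metrics.json", "w") as fh:
                    json.dump(report.to_dict(), fh, indent=2)
                report.per_patch.to_csv(out / "metrics_per_patch.csv",
                                        index=False)
                sweep = threshold_sweep(probs, gti,
                                        thresholds=config.sweep_thresholds,
                                        h=config.postproc.h,
                                        iou_threshold=config.iou_threshold,
                                        min_area=config.postproc.min_area)
                sweep.to_csv(out / "threshold_sweep.csv", index=False)
                state["report"] = report
            elif stage == "cohort":
                if "cohort" not in state:
                    raise RuntimeError("no cohort table; run 'synth' first")
                summary = stratify_cohort(state["cohort"],
                                          horizon=config.horizon)
                state["survival"] = summary
                summary.roc.to_csv(out / "td_roc.csv", index=False)
                for g, curve in summary.km_curves.items():
                    curve.to_csv(out / f"km_group{g}.csv", index=False)
                with open(out / "survival.json", "w") as fh:
                    json.dump({
                        "cutoff": summary.cutoff,
                        "auc": summary.auc,
                        "logrank_chi2": summary.logrank_chi2,
                        "logrank_p": summary.logrank_p,
                        "horizon": summary.horizon,
                        "group_sizes": summary.group_sizes,
                    }, fh, indent=2)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage-named rethrow
            raise StageError(stage, exc) from exc

    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": list(config.stages),
        "files": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    state["manifest"] = manifest
    run_pipeline.last_state = state  # introspection hook for tests/SDK use
    return out
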