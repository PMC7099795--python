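"""End-to-end pipeline driver: configuration, staged execution, provenance.

A run is described by a flat TOML configuration (paths, delta, forest
parameters, selection and CV settings).  ``run_pipeline`` executes the
stages in order — similarity matrices, sample assembly, normalization,
zero-column drop, importance ranking, k selection, then cross-validation
and/or prediction — writing each artifact as TSV next to a ``run.json``
manifest that records the effective configuration, its hash and every
seed, so identical configurations reproduce all deterministic artifacts
bitwise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .importance import ForestParams
from .model import RFLDA, cross_validate
from .io import write_prediction_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "sweep_grid"]


def sweep_grid(spec: str) -> tuple[int, ...]:
    """Parse a ``start:stop:step`` inclusive grid (e.g. ``50:1950:50``)."""
    try:
        start, stop, step = (int(x) for x in spec.split(":"))
    except ValueError:
        raise ValueError(f"bad sweep grid {spec!r}; expected start:stop:step") from None
    if step < 1 or stop < start:
        raise ValueError(f"bad sweep grid {spec!r}")
    return tuple(range(start, stop + 1, step))


@dataclass(frozen=True)
class RunConfig:
    """Effective settings of one pipeline run.

    Defaults follow the reference protocol: attenuation 0.5, 500 trees,
    mtry = p/3, 10 importance runs, top-300 selection, 5-fold CV with 10
    repetitions.
    """

    ld_path: str = ""
    md_path: str = ""
    lm_path: str = ""
    ontology_path: str = ""
    ontology_dialect: str = "edge_list"
    out_dir: str = "rflda_out"
    delta: float = 0.5
    n_trees: int = 500
    mtry: int | None = None  # None -> p/3 rule
    importance_runs: int = 10
    k: int = 300
    sweep: str = ""  # "start:stop:step" enables the accuracy sweep
    sweep_folds: int = 10
    cv_folds: int = 5
    cv_repetitions: int = 10
    mask_self: bool = True
    top_k_predictions: int = 50
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = tomllib.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def forest_params(self) -> ForestParams:
        return ForestParams(n_trees=self.n_trees, mtry=self.mtry, seed=self.seed)


def run_pipeline(
    config: RunConfig,
    stages: Sequence[str] = ("similarity", "fit", "cv", "predict"),
) -> dict[str, Path]:
    """Execute the pipeline stages, returning a name -> artifact path map.

    Any stage failure aborts with the stage name and cause; the manifest
    written so far marks the run incomplete.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "stages": {},
        "complete": False,
    }
    manifest_path = out / "run.json"
    artifacts: dict[str, Path] = {"manifest": manifest_path}

    model = RFLDA.from_files(
        config.ld_path,
        config.md_path,
        config.lm_path,
        config.ontology_path,
        dialect=config.ontology_dialect,
        delta=config.delta,
        mask_self=config.mask_self,
        params=config.forest_params(),
    )
    results = None

    def record(stage: str, **extra) -> None:
        manifest["stages"][stage] = {
            "seconds": round(time.time() - started, 3),
            "seed": config.seed,
            **extra,
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))

    try:
        for stage in stages:
            started = time.time()
            logger.info("stage %s started", stage)
            if stage == "similarity":
                model.matrices.dd.to_tsv(out / "dd.tsv")
                model.matrices.ll.to_tsv(out / "ll.tsv")
                artifacts["dd"] = out / "dd.tsv"
                artifacts["ll"] = out / "ll.tsv"
                record(stage)
            elif stage == "fit":
                results = model.fit(
                    n_importance_runs=config.importance_runs,
                    k=config.k,
                    sweep_ks=sweep_grid(config.sweep) if config.sweep else None,
                    sweep_folds=config.sweep_folds,
                )
                results.ranking.to_tsv(out / "importance.tsv")
                artifacts["importance"] = out / "importance.tsv"
                if results.accuracy_curve is not None:
                    results.accuracy_curve.to_tsv(out / "accuracy_curve.tsv")
                    artifacts["accuracy_curve"] = out / "accuracy_curve.tsv"
                (out / "selection.json").write_text(
                    json.dumps(
                        {
                            "kept": list(results.subset.kept),
                            "removed_all_zero": list(results.removed_features),
                            "provenance": results.subset.provenance,
                        },
                        indent=2,
                    )
                )
                artifacts["selection"] = out / "selection.json"
                (out / "summary.txt").write_text(results.summary() + "\n")
                artifacts["summary"] = out / "summary.txt"
                record(
                    stage,
                    k=len(results.subset.kept),
                    removed=len(results.removed_features),
                )
            elif stage == "cv":
                if results is None:
                    raise RuntimeError("cv stage requires the fit stage")
                cv = results.cross_validate(
                    folds=config.cv_folds, repetitions=config.cv_repetitions
                )
                cv.to_frame().to_csv(
                    out / "cv.tsv", sep="\t", index=False, float_format="%.10g"
                )
                artifacts["cv"] = out / "cv.tsv"
                record(
                    stage,
                    mean_auc=cv.mean_auc,
                    mean_aupr=cv.mean_aupr,
                    sd_auc_reps=cv.sd_auc_reps,
                    sd_auc_folds=cv.sd_auc_folds,
                )
            elif stage == "predict":
                if results is None:
                    raise RuntimeError("predict stage requires the fit stage")
                table = results.predict(top_k=config.top_k_predictions)
                write_prediction_table(
                    table, out / "predictions.tsv", top_k=config.top_k_predictions
                )
                artifacts["predictions"] = out / "predictions.tsv"
                record(stage, rows=len(table))
            else:
                raise ValueError(f"unknown stage {stage!r}")
            logger.info("stage %s finished", stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest_path.write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["complete"] = True
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return artifacts
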