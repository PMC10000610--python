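"""End-to-end orchestration: synthesise, slice, featurise, classify.

The pipeline mirrors the experimental design it emulates: four
roughness grades x two powder types x three replicates = 24 cones.
Everything downstream of the seed is deterministic, so a config +
seed pair fully reproduces feature tables and the classification
report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import synthetic
from .classify import SampleFeatures, cross_validate, extract_features, matrix_metrics
from .mesh_io import TriangleMesh

__all__ = ["PipelineConfig", "run_pipeline", "synthesize_dataset", "features_to_frame"]

log = logging.getLogger("powdercone")


@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run."""

    n_layers: int = 40
    grid_m: int = 512
    lam_min: float | None = None  # None, None = automatic band [2P/M, P/2]
    lam_max: float | None = None
    svm_degree: int = 2
    svm_c: float = 10.0
    cv_folds: int = 4
    seed: int = 0
    n_replicates: int = 3
    base_radius: float = synthetic.DEFAULT_BASE_RADIUS
    height: float = synthetic.DEFAULT_HEIGHT
    n_theta: int = 192
    n_z: int = 96
    out_dir: str = "powdercone_out"

    def validate(self) -> "PipelineConfig":
        if self.n_layers < 1 or self.grid_m < 16:
            raise ValueError("n_layers must be >= 1 and grid_m >= 16")
        if self.grid_m & (self.grid_m - 1):
            raise ValueError("grid_m must be a power of two")
        if (self.lam_min is None) != (self.lam_max is None):
            raise ValueError("set both lam_min and lam_max, or neither")
        if self.lam_min is not None and not 0 < self.lam_min < self.lam_max:
            raise ValueError("need 0 < lam_min < lam_max")
        if self.svm_degree < 1 or self.svm_c <= 0:
            raise ValueError("svm_degree must be >= 1 and svm_c > 0")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if min(self.base_radius, self.height) <= 0:
            raise ValueError("base_radius and height must be > 0")
        return self

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        """Load from a YAML/JSON key-value file; keyword overrides win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data).validate()

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def synthesize_dataset(config: PipelineConfig) -> list[tuple[str, int, TriangleMesh]]:
    """All 4 x 2 x n_replicates graded cones for the config's seed."""
    samples = []
    for class_id in range(4):
        for powder_type in synthetic.POWDER_TYPES:
            for rep in range(config.n_replicates):
                sample_seed = config.seed * 1000 + rep
                mesh = synthetic.make_class_sample(
                    class_id,
                    powder_type,
                    sample_seed,
                    base_radius=config.base_radius,
                    height=config.height,
                    n_theta=config.n_theta,
                    n_z=config.n_z,
                )
                sid = f"class{class_id}_{powder_type}_rep{rep}"
                samples.append((sid, class_id, mesh))
    return samples


def features_to_frame(features: list[SampleFeatures]) -> pd.DataFrame:
    """Wide feature table: sample_id, true_class, q_01.., std_01.."""
    n = len(features[0].q)
    rows = []
    for f in features:
        row = {"sample_id": f.sample_id, "true_class": f.true_class}
        row.update({f"q_{i + 1:02d}": f.q[i] for i in range(n)})
        row.update({f"std_{i + 1:02d}": f.std[i] for i in range(n)})
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Synthesise the graded dataset, extract features, cross-validate.

    Writes ``features.csv``, ``layers.csv`` (per-layer Q/std) and
    ``report.json`` into ``config.out_dir``; returns the report dict.
    Identical config + seed give identical outputs.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    log.info("pipeline start: seed=%d hash=%s", config.seed, config.config_hash())

    samples = synthesize_dataset(config)
    log.info("synthesised %d cones", len(samples))

    lam_band = None if config.lam_min is None else (config.lam_min, config.lam_max)
    features, labels, layer_rows = [], [], []
    for sid, class_id, mesh in samples:
        f = extract_features(
            mesh,
            n_layers=config.n_layers,
            M=config.grid_m,
            lam_band=lam_band,
            sample_id=sid,
            true_class=class_id,
        )
        features.append(f)
        labels.append(class_id)
        for i in range(config.n_layers):
            layer_rows.append(
                {
                    "sample_id": sid,
                    "layer_index": i,
                    "q": f.q[i],
                    "std": f.std[i],
                    "valid": bool(f.valid[i]),
                }
            )
        log.info("features %s: median Q = %.4g", sid, float(np.median(f.q)))

    frame = features_to_frame(features)
    features_path = os.path.join(config.out_dir, "features.csv")
    frame.to_csv(features_path, index=False, float_format="%.12g")
    pd.DataFrame(layer_rows).to_csv(
        os.path.join(config.out_dir, "layers.csv"), index=False, float_format="%.12g"
    )

    cv = cross_validate(
        features,
        labels,
        k=config.cv_folds,
        seed=config.seed,
        degree=config.svm_degree,
        C=config.svm_c,
    )
    metrics = matrix_metrics(cv.confusion)
    log.info("cross-validated accuracy %.3f (loss %.3f)", cv.accuracy, cv.loss)

    fixture = _classify.paper_confusion_matrix()
    fixture_metrics = matrix_metrics(fixture)

    def _listify(m: dict) -> dict:
        return {
            k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in m.items()
        }

    report = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_samples": len(samples),
        "confusion": cv.confusion.counts.tolist(),
        "accuracy": cv.accuracy,
        "loss": cv.loss,
        "metrics": _listify(metrics),
        "reference_fixture": {
            "confusion": fixture.counts.tolist(),
            "metrics": _listify(fixture_metrics),
        },
    }
    report_path = os.path.join(config.out_dir, "report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2)
    log.info("report written to %s", report_path)
    return report
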