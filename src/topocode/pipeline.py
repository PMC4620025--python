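"""End-to-end pipeline: simulate/segment/featurize/learn/encode/classify.

Stages run in order on synthetic scenes (or user TIFF frames):
binarization -> seeded watershed -> ROI extraction -> feature
extraction -> (optionally) topographic sparse coding -> one-vs-rest
kernel SVM -> confusion-count metrics. The train/test split is a
temporal prefix over frames, never random, so temporally adjacent
observations of the same cells cannot leak across the split.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .classify import SvmConfig, predict, train_svm
from .features import Standardizer, assemble_feature_matrix, extract_features
from .metrics import ClassificationReport, multiclass_report
from .preprocess import binarize, extract_rois, segment_nuclei
from .synthetic import GroundTruthScene, SynthImageConfig, generate_cell_frames
from .tsc import TscConfig, build_grouping_matrix, encode, learn

__all__ = [
    "PreprocessConfig",
    "FeatureConfig",
    "EvalConfig",
    "PipelineConfig",
    "RunManifest",
    "PipelineError",
    "run_pipeline",
    "load_config",
]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class PreprocessConfig:
    method: str = "otsu"
    manual_threshold: float | None = None
    opening_radius: int = 1
    # seeds closer than a typical nucleus radius belong to one nucleus,
    # so anaphase chromatid lobes are not split apart
    min_seed_distance: int = 12
    min_area: int = 10
    roi_rows: int = 48
    roi_cols: int = 48


@dataclass(frozen=True)
class FeatureConfig:
    name: str = "RAW"
    raw_rows: int = 9
    raw_cols: int = 6
    standardize: bool = True


@dataclass(frozen=True)
class EvalConfig:
    train_frames: int = 5  # temporal prefix used for training


@dataclass(frozen=True)
class PipelineConfig:
    synth: SynthImageConfig = field(default_factory=SynthImageConfig)
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    tsc: TscConfig = field(default_factory=lambda: TscConfig(k=16, max_outer_iters=40))
    svm: SvmConfig = field(default_factory=SvmConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    use_tsc: bool = True
    run_seed: int = 0
    output_dir: str | None = None


def _from_dict(cls, data: dict[str, Any]):
    """Instantiate a (possibly nested) config dataclass, rejecting unknown keys."""
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = known[key].type
        target = {
            "synth": SynthImageConfig,
            "preprocessing": PreprocessConfig,
            "features": FeatureConfig,
            "tsc": TscConfig,
            "svm": SvmConfig,
            "evaluation": EvalConfig,
        }.get(key)
        if target is not None and isinstance(value, dict):
            kwargs[key] = _from_dict(target, value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a nested YAML config; unknown keys are rejected up front."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("pipeline config must be a mapping")
    return _from_dict(PipelineConfig, data)


@dataclass
class RunManifest:
    config: dict[str, Any]
    version: str
    stage_seconds: dict[str, float] = field(default_factory=dict)
    artifact_digests: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "version": self.version,
                "stage_seconds": self.stage_seconds,
                "artifact_digests": self.artifact_digests,
            },
            indent=2,
            default=str,
        )


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def match_rois_to_truth(
    labels: np.ndarray, scene: GroundTruthScene
) -> dict[int, str]:
    """Map segmented region id -> ground-truth phase via centroid lookup.

    Each ground-truth centroid votes for the region containing it;
    regions hit by zero or multiple centroids are dropped (mis-split or
    merged nuclei carry no unambiguous label).
    """
    votes: dict[int, list[str]] = {}
    for phase, (r, c) in zip(scene.phases, scene.centroids):
        ri, ci = int(round(r)), int(round(c))
        if 0 <= ri < labels.shape[0] and 0 <= ci < labels.shape[1]:
            lab = int(labels[ri, ci])
            if lab > 0:
                votes.setdefault(lab, []).append(phase)
    return {lab: ph[0] for lab, ph in votes.items() if len(ph) == 1}


def _featurize(patches, cfg: FeatureConfig):
    kwargs = {}
    if cfg.name == "RAW":
        kwargs["out_shape"] = (cfg.raw_rows, cfg.raw_cols)
    return extract_features(patches, cfg.name, **kwargs)


def run_pipeline(
    config: PipelineConfig, scenes: list[GroundTruthScene] | None = None
) -> tuple[RunManifest, ClassificationReport]:
    """Execute every stage and return the manifest and test-set report.

    ``scenes`` may inject pre-generated frames (e.g. loaded from TIFF
    with known ground truth); by default they are simulated from
    ``config.synth`` reseeded with ``run_seed``.
    """
    manifest = RunManifest(config=asdict(config), version=__version__)
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        manifest.stage_seconds[name] = time.perf_counter() - t0
        return result

    if scenes is None:
        synth_cfg = SynthImageConfig(
            **{**asdict_shallow(config.synth), "seed": config.run_seed}
        )
        scenes = _stage("simulate", lambda: generate_cell_frames(synth_cfg))

    pp = config.preprocessing

    def _segment():
        out = []
        for scene in scenes:
            mask = binarize(
                scene.frame,
                method=pp.method,
                manual_threshold=pp.manual_threshold,
                opening_radius=pp.opening_radius,
            )
            labels = segment_nuclei(
                scene.frame, mask, pp.min_seed_distance, pp.min_area
            )
            out.append(labels)
        return out

    label_masks = _stage("segment", _segment)

    def _roi_stage():
        patches, phases, frame_ids = [], [], []
        for fi, (scene, labels) in enumerate(zip(scenes, label_masks)):
            mapping = match_rois_to_truth(labels, scene)
            rois = extract_rois(scene.frame, labels, (pp.roi_rows, pp.roi_cols))
            for roi in rois:
                if roi.cell_id in mapping:
                    patches.append(roi)
                    phases.append(mapping[roi.cell_id])
                    frame_ids.append(fi)
        return patches, phases, np.array(frame_ids)

    patches, phases, frame_ids = _stage("extract_rois", _roi_stage)
    if len(patches) == 0:
        raise PipelineError("stage 'extract_rois' failed: no labeled ROIs recovered")

    vectors = _stage("featurize", lambda: _featurize(patches, config.features))
    fm = assemble_feature_matrix(vectors)

    train_sel = frame_ids < config.evaluation.train_frames
    test_sel = ~train_sel
    if not train_sel.any() or not test_sel.any():
        raise PipelineError(
            "stage 'split' failed: temporal prefix leaves an empty train or test set"
        )
    X_train, X_test = fm.values[:, train_sel], fm.values[:, test_sel]
    y_train = [p for p, keep in zip(phases, train_sel) if keep]
    y_test = [p for p, keep in zip(phases, test_sel) if keep]

    if config.use_tsc:
        if config.features.standardize:
            std = Standardizer().fit(X_train)
            X_train_s, X_test_s = std.transform(X_train), std.transform(X_test)
        else:
            X_train_s, X_test_s = X_train, X_test
        # scale so sample columns have norm ~1: the per-column code bound
        # ||s_n||^2 <= C with C near 1 is then a natural ball
        scale = 1.0 / np.sqrt(X_train_s.shape[0])
        X_train_s, X_test_s = X_train_s * scale, X_test_s * scale

        def _learn_encode():
            tsc_cfg = TscConfig(**{**asdict_shallow(config.tsc), "seed": config.run_seed})
            A, s_train, _ = learn(X_train_s, tsc_cfg)
            gr, gc = tsc_cfg.grid_shape()
            V = build_grouping_matrix(gr, gc, tsc_cfg.group_size, tsc_cfg.wraparound)
            s_test, _ = encode(A, X_test_s, V, tsc_cfg)
            return A, s_train, s_test

        A, F_train, F_test = _stage("learn_encode", _learn_encode)
    else:
        F_train, F_test = X_train, X_test

    svm_cfg = SvmConfig(**{**asdict_shallow(config.svm), "seed": config.run_seed})
    model = _stage("train_svm", lambda: train_svm(F_train, y_train, svm_cfg))
    y_pred = _stage("predict", lambda: predict(model, F_test))
    report = _stage("evaluate", lambda: multiclass_report(y_test, y_pred))

    if out_dir:
        from .io import write_ground_truth, write_label_mask, write_matrix, write_tiff_stack

        write_tiff_stack(out_dir / "frames.tif", [s.frame for s in scenes])
        write_ground_truth(out_dir / "ground_truth.tsv", scenes)
        for fi, labels in enumerate(label_masks):
            write_label_mask(out_dir / f"labels_{fi:03d}.tif", labels)
        write_matrix(out_dir / "features.npz", fm.values, fm.feature_name)
        (out_dir / "report.json").write_text(_report_json(report))
        for p in sorted(out_dir.iterdir()):
            if p.is_file() and p.name != "manifest.json":
                manifest.artifact_digests[p.name] = _digest(p)
        (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest, report


def _report_json(report: ClassificationReport) -> str:
    return json.dumps(
        {
            "accuracy": report.accuracy,
            "error_rate": report.error_rate,
            "n_samples": report.n_samples,
            "per_class": {k: asdict(v) for k, v in report.per_class.items()},
            "macro": asdict(report.macro),
        },
        indent=2,
        default=str,
    )


def asdict_shallow(obj) -> dict[str, Any]:
    """Field dict of a dataclass without recursing into field values."""
    return {f.name: getattr(obj, f.name) for f in fields(obj)}
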