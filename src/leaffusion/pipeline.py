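"""End-to-end orchestration: extract -> balance -> evaluate -> similarity
-> stress, from a single serializable config."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .balancing import FeatureMatrix, smote_resample, standardize
from .descriptors import DescriptorConfig, extract_features
from .evaluation import ClassifierSpec, EvaluationReport, build_classifier, kfold_evaluate, split_indices
from .imaging import DEFAULT_RESIZE, LabelledDataset, load_dataset, load_image, resize_bilinear
from .similarity import SimilarityMatrix, class_mean_vectors, interclass_similarity
from .stress import StressCondition, stress_suite
from .synthetic import LeafClassSpec, SyntheticDatasetSpec, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    dataset_root: str | None = None
    synthetic: SyntheticDatasetSpec | None = None
    resize: tuple[int, int] = DEFAULT_RESIZE
    descriptors: DescriptorConfig = field(default_factory=DescriptorConfig)
    smote: bool = True
    smote_k: int = 5
    paper_order: bool = False
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15)
    folds: int = 5
    classifiers: tuple[str, ...] = ("SVM", "RandomForest", "GradientBoost", "SoftVote")
    stress_conditions: tuple[str, ...] = ()
    seed: int = 42
    out_dir: str = "runs/run"

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic"):
            syn = dict(d["synthetic"])
            syn["class_specs"] = [LeafClassSpec(**cs) for cs in syn["class_specs"]]
            if "image_size" in syn:
                syn["image_size"] = tuple(syn["image_size"])
            d["synthetic"] = SyntheticDatasetSpec(**syn)
        if d.get("descriptors"):
            desc = dict(d["descriptors"])
            for key in ("color_bins", "gabor_orientations", "gabor_sigmas"):
                if key in desc:
                    desc[key] = tuple(desc[key])
            d["descriptors"] = DescriptorConfig(**desc)
        for key in ("resize", "split_fractions", "classifiers", "stress_conditions"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


def parse_conditions(tokens: tuple[str, ...] | list[str], seed: int = 0) -> list[StressCondition]:
    """Parse 'noise:10,scale:64,rot:180,occ:0.2'-style condition tokens."""
    kinds = {"noise": "noise", "scale": "scale", "rot": "rotation", "rotation": "rotation", "occ": "occlusion", "occlusion": "occlusion"}
    out = []
    for tok in tokens:
        kind, _, value = tok.partition(":")
        if kind not in kinds:
            raise ValueError(f"unknown stress condition {tok!r}")
        out.append(StressCondition(kind=kinds[kind], parameter=float(value), seed=seed))
    return out


def extract_dataset_features(
    dataset: LabelledDataset,
    cfg: DescriptorConfig | None = None,
    resize: tuple[int, int] = DEFAULT_RESIZE,
) -> FeatureMatrix:
    """Load, resize and featurize every record of a dataset index."""
    cfg = cfg or DescriptorConfig()
    rows = []
    for rec in dataset.records:
        img = resize_bilinear(load_image(rec.path), *resize)
        rows.append(extract_features(img, cfg).values)
    return FeatureMatrix(np.stack(rows), dataset.labels, class_names=dataset.class_names)


def features_to_frame(data: FeatureMatrix, dataset: LabelledDataset | None = None) -> pd.DataFrame:
    cols = {f"f{i}": data.X[:, i] for i in range(data.X.shape[1])}
    frame = pd.DataFrame(cols)
    frame.insert(0, "label", data.y)
    frame.insert(0, "class_name", [data.class_names[c] for c in data.y])
    if dataset is not None and len(dataset.records) == len(data.y):
        frame.insert(0, "path", [str(r.path) for r in dataset.records])
    frame["synthetic"] = data.synthetic
    return frame


def frame_to_features(frame: pd.DataFrame) -> FeatureMatrix:
    feat_cols = [c for c in frame.columns if c.startswith("f") and c[1:].isdigit()]
    class_names = sorted(frame["class_name"].unique())
    synthetic = frame["synthetic"].to_numpy(dtype=bool) if "synthetic" in frame else None
    return FeatureMatrix(
        frame[feat_cols].to_numpy(dtype=np.float64),
        frame["label"].to_numpy(dtype=np.int64),
        class_names=class_names,
        synthetic=synthetic,
    )


def similarity_to_csv(S: SimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(S.values, index=S.class_order, columns=S.class_order).to_csv(path)


def similarity_heatmap(S: SimilarityMatrix, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 + 0.6 * len(S.class_order), 1.0 + 0.6 * len(S.class_order)))
    im = ax.imshow(S.values, vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(S.class_order)), S.class_order, rotation=45, ha="right")
    ax.set_yticks(range(len(S.class_order)), S.class_order)
    fig.colorbar(im, ax=ax, label="similarity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_report(report: EvaluationReport, similarity: SimilarityMatrix | None, out: str | Path) -> list[Path]:
    """Serialize an evaluation report as JSON plus a Markdown summary."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    payload = report.to_dict()
    if similarity is not None:
        payload["similarity"] = {"class_order": similarity.class_order, "values": similarity.values.tolist()}
    json_path = out / "report.json"
    json_path.write_text(json.dumps(payload, indent=2))

    lines = ["# Evaluation report", "", "## Cross-validated performance (CVp)", ""]
    lines.append("| Classifier | Accuracy | Macro P | Macro R | Macro F1 |")
    lines.append("|---|---|---|---|---|")
    for name, metrics in report.cv.items():
        lines.append(
            f"| {name} | {metrics['accuracy']:.4f} | {metrics['macro_precision']:.4f} "
            f"| {metrics['macro_recall']:.4f} | {metrics['macro_f1']:.4f} |"
        )
    lines += ["", "## Per-class metrics (fold means)", ""]
    for name in report.cv:
        rows = [f for f in report.folds if f.classifier == name]
        prec = np.mean([f.metrics["precision"] for f in rows], axis=0)
        rec = np.mean([f.metrics["recall"] for f in rows], axis=0)
        f1 = np.mean([f.metrics["f1"] for f in rows], axis=0)
        lines.append(f"### {name}")
        lines.append("")
        lines.append("| Class | Precision | Recall | F1 |")
        lines.append("|---|---|---|---|")
        for i, cls in enumerate(report.class_names):
            lines.append(f"| {cls} | {prec[i]:.4f} | {rec[i]:.4f} | {f1[i]:.4f} |")
        lines.append("")
    md_path = out / "report.md"
    md_path.write_text("\n".join(lines))
    return [json_path, md_path]


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the full pipeline and return the run directory.

    Artifacts: features.csv, segments.json, report.json, report.md,
    similarity.csv, similarity.png, optional stress.csv, config.json and
    run.log.  One root seed drives every stochastic stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root_logger = logging.getLogger("leaffusion")
    root_logger.addHandler(handler)
    stage = "configure"
    try:
        (out / "config.json").write_text(json.dumps(cfg.to_dict(), indent=2, default=str))

        stage = "dataset"
        if cfg.synthetic is not None:
            dataset = generate_dataset(cfg.synthetic, out / "images")
        elif cfg.dataset_root:
            dataset = load_dataset(cfg.dataset_root)
        else:
            raise ValueError("config needs either dataset_root or a synthetic spec")

        stage = "extract"
        data = extract_dataset_features(dataset, cfg.descriptors, cfg.resize)
        features_to_frame(data, dataset).to_csv(out / "features.csv", index=False)
        seg_probe = extract_features(
            resize_bilinear(load_image(dataset.records[0].path), *cfg.resize), cfg.descriptors
        )
        (out / "segments.json").write_text(
            json.dumps({"segments": seg_probe.segments, "descriptors": cfg.descriptors.to_dict()}, indent=2)
        )

        stage = "evaluate"
        smote_mode = "off" if not cfg.smote else ("paper_order" if cfg.paper_order else "guarded")
        specs = [ClassifierSpec(name=n, seed=cfg.seed) for n in cfg.classifiers]
        report = kfold_evaluate(data, specs, k=cfg.folds, seed=cfg.seed, smote_mode=smote_mode, smote_k=cfg.smote_k)

        stage = "similarity"
        std_all, _, _ = standardize(data)
        sim = interclass_similarity(class_mean_vectors(std_all))
        similarity_to_csv(sim, out / "similarity.csv")
        similarity_heatmap(sim, out / "similarity.png")

        stage = "report"
        write_report(report, sim, out)

        if cfg.stress_conditions:
            stage = "stress"
            run_stress(cfg, dataset, data, out)
        return out
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        raise
    finally:
        root_logger.removeHandler(handler)
        handler.close()


def run_stress(cfg: PipelineConfig, dataset: LabelledDataset, data: FeatureMatrix, out: Path) -> pd.DataFrame:
    """Train on the clean split, perturb only test images, re-score."""
    train_idx, _, test_idx = split_indices(data, cfg.split_fractions, seed=cfg.seed)
    train = data.subset(train_idx)
    if cfg.smote:
        train = smote_resample(train, k_neighbors=cfg.smote_k, seed=cfg.seed)
    train, _, scaler = standardize(train)
    models = {}
    for name in cfg.classifiers:
        model = build_classifier(ClassifierSpec(name=name, seed=cfg.seed))
        model.fit(train.X, train.y)
        models[name] = model

    test_images = [resize_bilinear(load_image(dataset.records[i].path), *cfg.resize) for i in test_idx]
    test_labels = data.y[test_idx]

    def featurize(img: np.ndarray) -> np.ndarray:
        resized = resize_bilinear(img, *cfg.resize)
        return scaler.transform(extract_features(resized, cfg.descriptors).values[None, :])[0]

    conditions = parse_conditions(cfg.stress_conditions, seed=cfg.seed)
    table = stress_suite(test_images, test_labels, models, featurize, conditions)
    table.to_csv(out / "stress.csv")
    return table
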