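"""End-to-end verification workflow.

The intended use of the trained models: before quantifying boron from a
micrograph, segment it, featurize it, project the features and ask the
classifier whether the acquisition is adequate. A :class:`ModelBundle`
carries everything that decision needs — the fitted PCA, the trained
model, the dropped feature columns and the operating threshold — so a
bundle directory is a self-contained, reusable verifier.

``run_pipeline`` drives the full synthetic study from one config:
simulate -> featurize -> balance/split -> PCA -> train -> evaluate, with
every stage's randomness derived from a single master seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import imageio.v3 as iio
import joblib
import numpy as np
import pandas as pd
import yaml

from . import classifiers, dataset, evaluation, simulate
from .features import featurize_image
from .segmentation import DEFAULT_THRESHOLD, segment_image

__all__ = [
    "VerificationResult",
    "ModelBundle",
    "features_from_images",
    "train_bundle",
    "classify_image",
    "run_pipeline",
    "PipelineConfigError",
]

log = logging.getLogger("trackqc")


@dataclass(frozen=True)
class VerificationResult:
    """Outcome of verifying one micrograph prior to quantification."""

    name: str
    probability: float | None
    decision: str  # "Accepted" | "Rejected" | "NotClassifiable"
    track_count: int
    threshold: float


@dataclass
class ModelBundle:
    """A trained verifier: transform + model + operating threshold."""

    model: classifiers.TrainedModel
    pca: dataset.PCATransform
    dropped_columns: tuple[str, ...]
    threshold: float
    segmentation_threshold: float = DEFAULT_THRESHOLD

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.pca.to_json(out / "pca.json")
        joblib.dump(self.model, out / "model.joblib")
        meta = {
            "kind": self.model.kind,
            "threshold": self.threshold,
            "dropped_columns": list(self.dropped_columns),
            "segmentation_threshold": self.segmentation_threshold,
        }
        (out / "bundle.json").write_text(json.dumps(meta, indent=2))
        if self.model.history:
            pd.DataFrame(self.model.history).to_csv(out / "history.csv", index=False)
        return out

    @classmethod
    def load(cls, bundle_dir: str | Path) -> "ModelBundle":
        bundle_dir = Path(bundle_dir)
        meta = json.loads((bundle_dir / "bundle.json").read_text())
        return cls(
            model=joblib.load(bundle_dir / "model.joblib"),
            pca=dataset.PCATransform.from_json(bundle_dir / "pca.json"),
            dropped_columns=tuple(meta["dropped_columns"]),
            threshold=float(meta["threshold"]),
            segmentation_threshold=float(meta["segmentation_threshold"]),
        )


def features_from_images(
    images: list[simulate.SyntheticImage],
    threshold: float = DEFAULT_THRESHOLD,
    split_overlaps: bool = True,
) -> pd.DataFrame:
    """Segment and featurize a list of synthetic frames into a table.

    Frames where nothing segments (possible under extreme over-lighting)
    are skipped with a log message, matching the rule that an empty
    image has no feature vector.
    """
    records, labels, names = [], [], []
    for i, img in enumerate(images):
        objs = segment_image(img.pixels, threshold=threshold, split=split_overlaps)
        if not objs:
            log.info("image %d segmented no objects; skipped", i)
            continue
        records.append(featurize_image(objs))
        labels.append(img.label)
        names.append(f"image_{i:05d}")
    return dataset.records_to_table(records, labels, names)


def _project(table: pd.DataFrame, bundle_pca: dataset.PCATransform) -> np.ndarray:
    return dataset.pca_transform(bundle_pca, table)


def train_bundle(
    train_table: pd.DataFrame,
    val_table: pd.DataFrame,
    model: str = "nn",
    variance_target: float = 0.999,
    precision_target: float = 0.97,
    svm_config: classifiers.SVMConfig | None = None,
    nn_config: classifiers.NNConfig | None = None,
    dropped_columns=dataset.DROPPED_BY_DEFAULT,
    segmentation_threshold: float = DEFAULT_THRESHOLD,
) -> ModelBundle:
    """Fit PCA on the training table, train a model, pick the threshold.

    The operating threshold is raised above 0.5 to the precision target
    on the validation scores when achievable, otherwise left at 0.5.
    """
    train_table = dataset.drop_uninformative(train_table, dropped_columns)
    val_table = dataset.drop_uninformative(val_table, dropped_columns)
    pca = dataset.pca_fit(train_table, variance_target=variance_target)
    x_train, y_train = classifiers.as_xy(train_table, _project(train_table, pca))
    x_val, y_val = classifiers.as_xy(val_table, _project(val_table, pca))
    if model == "svm":
        fitted, _ = classifiers.svm_search_and_train(x_train, y_train, svm_config)
    elif model == "nn":
        fitted = classifiers.nn_train(x_train, y_train, x_val, y_val, nn_config)
    else:
        raise ValueError(f"unknown model {model!r}")
    probs = classifiers.predict(fitted, x_val)
    try:
        op = evaluation.select_threshold_for_precision(y_val, probs, target=precision_target)
        threshold = max(op.threshold, 0.5)
    except ValueError:
        threshold = 0.5
    fitted.threshold = threshold
    return ModelBundle(
        model=fitted,
        pca=pca,
        dropped_columns=tuple(dropped_columns),
        threshold=threshold,
        segmentation_threshold=segmentation_threshold,
    )


def classify_image(image, bundle: ModelBundle, name: str = "image") -> VerificationResult:
    """Verify one micrograph: segment, featurize, project, predict.

    ``image`` may be a pixel array or a path to a PNG/TIFF file. An
    image in which nothing segments is reported as not classifiable.
    """
    if isinstance(image, (str, Path)):
        name = Path(image).name
        image = iio.imread(image)
    objs = segment_image(np.asarray(image), threshold=bundle.segmentation_threshold)
    if not objs:
        return VerificationResult(name, None, "NotClassifiable", 0, bundle.threshold)
    table = dataset.records_to_table([featurize_image(objs)], ["Accepted"])  # label placeholder
    x = _project(table.drop(columns=[c for c in bundle.dropped_columns if c in table.columns]), bundle.pca)
    prob = float(classifiers.predict(bundle.model, x)[0])
    decision = "Accepted" if prob > bundle.threshold else "Rejected"
    return VerificationResult(name, prob, decision, len(objs), bundle.threshold)


# ---------------------------------------------------------------------------
# pipeline runner

class PipelineConfigError(ValueError):
    """A pipeline config violating the schema."""


_CONFIG_SCHEMA = {
    # name: (type, default)  -- None default means required
    "out_dir": (str, None),
    "seed": (int, 0),
    "n_images": (int, 300),
    "fraction_adequate": (float, 0.5),
    "frame_height": (int, 962),
    "frame_width": (int, 1280),
    "model": (str, "nn"),
    "variance_target": (float, 0.999),
    "precision_target": (float, 0.97),
    "segmentation_threshold": (float, float(DEFAULT_THRESHOLD)),
    "svm_candidates": (int, 20),
    "nn_max_epochs": (int, 200),
}


def _validate_config(raw: dict) -> dict:
    unknown = set(raw) - set(_CONFIG_SCHEMA)
    if unknown:
        raise PipelineConfigError(f"unknown config field(s): {', '.join(sorted(unknown))}")
    cfg = {}
    for key, (typ, default) in _CONFIG_SCHEMA.items():
        if key in raw:
            try:
                cfg[key] = typ(raw[key])
            except (TypeError, ValueError) as exc:
                raise PipelineConfigError(f"config field {key!r} must be {typ.__name__}") from exc
        elif default is None:
            raise PipelineConfigError(f"missing required config field {key!r}")
        else:
            cfg[key] = default
    if cfg["model"] not in ("svm", "nn"):
        raise PipelineConfigError("config field 'model' must be 'svm' or 'nn'")
    return cfg


def run_pipeline(config: str | Path | dict) -> dict:
    """Execute simulate -> featurize -> train -> evaluate from a config.

    All randomness fans out deterministically from ``seed``. Artifacts
    (features.csv, model bundle, metrics.json) are written under
    ``out_dir``; the metrics dict is returned.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text()) or {}
    cfg = _validate_config(dict(config))
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg["seed"]).spawn(4)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    images = simulate.generate_dataset(
        cfg["n_images"],
        fraction_adequate=cfg["fraction_adequate"],
        rng_seed=seeds[0],
        shape=(cfg["frame_height"], cfg["frame_width"]),
    )
    timings["simulate_s"] = time.perf_counter() - t0
    log.info("simulated %d frames in %.1fs", len(images), timings["simulate_s"])

    t0 = time.perf_counter()
    table = features_from_images(images, threshold=cfg["segmentation_threshold"])
    dataset.write_feature_csv(table, out / "features.csv")
    timings["featurize_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    balanced = dataset.balance_classes(table, rng_seed=seeds[1])
    train_t, val_t, test_t = dataset.split(balanced, rng_seed=seeds[2])
    nn_seed = int(seeds[3].generate_state(1)[0] % (2**31))
    bundle = train_bundle(
        train_t,
        val_t,
        model=cfg["model"],
        variance_target=cfg["variance_target"],
        precision_target=cfg["precision_target"],
        svm_config=classifiers.SVMConfig(n_candidates=cfg["svm_candidates"], rng_seed=nn_seed),
        nn_config=classifiers.NNConfig(max_epochs=cfg["nn_max_epochs"], rng_seed=nn_seed),
        segmentation_threshold=cfg["segmentation_threshold"],
    )
    bundle.save(out / "model")
    timings["train_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    test_dropped = dataset.drop_uninformative(test_t, bundle.dropped_columns)
    x_test, y_test = classifiers.as_xy(test_dropped, dataset.pca_transform(bundle.pca, test_dropped))
    probs = classifiers.predict(bundle.model, x_test)
    cm_default = evaluation.confusion(y_test, probs, 0.5)
    cm_operating = evaluation.confusion(y_test, probs, bundle.threshold)
    _, _, auc_value = evaluation.roc_curve(y_test, probs)
    metrics = {
        "model": cfg["model"],
        "n_images": len(images),
        "n_features_rows": len(table),
        "pca_components": bundle.pca.n_components,
        "threshold": bundle.threshold,
        "test_auc": auc_value,
        "test_confusion_at_0.5": asdict(cm_default),
        "test_confusion_at_threshold": asdict(cm_operating),
        "test_accuracy": evaluation.accuracy(cm_default),
        "test_precision_at_threshold": evaluation.precision(cm_operating),
        "test_recall_at_threshold": evaluation.recall(cm_operating),
        "timings": timings,
    }
    timings["evaluate_s"] = time.perf_counter() - t0
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
    log.info("pipeline complete: %s", out / "metrics.json")
    return metrics
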