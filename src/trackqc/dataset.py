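"""Modeling-dataset assembly: feature-table I/O, balancing, splitting, PCA.

A feature table is a pandas ``DataFrame`` with the 36 summary-feature
columns (``<stat>_<descriptor>``), a ``track_count`` column, a binary
``label`` ("Accepted"/"Rejected") and a ``name`` identifier — the schema
of one row per micrograph.

The preprocessing chain used before classification is: drop the two
uninformative 5th-percentile columns, undersample the majority class to
a 50/50 balance, split into train/validation/test, then fit a
standardized (correlation-matrix) PCA on the training part and keep the
smallest number of components reaching the variance target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _PCA

from .features import FEATURE_COLUMNS

__all__ = [
    "LABELS",
    "DROPPED_BY_DEFAULT",
    "read_feature_csv",
    "write_feature_csv",
    "records_to_table",
    "drop_uninformative",
    "balance_classes",
    "split",
    "pearson_correlation",
    "PCATransform",
    "pca_fit",
    "pca_transform",
    "feature_columns_of",
]

LABELS = ("Accepted", "Rejected")

#: 5th-percentile columns dropped for carrying no information: in every
#: image, well over 5% of the objects sit in the first bin of both
#: clumpiness and roundness, pinning their 5th percentiles.
DROPPED_BY_DEFAULT = ("p5_clumpiness", "p5_roundness")

_META_COLUMNS = ("track_count", "label", "name")

_LABEL_ALIASES = {
    "accepted": "Accepted",
    "rejected": "Rejected",
    "1": "Accepted",
    "0": "Rejected",
}


class FeatureTableError(ValueError):
    """A feature CSV violating the schema."""


def feature_columns_of(table: pd.DataFrame) -> list[str]:
    """The feature columns present in a table, in canonical order."""
    return [c for c in FEATURE_COLUMNS if c in table.columns]


def _normalize_label(value) -> str:
    key = str(value).strip().lower()
    if key not in _LABEL_ALIASES:
        raise FeatureTableError(f"unknown label {value!r}; expected Accepted/Rejected")
    return _LABEL_ALIASES[key]


def records_to_table(records: list[dict], labels: list[str], names: list[str] | None = None) -> pd.DataFrame:
    """Assemble per-image feature dicts into a feature table."""
    if not len(records) == len(labels):
        raise ValueError("records and labels must align")
    table = pd.DataFrame.from_records(records)
    table["label"] = [_normalize_label(lb) for lb in labels]
    table["name"] = names if names is not None else [f"image_{i:05d}" for i in range(len(records))]
    return table.reset_index(drop=True)


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    """Load a per-image feature table, validating the schema.

    Column names are matched case-insensitively against the canonical
    header, so external exports with different capitalisation load
    unchanged. Missing feature columns, non-numeric features and
    unknown labels each raise a distinct :class:`FeatureTableError`.
    """
    table = pd.read_csv(path)
    rename = {}
    canonical = {c.lower(): c for c in (*FEATURE_COLUMNS, *_META_COLUMNS)}
    for col in table.columns:
        key = col.strip().lower()
        if key in canonical:
            rename[col] = canonical[key]
    table = table.rename(columns=rename)
    missing = [c for c in (*FEATURE_COLUMNS, "label") if c not in table.columns]
    if missing:
        raise FeatureTableError(f"missing required column(s): {', '.join(missing)}")
    feats = table.loc[:, list(FEATURE_COLUMNS)]
    numeric = feats.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.columns[numeric.isna().any()].tolist()
        raise FeatureTableError(f"non-numeric feature value(s) in column(s): {', '.join(bad)}")
    table.loc[:, list(FEATURE_COLUMNS)] = numeric
    table["label"] = [_normalize_label(v) for v in table["label"]]
    if "name" not in table.columns:
        table["name"] = [f"row_{i:05d}" for i in range(len(table))]
    return table.reset_index(drop=True)


def write_feature_csv(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def drop_uninformative(table: pd.DataFrame, columns=DROPPED_BY_DEFAULT) -> pd.DataFrame:
    """Remove named feature columns (default: the two pinned p5 columns)."""
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise FeatureTableError(f"cannot drop absent column(s): {', '.join(missing)}")
    return table.drop(columns=list(columns))


def balance_classes(table: pd.DataFrame, rng_seed=0) -> pd.DataFrame:
    """Random undersampling of the majority class to a 50/50 balance.

    Returns a subset of the input rows of size ``2 * min(class counts)``,
    seeded and order-preserving.
    """
    counts = table["label"].value_counts()
    if len(counts) < 2:
        raise FeatureTableError("balancing requires both classes present")
    n_keep = int(counts.min())
    rng = np.random.default_rng(rng_seed)
    keep_idx: list[np.ndarray] = []
    for label in LABELS:
        idx = table.index[table["label"] == label].to_numpy()
        if idx.size > n_keep:
            idx = rng.choice(idx, size=n_keep, replace=False)
        keep_idx.append(idx)
    keep = np.sort(np.concatenate(keep_idx))
    return table.loc[keep].reset_index(drop=True)


def split(
    table: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.64, 0.16, 0.20),
    rng_seed=0,
    stratified: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Disjoint train/validation/test partition.

    The default fractions reproduce a 20% held-out test set followed by
    a 20%-of-the-remainder validation set (0.64/0.16/0.20 overall).
    Stratified splitting preserves the class balance in each part.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(rng_seed)
    n = len(table)

    def _partition(indices: np.ndarray) -> list[np.ndarray]:
        perm = rng.permutation(indices)
        n_train = int(round(fractions[0] * len(indices)))
        n_val = int(round(fractions[1] * len(indices)))
        return [perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]]

    if stratified and "label" in table.columns:
        parts = [[], [], []]
        for label in sorted(table["label"].unique()):
            for i, chunk in enumerate(_partition(table.index[table["label"] == label].to_numpy())):
                parts[i].append(chunk)
        idx_sets = [np.sort(np.concatenate(p)) if p else np.array([], dtype=int) for p in parts]
    else:
        idx_sets = [np.sort(p) for p in _partition(np.arange(n))]
    return tuple(table.loc[idx].reset_index(drop=True) for idx in idx_sets)


def pearson_correlation(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the feature columns.

    Symmetric with unit diagonal; entries for constant columns are NaN
    (undefined correlation).
    """
    cols = feature_columns_of(table)
    if len(table) < 2:
        raise ValueError("correlation requires at least 2 rows")
    return table.loc[:, cols].corr(method="pearson")


@dataclass(frozen=True)
class PCATransform:
    """Fitted standardization + principal-component projection.

    Stores per-feature centers/scales (training statistics), the full
    orthonormal component matrix, explained-variance fractions, and the
    number of leading components retained to reach the variance target.
    """

    feature_names: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray
    components: np.ndarray  # (n_features, n_features), orthonormal rows
    explained_variance_ratio: np.ndarray
    n_components: int
    variance_target: float
    standardized: bool

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "feature_names": list(self.feature_names),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "components": self.components.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "n_components": self.n_components,
            "variance_target": self.variance_target,
            "standardized": self.standardized,
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PCATransform":
        payload = json.loads(Path(path).read_text())
        return cls(
            feature_names=tuple(payload["feature_names"]),
            center=np.asarray(payload["center"]),
            scale=np.asarray(payload["scale"]),
            components=np.asarray(payload["components"]),
            explained_variance_ratio=np.asarray(payload["explained_variance_ratio"]),
            n_components=int(payload["n_components"]),
            variance_target=float(payload["variance_target"]),
            standardized=bool(payload["standardized"]),
        )


def _feature_matrix(table: pd.DataFrame, feature_names) -> np.ndarray:
    missing = [c for c in feature_names if c not in table.columns]
    if missing:
        raise FeatureTableError(f"table lacks fitted feature column(s): {', '.join(missing)}")
    return table.loc[:, list(feature_names)].to_numpy(dtype=np.float64)


def pca_fit(
    table: pd.DataFrame, variance_target: float = 0.999, standardize: bool = True
) -> PCATransform:
    """Fit PCA on the (training) feature columns.

    With ``standardize`` (the default) features are z-scored on the
    training statistics first, which makes this a correlation-matrix
    PCA; zero-variance columns get unit scale. The smallest number of
    leading components whose cumulative explained variance reaches
    ``variance_target`` is retained.
    """
    cols = feature_columns_of(table)
    x = _feature_matrix(table, cols)
    if x.shape[0] < 2:
        raise ValueError("pca_fit requires at least 2 rows")
    center = x.mean(axis=0)
    if standardize:
        scale = x.std(axis=0, ddof=0)
        scale[scale == 0.0] = 1.0
    else:
        scale = np.ones(x.shape[1])
    z = (x - center) / scale
    pca = _PCA(n_components=None, svd_solver="full")
    pca.fit(z)
    ratios = pca.explained_variance_ratio_
    n_keep = int(np.searchsorted(np.cumsum(ratios), variance_target) + 1)
    n_keep = min(n_keep, ratios.size)
    return PCATransform(
        feature_names=tuple(cols),
        center=center,
        scale=scale,
        components=pca.components_,
        explained_variance_ratio=ratios,
        n_components=n_keep,
        variance_target=variance_target,
        standardized=standardize,
    )


def pca_transform(transform: PCATransform, table: pd.DataFrame, n_components: int | None = None) -> np.ndarray:
    """Project a table onto the retained principal components."""
    k = transform.n_components if n_components is None else n_components
    x = _feature_matrix(table, transform.feature_names)
    z = (x - transform.center) / transform.scale
    return z @ transform.components[:k].T
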