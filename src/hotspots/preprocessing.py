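"""Labelling, splitting, scaling, PCA and resampling.

A feature table is a pandas DataFrame with reserved identifier columns
(``complex``, ``chain``, ``residue``), an optional experimental column
``ddg`` (kcal/mol), a label column ``class`` with values HS/NS, and any
number of numeric feature columns.

Six dataset variants are produced from one train/test split:
Scaled, ScaledUp, ScaledDown (z-scores, optionally followed by up- or
down-sampling of the training set) and PCA, PCAUp, PCADown (z-scores
followed by principal-component reduction retaining the smallest number
of components whose cumulative variance ratio reaches 95%).  Test data
are always transformed with statistics derived from the training data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

ID_COLUMNS = ("complex", "chain", "residue", "res_name")
LABEL_COLUMN = "class"
DDG_COLUMN = "ddg"
HS_THRESHOLD = 2.0  # kcal/mol
VARIANT_NAMES = ("Scaled", "ScaledUp", "ScaledDown", "PCA", "PCAUp", "PCADown")


def feature_columns(table: pd.DataFrame) -> list[str]:
    reserved = set(ID_COLUMNS) | {LABEL_COLUMN, DDG_COLUMN}
    return [c for c in table.columns if c not in reserved]


def label_from_ddg(ddg: float) -> str:
    """HS iff the alanine-mutation binding free-energy change >= 2.0 kcal/mol."""
    if not np.isfinite(ddg):
        raise ValueError("ddg must be finite")
    return "HS" if ddg >= HS_THRESHOLD else "NS"


def apply_labels(table: pd.DataFrame) -> pd.DataFrame:
    """Derive the class column from ddg; drop rows with missing ddg."""
    if DDG_COLUMN not in table.columns:
        raise ValueError(f"table has no {DDG_COLUMN!r} column")
    missing = table[DDG_COLUMN].isna()
    if missing.any():
        logger.warning(
            "excluding %d observations with missing ddg", int(missing.sum())
        )
        table = table.loc[~missing]
    table = table.copy()
    table[LABEL_COLUMN] = table[DDG_COLUMN].map(label_from_ddg)
    return table


def load_feature_table(path) -> pd.DataFrame:
    """Read a labelled feature CSV, deriving labels from ddg if needed."""
    table = pd.read_csv(path)
    if LABEL_COLUMN not in table.columns:
        table = apply_labels(table)
    bad = set(table[LABEL_COLUMN]) - {"HS", "NS"}
    if bad:
        raise ValueError(f"invalid class labels: {sorted(bad)}")
    feats = feature_columns(table)
    n_missing = int(table[feats].isna().any(axis=1).sum())
    if n_missing:
        logger.warning("dropping %d observations with missing features", n_missing)
        table = table.loc[~table[feats].isna().any(axis=1)]
    return table.reset_index(drop=True)


def dataset_composition(table: pd.DataFrame) -> dict[str, int]:
    """Bookkeeping summary: observations, complexes, HS/NS, feature count."""
    return {
        "n_observations": len(table),
        "n_complexes": int(table["complex"].nunique()) if "complex" in table else 0,
        "n_hs": int((table[LABEL_COLUMN] == "HS").sum()),
        "n_ns": int((table[LABEL_COLUMN] == "NS").sum()),
        "n_features": len(feature_columns(table)),
    }


def stratified_split(
    table: pd.DataFrame, train_fraction: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class-stratified random partition into train and test.

    The overall train size is round(train_fraction * n); per-class sizes
    follow largest-remainder allocation of the class quotas, so a
    127 HS / 407 NS table at 0.7 yields 89 + 285 = 374 train / 160 test
    and a 5/5 table at 0.5 yields a 5/5 partition.
    """
    classes = sorted(table[LABEL_COLUMN].unique())
    if len(classes) < 2:
        raise ValueError("both HS and NS must be present for a stratified split")
    idx_by_class = {
        cls: table.index[table[LABEL_COLUMN] == cls].to_numpy() for cls in classes
    }
    for cls, idx in idx_by_class.items():
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than 2 observations")
    n_total = int(np.floor(train_fraction * len(table) + 0.5))
    quotas = {cls: train_fraction * len(idx) for cls, idx in idx_by_class.items()}
    sizes = {cls: int(np.floor(q)) for cls, q in quotas.items()}
    leftover = n_total - sum(sizes.values())
    for cls in sorted(classes, key=lambda c: quotas[c] - sizes[c], reverse=True):
        if leftover <= 0:
            break
        sizes[cls] += 1
        leftover -= 1
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    for cls in classes:
        idx = idx_by_class[cls]
        perm = rng.permutation(len(idx))
        train_idx.extend(idx[perm[: sizes[cls]]])
    train_mask = table.index.isin(train_idx)
    return (
        table.loc[train_mask].reset_index(drop=True),
        table.loc[~train_mask].reset_index(drop=True),
    )


class ZScoreScaler(BaseEstimator, TransformerMixin):
    """Column-wise z-scoring with sample (ddof=1) standard deviation.

    Zero-variance columns are dropped and recorded.  Test data must be
    transformed with the statistics learned from the training data.
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if len(X) == 0:
            raise ValueError("cannot fit scaler on an empty table")
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.any():
            raise ValueError("all feature columns have zero variance")
        self.dropped_ = list(X.columns[~keep])
        if self.dropped_:
            logger.warning("dropping %d zero-variance columns", len(self.dropped_))
        self.columns_ = list(X.columns[keep])
        self.mean_ = mean[keep]
        self.scale_ = sd[keep]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        return (X[self.columns_] - self.mean_) / self.scale_


class VarianceThresholdPCA(BaseEstimator, TransformerMixin):
    """PCA keeping the fewest components with cumulative variance >= threshold."""

    def __init__(self, threshold: float = 0.95):
        self.threshold = threshold

    def fit(self, X, y=None):
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must lie in (0, 1]")
        X = np.asarray(X, dtype=float)
        pca = PCA(n_components=min(X.shape), random_state=0).fit(X)
        ratio = np.cumsum(pca.explained_variance_ratio_)
        self.n_components_ = int(np.searchsorted(ratio, self.threshold - 1e-12) + 1)
        self.pca_ = pca
        self.explained_variance_ = pca.explained_variance_[: self.n_components_]
        self.cumulative_ratio_ = float(ratio[self.n_components_ - 1])
        return self

    def transform(self, X) -> pd.DataFrame:
        Z = self.pca_.transform(np.asarray(X, dtype=float))[:, : self.n_components_]
        return pd.DataFrame(
            Z, columns=[f"PC{i + 1}" for i in range(self.n_components_)]
        )


@dataclass
class PreprocessState:
    """Train-derived statistics reapplied to held-out data."""

    scaler: ZScoreScaler
    pca: VarianceThresholdPCA | None = None
    version: str = "1"

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        feats = feature_columns(table)
        missing = [c for c in self.scaler.columns_ if c not in feats]
        if missing:
            raise ValueError(
                f"feature schema mismatch: {len(missing)} training feature(s) "
                f"missing from input, e.g. {missing[:5]}"
            )
        Z = self.scaler.transform(table[feats])
        if self.pca is not None:
            Z = self.pca.transform(Z)
        Z.index = table.index
        keep = [c for c in table.columns if c in set(ID_COLUMNS) | {LABEL_COLUMN, DDG_COLUMN}]
        return pd.concat([table[keep], Z], axis=1)

    def to_json(self) -> str:
        doc = {
            "version": self.version,
            "columns": self.scaler.columns_,
            "dropped": self.scaler.dropped_,
            "mean": self.scaler.mean_.tolist(),
            "scale": self.scaler.scale_.tolist(),
        }
        if self.pca is not None:
            doc["pca"] = {
                "threshold": self.pca.threshold,
                "n_components": self.pca.n_components_,
                "mean": self.pca.pca_.mean_.tolist(),
                "components": self.pca.pca_.components_[
                    : self.pca.n_components_
                ].tolist(),
                "explained_variance": self.pca.explained_variance_.tolist(),
            }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "PreprocessState":
        doc = json.loads(text)
        if doc.get("version") != "1":
            raise ValueError(f"unsupported preprocess-state version: {doc.get('version')!r}")
        scaler = ZScoreScaler()
        scaler.columns_ = doc["columns"]
        scaler.dropped_ = doc["dropped"]
        scaler.mean_ = pd.Series(doc["mean"], index=doc["columns"])
        scaler.scale_ = pd.Series(doc["scale"], index=doc["columns"])
        pca = None
        if "pca" in doc:
            p = doc["pca"]
            pca = VarianceThresholdPCA(threshold=p["threshold"])
            inner = PCA()
            inner.mean_ = np.array(p["mean"])
            inner.components_ = np.array(p["components"])
            inner.explained_variance_ = np.array(p["explained_variance"])
            pca.pca_ = inner
            pca.n_components_ = p["n_components"]
            pca.explained_variance_ = np.array(p["explained_variance"])
        return cls(scaler=scaler, pca=pca)


def upsample_minor(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Sample the minority class with replacement up to the majority size.

    Every majority row is preserved exactly once; added rows are drawn
    only from the original minority rows.
    """
    counts = table[LABEL_COLUMN].value_counts()
    if len(counts) < 2:
        raise ValueError("up-sampling requires both classes")
    minor = counts.idxmin()
    n_major, n_minor = counts.max(), counts.min()
    if n_major == n_minor:
        return table.copy()
    rng = np.random.default_rng(seed)
    minor_rows = table[table[LABEL_COLUMN] == minor]
    extra = minor_rows.iloc[rng.integers(0, n_minor, size=n_major - n_minor)]
    return pd.concat([table, extra], ignore_index=True)


def downsample_major(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Subsample every class without replacement down to the minority size."""
    counts = table[LABEL_COLUMN].value_counts()
    if len(counts) < 2:
        raise ValueError("down-sampling requires both classes")
    n_minor = counts.min()
    rng = np.random.default_rng(seed)
    parts = []
    for cls in sorted(counts.index):
        rows = table[table[LABEL_COLUMN] == cls]
        pick = rng.choice(len(rows), size=n_minor, replace=False)
        parts.append(rows.iloc[np.sort(pick)])
    return pd.concat(parts, ignore_index=True)


@dataclass
class DatasetVariant:
    name: str
    train: pd.DataFrame
    test: pd.DataFrame
    state: PreprocessState
    resampling: str = "none"
    #: train table before resampling; cross-validation resamples inside
    #: each training fold from this to avoid duplicated rows straddling folds
    base_train: pd.DataFrame = None

    def __post_init__(self):
        if self.base_train is None:
            self.base_train = self.train


def build_variants(
    train: pd.DataFrame,
    test: pd.DataFrame,
    threshold: float = 0.95,
    seed: int = 0,
) -> dict[str, DatasetVariant]:
    """The six preprocessing regimes (scale -> [PCA] -> [resample])."""
    feats = feature_columns(train)
    scaler = ZScoreScaler().fit(train[feats])
    scaled_state = PreprocessState(scaler=scaler)
    train_scaled = scaled_state.transform(train)
    test_scaled = scaled_state.transform(test)

    pca = VarianceThresholdPCA(threshold=threshold).fit(
        scaler.transform(train[feats])
    )
    pca_state = PreprocessState(scaler=scaler, pca=pca)
    train_pca = pca_state.transform(train)
    test_pca = pca_state.transform(test)

    variants = {}
    for base_name, tr, te, state in (
        ("Scaled", train_scaled, test_scaled, scaled_state),
        ("PCA", train_pca, test_pca, pca_state),
    ):
        variants[base_name] = DatasetVariant(base_name, tr, te, state)
        variants[base_name + "Up"] = DatasetVariant(
            base_name + "Up", upsample_minor(tr, seed), te, state, "up", tr
        )
        variants[base_name + "Down"] = DatasetVariant(
            base_name + "Down", downsample_major(tr, seed), te, state, "down", tr
        )
    return {name: variants[name] for name in VARIANT_NAMES}
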