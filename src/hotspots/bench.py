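"""Classifier clustering, cross-validated benchmarking and MANOVA.

The 51 candidate algorithm names are characterised by binary capability
tags (bagging, boosting, kernel method, discriminant analysis, ...);
Jaccard distances between tag vectors feed complete-linkage hierarchical
clustering cut at five clusters.  A representative registry of scikit-learn
models spanning those clusters is benchmarked with repeated stratified
10-fold cross-validation on each dataset variant; the champion of each
cluster maximises AUROC + TPR + TNR.  One-way MANOVA (Pillai trace) tests
whether metric profiles differ between clusters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import f as f_dist
from sklearn.base import clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from . import metrics as hm
from .preprocessing import (
    LABEL_COLUMN,
    DatasetVariant,
    downsample_major,
    feature_columns,
    upsample_minor,
)

logger = logging.getLogger(__name__)

ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")


def load_tag_matrix() -> pd.DataFrame:
    """Binary capability-tag matrix for the 51 candidate algorithm names."""
    with resources.files("hotspots.data").joinpath("algorithm_tags.csv").open() as fh:
        tags = pd.read_csv(fh, index_col="algorithm")
    return tags


def jaccard_distance(tags: pd.DataFrame) -> pd.DataFrame:
    """d(a, b) = 1 - |a AND b| / |a OR b| on binary tag vectors."""
    X = tags.to_numpy(dtype=bool)
    if ((X != 0) & (X != 1)).any():
        raise ValueError("tag matrix must be binary")
    inter = (X[:, None, :] & X[None, :, :]).sum(axis=2).astype(float)
    union = (X[:, None, :] | X[None, :, :]).sum(axis=2).astype(float)
    with np.errstate(invalid="ignore"):
        dist = 1.0 - inter / union
    if np.isnan(dist).any():
        warnings.warn("all-zero tag vector pair; defining distance as 0")
        dist = np.nan_to_num(dist, nan=0.0)
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=tags.index, columns=tags.index)


def cluster_algorithms(dist: pd.DataFrame, k: int = 5) -> dict[str, str]:
    """Complete-linkage hierarchical clustering cut at k clusters.

    Rows are processed in lexicographic algorithm order so linkage
    tie-breaks are deterministic.  Cluster labels are Roman numerals in
    order of each cluster's first (lexicographically smallest) member.
    """
    if k > len(dist):
        raise ValueError(f"k={k} exceeds the number of algorithms ({len(dist)})")
    order = sorted(dist.index)
    d = dist.loc[order, order].to_numpy(dtype=float)
    n = len(order)
    if k == n:
        raw = np.arange(1, k + 1)
    else:
        Z = linkage(squareform(d, checks=False), method="complete")
        # cut after the first n-k merges (not at a height threshold):
        # tied merge heights are common with Jaccard distances and a
        # height cut cannot then produce exactly k clusters
        parent = list(range(2 * n - 1))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for m in range(n - k):
            a, b = int(Z[m, 0]), int(Z[m, 1])
            parent[find(a)] = parent[find(b)] = n + m
        roots: dict[int, int] = {}
        raw = np.array(
            [roots.setdefault(find(i), len(roots) + 1) for i in range(n)]
        )
    relabel: dict[int, str] = {}
    for name, c in zip(order, raw):
        if c not in relabel:
            relabel[c] = ROMAN[len(relabel)]
    return {name: relabel[c] for name, c in zip(order, raw)}


def default_registry(random_state: int = 0) -> dict[str, object]:
    """Representative scikit-learn models keyed by candidate algorithm name.

    A subset of the 51 names spanning all five capability clusters; each
    entry is the closest scikit-learn realisation of the named method
    ("pda" is a shrinkage discriminant classifier, "plr" an L2-penalised
    logistic regression, "LogitBoost" a gradient-boosted stage-wise
    additive model).
    """
    return {
        "rf": RandomForestClassifier(n_estimators=200, random_state=random_state),
        "LogitBoost": GradientBoostingClassifier(random_state=random_state),
        "glm": LogisticRegression(penalty=None, max_iter=2000),
        "plr": LogisticRegression(C=1.0, max_iter=2000),
        "svmPoly": SVC(kernel="poly", degree=3, coef0=1.0, C=1.0,
                       random_state=random_state),
        "svmRadial": SVC(kernel="rbf", C=1.0, random_state=random_state),
        "knn": KNeighborsClassifier(n_neighbors=7),
        "nb": GaussianNB(),
        "lda": LinearDiscriminantAnalysis(),
        "qda": QuadraticDiscriminantAnalysis(reg_param=0.1),
        "pda": LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto"),
    }


def model_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous scores for AUROC: probability of HS, else decision value."""
    if hasattr(model, "predict_proba"):
        classes = list(model.classes_)
        return model.predict_proba(X)[:, classes.index(1)]
    return model.decision_function(X)


@dataclass
class CvResult:
    algorithm: str
    variant: str
    metrics: dict[str, float]
    n_failures: int = 0

    @property
    def selection_score(self) -> float:
        return (
            self.metrics.get("AUROC", np.nan)
            + self.metrics.get("TPR", np.nan)
            + self.metrics.get("TNR", np.nan)
        )


def _fold_metrics(model, X_tr, y_tr, X_te, y_te) -> dict[str, float]:
    model.fit(X_tr, y_tr)
    pred = np.where(model.predict(X_te) == 1, "HS", "NS")
    truth = np.where(y_te == 1, "HS", "NS")
    report = hm.full_report(pred, truth, model_scores(model, X_te))
    return report.as_dict()


def benchmark(
    models: dict[str, object],
    variants: dict[str, DatasetVariant],
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> list[CvResult]:
    """Repeated stratified k-fold CV of every model on every variant.

    Up-/down-sampling variants re-apply their resampling inside each
    training fold only, so duplicated minority rows never straddle a fold
    boundary.  Models raising on any fold are recorded with the folds
    that succeeded; models failing everywhere are omitted.
    """
    results: list[CvResult] = []
    for vname, variant in variants.items():
        base = variant.base_train
        feats = feature_columns(base)
        X = base[feats].to_numpy(dtype=float)
        y = (base[LABEL_COLUMN] == "HS").to_numpy(dtype=int)
        cv = RepeatedStratifiedKFold(
            n_splits=folds, n_repeats=repeats, random_state=seed
        )
        for name in sorted(models):
            fold_rows, failures = [], 0
            for tr_idx, te_idx in cv.split(X, y):
                df_tr = base.iloc[tr_idx]
                if variant.resampling == "up":
                    df_tr = upsample_minor(df_tr, seed)
                elif variant.resampling == "down":
                    df_tr = downsample_major(df_tr, seed)
                X_tr = df_tr[feats].to_numpy(dtype=float)
                y_tr = (df_tr[LABEL_COLUMN] == "HS").to_numpy(dtype=int)
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        fold_rows.append(
                            _fold_metrics(clone(models[name]), X_tr, y_tr,
                                          X[te_idx], y[te_idx])
                        )
                except Exception as exc:  # convergence/degenerate-fold failures
                    failures += 1
                    logger.debug("%s on %s failed a fold: %s", name, vname, exc)
            if not fold_rows:
                logger.warning("%s did not converge on %s; omitted", name, vname)
                continue
            frame = pd.DataFrame(fold_rows)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN metric
                means = {c: float(np.nanmean(frame[c])) for c in frame.columns}
            results.append(
                CvResult(
                    algorithm=name, variant=vname,
                    metrics=means, n_failures=failures,
                )
            )
    return results


def select_champions(
    results: list[CvResult],
    clusters: dict[str, str],
    variant: str,
) -> dict[str, str]:
    """Per cluster, the algorithm maximising AUROC + TPR + TNR.

    Ties break to the lexicographically smaller name.  Clusters with no
    surviving result are skipped with a warning.
    """
    by_cluster: dict[str, list[CvResult]] = {}
    for r in results:
        if r.variant != variant or r.algorithm not in clusters:
            continue
        by_cluster.setdefault(clusters[r.algorithm], []).append(r)
    champions: dict[str, str] = {}
    for label in sorted(set(clusters.values())):
        rows = by_cluster.get(label, [])
        if not rows:
            logger.warning("cluster %s has no benchmark result; skipped", label)
            continue
        best = max(
            sorted(rows, key=lambda r: r.algorithm),
            key=lambda r: (np.nan_to_num(r.selection_score, nan=-np.inf)),
        )
        champions[label] = best.algorithm
    return champions


def results_frame(results: list[CvResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"algorithm": r.algorithm, "variant": r.variant,
               "n_failures": r.n_failures, **r.metrics}
        rows.append(row)
    return pd.DataFrame(rows)


def manova_pillai(
    responses: pd.DataFrame, groups: dict[str, str] | pd.Series
) -> tuple[float, float]:
    """One-way MANOVA via the Pillai trace.

    ``responses``: one row per algorithm, columns are metrics; ``groups``
    maps algorithm name to cluster label.  Between-group (H) and
    within-group (E) scatter matrices give A = H E^-1; the Pillai trace is
    V = sum(lambda / (1 + lambda)) over eigenvalues of A, with the
    standard F approximation for the p-value.
    """
    g = pd.Series(groups)
    common = responses.index.intersection(g.index)
    X = responses.loc[common].to_numpy(dtype=float)
    labels = g.loc[common].to_numpy()
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("MANOVA needs at least two groups")
    if any((labels == u).sum() < 2 for u in uniq):
        raise ValueError("every group needs at least two members")
    p = X.shape[1]
    if p < 2:
        raise ValueError("MANOVA needs at least two response metrics")
    grand = X.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for u in uniq:
        block = X[labels == u]
        d = (block.mean(axis=0) - grand)[:, None]
        H += len(block) * (d @ d.T)
        centred = block - block.mean(axis=0)
        E += centred.T @ centred
    try:
        A = H @ np.linalg.inv(E)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "within-group scatter matrix is singular; reduce the number of "
            "response metrics or add algorithms"
        ) from exc
    eig = np.linalg.eigvals(A).real
    eig = np.clip(eig, 0.0, None)
    V = float(np.sum(eig / (1.0 + eig)))
    n_obs, g_count = X.shape[0], len(uniq)
    s = min(p, g_count - 1)
    m = (abs(p - g_count + 1) - 1) / 2.0
    n_par = (n_obs - g_count - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * n_par + s + 1)
    if df2 <= 0 or V >= s:
        return V, float("nan")
    F = (df2 / df1) * (V / (s - V))
    pval = float(f_dist.sf(F, df1, df2))
    return V, pval
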