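"""Stacked hot-spot classifier.

Champion base learners (by default a random forest, a polynomial-kernel
SVM and a shrinkage discriminant classifier) are combined by a logistic
meta-model:

    logit(pi) = ln(pi / (1 - pi)) = beta0 + sum_i beta_i X_i

where the covariates X_i are the base learners' binary classifications.
The meta-model is fitted on OUT-OF-FOLD base predictions (cross-fitting),
so it never sees a base learner's in-sample output, and its covariates
are pruned by bidirectional stepwise selection on Wald p-values.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

logger = logging.getLogger(__name__)

ARCHIVE_VERSION = "1"


def default_base_estimators(random_state: int | None = 0):
    """rf + polynomial-kernel SVM + penalized (shrinkage) discriminant."""
    return [
        ("rf", RandomForestClassifier(n_estimators=200, random_state=random_state)),
        ("svmPoly", SVC(kernel="poly", degree=3, coef0=1.0, C=1.0,
                        random_state=random_state)),
        ("pda", LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")),
    ]


def _wald_pvalues(result) -> pd.Series:
    return result.pvalues.drop("const", errors="ignore")


_SEPARATION_COEF = 15.0  # |beta| beyond this on 0/1 covariates means separation


def _fit_mle(X: pd.DataFrame, y: np.ndarray):
    """Maximum-likelihood logit; flags (quasi-)separated fits.

    Separated fits still expose a valid log-likelihood but their Wald
    statistics are degenerate (Hauck-Donner), so callers must switch to
    likelihood-ratio reasoning when the flag is set.
    """
    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, design)
        try:
            result = model.fit(disp=0, maxiter=200)
        except Exception:  # singular Hessian under separation/collinearity
            result = model.fit(method="bfgs", disp=0, maxiter=500)
    try:
        bse_ok = bool(np.isfinite(result.bse).all())
    except Exception:
        bse_ok = False
    sep = (
        not bse_ok
        or not np.isfinite(result.params).all()
        or bool((np.abs(result.params.drop("const", errors="ignore"))
                 > _SEPARATION_COEF).any())
    )
    return result, sep


def _fit_logit(X: pd.DataFrame, y: np.ndarray):
    """Final-model fit: MLE, or an L2-penalised fallback under separation."""
    try:
        result, sep = _fit_mle(X, y)
        if not sep:
            return result, False
    except Exception:
        pass
    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = sm.GLM(
            y, design, family=sm.families.Binomial()
        ).fit_regularized(alpha=1.0 / max(len(y), 1), L1_wt=0.0)
    return result, True


def stepwise_select(
    X: pd.DataFrame,
    y: np.ndarray,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.05,
) -> list[str]:
    """Bidirectional stepwise covariate selection on Wald statistics.

    Forward step: add the candidate with the smallest p-value if it is
    below ``alpha_enter`` — the Wald p of its coefficient, or, when the
    candidate fit is (quasi-)separated and Wald statistics degenerate, a
    one-degree likelihood-ratio test against the current model.  Backward
    step: drop the included covariate with the largest Wald p-value if it
    exceeds ``alpha_remove`` (skipped under separation, where every
    retained covariate is at the boundary).  Candidates are scanned in
    lexicographic order, so ties are deterministic.  Returns the selected
    column names (possibly empty: intercept-only).
    """
    from scipy.stats import chi2

    if X.shape[1] == 0:
        raise ValueError("no candidate covariates for stepwise selection")

    def _llf(cols: list[str]) -> float:
        try:
            result, _ = _fit_mle(X[cols] if cols else X.iloc[:, :0], y)
            return float(result.llf)
        except Exception:  # last resort: near-unpenalised ridge likelihood
            from sklearn.linear_model import LogisticRegression

            if cols:
                lr = LogisticRegression(C=1e3, max_iter=1000).fit(X[cols], y)
                p = lr.predict_proba(X[cols])[:, 1]
            else:
                p = np.full(len(y), y.mean())
            p = np.clip(p, 1e-12, 1 - 1e-12)
            return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))

    selected: list[str] = []
    visited = {()}
    changed = True
    while changed:
        changed = False
        remaining = sorted(c for c in X.columns if c not in selected)
        llf0 = _llf(selected) if remaining else None
        best_name, best_p = None, np.inf
        for name in remaining:
            try:
                result, sep = _fit_mle(X[selected + [name]], y)
            except Exception:
                continue
            if sep:
                lr = max(2.0 * (float(result.llf) - llf0), 0.0)
                p = float(chi2.sf(lr, 1))
            else:
                p = float(_wald_pvalues(result).get(name, np.inf))
            if p < best_p - 1e-12:
                best_name, best_p = name, p
        if best_name is not None and best_p < alpha_enter:
            selected.append(best_name)
            selected.sort()
            changed = True
        if selected:
            try:
                result, sep = _fit_mle(X[selected], y)
            except Exception:
                sep = True
            if not sep:
                pvals = _wald_pvalues(result)
                worst = pvals.idxmax()
                if float(pvals.max()) > alpha_remove:
                    selected.remove(worst)
                    changed = True
        state = tuple(selected)
        if changed and state in visited:  # add/remove cycle: stop
            break
        visited.add(state)
    if not selected:
        logger.warning("stepwise selection removed all covariates; "
                       "keeping intercept-only meta-model")
    return selected


class StackedHotspotClassifier(BaseEstimator, ClassifierMixin):
    """Hot-spot/null-spot classifier stacking base learners with a logit.

    Parameters
    ----------
    base_estimators : list of (name, estimator), optional
        Champion base classifiers.  Defaults to rf + svmPoly + pda.
    cv : int
        Folds used to produce out-of-fold base predictions for the
        meta-model (cross-fitting; leakage guard).
    alpha : float
        Wald significance level for bidirectional stepwise selection.
    threshold : float
        Probability threshold for calling HS; the boundary pi == threshold
        is classified HS.
    use_probabilities : bool
        Feed base probabilities instead of binary classifications to the
        meta-model.
    stepwise : bool
        Disable to keep the full (all base learners) regression.
    """

    def __init__(
        self,
        base_estimators=None,
        cv: int = 5,
        alpha: float = 0.05,
        threshold: float = 0.5,
        use_probabilities: bool = False,
        stepwise: bool = True,
        random_state: int | None = 0,
    ):
        self.base_estimators = base_estimators
        self.cv = cv
        self.alpha = alpha
        self.threshold = threshold
        self.use_probabilities = use_probabilities
        self.stepwise = stepwise
        self.random_state = random_state

    def _encode_y(self, y) -> np.ndarray:
        y = np.asarray(y)
        if y.dtype.kind in "UO":
            valid = set(np.unique(y)) - {"HS", "NS"}
            if valid:
                raise ValueError(f"labels must be HS/NS; got {sorted(valid)}")
            return (y == "HS").astype(int)
        return y.astype(int)

    def _base_matrix(self, estimators, X) -> pd.DataFrame:
        cols = {}
        for name, est in estimators:
            if self.use_probabilities and hasattr(est, "predict_proba"):
                classes = list(est.classes_)
                cols[name] = est.predict_proba(X)[:, classes.index(1)]
            else:
                cols[name] = est.predict(X).astype(float)
        return pd.DataFrame(cols)

    def fit(self, X, y):
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie strictly inside (0, 1)")
        X, y01 = check_X_y(np.asarray(X, dtype=float), self._encode_y(y))
        if len(np.unique(y01)) < 2:
            raise ValueError("training data must contain both HS and NS")
        base = self.base_estimators or default_base_estimators(self.random_state)
        skf = StratifiedKFold(
            n_splits=self.cv, shuffle=True, random_state=self.random_state
        )
        oof_cols, fitted = {}, []
        for name, est in base:
            est = clone(est)
            try:
                method = (
                    "predict_proba"
                    if self.use_probabilities and hasattr(est, "predict_proba")
                    else "predict"
                )
                oof = cross_val_predict(est, X, y01, cv=skf, method=method)
                if oof.ndim == 2:
                    oof = oof[:, 1]
                est.fit(X, y01)
            except Exception as exc:
                logger.warning("base learner %s failed to fit (%s); excluded",
                               name, exc)
                continue
            oof_cols[name] = oof.astype(float)
            fitted.append((name, est))
        if not fitted:
            raise RuntimeError("no base learner could be fitted")
        self.base_estimators_ = fitted
        oof_frame = pd.DataFrame(oof_cols)
        #: provenance guard — meta inputs are strictly out-of-fold
        self.meta_inputs_out_of_fold_ = True
        if self.stepwise:
            self.selected_ = stepwise_select(oof_frame, y01,
                                             self.alpha, self.alpha)
        else:
            self.selected_ = sorted(oof_frame.columns)
        result, self.separation_ = _fit_logit(oof_frame[self.selected_], y01)
        params = result.params
        self.intercept_ = float(params.get("const", 0.0))
        self.coef_ = {name: float(params[name]) for name in self.selected_}
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def _pi(self, X) -> np.ndarray:
        check_is_fitted(self, "base_estimators_")
        X = check_array(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; the model was fitted on "
                f"{self.n_features_in_}"
            )
        base_out = self._base_matrix(self.base_estimators_, X)
        eta = np.full(len(X), self.intercept_, dtype=float)
        for name in self.selected_:
            eta += self.coef_[name] * base_out[name].to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    def predict_proba(self, X) -> np.ndarray:
        pi = self._pi(X)
        return np.column_stack([1.0 - pi, pi])

    def predict(self, X) -> np.ndarray:
        return (self._pi(X) >= self.threshold).astype(int)

    def predict_labels(self, X) -> np.ndarray:
        return np.where(self.predict(X) == 1, "HS", "NS")


def save_model(model, path, preprocess_state=None, metadata=None) -> None:
    """Archive a fitted model (plus optional preprocess state) to disk."""
    check_is_fitted(model, "base_estimators_")
    payload = {
        "version": ARCHIVE_VERSION,
        "model": model,
        "preprocess_state": preprocess_state.to_json() if preprocess_state else None,
        "metadata": metadata or {},
    }
    joblib.dump(payload, path)


def load_model(path):
    """Load an archived model; returns (model, preprocess_state, metadata)."""
    from .preprocessing import PreprocessState

    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ValueError(f"cannot read model archive {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("version") != ARCHIVE_VERSION:
        raise ValueError(
            f"unsupported model-archive version: "
            f"{payload.get('version') if isinstance(payload, dict) else '???'!r}"
        )
    state = (
        PreprocessState.from_json(payload["preprocess_state"])
        if payload.get("preprocess_state")
        else None
    )
    return payload["model"], state, payload.get("metadata", {})
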