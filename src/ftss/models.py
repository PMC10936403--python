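"""Statistical-learning pipelines for balance, cognition, and falls-risk outcomes.

Two cross-validated pipelines operate on the per-subject design matrix
(first trial's movement features + age, sex, height, weight, optional
pairwise interactions):

* **classification** — logistic regression with sequential forward feature
  selection (SFS) nested inside 10-fold cross-validation.  Selection is
  performed on each training fold only (inner 5-fold CV accuracy), so
  held-out performance is unbiased; every model is constrained to include
  the total FTSS time.  Outer-fold predictions are pooled into one
  confusion matrix.
* **regression** — Poisson regression (log link, suitable for the
  count-valued MMSE and BBS scores) with elastic-net model selection at
  mixing parameter alpha = 0.1 (mostly ridge, some sparsity).  The penalty
  strength is chosen per fold by inner-validation deviance subject to an a
  priori model size of 3–20 features; total time is excluded from the
  penalty so it is always retained.  The active set is then refit by
  unpenalized maximum likelihood before predicting the held-out subjects.

Fold assignment is a pure function of the subject order and the seed, so
every run is exactly reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as spstats
from sklearn.model_selection import KFold, StratifiedKFold

from .cohort_stats import Cohort
from .errors import ContractError, DataError

log = logging.getLogger(__name__)

DEMOGRAPHICS = ("age", "sex", "height_cm", "weight_kg")

#: elastic-net mixing parameter (lasso weight), fixed a priori
ELASTIC_NET_ALPHA = 0.1
#: a priori model-size bounds for the elastic-net models
SIZE_BOUNDS = (3, 20)
FORCED_FEATURE = "total_time"


# ---------------------------------------------------------------------------
# design matrix


@dataclass(frozen=True)
class DesignMatrix:
    """Per-subject predictor table; standardization happens per training fold."""

    frame: pd.DataFrame  # index: subject_id, columns: predictors
    binary_columns: tuple = ()

    @property
    def feature_names(self) -> tuple:
        return tuple(self.frame.columns)

    @property
    def subject_ids(self) -> tuple:
        return tuple(self.frame.index)

    def standardize(self, train_idx: np.ndarray) -> np.ndarray:
        """Z-score continuous columns using training-row statistics only."""
        X = self.frame.to_numpy(dtype=float).copy()
        cont = [j for j, c in enumerate(self.frame.columns) if c not in self.binary_columns]
        mu = X[np.ix_(train_idx, cont)].mean(axis=0)
        sd = X[np.ix_(train_idx, cont)].std(axis=0, ddof=0)
        sd[sd < 1e-12] = 1.0
        X[:, cont] = (X[:, cont] - mu) / sd
        return X


def _interaction_name(a: str, b: str) -> str:
    a, b = sorted((a, b))
    return f"{a}:{b}"


def build_design_matrix(
    cohort: Cohort,
    features: pd.DataFrame,
    stratum: str = "pooled",
    interactions: bool = False,
    interaction_candidates=None,
) -> DesignMatrix:
    """Assemble the per-subject design matrix.

    Only the first trial per subject enters (single-assessment scenario).
    Demographics (age, sex, height, weight) are appended; sex is removed in
    sex-stratified matrices where it is constant.  With ``interactions``,
    all pairwise products among ``interaction_candidates`` (default:
    demographics + total time) are added under canonical "A:B" names.
    Constant columns are dropped with a warning.
    """
    if stratum not in ("pooled", "male", "female"):
        raise ContractError(f"unknown stratum {stratum!r}")
    if "subject_id" not in features.columns:
        raise DataError("features frame needs a subject_id column")
    first = (
        features.sort_values(["subject_id", "trial_id"])
        if "trial_id" in features.columns
        else features
    )
    first = first.groupby("subject_id", sort=True).head(1).set_index("subject_id")
    first = first.drop(columns=[c for c in ("trial_id",) if c in first.columns])

    clin = cohort.frame.set_index("subject_id")
    demo = clin[["age", "height_cm", "weight_kg"]].copy()
    demo["sex"] = (clin["sex"] == "male").astype(float)
    df = first.join(demo, how="inner")
    if stratum != "pooled":
        df = df[df["sex"] == (1.0 if stratum == "male" else 0.0)]
        df = df.drop(columns=["sex"])
        assert "sex" not in df.columns
    if len(df) == 0:
        raise DataError(f"no subjects left in stratum {stratum!r}")

    binary = tuple(c for c in ("sex",) if c in df.columns)
    if interactions:
        if interaction_candidates is None:
            interaction_candidates = [
                c for c in (FORCED_FEATURE, "age", "sex", "height_cm", "weight_kg")
                if c in df.columns
            ]
        cand = [c for c in interaction_candidates if c in df.columns]
        for i, a in enumerate(cand):
            for b in cand[i + 1:]:
                df[_interaction_name(a, b)] = df[a] * df[b]

    constant = [c for c in df.columns if np.ptp(df[c].to_numpy(dtype=float)) < 1e-12]
    if constant:
        log.warning("dropping constant design columns: %s", ", ".join(constant))
        df = df.drop(columns=constant)
    return DesignMatrix(frame=df, binary_columns=binary)


def outcome_labels(cohort: Cohort, outcome: str) -> pd.Series:
    """Binary label (classification) or count score (regression) per subject."""
    clin = cohort.frame.set_index("subject_id")
    mapping = {
        "balance": clin["balance_impaired"].astype(int),
        "cognition": clin["cognitive_impaired"].astype(int),
        "falls": clin["faller"].astype(int),
        "bbs": clin["bbs"].astype(int),
        "mmse": clin["mmse"].astype(int),
    }
    if outcome not in mapping:
        raise ContractError(f"unknown outcome {outcome!r}")
    return mapping[outcome]


# ---------------------------------------------------------------------------
# metrics


def _safe_pct(num: float, den: float):
    return 100.0 * num / den if den > 0 else None


def classification_metrics(confusion: dict) -> dict:
    """Accuracy, sensitivity, specificity, PPV, NPV (percent) from tp/fp/tn/fn."""
    tp, fp, tn, fn = (confusion[k] for k in ("tp", "fp", "tn", "fn"))
    total = tp + fp + tn + fn
    if total < 1:
        raise DataError("empty confusion matrix")
    return {
        "acc": _safe_pct(tp + tn, total),
        "sens": _safe_pct(tp, tp + fn),
        "spec": _safe_pct(tn, tn + fp),
        "ppv": _safe_pct(tp, tp + fp),
        "npv": _safe_pct(tn, tn + fn),
    }


def regression_metrics(y_true, y_pred) -> dict:
    """R², RMSE (score points) and Spearman rho on pooled CV predictions."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 3:
        raise DataError("regression metrics need equal-length vectors of >= 3")
    ss_tot = np.sum((y_true - y_true.mean()) ** 2)
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    if ss_tot < 1e-12:
        r2 = None
    else:
        r2 = float(1.0 - np.sum((y_true - y_pred) ** 2) / ss_tot)
    if np.ptp(y_pred) < 1e-12 or np.ptp(y_true) < 1e-12:
        rho = None
    else:
        rho = float(spstats.spearmanr(y_true, y_pred).statistic)
    return {"r2": r2, "rmse": rmse, "rho": rho}


# ---------------------------------------------------------------------------
# logistic regression + sequential forward selection


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))


def fit_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 1e-6,
                 max_iter: int = 30, tol: float = 1e-9) -> np.ndarray:
    """Maximum-likelihood logistic fit by Newton iteration.

    A tiny ridge term (default 1e-6, intercept unpenalized) keeps the
    Hessian invertible under complete separation; at this magnitude it is
    numerically indistinguishable from the MLE on non-separated data.
    """
    n, p = X.shape
    Xb = np.hstack([np.ones((n, 1)), X])
    beta = np.zeros(p + 1)
    pen = ridge * np.r_[0.0, np.ones(p)]
    for _ in range(max_iter):
        mu = _sigmoid(Xb @ beta)
        w = np.maximum(mu * (1 - mu), 1e-12)
        grad = Xb.T @ (y - mu) - pen * beta
        hess = (Xb * w[:, None]).T @ Xb + np.diag(pen + 1e-12)
        step = np.linalg.solve(hess, grad)
        beta += step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def _predict_logistic(beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    return _sigmoid(beta[0] + X @ beta[1:])


def _inner_cv_accuracy(X: np.ndarray, y: np.ndarray, cols: list,
                       inner_folds: int, seed: int) -> float:
    splitter = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    correct = 0
    for tr, va in splitter.split(X, y):
        beta = fit_logistic(X[np.ix_(tr, cols)], y[tr])
        pred = _predict_logistic(beta, X[np.ix_(va, cols)]) >= 0.5
        correct += int(np.sum(pred == (y[va] == 1)))
    return correct / y.size


@dataclass(frozen=True)
class ClassificationReport:
    outcome: str
    sensor: str
    stratum: str
    acc: float
    sens: float
    spec: float
    ppv: float
    npv: float
    confusion: dict
    selected_features: tuple  # one tuple of names per outer fold
    n: int

    def metrics(self) -> dict:
        return {k: getattr(self, k) for k in ("acc", "sens", "spec", "ppv", "npv")}


def sfs_logistic_cv(
    dm: DesignMatrix,
    y,
    k_folds: int = 10,
    forced=(FORCED_FEATURE,),
    seed: int = 0,
    inner_folds: int = 5,
    min_improvement: float = 0.005,
    max_features: int = 10,
    outcome: str = "",
    sensor: str = "",
    stratum: str = "pooled",
) -> ClassificationReport:
    """Nested-CV logistic classification with sequential forward selection.

    Per outer fold: starting from the forced set, greedily add the candidate
    that maximizes inner 5-fold CV accuracy on the training fold, stopping
    when the best addition improves accuracy by less than
    ``min_improvement`` (0.5 percentage points) or ``max_features`` is
    reached.  The final model is fit on the whole training fold and
    held-out subjects are classified at probability 0.5.  Outer-fold
    predictions are pooled into a single confusion matrix.
    """
    y = np.asarray(y, dtype=float)
    if y.size != len(dm.frame):
        raise DataError("label vector does not match design matrix rows")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise DataError(f"need exactly 2 classes, got {classes.size}")
    if counts.min() < k_folds:
        raise DataError(
            f"minority class ({counts.min()} subjects) cannot stratify {k_folds} folds"
        )
    names = dm.feature_names
    forced_idx = [names.index(f) for f in forced if f in names]
    if len(forced_idx) != len(tuple(forced)):
        missing = [f for f in forced if f not in names]
        raise ContractError(f"forced features absent from design matrix: {missing}")
    candidates = [j for j in range(len(names)) if j not in forced_idx]

    outer = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    tp = fp = tn = fn = 0
    selected_per_fold = []
    for fold, (tr, te) in enumerate(outer.split(dm.frame, y)):
        X = dm.standardize(tr)
        inner_seed = seed * 1000 + fold
        selected = list(forced_idx)
        current = _inner_cv_accuracy(X[tr], y[tr], selected, inner_folds, inner_seed)
        remaining = list(candidates)
        while remaining and len(selected) < max_features:
            scores = [
                _inner_cv_accuracy(X[tr], y[tr], selected + [j], inner_folds, inner_seed)
                for j in remaining
            ]
            best = int(np.argmax(scores))
            if scores[best] - current < min_improvement:
                break
            current = scores[best]
            selected.append(remaining.pop(best))
        beta = fit_logistic(X[np.ix_(tr, selected)], y[tr])
        pred = _predict_logistic(beta, X[np.ix_(te, selected)]) >= 0.5
        truth = y[te] == 1
        tp += int(np.sum(pred & truth))
        fp += int(np.sum(pred & ~truth))
        tn += int(np.sum(~pred & ~truth))
        fn += int(np.sum(~pred & truth))
        selected_per_fold.append(tuple(names[j] for j in selected))

    confusion = {"tp": tp, "fp": fp, "tn": tn, "fn": fn}
    m = classification_metrics(confusion)
    return ClassificationReport(
        outcome=outcome, sensor=sensor, stratum=stratum,
        confusion=confusion, selected_features=tuple(selected_per_fold),
        n=int(y.size), **m,
    )


def mean_of_sexes(male: ClassificationReport, female: ClassificationReport) -> dict:
    """Unweighted mean of male and female model metrics."""
    out = {}
    for k in ("acc", "sens", "spec", "ppv", "npv"):
        a, b = getattr(male, k), getattr(female, k)
        out[k] = None if a is None or b is None else 0.5 * (a + b)
    return out


# ---------------------------------------------------------------------------
# Poisson elastic net


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.maximum(mu, 1e-10)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def poisson_elastic_net_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    alpha: float = ELASTIC_NET_ALPHA,
    penalty_free: np.ndarray | None = None,
):
    """Elastic-net-penalized Poisson coefficient path (warm-started).

    ``penalty_free`` marks columns excluded from the penalty (the forced
    feature); the intercept is never penalized.  Returns an array of
    coefficient vectors, one per penalty strength, each of length
    ``1 + n_columns`` (intercept first).
    """
    n, p = X.shape
    Xb = np.hstack([np.ones((n, 1)), X])
    weight = np.ones(p + 1)
    weight[0] = 0.0
    if penalty_free is not None:
        weight[1:][np.asarray(penalty_free, dtype=bool)] = 0.0
    model = sm.GLM(y, Xb, family=sm.families.Poisson())
    start = None
    out = np.empty((lambdas.size, p + 1))
    for i, lam in enumerate(lambdas):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit_regularized(
                method="elastic_net", alpha=lam * weight, L1_wt=alpha,
                start_params=start, cnvrg_tol=1e-7,
            )
        out[i] = res.params
        start = res.params
    return out


def _refit_active(X: np.ndarray, y: np.ndarray, active: list) -> np.ndarray:
    """Unpenalized Poisson MLE on the active columns (relaxed elastic net)."""
    Xb = np.hstack([np.ones((X.shape[0], 1)), X[:, active]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, Xb, family=sm.families.Poisson()).fit()
    return res.params


@dataclass(frozen=True)
class RegressionReport:
    outcome: str
    sensor: str
    stratum: str
    r2: float
    rmse: float
    rho: float
    dof: float  # median selected model size across folds
    n: int
    selected_features: tuple = ()  # one tuple of names per fold
    fold_coefficients: tuple = ()  # one {name: coef} dict per fold (standardized scale)
    size_bound_warnings: int = 0

    def metrics(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse, "rho": self.rho, "dof": self.dof}


def poisson_elastic_net_cv(
    dm: DesignMatrix,
    y,
    alpha: float = ELASTIC_NET_ALPHA,
    size_bounds=SIZE_BOUNDS,
    k_folds: int = 10,
    forced=(FORCED_FEATURE,),
    seed: int = 0,
    n_lambdas: int = 25,
    outcome: str = "",
    sensor: str = "",
    stratum: str = "pooled",
) -> RegressionReport:
    """Cross-validated Poisson elastic net with a priori model-size bounds.

    Per outer fold the penalty path is fit on an inner training split
    (75% of the fold's training subjects) and scored by Poisson deviance on
    the held-back 25%; among penalties whose active-set size lies within
    ``size_bounds`` the deviance minimizer is chosen (nearest-size model,
    with a warning, if none qualifies).  The winning active set is refit by
    unpenalized maximum likelihood on the full training fold before
    predicting the held-out subjects through the log link.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise DataError("Poisson regression needs non-negative integer scores")
    if y.size != len(dm.frame):
        raise DataError("score vector does not match design matrix rows")
    names = dm.feature_names
    forced_mask = np.array([c in tuple(forced) for c in names])
    if forced_mask.sum() != len(tuple(forced)):
        missing = [f for f in forced if f not in names]
        raise ContractError(f"forced features absent from design matrix: {missing}")

    outer = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    y_true_pool, y_pred_pool = [], []
    sizes, selected_per_fold, coef_per_fold = [], [], []
    n_warn = 0
    lo, hi = size_bounds
    for fold, (tr, te) in enumerate(outer.split(dm.frame)):
        X = dm.standardize(tr)
        rng = np.random.default_rng(seed * 1000 + fold)
        perm = rng.permutation(tr.size)
        n_fit = max(int(round(0.75 * tr.size)), 2)
        fit_idx, val_idx = tr[perm[:n_fit]], tr[perm[n_fit:]]

        resid = y[fit_idx] - y[fit_idx].mean()
        grad = np.abs(X[fit_idx][:, ~forced_mask].T @ resid) / fit_idx.size
        lam_max = grad.max() / max(alpha, 1e-3) * 1.05
        lambdas = np.geomspace(lam_max, lam_max * 1e-3, n_lambdas)
        path = poisson_elastic_net_path(
            X[fit_idx], y[fit_idx], lambdas, alpha=alpha, penalty_free=forced_mask
        )

        best = None  # (in_bounds, -closeness, -deviance) style choice below
        for coefs in path:
            active = list(np.flatnonzero(np.abs(coefs[1:]) > 1e-8))
            for j in np.flatnonzero(forced_mask):
                if j not in active:
                    active.append(int(j))
            size = len(active)
            mu = np.exp(np.clip(coefs[0] + X[val_idx] @ coefs[1:], -30, 30))
            dev = _poisson_deviance(y[val_idx], mu)
            in_bounds = lo <= size <= hi
            dist = 0 if in_bounds else min(abs(size - lo), abs(size - hi))
            key = (dist, dev)
            if best is None or key < best[0]:
                best = (key, sorted(active), size)
        (dist, _), active, size = best
        if dist > 0:
            n_warn += 1
            log.warning("fold %d: no penalty met size bounds %s; nearest size %d used",
                        fold, size_bounds, size)
        beta = _refit_active(X[tr], y[tr], active)
        eta = beta[0] + X[np.ix_(te, active)] @ beta[1:]
        y_pred_pool.append(np.exp(np.clip(eta, -30, 30)))
        y_true_pool.append(y[te])
        sizes.append(len(active))
        selected_per_fold.append(tuple(names[j] for j in active))
        coef_per_fold.append({names[j]: float(b) for j, b in zip(active, beta[1:])})

    y_true = np.concatenate(y_true_pool)
    y_pred = np.concatenate(y_pred_pool)
    m = regression_metrics(y_true, y_pred)
    return RegressionReport(
        outcome=outcome, sensor=sensor, stratum=stratum,
        r2=m["r2"], rmse=m["rmse"], rho=m["rho"],
        dof=float(np.median(sizes)), n=int(y.size),
        selected_features=tuple(selected_per_fold),
        fold_coefficients=tuple(coef_per_fold),
        size_bound_warnings=n_warn,
    )
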