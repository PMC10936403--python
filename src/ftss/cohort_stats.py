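"""Clinical data model, outcome labeling, and exploratory statistics.

Covers the cohort side of the analysis: per-subject clinical covariates
(age, sex, anthropometrics, MMSE, BBS, 12-month falls history), the
derived binary outcomes (faller status, cognitive impairment at MMSE < 27,
balance impairment at BBS < 53), feature–score associations (Spearman),
faller/non-faller group differences (Wilcoxon rank-sum), categorical
between-arm comparisons (chi-square), and intra-session reliability of the
movement features via the two-way random-effects, absolute-agreement,
average-measures intraclass correlation ICC(2,k).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .errors import DataError, DegenerateInputError

MMSE_IMPAIRMENT_THRESHOLD = 27
BBS_IMPAIRMENT_THRESHOLD = 53

#: ICC banding cut-points: > 0.9 excellent, > 0.75 good, >= 0.5 moderate, else poor
ICC_BANDS = (0.5, 0.75, 0.9)

COHORT_COLUMNS = (
    "subject_id",
    "age",
    "sex",
    "height_cm",
    "weight_kg",
    "mmse",
    "bbs",
    "falls_12mo",
    "injurious_fall",
    "arm",
)


@dataclass(frozen=True)
class SubjectRecord:
    """Clinical covariates for one participant."""

    subject_id: str
    age: float
    sex: str  # "male" | "female"
    height_cm: float
    weight_kg: float
    mmse: int
    bbs: int
    falls_12mo: int
    injurious_fall: bool
    arm: str = "clinic"  # "home" | "clinic"

    def __post_init__(self):
        if not 0 <= self.mmse <= 30:
            raise DataError(f"MMSE must be in 0-30, got {self.mmse}")
        if not 0 <= self.bbs <= 56:
            raise DataError(f"BBS must be in 0-56, got {self.bbs}")
        if self.falls_12mo < 0:
            raise DataError("falls_12mo must be non-negative")
        if self.sex not in ("male", "female"):
            raise DataError(f"sex must be male/female, got {self.sex!r}")
        if self.arm not in ("home", "clinic"):
            raise DataError(f"arm must be home/clinic, got {self.arm!r}")


class Cohort:
    """A set of :class:`SubjectRecord` with frame-based access for the models."""

    def __init__(self, subjects):
        self.subjects = tuple(subjects)
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate subject ids in cohort")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(s) for s in self.subjects])
        df["faller"] = [label_faller(s) for s in self.subjects]
        labels = [dichotomize_scores(s) for s in self.subjects]
        df["cognitive_impaired"] = [d["cognitive_impaired"] for d in labels]
        df["balance_impaired"] = [d["balance_impaired"] for d in labels]
        return df

    def to_csv(self, path) -> None:
        pd.DataFrame([asdict(s) for s in self.subjects]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        df = pd.read_csv(path)
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"cohort file missing columns: {', '.join(missing)}")
        return cls(
            SubjectRecord(
                subject_id=str(r.subject_id),
                age=float(r.age),
                sex=str(r.sex),
                height_cm=float(r.height_cm),
                weight_kg=float(r.weight_kg),
                mmse=int(r.mmse),
                bbs=int(r.bbs),
                falls_12mo=int(r.falls_12mo),
                injurious_fall=bool(r.injurious_fall),
                arm=str(r.arm),
            )
            for r in df.itertuples()
        )


# ---------------------------------------------------------------------------
# outcome labeling


def label_faller(rec: SubjectRecord) -> bool:
    """Faller: more than one fall in 12 months, or any injurious fall.

    The injurious criterion presupposes at least one fall.
    """
    return rec.falls_12mo > 1 or (rec.falls_12mo >= 1 and rec.injurious_fall)


def dichotomize_scores(rec: SubjectRecord) -> dict:
    """Binary impairment labels: MMSE < 27 (cognition), BBS < 53 (balance)."""
    return {
        "cognitive_impaired": rec.mmse < MMSE_IMPAIRMENT_THRESHOLD,
        "balance_impaired": rec.bbs < BBS_IMPAIRMENT_THRESHOLD,
    }


# ---------------------------------------------------------------------------
# association tests


def average_trials(features: pd.DataFrame) -> pd.DataFrame:
    """Per-subject trial average of every feature column.

    ``features`` has one row per trial with a ``subject_id`` column; the
    result has one row per subject.  Averaging precedes any testing so each
    subject contributes one observation.
    """
    if "subject_id" not in features.columns:
        raise DataError("features frame needs a subject_id column")
    return features.groupby("subject_id", sort=True).mean(numeric_only=True).reset_index()


def association_tests(cohort: Cohort, features: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho of each feature vs MMSE and BBS, and faller/non-faller Wilcoxon.

    Features are averaged per subject across trials before testing.
    Constant features are reported with status "constant" and NA statistics
    rather than propagating NaN.
    """
    per_subject = average_trials(features)
    clin = cohort.frame[["subject_id", "mmse", "bbs", "faller"]]
    merged = per_subject.merge(clin, on="subject_id", how="inner")
    if len(merged) < 4:
        raise DataError("association tests need at least 4 matched subjects")
    feature_cols = [c for c in per_subject.columns if c != "subject_id"]
    faller = merged["faller"].to_numpy(dtype=bool)
    if faller.sum() < 2 or (~faller).sum() < 2:
        raise DataError("need >= 2 subjects in each fall-status group")
    rows = []
    for feat in feature_cols:
        x = merged[feat].to_numpy(dtype=float)
        row = {"feature": feat, "status": "ok"}
        if np.ptp(x) < 1e-12:
            row.update(
                status="constant",
                rho_mmse=np.nan, p_mmse=np.nan, rho_bbs=np.nan, p_bbs=np.nan,
                wilcoxon_stat=np.nan, wilcoxon_p=np.nan,
            )
        else:
            for score in ("mmse", "bbs"):
                rho, p = spstats.spearmanr(x, merged[score])
                row[f"rho_{score}"] = float(rho)
                row[f"p_{score}"] = float(p)
            stat, p = spstats.ranksums(x[faller], x[~faller])
            row["wilcoxon_stat"] = float(stat)
            row["wilcoxon_p"] = float(p)
        rows.append(row)
    return pd.DataFrame(rows)


def chi_square_arms(cohort: Cohort, column: str) -> dict:
    """Chi-square test of proportions for a categorical column across study arms."""
    df = cohort.frame
    table = pd.crosstab(df["arm"], df[column])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise DataError(f"chi-square needs a 2x2+ table, got {table.shape}")
    stat, p, dof, _ = spstats.chi2_contingency(table.to_numpy(), correction=False)
    return {"statistic": float(stat), "p": float(p), "dof": int(dof)}


# ---------------------------------------------------------------------------
# intra-session reliability


@dataclass(frozen=True)
class ReliabilityResult:
    feature_name: str
    icc: float
    ci_low: float
    ci_high: float
    band: str
    n_subjects: int
    n_trials: int
    n_dropped: int = 0


def icc_band(icc: float) -> str:
    """Reliability band with strict 'greater than' at 0.75 and 0.9; 0.5 is moderate."""
    if icc > ICC_BANDS[2]:
        return "excellent"
    if icc > ICC_BANDS[1]:
        return "good"
    if icc >= ICC_BANDS[0]:
        return "moderate"
    return "poor"


def icc_2k(matrix, feature_name: str = "", n_dropped: int = 0,
           confidence: float = 0.95) -> ReliabilityResult:
    """ICC(2,k): two-way random effects, absolute agreement, average of k trials.

    ``matrix`` is subjects × trials with no missing cells.  The estimate is
    formed from the two-way ANOVA mean squares (rows = subjects,
    columns = trials):

        ICC(2,k) = (MS_R - MS_E) / (MS_R + (MS_C - MS_E) / n)

    with the confidence interval by the F-distribution method of the
    single-measure absolute-agreement ICC followed by the Spearman-Brown
    step up to k measurements.  A degenerate matrix (no between-subject
    variance) yields icc <= 0 and band "poor".
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 3 or M.shape[1] < 2:
        raise DataError(f"ICC needs >= 3 subjects x >= 2 trials, got {M.shape}")
    if not np.all(np.isfinite(M)):
        raise DataError("ICC matrix has missing cells; drop incomplete subjects first")
    n, k = M.shape
    gm = M.mean()
    row_means = M.mean(axis=1)
    col_means = M.mean(axis=0)
    msr = k * np.sum((row_means - gm) ** 2) / (n - 1)
    msc = n * np.sum((col_means - gm) ** 2) / (k - 1)
    mse = np.sum((M - row_means[:, None] - col_means[None, :] + gm) ** 2) / (
        (n - 1) * (k - 1)
    )

    denom = msr + (msc - mse) / n
    if denom <= 0 or not np.isfinite(denom):
        icc = 0.0 if msr <= mse else np.nan
        return ReliabilityResult(feature_name, float(icc), np.nan, np.nan, "poor",
                                 n, k, n_dropped)
    icc_k = float((msr - mse) / denom)

    # F-method CI for the single-measure absolute-agreement ICC, then
    # Spearman-Brown to average measures.
    icc_1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    alpha = 1.0 - confidence
    if mse <= 0:
        lo_k, hi_k = icc_k, icc_k  # perfect agreement: interval collapses
    else:
        fj = msc / mse
        num = (k - 1) * (n - 1) * (
            k * icc_1 * fj + n * (1 + (k - 1) * icc_1) - k * icc_1
        ) ** 2
        den = (n - 1) * k**2 * icc_1**2 * fj**2 + (
            n * (1 + (k - 1) * icc_1) - k * icc_1
        ) ** 2
        v = num / den
        f_u = spstats.f.ppf(1 - alpha / 2, n - 1, v)
        f_l = spstats.f.ppf(1 - alpha / 2, v, n - 1)
        lo_1 = n * (msr - f_u * mse) / (
            f_u * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi_1 = n * (f_l * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_l * msr
        )
        lo_k = lo_1 * k / (1 + (k - 1) * lo_1)
        hi_k = hi_1 * k / (1 + (k - 1) * hi_1)
    lo_k = min(lo_k, icc_k)
    hi_k = max(hi_k, icc_k)
    return ReliabilityResult(
        feature_name, icc_k, float(lo_k), float(hi_k), icc_band(icc_k), n, k, n_dropped
    )


def reliability_table(features: pd.DataFrame, n_trials: int) -> pd.DataFrame:
    """ICC(2,k) for every feature column over subjects with complete trials.

    ``features`` has one row per trial with ``subject_id`` and ``trial_id``
    columns.  Subjects with fewer than ``n_trials`` trials are dropped and
    counted in ``n_dropped``.
    """
    for col in ("subject_id", "trial_id"):
        if col not in features.columns:
            raise DataError(f"features frame needs a {col} column")
    counts = features.groupby("subject_id").size()
    complete = counts[counts >= n_trials].index
    n_dropped = int((~counts.index.isin(complete)).sum())
    sub = features[features["subject_id"].isin(complete)]
    sub = sub.sort_values(["subject_id", "trial_id"]).groupby("subject_id").head(n_trials)
    sub = sub.assign(__rank=sub.groupby("subject_id").cumcount())
    feature_cols = [
        c for c in features.columns
        if c not in ("subject_id", "trial_id") and pd.api.types.is_numeric_dtype(features[c])
    ]
    rows = []
    for feat in feature_cols:
        M = sub.pivot(index="subject_id", columns="__rank", values=feat).to_numpy()
        try:
            r = icc_2k(M, feature_name=feat, n_dropped=n_dropped)
            rows.append({
                "feature": feat, "icc": r.icc, "ci_low": r.ci_low,
                "ci_high": r.ci_high, "band": r.band,
                "n_subjects": r.n_subjects, "n_trials": r.n_trials,
                "n_dropped": r.n_dropped,
            })
        except DegenerateInputError:
            rows.append({
                "feature": feat, "icc": np.nan, "ci_low": np.nan,
                "ci_high": np.nan, "band": "poor",
                "n_subjects": len(complete), "n_trials": n_trials,
                "n_dropped": n_dropped,
            })
    return pd.DataFrame(rows)
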