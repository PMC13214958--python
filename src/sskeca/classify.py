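"""Subject-level cross-validated classification with majority voting.

Diagnosis is a subject-level question, but each subject contributes many
trial-level samples.  The protocol here is:

* subjects (not samples) are partitioned into k stratified folds, each
  preserving the cohort's SZ:HC ratio, after a seeded permutation
  (40 SZ + 50 HC at k=5 gives exactly 8 SZ + 10 HC per test fold);
* per fold, the feature transform is FIT on training-fold rows only and
  APPLIED to test rows (no test statistic ever enters the scaler,
  bandwidth, or eigensystem), then a classifier is fit on the
  transformed training rows;
* each test subject's sample-level predictions are aggregated by
  majority vote: the subject is called SZ iff the fraction of
  SZ-labelled samples STRICTLY exceeds the vote threshold (default 50%;
  an exact tie is HC);
* subject-level accuracy, precision, recall, F1 (SZ positive) and AUC
  (scored by the vote fraction) are reported as mean +- SD across folds
  with 95% BCa bootstrap confidence intervals over pooled subject-level
  outcomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .features import FEATURE_NAMES
from .transform import make_transform
from .utils import spawn_seed

__all__ = [
    "FoldPlan",
    "PipelineSpec",
    "CVResult",
    "MetricSummary",
    "stratified_subject_folds",
    "run_cv",
    "vote_subject",
    "subject_metrics",
    "bca_ci",
    "available_classifiers",
]

METRIC_NAMES = ["accuracy", "precision", "recall", "f1", "auc"]


# ---------------------------------------------------------------------------
# fold plan


@dataclass(frozen=True)
class FoldPlan:
    """A subject-level partition into k stratified test folds."""

    folds: tuple[tuple[str, ...], ...]
    labels: dict[str, str]  # subject -> SZ|HC
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def fold_counts(self) -> list[dict[str, int]]:
        return [
            {g: sum(self.labels[s] == g for s in fold) for g in ("SZ", "HC")}
            for fold in self.folds
        ]

    def subjects(self) -> set[str]:
        return {s for fold in self.folds for s in fold}

    def validate(self) -> None:
        flat = [s for fold in self.folds for s in fold]
        if len(flat) != len(set(flat)):
            raise ValueError("fold plan is not disjoint")
        if set(flat) != set(self.labels):
            raise ValueError("fold plan does not cover all subjects")


def stratified_subject_folds(
    subject_ids, labels, k: int = 5, seed: int = 0
) -> FoldPlan:
    """Partition subjects into k folds preserving per-class proportions.

    Deterministic given ``seed``; per-fold class counts differ by at most
    one from exact proportionality (round-robin deal after a seeded
    shuffle within each class).
    """
    subject_ids = [str(s) for s in subject_ids]
    labels = [str(g) for g in labels]
    if len(subject_ids) != len(labels):
        raise ValueError("subject_ids and labels must align")
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("duplicate subject ids")
    if k < 2:
        raise ValueError("k >= 2 folds required")
    by_class: dict[str, list[str]] = {}
    for s, g in zip(subject_ids, labels):
        by_class.setdefault(g, []).append(s)
    for g, members in by_class.items():
        if len(members) < k:
            raise ValueError(f"class {g!r} has {len(members)} subjects < k={k}")
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    for g in sorted(by_class):
        members = list(by_class[g])
        rng.shuffle(members)
        for i, s in enumerate(members):
            folds[i % k].append(s)
    plan = FoldPlan(
        folds=tuple(tuple(f) for f in folds),
        labels=dict(zip(subject_ids, labels)),
        seed=seed,
    )
    plan.validate()
    return plan


# ---------------------------------------------------------------------------
# pipeline spec and classifier registry


def _default_transform() -> dict:
    return {"method": "SSKECA", "ncomp": 21, "w": 1.0, "beta": 0.01}


@dataclass
class PipelineSpec:
    """Transform + classifier + voting configuration for one CV run."""

    transform: dict = field(default_factory=_default_transform)
    classifier: str = "AdaBoost"
    classifier_params: dict = field(default_factory=dict)
    vote_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.vote_threshold < 1:
            raise ValueError("vote threshold must be in (0, 1)")


def available_classifiers() -> list[str]:
    return ["AdaBoost", "RF", "KNN", "SVM", "MLP", "XGBoost", "LightGBM"]


def make_classifier(name: str, params: dict | None = None, seed: int = 0):
    """Build a seeded classifier by registry name (library defaults otherwise)."""
    params = dict(params or {})
    if name == "AdaBoost":
        return AdaBoostClassifier(random_state=seed, **params)
    if name == "RF":
        return RandomForestClassifier(random_state=seed, **params)
    if name == "KNN":
        return KNeighborsClassifier(**params)
    if name == "SVM":
        params.setdefault("probability", True)
        return SVC(random_state=seed, **params)
    if name == "MLP":
        params.setdefault("max_iter", 1000)
        return MLPClassifier(random_state=seed, **params)
    if name == "XGBoost":
        from xgboost import XGBClassifier

        params.setdefault("eval_metric", "logloss")
        params.setdefault("n_jobs", 1)
        return XGBClassifier(random_state=seed, **params)
    if name == "LightGBM":
        from lightgbm import LGBMClassifier

        params.setdefault("verbose", -1)
        params.setdefault("n_jobs", 1)
        return LGBMClassifier(random_state=seed, **params)
    raise ValueError(
        f"unknown classifier {name!r}; available: {', '.join(available_classifiers())}"
    )


# ---------------------------------------------------------------------------
# voting and metrics


def vote_subject(sample_labels, threshold: float = 0.5) -> str:
    """Majority-vote one subject's sample labels into a diagnosis.

    ``sample_labels`` may be 'SZ'/'HC' strings or 0/1 integers (1 = SZ).
    The subject is SZ iff the SZ fraction STRICTLY exceeds ``threshold``.
    """
    labels = list(sample_labels)
    if not labels:
        raise ValueError("cannot vote on an empty sample set")
    frac = np.mean([1 if (l == "SZ" or l == 1) else 0 for l in labels])
    return "SZ" if frac > threshold else "HC"


def _rank_auc(truth: np.ndarray, score: np.ndarray) -> float:
    """ROC AUC via the Mann-Whitney rank statistic (tie-aware)."""
    n1 = int(truth.sum())
    n0 = truth.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: one-class truth")
    ranks = rankdata(score)
    return float((ranks[truth == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


def _metric_values(truth: np.ndarray, pred: np.ndarray, score: np.ndarray) -> dict[str, float]:
    tp = int(((pred == 1) & (truth == 1)).sum())
    fp = int(((pred == 1) & (truth == 0)).sum())
    fn = int(((pred == 0) & (truth == 1)).sum())
    acc = float((pred == truth).mean())
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    auc = _rank_auc(truth, score)
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1, "auc": auc}


@dataclass(frozen=True)
class MetricSummary:
    mean: float
    sd: float
    ci_lo: float
    ci_hi: float


def bca_ci(
    values: np.ndarray,
    stat=np.mean,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap confidence interval.

    ``values`` is an array whose FIRST axis indexes observations (rows may
    be vectors, e.g. (truth, prediction) pairs); ``stat`` maps a resampled
    array to a scalar.  Acceleration comes from the jackknife; a
    zero-variance jackknife falls back to the percentile interval with a
    warning.  Deterministic given ``seed``.
    """
    values = np.asarray(values)
    n = values.shape[0]
    if n < 2:
        raise ValueError("bca_ci requires n >= 2")
    if B < 100:
        raise ValueError("bca_ci requires B >= 100")
    theta_hat = float(stat(values))
    rng = np.random.default_rng(seed)
    thetas = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        thetas[b] = stat(values[idx])
    # a stat can be undefined on rare degenerate resamples (e.g. one-class
    # AUC); those replicates are dropped from the bootstrap distribution
    thetas = thetas[np.isfinite(thetas)]
    if thetas.size < 2 or not np.isfinite(theta_hat):
        return float("nan"), float("nan")
    B = thetas.size
    if np.ptp(thetas) == 0:
        return float(thetas[0]), float(thetas[0])
    jack = np.array([stat(np.delete(values, i, axis=0)) for i in range(n)])
    d = jack.mean() - jack
    denom = (d**2).sum() ** 1.5
    prop = np.clip(np.mean(thetas < theta_hat), 1.0 / (B + 1), B / (B + 1.0))
    z0 = norm.ppf(prop)
    if denom == 0:
        warnings.warn("zero-variance jackknife; falling back to percentile interval")
        lo, hi = np.quantile(thetas, [alpha / 2, 1 - alpha / 2])
        return float(lo), float(hi)
    a = (d**3).sum() / (6.0 * denom)
    z_lo, z_hi = norm.ppf(alpha / 2), norm.ppf(1 - alpha / 2)
    a1 = norm.cdf(z0 + (z0 + z_lo) / (1 - a * (z0 + z_lo)))
    a2 = norm.cdf(z0 + (z0 + z_hi) / (1 - a * (z0 + z_hi)))
    lo, hi = np.quantile(thetas, [a1, a2])
    return float(lo), float(hi)


def subject_metrics(
    subject_df: pd.DataFrame, B: int = 1000, seed: int = 0
) -> dict[str, MetricSummary]:
    """Pooled subject-level metrics with fold mean +- SD and 95% BCa CIs.

    ``subject_df`` needs columns ``y_true`` (0/1, 1 = SZ), ``y_voted``,
    ``vote_fraction`` and ``fold``.
    """
    truth = subject_df["y_true"].to_numpy(int)
    pred = subject_df["y_voted"].to_numpy(int)
    score = subject_df["vote_fraction"].to_numpy(float)
    per_fold = []
    for _, grp in subject_df.groupby("fold"):
        try:
            per_fold.append(
                _metric_values(
                    grp["y_true"].to_numpy(int),
                    grp["y_voted"].to_numpy(int),
                    grp["vote_fraction"].to_numpy(float),
                )
            )
        except ValueError:
            per_fold.append({m: np.nan for m in METRIC_NAMES})
    fold_df = pd.DataFrame(per_fold)
    data = np.column_stack([truth, pred, score])

    def stat_for(metric):
        def _stat(rows):
            t, p, s = rows[:, 0].astype(int), rows[:, 1].astype(int), rows[:, 2]
            try:
                return _metric_values(t, p, s)[metric]
            except ValueError:
                return np.nan
        return _stat

    out = {}
    for i, metric in enumerate(METRIC_NAMES):
        lo, hi = bca_ci(data, stat=stat_for(metric), B=B, seed=spawn_seed(seed, f"bca/{metric}"))
        out[metric] = MetricSummary(
            mean=float(fold_df[metric].mean()),
            sd=float(fold_df[metric].std(ddof=1)),
            ci_lo=lo,
            ci_hi=hi,
        )
    return out


# ---------------------------------------------------------------------------
# the cross-validation loop


@dataclass
class CVResult:
    """Everything one CV run produced, sample level up to subject level."""

    spec: PipelineSpec
    plan: FoldPlan
    sample_predictions: pd.DataFrame  # per test sample: fold, y_true, y_pred, score
    subject_votes: pd.DataFrame  # per subject: vote_fraction, y_voted, y_true, fold
    fold_metrics: pd.DataFrame  # subject-level metrics per fold
    metrics: dict[str, MetricSummary]
    fold_models: list = field(default_factory=list)  # fitted transform per fold

    @property
    def sample_accuracy(self) -> float:
        df = self.sample_predictions
        return float((df["y_pred"] == df["y_true"]).mean())

    @property
    def subject_accuracy(self) -> float:
        df = self.subject_votes
        return float((df["y_voted"] == df["y_true"]).mean())


def _grid_select_ncomp(Xtr, ytr, subj_tr, spec: PipelineSpec, grid, seed: int) -> int:
    """Pick ncomp by inner subject-level CV accuracy on the training fold."""
    uniq = pd.DataFrame({"s": subj_tr, "y": ytr}).drop_duplicates("s")
    inner = stratified_subject_folds(
        uniq["s"], np.where(uniq["y"] == 1, "SZ", "HC"), k=3, seed=seed
    )
    best_ncomp, best_acc = None, -np.inf
    for ncomp in grid:
        correct = total = 0
        for fold in inner.folds:
            te = np.isin(subj_tr, fold)
            tcfg = dict(spec.transform)
            tcfg["ncomp"] = int(ncomp)
            try:
                tr_model = make_transform(**tcfg)
                Zi = tr_model.fit_transform(Xtr[~te], ytr[~te])
                Zo = tr_model.transform(Xtr[te])
            except ValueError:
                break  # ncomp exceeds retained components on this fold
            clf = make_classifier(spec.classifier, spec.classifier_params, seed)
            clf.fit(Zi, ytr[~te])
            pred = clf.predict(Zo)
            for s in fold:
                m = subj_tr[te] == s
                if m.any():
                    voted = 1 if pred[m].mean() > spec.vote_threshold else 0
                    correct += int(voted == ytr[te][m][0])
                    total += 1
        if total and correct / total > best_acc:
            best_acc, best_ncomp = correct / total, int(ncomp)
    if best_ncomp is None:
        raise ValueError("ncomp grid search found no feasible value")
    return best_ncomp


def run_cv(
    table: pd.DataFrame,
    spec: PipelineSpec,
    plan: FoldPlan,
    features: list[str] | None = None,
    ci: bool = True,
) -> CVResult:
    """Leak-free subject-grouped cross-validation over a feature table.

    Per fold the transform is fitted on training rows only; all of a
    subject's samples share that subject's fold assignment.  ``features``
    restricts the columns used (default: the canonical 24).  ``ci=False``
    skips the BCa bootstrap (point metrics only), useful in bulk runs
    such as ablation loops or seed sweeps.
    """
    plan.validate()
    if plan.k < 2:
        raise ValueError("k >= 2 folds required")
    features = list(features or FEATURE_NAMES)
    missing = set(table["subject_id"].astype(str)) - plan.subjects()
    if missing:
        raise ValueError(f"table subjects not in fold plan: {sorted(missing)[:5]}")
    X = table[features].to_numpy(float)
    y = (table["group"] == "SZ").to_numpy(int)
    subjects = table["subject_id"].astype(str).to_numpy()

    sample_rows = []
    fold_models = []
    for i, fold in enumerate(plan.folds):
        test_mask = np.isin(subjects, fold)
        if not test_mask.any():
            continue
        Xtr, ytr = X[~test_mask], y[~test_mask]
        tcfg = dict(spec.transform)
        if tcfg.get("ncomp") == "grid":
            grid = range(1, min(len(Xtr) - 1, len(features)) + 1)
            tcfg["ncomp"] = _grid_select_ncomp(
                Xtr, ytr, subjects[~test_mask], spec, grid, spawn_seed(spec.seed, f"grid/{i}")
            )
        tr_model = make_transform(**tcfg)
        Ztr = tr_model.fit_transform(Xtr, ytr)
        Zte = tr_model.transform(X[test_mask])
        fold_models.append(tr_model)
        clf = make_classifier(
            spec.classifier, spec.classifier_params, seed=spawn_seed(spec.seed, f"clf/{i}")
        )
        clf.fit(Ztr, ytr)
        pred = clf.predict(Zte)
        if hasattr(clf, "predict_proba"):
            score = clf.predict_proba(Zte)[:, 1]
        elif hasattr(clf, "decision_function"):
            score = clf.decision_function(Zte)
        else:
            score = pred.astype(float)
        meta = table.loc[test_mask, ["subject_id", "trial_id", "image_id", "category_id"]]
        block = meta.copy()
        block["fold"] = i
        block["y_true"] = y[test_mask]
        block["y_pred"] = pred
        block["score"] = score
        sample_rows.append(block)
    sample_df = pd.concat(sample_rows, ignore_index=True)

    votes = []
    for subject, grp in sample_df.groupby("subject_id"):
        frac = float(grp["y_pred"].mean())
        votes.append(
            {
                "subject_id": subject,
                "fold": int(grp["fold"].iloc[0]),
                "y_true": int(grp["y_true"].iloc[0]),
                "vote_fraction": frac,
                "y_voted": 1 if frac > spec.vote_threshold else 0,
                "n_samples": len(grp),
            }
        )
    subject_df = pd.DataFrame(votes)

    if ci:
        metrics = subject_metrics(subject_df, seed=spawn_seed(spec.seed, "metrics"))
    else:
        fold_vals = []
        for _, grp in subject_df.groupby("fold"):
            try:
                fold_vals.append(
                    _metric_values(
                        grp["y_true"].to_numpy(int),
                        grp["y_voted"].to_numpy(int),
                        grp["vote_fraction"].to_numpy(float),
                    )
                )
            except ValueError:
                fold_vals.append({m: np.nan for m in METRIC_NAMES})
        fv = pd.DataFrame(fold_vals)
        metrics = {
            m: MetricSummary(
                mean=float(fv[m].mean()),
                sd=float(fv[m].std(ddof=1)),
                ci_lo=float("nan"),
                ci_hi=float("nan"),
            )
            for m in METRIC_NAMES
        }
    per_fold = []
    for fold_id, grp in subject_df.groupby("fold"):
        try:
            vals = _metric_values(
                grp["y_true"].to_numpy(int),
                grp["y_voted"].to_numpy(int),
                grp["vote_fraction"].to_numpy(float),
            )
        except ValueError:
            vals = {m: np.nan for m in METRIC_NAMES}
        per_fold.append({"fold": fold_id, **vals})
    return CVResult(
        spec=spec,
        plan=plan,
        sample_predictions=sample_df,
        subject_votes=subject_df,
        fold_metrics=pd.DataFrame(per_fold),
        metrics=metrics,
        fold_models=fold_models,
    )
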