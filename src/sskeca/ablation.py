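"""Dual-level feature-ablation importance.

The importance of a feature is the drop in classification accuracy
(delta-ACC) when the full pipeline - transform fitted on the remaining
features, classifier retrained - is re-run without it, relative to the
full-feature baseline.  Both runs share the same fold plan and seeds, so
the difference isolates the feature rather than fold noise.  The drop is
measured at two levels: sample-level (per-trial predictions) and
subject-level (majority-voted diagnoses).  Total importance is their sum;
a feature is retained as a candidate biomarker iff its total importance
is strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .classify import CVResult, FoldPlan, PipelineSpec, run_cv
from .features import FEATURE_NAMES

__all__ = [
    "AblationReport",
    "dual_ablation",
    "sample_level_importance",
    "subject_level_importance",
    "importance_report",
]


@dataclass
class AblationReport:
    table: pd.DataFrame  # feature, sample_dacc, subject_dacc, total, retained
    baseline_sample_accuracy: float
    baseline_subject_accuracy: float
    pearson_r: float

    @property
    def retained_features(self) -> list[str]:
        return self.table.loc[self.table["retained"], "feature"].tolist()


def dual_ablation(
    table: pd.DataFrame,
    spec: PipelineSpec,
    plan: FoldPlan,
    features: list[str] | None = None,
    mask: str = "drop",
    baseline: CVResult | None = None,
) -> tuple[pd.Series, pd.Series, CVResult]:
    """Per-feature (sample delta-ACC, subject delta-ACC) plus the baseline run.

    ``mask='drop'`` removes the feature column globally (default);
    ``mask='impute'`` instead replaces it with the training-fold mean,
    simulating per-subject missing data while keeping dimensionality.
    """
    features = list(features or [c for c in FEATURE_NAMES if c in table.columns])
    if len(features) < 2:
        raise ValueError("ablation requires at least 2 features")
    if mask not in ("drop", "impute"):
        raise ValueError("mask must be 'drop' or 'impute'")
    if baseline is None:
        baseline = run_cv(table, spec, plan, features=features, ci=False)
    sample_dacc, subject_dacc = {}, {}
    for feat in features:
        if mask == "drop":
            kept = [f for f in features if f != feat]
            ablated = run_cv(table, spec, plan, features=kept, ci=False)
        else:
            masked = table.copy()
            masked[feat] = masked[feat].mean()
            ablated = run_cv(masked, spec, plan, features=features, ci=False)
        sample_dacc[feat] = baseline.sample_accuracy - ablated.sample_accuracy
        subject_dacc[feat] = baseline.subject_accuracy - ablated.subject_accuracy
    return (
        pd.Series(sample_dacc, name="sample_dacc"),
        pd.Series(subject_dacc, name="subject_dacc"),
        baseline,
    )


def sample_level_importance(
    table: pd.DataFrame, spec: PipelineSpec, plan: FoldPlan, **kw
) -> pd.Series:
    """Sample-level delta-ACC per feature (shared plan/seed with baseline)."""
    sample, _, _ = dual_ablation(table, spec, plan, **kw)
    return sample


def subject_level_importance(
    table: pd.DataFrame, spec: PipelineSpec, plan: FoldPlan, **kw
) -> pd.Series:
    """Subject-level (voted) delta-ACC per feature."""
    _, subject, _ = dual_ablation(table, spec, plan, **kw)
    return subject


def importance_report(
    sample_dacc: pd.Series,
    subject_dacc: pd.Series,
    baseline_sample_accuracy: float = float("nan"),
    baseline_subject_accuracy: float = float("nan"),
) -> AblationReport:
    """Combine the two importance vectors into a ranked report.

    Total importance = sample + subject delta-ACC; retained iff total is
    STRICTLY positive.  Pearson r relates the two vectors across all
    features.  Ordered by total descending, alphabetical tie-break.
    """
    if not sample_dacc.index.equals(subject_dacc.index):
        if set(sample_dacc.index) != set(subject_dacc.index):
            raise ValueError("importance vectors must share feature names")
        subject_dacc = subject_dacc.reindex(sample_dacc.index)
    total = sample_dacc + subject_dacc
    df = pd.DataFrame(
        {
            "feature": sample_dacc.index,
            "sample_dacc": sample_dacc.to_numpy(float),
            "subject_dacc": subject_dacc.to_numpy(float),
            "total": total.to_numpy(float),
        }
    )
    df["retained"] = df["total"] > 0
    df = df.sort_values(["total", "feature"], ascending=[False, True]).reset_index(drop=True)
    if len(df) >= 2 and df["sample_dacc"].std() > 0 and df["subject_dacc"].std() > 0:
        r = float(pearsonr(df["sample_dacc"], df["subject_dacc"])[0])
    else:
        r = float("nan")
    return AblationReport(
        table=df,
        baseline_sample_accuracy=baseline_sample_accuracy,
        baseline_subject_accuracy=baseline_subject_accuracy,
        pearson_r=r,
    )
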