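"""Top-level modelling interface: build from a feature table, fit, inspect.

:class:`EyeMovementClassifier` bundles a feature table with a pipeline
specification (transform + classifier + voting) and a subject-level fold
plan; :meth:`~EyeMovementClassifier.fit` runs the cross-validated
pipeline and returns an :class:`EyeMovementResults` carrying per-sample
predictions, per-subject votes, fold metrics with BCa confidence
intervals, and a printable summary.  Ablation importance, semantic
stimulus analysis and plotting hang off the results object.

Example
-------
>>> from sskeca import synth, model
>>> table = synth.generate_feature_table(synth.default_profile(), seed=7)
>>> res = model.EyeMovementClassifier(table, seed=7).fit()
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

import pandas as pd

from .ablation import AblationReport, dual_ablation, importance_report
from .classify import (
    CVResult,
    FoldPlan,
    MetricSummary,
    PipelineSpec,
    run_cv,
    stratified_subject_folds,
)
from .features import FEATURE_NAMES, build_feature_table
from .semantic import SemanticReport, category_accuracy, evaluate_reduced
from .utils import spawn_seed

__all__ = ["EyeMovementClassifier", "EyeMovementResults"]


class EyeMovementClassifier:
    """Subject-level SZ-vs-HC classifier over a hybrid feature table.

    Parameters
    ----------
    table : pandas.DataFrame
        Feature table with the metadata columns ``subject_id, group,
        trial_id, image_id, category_id`` and the 24 canonical features.
    spec : PipelineSpec, optional
        Transform/classifier/voting configuration (default:
        SSKECA with 21 components + AdaBoost, 50% vote threshold).
    k : int
        Number of stratified subject folds.
    seed : int
        Run seed; fold shuffling, classifier seeds and bootstrap seeds
        are all derived from it deterministically.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        spec: PipelineSpec | None = None,
        k: int = 5,
        seed: int = 0,
    ):
        missing = [c for c in FEATURE_NAMES if c not in table.columns]
        if missing:
            raise ValueError(f"feature table missing column(s): {missing[:5]}")
        self.table = table
        self.seed = seed
        self.k = k
        self.spec = spec or PipelineSpec(seed=spawn_seed(seed, "pipeline"))
        subjects = table.drop_duplicates("subject_id")
        self.plan: FoldPlan = stratified_subject_folds(
            subjects["subject_id"], subjects["group"], k=k, seed=spawn_seed(seed, "folds")
        )

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kw) -> "EyeMovementClassifier":
        return cls(table, **kw)

    @classmethod
    def from_trials(cls, trials, config=None, **kw) -> "EyeMovementClassifier":
        """Build from event-level trial records (features extracted here)."""
        return cls(build_feature_table(trials, config), **kw)

    def fit(self) -> "EyeMovementResults":
        cv = run_cv(self.table, self.spec, self.plan)
        return EyeMovementResults(self, cv)


class EyeMovementResults:
    """Fitted cross-validation results with diagnostics and follow-up analyses."""

    def __init__(self, model: EyeMovementClassifier, cv: CVResult):
        self.model = model
        self.cv = cv

    @property
    def metrics(self) -> dict[str, MetricSummary]:
        return self.cv.metrics

    @property
    def subject_predictions(self) -> pd.DataFrame:
        return self.cv.subject_votes

    @property
    def subject_accuracy(self) -> float:
        return self.cv.subject_accuracy

    @property
    def sample_accuracy(self) -> float:
        return self.cv.sample_accuracy

    def summary(self) -> str:
        """Plain-text report: configuration, per-fold and pooled metrics."""
        from .report import format_metric_cell

        spec = self.cv.spec
        lines = [
            "Subject-level eye-movement classification",
            "=" * 57,
            f"transform: {spec.transform.get('method', 'SSKECA')}"
            f"  ncomp={spec.transform.get('ncomp')}  beta={spec.transform.get('beta')}",
            f"classifier: {spec.classifier}   folds: {self.cv.plan.k}"
            f"   vote threshold: {spec.vote_threshold:g}",
            f"subjects: {len(self.cv.subject_votes)}"
            f"   samples: {len(self.cv.sample_predictions)}",
            "-" * 57,
            f"{'metric':<12}{'mean ± SD (95% BCa CI)':<34}",
        ]
        for name, m in self.metrics.items():
            lines.append(f"{name:<12}{format_metric_cell(m.mean, m.sd, m.ci_lo, m.ci_hi):<34}")
        lines.append("-" * 57)
        lines.append(f"sample-level accuracy: {self.sample_accuracy:.3f}")
        return "\n".join(lines)

    def ablation(self, features=None, mask: str = "drop") -> AblationReport:
        """Dual-level delta-ACC feature importance under the same fold plan."""
        sample, subject, baseline = dual_ablation(
            self.model.table, self.cv.spec, self.cv.plan, features=features, mask=mask,
            baseline=self.cv,
        )
        return importance_report(
            sample, subject, baseline.sample_accuracy, baseline.subject_accuracy
        )

    def semantic(self, threshold: float = 0.85) -> SemanticReport:
        """Per-category / per-image accuracy and threshold selection."""
        return category_accuracy(self.cv, threshold=threshold)

    def evaluate_reduced(self, image_ids) -> CVResult:
        """Re-run the CV restricted to the given stimulus images."""
        return evaluate_reduced(self.model.table, image_ids, self.cv.spec, self.cv.plan)

    def plot_vote_fractions(self, ax=None):
        """Bar plot of per-subject SZ vote fractions, coloured by true group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        df = self.cv.subject_votes.sort_values(["y_true", "vote_fraction"]).reset_index()
        colors = df["y_true"].map({1: "tab:red", 0: "tab:blue"})
        ax.bar(range(len(df)), df["vote_fraction"], color=colors)
        ax.axhline(self.cv.spec.vote_threshold, color="k", ls="--", lw=1)
        ax.set_ylabel("SZ vote fraction")
        ax.set_xlabel("subject (sorted)")
        return ax
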