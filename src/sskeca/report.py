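"""Pipeline orchestration, configuration, and report rendering.

A :class:`RunConfig` (loadable from YAML) describes one end-to-end run:
where the data come from (an event CSV, a feature CSV, or the synthetic
generator), the pipeline specification, fold/seed settings, and optional
ablation / semantic stages.  :func:`run_pipeline` executes
extract -> transform+CV -> (ablate / semantic) and returns a
:class:`RunReport` whose embedded config snapshot suffices to reproduce
the run bit-for-bit given the same inputs.  A single run seed fans out
to per-stage child seeds (see :func:`sskeca.utils.spawn_seed`), so
toggling an optional stage never shifts another stage's randomness.

Metric tables are rendered in the house style ``mean ± SD (lo–hi)``;
values are stored at full precision and rounded only at display time
(3 decimal places).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from .classify import MetricSummary, PipelineSpec, stratified_subject_folds, run_cv
from .events import CleaningConfig, read_trials
from .features import FEATURE_NAMES, METADATA_COLUMNS, build_feature_table
from .utils import spawn_seed

__all__ = [
    "RunConfig",
    "RunReport",
    "run_pipeline",
    "render_metric_table",
    "format_metric_cell",
]

_LAYOUTS = {
    "transform-comparison": ["Algorithm", "Classifier", "Dim"],
    "classifier-robustness": ["Classifier", "Dim"],
    "reduced-set": ["Classifier", "Dim"],
}


def format_metric_cell(mean: float, sd: float, lo: float, hi: float, dp: int = 3) -> str:
    """``0.933 ± 0.061 (0.871–0.967)`` - display rounding only."""
    return f"{mean:.{dp}f} ± {sd:.{dp}f} ({lo:.{dp}f}–{hi:.{dp}f})"


def render_metric_table(rows: list[dict], layout: str) -> pd.DataFrame:
    """Render result rows into one of the standard table layouts.

    Each row dict carries the layout's label columns plus a ``metrics``
    mapping of metric name -> :class:`MetricSummary`.
    """
    if layout not in _LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; choose from {sorted(_LAYOUTS)}")
    if not rows:
        raise ValueError("no results to render")
    labels = _LAYOUTS[layout]
    out = []
    for row in rows:
        rec = {col: row.get(col, "") for col in labels}
        for name, m in row["metrics"].items():
            rec[name] = format_metric_cell(m.mean, m.sd, m.ci_lo, m.ci_hi)
        out.append(rec)
    return pd.DataFrame(out)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; see module docstring."""

    seed: int | None = None
    events_path: str | None = None
    features_path: str | None = None
    simulate: dict | None = None  # SyntheticProfile overrides, or {} for defaults
    folds: int = 5
    cleaning: dict = field(default_factory=dict)
    transform: dict = field(default_factory=dict)
    classifier: str = "AdaBoost"
    classifier_params: dict = field(default_factory=dict)
    vote_threshold: float = 0.5
    ablation: bool = False
    semantic: bool = False
    semantic_threshold: float = 0.85
    out: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def validate(self) -> None:
        sources = [self.events_path, self.features_path, self.simulate]
        if sum(s is not None for s in sources) != 1:
            raise ValueError("exactly one of events_path / features_path / simulate required")
        if self.seed is None:
            raise ValueError("seed is mandatory (stochastic stages enabled)")


@dataclass
class RunReport:
    config: dict
    versions: dict
    timings: dict
    metrics: dict  # metric -> {mean, sd, ci_lo, ci_hi}
    subject_votes: list[dict]
    ablation: list[dict] | None = None
    semantic: dict | None = None
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=float)


def _versions() -> dict:
    import numpy, pandas, scipy, sklearn

    from . import __version__

    return {
        "sskeca": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "sklearn": sklearn.__version__,
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full pipeline described by ``config``."""
    from . import synth
    from .ablation import dual_ablation, importance_report
    from .semantic import category_accuracy

    config.validate()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    if config.simulate is not None:
        profile = synth.SyntheticProfile(**config.simulate)
        table = synth.generate_feature_table(profile, seed=spawn_seed(config.seed, "simulate"))
    elif config.events_path is not None:
        trials = read_trials(config.events_path)
        table = build_feature_table(trials, CleaningConfig(**config.cleaning))
    else:
        table = pd.read_csv(config.features_path, dtype={"subject_id": str})
        missing = [c for c in METADATA_COLUMNS + FEATURE_NAMES if c not in table.columns]
        if missing:
            raise ValueError(f"feature CSV missing column(s): {missing[:5]}")
    timings["extract"] = time.perf_counter() - t0

    spec = PipelineSpec(
        transform={"method": "SSKECA", "ncomp": 21, "w": 1.0, "beta": 0.01, **config.transform},
        classifier=config.classifier,
        classifier_params=config.classifier_params,
        vote_threshold=config.vote_threshold,
        seed=spawn_seed(config.seed, "pipeline"),
    )
    subjects = table.drop_duplicates("subject_id")
    plan = stratified_subject_folds(
        subjects["subject_id"], subjects["group"], k=config.folds,
        seed=spawn_seed(config.seed, "folds"),
    )
    t0 = time.perf_counter()
    cv = run_cv(table, spec, plan)
    timings["cv"] = time.perf_counter() - t0

    ablation_rows = None
    if config.ablation:
        t0 = time.perf_counter()
        sample, subject, baseline = dual_ablation(table, spec, plan, baseline=cv)
        rep = importance_report(sample, subject, baseline.sample_accuracy, baseline.subject_accuracy)
        ablation_rows = rep.table.to_dict("records")
        timings["ablation"] = time.perf_counter() - t0
    semantic_payload = None
    if config.semantic:
        t0 = time.perf_counter()
        rep = category_accuracy(cv, threshold=config.semantic_threshold)
        semantic_payload = {
            "threshold": rep.threshold,
            "selected_images": rep.selected_images,
            "category_accuracy": rep.category_table.to_dict("records"),
        }
        timings["semantic"] = time.perf_counter() - t0

    report = RunReport(
        config=asdict(config),
        versions=_versions(),
        timings=timings,
        metrics={
            name: {"mean": m.mean, "sd": m.sd, "ci_lo": m.ci_lo, "ci_hi": m.ci_hi}
            for name, m in cv.metrics.items()
        },
        subject_votes=cv.subject_votes.to_dict("records"),
        ablation=ablation_rows,
        semantic=semantic_payload,
    )
    if config.out:
        report.to_json(config.out)
    return report
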