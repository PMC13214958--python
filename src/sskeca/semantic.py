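"""Stimulus-category analysis and threshold-based image-set reduction.

Different stimulus categories discriminate the groups unequally well.
From the pooled out-of-fold sample predictions of a baseline CV run this
module computes per-category and per-image classification accuracy
(correct samples / total samples), selects the images whose accuracy
meets an accuracy threshold (inclusive, default 0.85), and re-evaluates
the full pipeline on the reduced stimulus set.  Selection is per image
(categories are a reporting grouping); per-image accuracy comes from the
baseline run's pooled test predictions, with no per-image retraining.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .classify import CVResult, FoldPlan, PipelineSpec, run_cv

__all__ = ["SemanticReport", "category_accuracy", "select_images", "evaluate_reduced"]


@dataclass
class SemanticReport:
    category_table: pd.DataFrame  # category_id, accuracy, n_samples
    image_accuracy: pd.Series  # image_id -> accuracy
    selected_images: list[int]
    threshold: float


def category_accuracy(cv: CVResult, threshold: float = 0.85) -> SemanticReport:
    """Per-category and per-image accuracy over pooled test-fold predictions."""
    df = cv.sample_predictions
    if df["image_id"].isna().any() or df["category_id"].isna().any():
        raise ValueError("sample predictions lack image/category metadata")
    correct = (df["y_pred"] == df["y_true"]).astype(float)
    cat = (
        pd.DataFrame({"category_id": df["category_id"], "correct": correct})
        .groupby("category_id")
        .agg(accuracy=("correct", "mean"), n_samples=("correct", "size"))
        .reset_index()
    )
    img = (
        pd.DataFrame({"image_id": df["image_id"], "correct": correct})
        .groupby("image_id")["correct"]
        .mean()
    )
    selected = select_images(img, threshold)
    return SemanticReport(
        category_table=cat, image_accuracy=img, selected_images=selected, threshold=threshold
    )


def select_images(per_image_acc: pd.Series, threshold: float) -> list[int]:
    """Image ids with accuracy >= threshold (inclusive), ascending order."""
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    chosen = sorted(int(i) for i, a in per_image_acc.items() if a >= threshold)
    if not chosen:
        warnings.warn("no image meets the accuracy threshold; returning empty selection")
    return chosen


def evaluate_reduced(
    table: pd.DataFrame, image_ids, spec: PipelineSpec, plan: FoldPlan
) -> CVResult:
    """Re-run the full CV restricted to the selected stimulus images.

    The fold plan (hence the subject partition and seeds) is unchanged, so
    the comparison against the full-set baseline isolates the stimulus
    reduction.  A subject losing all samples aborts with an error naming
    the subject.
    """
    image_ids = sorted(set(int(i) for i in image_ids))
    if not image_ids:
        raise ValueError("empty image selection")
    reduced = table[table["image_id"].isin(image_ids)]
    lost = set(table["subject_id"].astype(str)) - set(reduced["subject_id"].astype(str))
    if lost:
        raise ValueError(f"subject(s) lost all samples under reduction: {sorted(lost)[:5]}")
    return run_cv(reduced, spec, plan)
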