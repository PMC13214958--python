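"""The 24-dimensional hybrid eye-movement feature set and group statistics.

Each trial (one subject viewing one image) yields one feature vector with
four blocks:

* fixation features (FF, 9): count, average/max/min fixation duration,
  fixation skewness, total fixation duration, outside-fixation count, and
  average tracker x/y resolution over fixations;
* saccade features (SAF, 4): average velocity, total amplitude, count,
  average duration;
* pupil-size features (PSF, 7): dynamic range ``(max - min) / avg`` and
  size ratio ``max / avg`` of the pupil trace, min/avg/max pupil size, and
  the gaze x/y position at the maximum-pupil sample;
* biological features (BF, 4): recording duration, valid gaze-sample
  count, valid viewing duration, blink count.

Conventions (fixed so ports agree):

* *fixation skewness* is the mean Euclidean distance (px) of cleaned
  fixation centroids from the screen centre - a central-bias statistic
  (smaller = more centrally biased);
* *outside fixation count* is computed on the PRE-cleaning record
  (cleaning removes those fixations, the feature still sees them);
* *valid viewing duration* is the summed duration of all fixations
  landing inside the display before duration-based cleaning, whereas
  *fix duration* sums only cleaned fixations - hence VVD >= fix duration
  structurally;
* *sample count* counts valid gaze samples (one per millisecond of
  binocular-equivalent recording).

Group comparisons use Welch's two-sample t-test (Satterthwaite df),
pooled-SD Cohen's d, and Yates-corrected chi-square for 2x2 counts,
reported as raw (uncorrected) p-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .events import CleaningConfig, CleaningStats, TrialRecord, clean_trial

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_BLOCKS",
    "METADATA_COLUMNS",
    "FeatureVector",
    "extract_features",
    "build_feature_table",
    "welch_t",
    "cohens_d",
    "chi2_yates",
    "group_stats_table",
    "EmptyTableError",
]

logger = logging.getLogger(__name__)


class EmptyTableError(ValueError):
    """Raised when no valid trials remain to build a feature table."""


#: Feature blocks in canonical report order.
FEATURE_BLOCKS = {
    "FF": [
        "fix_count",
        "avg_fix_duration",
        "max_fix_duration",
        "fix_skewness",
        "fix_duration",
        "outside_fix_count",
        "avg_fix_x_res",
        "avg_fix_y_res",
        "min_fix_duration",
    ],
    "SAF": ["avg_sac_velocity", "sac_amplitude", "sac_count", "avg_sac_duration"],
    "PSF": [
        "dr_pupil_size",
        "pupil_size_ratio",
        "min_pupil_size",
        "avg_pupil_size",
        "max_pupil_size",
        "y_to_max_pupil",
        "x_to_max_pupil",
    ],
    "BF": ["duration", "sample_count", "valid_viewing_duration", "blink_count"],
}

#: Canonical column order of the 24 features.
FEATURE_NAMES: list[str] = [name for block in FEATURE_BLOCKS.values() for name in block]

METADATA_COLUMNS = ["subject_id", "group", "trial_id", "image_id", "category_id"]


@dataclass
class FeatureVector:
    values: dict[str, float]
    valid: bool = True
    invalid_reason: str | None = None

    def as_row(self) -> list[float]:
        return [self.values[name] for name in FEATURE_NAMES]


def _dist_from_center(trial: TrialRecord, x: float, y: float) -> float:
    cx, cy = trial.screen_width / 2.0, trial.screen_height / 2.0
    return math.hypot(x - cx, y - cy)


def _inside(trial: TrialRecord, x: float, y: float) -> bool:
    return 0 <= x < trial.screen_width and 0 <= y < trial.screen_height


def extract_features(
    trial: TrialRecord,
    cleaned: TrialRecord | None = None,
    stats: CleaningStats | None = None,
    config: CleaningConfig | None = None,
) -> FeatureVector:
    """Compute the 24 hybrid features for one trial.

    ``cleaned`` must derive from ``trial`` via :func:`~sskeca.events.clean_trial`;
    if omitted it is computed here.  Trials with no cleaned fixations or no
    valid gaze samples are flagged invalid (their pupil / fixation blocks
    are undefined) and dropped by :func:`build_feature_table`.
    """
    if cleaned is None:
        cleaned, stats = clean_trial(trial, config)
    f: dict[str, float] = {}

    fix = cleaned.fixations
    durs = np.array([e.duration_ms for e in fix], dtype=float)
    f["fix_count"] = float(len(fix))
    if len(fix):
        f["avg_fix_duration"] = float(durs.mean())
        f["max_fix_duration"] = float(durs.max())
        f["min_fix_duration"] = float(durs.min())
        f["fix_duration"] = float(durs.sum())
        f["fix_skewness"] = float(
            np.mean([_dist_from_center(trial, e.x_px, e.y_px) for e in fix])
        )
        f["avg_fix_x_res"] = float(np.mean([e.x_res for e in fix]))
        f["avg_fix_y_res"] = float(np.mean([e.y_res for e in fix]))
    else:
        for name in (
            "avg_fix_duration",
            "max_fix_duration",
            "min_fix_duration",
            "fix_duration",
            "fix_skewness",
            "avg_fix_x_res",
            "avg_fix_y_res",
        ):
            f[name] = float("nan")
    # outside-fixation count and valid viewing duration use the pre-cleaning record
    f["outside_fix_count"] = float(
        sum(not _inside(trial, e.x_px, e.y_px) for e in trial.fixations)
    )
    f["valid_viewing_duration"] = float(
        sum(e.duration_ms for e in trial.fixations if _inside(trial, e.x_px, e.y_px))
    )

    sac = cleaned.saccades
    if sac:
        f["avg_sac_velocity"] = float(np.mean([e.velocity_dps for e in sac]))
        f["sac_amplitude"] = float(sum(e.amplitude_deg for e in sac))  # per-trial total
        f["avg_sac_duration"] = float(np.mean([e.duration_ms for e in sac]))
    else:
        f["avg_sac_velocity"] = 0.0
        f["sac_amplitude"] = 0.0
        f["avg_sac_duration"] = 0.0
    f["sac_count"] = float(len(sac))

    valid_samples = [s for s in trial.samples if s.valid]
    if valid_samples:
        pupils = np.array([s.pupil for s in valid_samples])
        pmin, pavg, pmax = float(pupils.min()), float(pupils.mean()), float(pupils.max())
        f["min_pupil_size"] = pmin
        f["avg_pupil_size"] = pavg
        f["max_pupil_size"] = pmax
        f["dr_pupil_size"] = (pmax - pmin) / pavg if pavg else float("nan")
        f["pupil_size_ratio"] = pmax / pavg if pavg else float("nan")
        imax = int(np.argmax(pupils))  # first maximum on ties
        f["x_to_max_pupil"] = float(valid_samples[imax].x_px)
        f["y_to_max_pupil"] = float(valid_samples[imax].y_px)
    else:
        for name in FEATURE_BLOCKS["PSF"]:
            f[name] = float("nan")

    f["duration"] = float(trial.duration_ms or 0.0)
    f["sample_count"] = float(len(valid_samples))
    f["blink_count"] = float(len(trial.blinks))

    if not fix:
        return FeatureVector(f, valid=False, invalid_reason="no cleaned fixations")
    if not valid_samples:
        return FeatureVector(f, valid=False, invalid_reason="no valid gaze samples")
    return FeatureVector(f)


def build_feature_table(
    trials: list[TrialRecord], config: CleaningConfig | None = None
) -> pd.DataFrame:
    """One feature row per valid trial, metadata columns first.

    Invalid trials (see :func:`extract_features`) are logged and dropped;
    an all-invalid input raises :class:`EmptyTableError`.
    """
    if not trials:
        raise EmptyTableError("no trials supplied")
    rows = []
    for trial in trials:
        cleaned, stats = clean_trial(trial, config)
        vec = extract_features(trial, cleaned, stats)
        if not vec.valid:
            logger.warning(
                "dropping trial subject=%s trial=%s: %s",
                trial.subject_id,
                trial.trial_id,
                vec.invalid_reason,
            )
            continue
        rows.append(
            [
                trial.subject_id,
                trial.group,
                trial.trial_id,
                trial.image_id,
                trial.category_id,
                *vec.as_row(),
            ]
        )
    if not rows:
        raise EmptyTableError("all trials invalid")
    table = pd.DataFrame(rows, columns=METADATA_COLUMNS + FEATURE_NAMES)
    dup = table.duplicated(subset=["subject_id", "trial_id"])
    if dup.any():
        raise ValueError("duplicated (subject, trial) rows in feature table")
    return table


# ---------------------------------------------------------------------------
# Group-comparison statistics (from summaries)


def welch_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's two-sample t from group summaries.

    Returns ``(t, df, p)`` with Satterthwaite degrees of freedom and a
    two-sided p-value.  ``t`` is signed as ``mean1 - mean2``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("welch_t requires n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if v1 + v2 == 0:
        raise ValueError("zero pooled variance")
    t = (mean1 - mean2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return t, df, float(p)


def cohens_d(mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int) -> float:
    """Pooled-SD standardized mean difference ``(mean1 - mean2) / s_pooled``."""
    if n1 < 2 or n2 < 2:
        raise ValueError("cohens_d requires n >= 2 per group")
    s_pooled_sq = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if s_pooled_sq == 0:
        raise ValueError("zero pooled standard deviation")
    return (mean1 - mean2) / math.sqrt(s_pooled_sq)


def chi2_yates(table) -> tuple[float, float]:
    """Chi-square with Yates continuity correction on a 2x2 count table."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("chi2_yates expects a 2x2 table")
    if (obs < 0).any():
        raise ValueError("cell counts must be >= 0")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    chi2, p, _, _ = sps.chi2_contingency(obs, correction=True)
    return float(chi2), float(p)


def group_stats_table(table: pd.DataFrame, by_subject: bool = False) -> pd.DataFrame:
    """Per-feature HC-vs-SZ summaries with Welch t, p, and Cohen's d.

    By default statistics are computed over sample-level rows (one row per
    trial); ``by_subject=True`` first averages each subject's trials so the
    unit of analysis is the subject.  The t sign convention is HC minus SZ.
    A feature constant in both groups yields NaN statistics (flagged, not
    fatal).  Raw p-values; no multiplicity correction.
    """
    groups = set(table["group"])
    if groups != {"HC", "SZ"}:
        raise ValueError(f"need both HC and SZ groups, got {sorted(groups)}")
    data = table
    if by_subject:
        data = (
            table.groupby(["subject_id", "group"], as_index=False)[FEATURE_NAMES].mean()
        )
    hc = data[data["group"] == "HC"]
    sz = data[data["group"] == "SZ"]
    if len(hc) < 2 or len(sz) < 2:
        raise ValueError("need at least 2 rows per group")
    out = []
    for name in FEATURE_NAMES:
        h, s = hc[name].to_numpy(float), sz[name].to_numpy(float)
        row = {
            "feature": name,
            "hc_mean": h.mean(),
            "hc_sd": h.std(ddof=1),
            "n_hc": len(h),
            "sz_mean": s.mean(),
            "sz_sd": s.std(ddof=1),
            "n_sz": len(s),
        }
        try:
            t, df, p = welch_t(row["hc_mean"], row["hc_sd"], len(h), row["sz_mean"], row["sz_sd"], len(s))
            d = cohens_d(row["hc_mean"], row["hc_sd"], len(h), row["sz_mean"], row["sz_sd"], len(s))
        except ValueError:
            t = df = p = d = float("nan")
        row.update({"t": t, "df": df, "p": p, "cohens_d": d})
        out.append(row)
    return pd.DataFrame(out).set_index("feature")
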