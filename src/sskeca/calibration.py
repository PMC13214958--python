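"""Reference cohort calibration.

Group-level summaries (mean, SD per feature and group) of a free-viewing
eye-tracking cohort of 40 schizophrenia patients (SZ) and 50 healthy
controls (HC): 100 semantic images per participant, 5 s per image preceded
by a 1.5 s central fixation cross, recorded on an 800x600 display.

These numbers serve two purposes:

* they are the default targets of the synthetic-data generators
  (:mod:`sskeca.synth`), so simulated cohorts reproduce the reference
  group statistics; and
* they are the worked-example inputs for the summary-statistics helpers
  (:func:`sskeca.features.welch_t`, :func:`sskeca.features.cohens_d`,
  :func:`sskeca.features.chi2_yates`).

Values are stored per feature as ``(hc_mean, hc_sd, sz_mean, sz_sd)`` in
the canonical feature order of :data:`sskeca.features.FEATURE_NAMES`.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GroupTarget:
    """Per-feature group summary: means and SDs for HC and SZ."""

    hc_mean: float
    hc_sd: float
    sz_mean: float
    sz_sd: float


#: Number of subjects per group in the reference cohort.
GROUP_SIZES = {"HC": 50, "SZ": 40}

#: Canonical feature -> (HC mean, HC sd, SZ mean, SZ sd).
REFERENCE_SUMMARIES: dict[str, GroupTarget] = {
    # fixation features (FF)
    "fix_count": GroupTarget(13.39, 2.86, 11.20, 2.41),
    "avg_fix_duration": GroupTarget(375.18, 172.80, 372.82, 127.16),
    "max_fix_duration": GroupTarget(795.31, 343.54, 787.60, 245.97),
    "fix_skewness": GroupTarget(163.69, 25.15, 155.04, 27.09),
    "fix_duration": GroupTarget(3789.46, 513.26, 3493.68, 641.91),
    "outside_fix_count": GroupTarget(0.49, 1.50, 0.58, 0.75),
    "avg_fix_x_res": GroupTarget(23.08, 0.12, 23.10, 0.21),
    "avg_fix_y_res": GroupTarget(22.68, 0.18, 22.79, 0.39),
    "min_fix_duration": GroupTarget(148.05, 88.72, 137.51, 62.00),
    # saccade features (SAF)
    "avg_sac_velocity": GroupTarget(144.72, 38.59, 79.44, 31.54),
    "sac_amplitude": GroupTarget(132.73, 75.80, 63.72, 20.30),
    "sac_count": GroupTarget(13.83, 2.86, 11.69, 2.37),
    "avg_sac_duration": GroupTarget(6.27, 1.36, 5.45, 1.32),
    # pupil size features (PSF)
    "dr_pupil_size": GroupTarget(0.36, 0.06, 0.30, 0.09),
    "pupil_size_ratio": GroupTarget(1.15, 0.03, 1.13, 0.04),
    "min_pupil_size": GroupTarget(1439.83, 527.37, 1669.00, 785.94),
    "avg_pupil_size": GroupTarget(1823.20, 675.95, 2007.52, 906.47),
    "max_pupil_size": GroupTarget(2096.02, 769.00, 2263.21, 1007.77),
    "y_to_max_pupil": GroupTarget(325.66, 28.34, 333.79, 47.74),
    "x_to_max_pupil": GroupTarget(381.52, 39.28, 383.04, 51.49),
    # biological features (BF)
    "duration": GroupTarget(6804.59, 5.37, 6811.59, 10.42),
    "sample_count": GroupTarget(6803.99, 5.47, 6810.59, 10.42),
    "valid_viewing_duration": GroupTarget(4708.35, 201.55, 4605.75, 220.41),
    "blink_count": GroupTarget(2.53, 1.27, 3.32, 2.42),
}

#: Demographics of the reference cohort, same (hc_mean, hc_sd, sz_mean, sz_sd)
#: layout.  Only rows whose printed test statistics reproduce from the
#: summaries are shipped as worked examples (age does not; see docs/methods.md).
DEMOGRAPHICS = {
    "education_years": GroupTarget(13.40, 1.39, 11.90, 1.13),
    "age_years": GroupTarget(32.40, 5.82, 34.80, 11.90),
}

#: Gender 2x2 contingency table of the reference cohort,
#: rows = (SZ, HC), columns = (male, female).
GENDER_TABLE = [[28, 12], [29, 21]]

#: Stimulus-protocol constants of the reference cohort.
PROTOCOL = {
    "screen_width_px": 800,
    "screen_height_px": 600,
    "trials_per_subject": 100,
    "n_images": 100,
    "n_categories": 20,
    "cross_ms": 1500.0,
    "image_ms": 5000.0,
}
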