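"""Synthetic cohorts calibrated to the reference group summaries.

Real free-viewing recordings of the reference cohort are not publicly
available, so this module emulates their statistical structure at two
levels:

* :func:`generate_feature_table` draws 24-dimensional feature rows
  directly.  Each feature is a Gaussian two-level model: a per-subject
  random effect plus per-trial noise.  The split is calibrated so that
  (a) the SD of per-subject trial means matches the reference group SD
  (the reference summaries are subject-level statistics over 50 HC / 40
  SZ subjects), and (b) the intraclass correlation - the fraction of
  per-trial variance that is between subjects - equals ``icc``.
  Min/avg/max triples (fixation duration, pupil size) share a latent
  factor and are order-enforced per row; pupil dynamic range and size
  ratio are recomputed from the generated min/avg/max rather than drawn.
  Counts are rounded to non-negative integers (slightly biased upward
  for near-zero means such as the outside-fixation count).

* :func:`generate_trials` synthesizes full event streams whose extracted
  features recover the same targets: per trial it draws a latent feature
  row, then constructs fixations whose durations sum to the total
  fixation duration (each within the 80-2000 ms cleaning window),
  centroids at the target mean distance from screen centre, saccades
  with unit-floor amplitudes summing to the amplitude target and exact
  mean velocity/duration, a 1 ms-resolution pupil trace with exact
  min/avg/max, plus deliberately cleanable events: outside-display
  fixations realizing the outside-fixation count and sub-80 ms filler
  fixations realizing the excess of valid viewing duration over total
  (cleaned) fixation duration.  The order-statistic fixation-duration
  features (avg/max/min) are emergent rather than targeted - the
  reference summaries are not jointly realizable by a single event
  stream (see docs/methods.md).

Everything is deterministic given ``(profile, seed)``.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .calibration import GROUP_SIZES, PROTOCOL, REFERENCE_SUMMARIES, GroupTarget
from .events import BlinkEvent, FixationEvent, GazeSample, SaccadeEvent, TrialRecord
from .features import FEATURE_NAMES, METADATA_COLUMNS

__all__ = ["SyntheticProfile", "default_profile", "generate_feature_table", "generate_trials"]

_COUNT_FEATURES = {"fix_count", "sac_count", "blink_count", "outside_fix_count", "sample_count"}
_TRIPLES = [
    ("min_fix_duration", "avg_fix_duration", "max_fix_duration"),
    ("min_pupil_size", "avg_pupil_size", "max_pupil_size"),
]
_TRIPLE_R = 0.95  # shared-factor loading within a min/avg/max triple


@dataclass(frozen=True)
class SyntheticProfile:
    """Targets and design parameters of a synthetic cohort."""

    n_sz: int = GROUP_SIZES["SZ"]
    n_hc: int = GROUP_SIZES["HC"]
    trials_per_subject: int = PROTOCOL["trials_per_subject"]
    icc: float = 0.5
    targets: dict[str, GroupTarget] = field(
        default_factory=lambda: dict(REFERENCE_SUMMARIES)
    )
    n_images: int = PROTOCOL["n_images"]
    n_categories: int = PROTOCOL["n_categories"]
    cross_ms: float = PROTOCOL["cross_ms"]
    image_ms: float = PROTOCOL["image_ms"]
    screen_width: int = PROTOCOL["screen_width_px"]
    screen_height: int = PROTOCOL["screen_height_px"]
    heavy_tails: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.icc < 1:
            raise ValueError("icc must be in [0, 1)")
        if self.n_sz < 2 or self.n_hc < 2:
            raise ValueError("group sizes must be >= 2")
        for name, t in self.targets.items():
            if t.hc_sd < 0 or t.sz_sd < 0:
                raise ValueError(f"negative SD target for {name}")

    def hash(self) -> str:
        payload = asdict(self)
        payload["targets"] = {k: asdict(v) for k, v in sorted(self.targets.items())}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def category_of(self, image_id: int) -> int:
        per_cat = max(1, self.n_images // self.n_categories)
        return min((image_id - 1) // per_cat, self.n_categories - 1) + 1


def default_profile() -> SyntheticProfile:
    """The shipped calibration: 40 SZ / 50 HC, 100 trials each, ICC 0.5."""
    return SyntheticProfile()


# ---------------------------------------------------------------------------
# latent two-level feature rows


def _variance_split(sd: float, icc: float, m: int) -> tuple[float, float]:
    """(tau, sigma_w): between-subject SD and trial SD.

    Calibrated so Var(subject mean of m trials) = sd**2 and
    ICC = tau^2 / (tau^2 + sigma_w^2) = icc.
    """
    tau2 = sd**2 * icc * m / (icc * m + 1 - icc) if icc > 0 else 0.0
    sig2 = (sd**2 - tau2) * m
    return math.sqrt(tau2), math.sqrt(max(sig2, 0.0))


def _draw(rng: np.random.Generator, size, heavy: bool) -> np.ndarray:
    if heavy:
        df = 5.0
        return rng.standard_t(df, size=size) / math.sqrt(df / (df - 2))
    return rng.standard_normal(size=size)


def _latent_rows(
    profile: SyntheticProfile, rng: np.random.Generator, group: str, n_subj: int
) -> pd.DataFrame:
    """Raw (unrounded, real-valued) latent feature rows for one group."""
    m = profile.trials_per_subject
    total = n_subj * m
    triple_members = {name for triple in _TRIPLES for name in triple}
    cols: dict[str, np.ndarray] = {}

    # shared latent factors for the ordered triples
    shared_subj = {t: _draw(rng, n_subj, profile.heavy_tails) for t in _TRIPLES}
    shared_trial = {t: _draw(rng, total, profile.heavy_tails) for t in _TRIPLES}

    for name in FEATURE_NAMES:
        if name in ("dr_pupil_size", "pupil_size_ratio"):
            continue  # recomputed from the pupil triple
        t = profile.targets[name]
        mean, sd = (t.hc_mean, t.hc_sd) if group == "HC" else (t.sz_mean, t.sz_sd)
        tau, sig = _variance_split(sd, profile.icc, m)
        eps_s = _draw(rng, n_subj, profile.heavy_tails)
        eps_t = _draw(rng, total, profile.heavy_tails)
        triple = next((tr for tr in _TRIPLES if name in tr), None)
        if triple is not None:
            r = _TRIPLE_R
            eps_s = r * shared_subj[triple] + math.sqrt(1 - r**2) * eps_s
            eps_t = r * shared_trial[triple] + math.sqrt(1 - r**2) * eps_t
        subj_effect = mean + tau * eps_s
        cols[name] = np.repeat(subj_effect, m) + sig * eps_t

    for lo, mid, hi in _TRIPLES:
        stacked = np.sort(np.column_stack([cols[lo], cols[mid], cols[hi]]), axis=1)
        cols[lo], cols[mid], cols[hi] = stacked[:, 0], stacked[:, 1], stacked[:, 2]

    # structural couplings and domain clipping
    avg_p = np.clip(cols["avg_pupil_size"], 1.0, None)
    min_p = np.clip(cols["min_pupil_size"], 0.0, avg_p)
    max_p = np.maximum(cols["max_pupil_size"], avg_p)
    cols["min_pupil_size"], cols["avg_pupil_size"], cols["max_pupil_size"] = min_p, avg_p, max_p
    cols["dr_pupil_size"] = (max_p - min_p) / avg_p
    cols["pupil_size_ratio"] = max_p / avg_p
    for name in (
        "fix_skewness",
        "fix_duration",
        "valid_viewing_duration",
        "avg_sac_velocity",
        "sac_amplitude",
        "avg_sac_duration",
        "avg_fix_x_res",
        "avg_fix_y_res",
        "min_fix_duration",
        "avg_fix_duration",
        "max_fix_duration",
        "duration",
    ):
        cols[name] = np.clip(cols[name], 0.0, None)
    # valid viewing duration counts every inside fixation, cleaned total only
    # the 80-2000 ms survivors, so VVD >= fix duration structurally
    cols["valid_viewing_duration"] = np.maximum(
        cols["valid_viewing_duration"], cols["fix_duration"]
    )
    for name in _COUNT_FEATURES:
        cols[name] = np.clip(np.rint(cols[name]), 0, None)
    cols["fix_count"] = np.clip(cols["fix_count"], 1, None)
    cols["x_to_max_pupil"] = np.clip(cols["x_to_max_pupil"], 0, profile.screen_width - 1)
    cols["y_to_max_pupil"] = np.clip(cols["y_to_max_pupil"], 0, profile.screen_height - 1)
    return pd.DataFrame({name: cols[name] for name in FEATURE_NAMES})


def _metadata(profile: SyntheticProfile, group: str, n_subj: int, start: int) -> pd.DataFrame:
    m = profile.trials_per_subject
    subj = [f"{group}{i + 1:03d}" for i in range(n_subj)]
    rows = {
        "subject_id": np.repeat(subj, m),
        "group": group,
        "trial_id": np.tile(np.arange(1, m + 1), n_subj),
    }
    image = (np.arange(n_subj * m) + start) % profile.n_images + 1
    rows["image_id"] = image
    rows["category_id"] = [profile.category_of(i) for i in image]
    return pd.DataFrame(rows)


def generate_feature_table(profile: SyntheticProfile, seed: int = 0) -> pd.DataFrame:
    """Draw a full synthetic feature table (metadata + 24 features)."""
    rng = np.random.default_rng(seed)
    parts = []
    for group, n_subj in (("HC", profile.n_hc), ("SZ", profile.n_sz)):
        meta = _metadata(profile, group, n_subj, start=0)
        latent = _latent_rows(profile, rng, group, n_subj)
        parts.append(pd.concat([meta.reset_index(drop=True), latent], axis=1))
    table = pd.concat(parts, ignore_index=True)
    return table[METADATA_COLUMNS + FEATURE_NAMES]


# ---------------------------------------------------------------------------
# event-stream synthesis


def _mean_exact(rng, n: int, mean: float, spread: float = 0.5) -> np.ndarray:
    """n positive values with exact mean: symmetric +-delta pairs around it."""
    if n == 1 or mean <= 0:
        return np.full(n, max(mean, 0.0))
    half = n // 2
    delta = rng.uniform(0, spread, size=half)
    vals = np.concatenate(
        [mean * (1 + delta), mean * (1 - delta), [mean] if n % 2 else []]
    )
    rng.shuffle(vals)
    return vals


def _fixation_durations(rng, n: int, total: float) -> np.ndarray:
    """n durations in [86, 1990] summing exactly to total (clipped if infeasible)."""
    lo, hi = 86.0, 1990.0
    total = float(np.clip(total, n * lo, n * hi))
    d = lo + (total - n * lo) * rng.dirichlet(np.full(n, 8.0))
    for _ in range(20):
        excess = np.clip(d - hi, 0, None)
        if not excess.any():
            break
        d = np.clip(d, lo, hi)
        room = hi - d
        d += excess.sum() * room / room.sum()
    return d


def _pupil_trace(rng, n: int, pmin: float, pavg: float, pmax: float) -> np.ndarray:
    """n pupil values with exact min, mean and max (unique maximum)."""
    pmin = min(pmin, pavg)
    pmax = max(pmax, pavg + 1e-9)
    if n < 3:
        return np.full(n, pavg)
    c = (n * pavg - pmin - pmax) / (n - 2)
    c = float(np.clip(c, pmin, pmax))
    jitter_scale = 0.01 * (pmax - pmin + 1e-9)
    jitter_scale = min(jitter_scale, (pmax - c) / 2, (c - pmin) / 2) if pmax > pmin else 0.0
    eps = rng.uniform(-1, 1, size=n - 2)
    body = c + max(jitter_scale, 0.0) * (eps - eps.mean())
    return np.concatenate([[pmin, pmax], body])


def _fixation_positions(rng, n: int, mean_dist: float, width: int, height: int):
    """n centroids inside the display with exact mean distance from centre."""
    cap = min(width, height) / 2 - 20
    mean_dist = float(np.clip(mean_dist, 1.0, cap))
    a = min(0.7, cap / mean_dist - 1)
    half = n // 2
    delta = rng.uniform(0, a, size=half)
    radii = np.concatenate(
        [mean_dist * (1 + delta), mean_dist * (1 - delta), [mean_dist] if n % 2 else []]
    )
    rng.shuffle(radii)
    theta = rng.uniform(0, 2 * math.pi, size=n)
    x = width / 2 + radii * np.cos(theta)
    y = height / 2 + radii * np.sin(theta)
    return x, y


def _synthesize_trial(
    profile: SyntheticProfile, rng: np.random.Generator, meta: dict, row: pd.Series
) -> TrialRecord:
    W, H = profile.screen_width, profile.screen_height
    n_fix = int(row["fix_count"])
    total_fix = float(row["fix_duration"])
    n_fix = max(n_fix, 1, math.ceil(total_fix / 1900.0))
    durs = _fixation_durations(rng, n_fix, total_fix)
    xs, ys = _fixation_positions(rng, n_fix, row["fix_skewness"], W, H)
    x_res = _mean_exact(rng, n_fix, max(row["avg_fix_x_res"], 1e-6), spread=0.005)
    y_res = _mean_exact(rng, n_fix, max(row["avg_fix_y_res"], 1e-6), spread=0.005)

    n_sac = int(row["sac_count"])
    amp_total = max(float(row["sac_amplitude"]), n_sac * 1.05)
    if n_sac:
        amps = 1.05 + (amp_total - 1.05 * n_sac) * rng.dirichlet(np.full(n_sac, 8.0))
        vels = _mean_exact(rng, n_sac, max(row["avg_sac_velocity"], 1.0), spread=0.3)
        sac_durs = np.clip(
            _mean_exact(rng, n_sac, max(row["avg_sac_duration"], 0.5), spread=0.3), 0.2, None
        )
    else:
        amps = vels = sac_durs = np.array([])

    # timeline: filler (sub-80ms, cleaned away) -> main fixations with saccade gaps
    fixations: list[FixationEvent] = []
    saccades: list[SaccadeEvent] = []
    t = 10.0
    gap = float(row["valid_viewing_duration"]) - float(durs.sum())
    if gap > 1.0:
        k = max(1, math.ceil(gap / 75.0))
        each = gap / k
        fx, fy = _fixation_positions(rng, k, min(row["fix_skewness"], 100.0), W, H)
        for i in range(k):
            fixations.append(
                FixationEvent(t, each, fx[i], fy[i], x_res[0], y_res[0], row["avg_pupil_size"])
            )
            t += each + 1.0
    for i in range(n_fix):
        fixations.append(
            FixationEvent(t, float(durs[i]), xs[i], ys[i], x_res[i], y_res[i], row["avg_pupil_size"])
        )
        t += durs[i]
        if i < n_sac:
            saccades.append(SaccadeEvent(t, float(sac_durs[i]), float(amps[i]), float(vels[i])))
            t += sac_durs[i]
        t += 2.0
    for i in range(n_fix, n_sac):  # leftover saccades appended after the block
        saccades.append(SaccadeEvent(t, float(sac_durs[i]), float(amps[i]), float(vels[i])))
        t += sac_durs[i] + 2.0
    n_out = int(row["outside_fix_count"])
    for _ in range(n_out):
        fixations.append(FixationEvent(t, 200.0, W + 50.0, H / 2.0, x_res[0], y_res[0], 0.0))
        t += 202.0
    blinks = []
    for _ in range(int(row["blink_count"])):
        d = float(rng.uniform(100, 300))
        blinks.append(BlinkEvent(t, d))
        t += d + 2.0

    n_samples = max(int(round(row["duration"])), int(math.ceil(t)) + 10, 100)
    pupils = _pupil_trace(
        rng, n_samples, row["min_pupil_size"], row["avg_pupil_size"], row["max_pupil_size"]
    )
    order = rng.permutation(n_samples)
    pupils = pupils[np.argsort(order)]  # scatter min/max to random timestamps
    sx = rng.uniform(0, W, size=n_samples)
    sy = rng.uniform(0, H, size=n_samples)
    imax = int(np.argmax(pupils))
    sx[imax] = row["x_to_max_pupil"]
    sy[imax] = row["y_to_max_pupil"]
    samples = [
        GazeSample(float(i + 1), float(sx[i]), float(sy[i]), float(pupils[i]))
        for i in range(n_samples)
    ]

    trial = TrialRecord(
        subject_id=meta["subject_id"],
        group=meta["group"],
        trial_id=int(meta["trial_id"]),
        image_id=int(meta["image_id"]),
        category_id=int(meta["category_id"]),
        screen_width=W,
        screen_height=H,
        duration_ms=float(n_samples),
        fixations=fixations,
        saccades=saccades,
        blinks=blinks,
        samples=samples,
    )
    trial.validate()
    return trial


def _generate_trials_with_latent(
    profile: SyntheticProfile, seed: int = 0
) -> tuple[list[TrialRecord], pd.DataFrame]:
    """As :func:`generate_trials`, also returning the per-trial latent targets."""
    rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []
    latents = []
    for group, n_subj in (("HC", profile.n_hc), ("SZ", profile.n_sz)):
        meta = _metadata(profile, group, n_subj, start=0)
        latent = _latent_rows(profile, rng, group, n_subj)
        for i in range(len(meta)):
            trials.append(
                _synthesize_trial(profile, rng, meta.iloc[i].to_dict(), latent.iloc[i])
            )
        latents.append(pd.concat([meta, latent], axis=1))
    return trials, pd.concat(latents, ignore_index=True)


def generate_trials(profile: SyntheticProfile, seed: int = 0) -> list[TrialRecord]:
    """Synthesize event-level trials whose extracted features hit the targets.

    Memory scales with subjects x trials x recording duration (one gaze
    sample per millisecond); full-cohort event synthesis is intended for
    modest profiles, the feature-level generator for large ones.
    """
    return _generate_trials_with_latent(profile, seed)[0]
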