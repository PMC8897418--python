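"""Pacing-response classification.

Two independent routes classify each captured paced beat as selective HBP,
nonselective HBP or right-ventricular pacing:

* ``classify_by_ims`` -- the automated route: a pair of IMS cutoffs
  (c_low, c_high); a score at or above the high cutoff is selective capture,
  between the cutoffs nonselective, below the low cutoff RVP.
* ``classify_conventional`` -- a rule-based surrogate for the
  electrophysiologists' criteria: selective capture shows an isoelectric
  stimulus-to-QRS latency with unchanged QRS duration; nonselective capture
  is fused to the stimulus with a widened QRS but preserved terminal
  (conduction-system) activation; loss of His capture leaves a purely
  myocardial morphology.

``validate_reference`` applies the acceptance rule for the intrinsic
reference: the template is usable only if at least 75% of consecutive
intrinsic beats score an IMS >= 97%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphology import Template, compute_lat, detect_qrs_onset, pearson
from .synthetic_ecg import Beat, BeatClass, measure_qrs_bounds

__all__ = [
    "ThresholdSet",
    "ClassifiedBeat",
    "ReferenceReport",
    "validate_reference",
    "classify_by_ims",
    "classify_conventional",
]


@dataclass(frozen=True)
class ThresholdSet:
    """IMS cutoffs (percent): >= c_high selective, >= c_low nonselective."""

    c_low_pct: float
    c_high_pct: float

    def __post_init__(self):
        if not 0.0 <= self.c_low_pct < self.c_high_pct <= 100.0:
            raise ValueError("need 0 <= c_low < c_high <= 100")


#: Cutoff pair best separating the three pacing responses in the study data.
STUDY_THRESHOLDS = ThresholdSet(78.4, 88.9)


@dataclass(frozen=True)
class ClassifiedBeat:
    beat_id: str
    ims_pct: float
    predicted_class: BeatClass
    conventional_class: BeatClass
    agree: bool


@dataclass(frozen=True)
class ReferenceReport:
    """Outcome of the intrinsic-reference acceptance rule."""

    passed: bool
    n: int
    fraction: float
    score_threshold_pct: float
    min_fraction: float

    def __str__(self):  # used verbatim in pipeline abort messages
        verdict = "PASS" if self.passed else "FAIL"
        return (f"reference validation {verdict}: {self.fraction:.0%} of "
                f"{self.n} intrinsic beats scored IMS >= "
                f"{self.score_threshold_pct:g}%")


def validate_reference(intrinsic_scores, min_fraction: float = 0.75,
                       score_threshold_pct: float = 97.0,
                       min_n: int = 5) -> ReferenceReport:
    """Accept the reference iff enough intrinsic beats match it closely.

    Pass requires n >= min_n beats and at least ``min_fraction`` of them
    scoring at or above ``score_threshold_pct``.  Empty input fails with
    n = 0.  Invariant to score order.
    """
    scores = np.asarray(list(intrinsic_scores), dtype=float)
    n = scores.size
    frac = float(np.mean(scores >= score_threshold_pct)) if n else 0.0
    return ReferenceReport(passed=(n >= min_n and frac >= min_fraction),
                           n=n, fraction=frac,
                           score_threshold_pct=score_threshold_pct,
                           min_fraction=min_fraction)


def classify_by_ims(ims_pct: float, thresholds: ThresholdSet) -> BeatClass:
    """Three-class step function on the IMS; >= assigns the higher class."""
    if ims_pct >= thresholds.c_high_pct:
        return BeatClass.S_HBP
    if ims_pct >= thresholds.c_low_pct:
        return BeatClass.NS_HBP
    return BeatClass.RVP


#: A paced QRS starting more than this after the stimulus has an isoelectric
#: latency (conduction-system capture only); at or below, it is fused.
_FUSION_LATENCY_MS = 10.0
#: Terminal-activation similarity above which a fused beat still carries a
#: conduction-system component (nonselective rather than pure RV capture).
_TERMINAL_R_MIN = 0.5
_TERMINAL_WINDOW_MS = 60.0


def _terminal_similarity(beat: Beat, template: Template) -> float:
    """Mean per-lead correlation over the last 60 ms of the QRS, offset-aligned.

    Nonselective fusion preserves late conduction-system activation, so its
    terminal QRS still matches the intrinsic template; pure myocardial
    capture does not.
    """
    fs = beat.sampling_rate_hz
    w = int(round(_TERMINAL_WINDOW_MS * fs / 1000.0))
    _, off_b = measure_qrs_bounds(beat.samples, fs)
    _, off_t = measure_qrs_bounds(template.beat.samples, fs)
    jb = int(round(off_b * fs / 1000.0))
    jt = int(round(off_t * fs / 1000.0))
    b = beat.samples[:, max(0, jb - w):jb]
    t = template.beat.samples[:, max(0, jt - w):jt]
    m = min(b.shape[1], t.shape[1])
    rs = [pearson(b[k, -m:], t[k, -m:]) for k in range(12)]
    return float(np.mean(rs))


def classify_conventional(beat: Beat, template: Template,
                          qrsd_tol_ms: float = 10.0) -> BeatClass:
    """Rule-based surrogate for the established pacing-response criteria.

    Requires a captured paced beat (LAT <= 0); non-captured beats must be
    filtered out beforehand and raise here.
    """
    if beat.stimulus_time_ms is None:
        raise ValueError("conventional classification needs a paced beat")
    if compute_lat(beat) > 0:
        raise ValueError("non-captured beat: filter by LAT before classifying")
    latency = detect_qrs_onset(beat) - beat.stimulus_time_ms
    on_b, off_b = measure_qrs_bounds(beat.samples, beat.sampling_rate_hz)
    on_t, off_t = measure_qrs_bounds(template.beat.samples,
                                     template.beat.sampling_rate_hz)
    widened = abs((off_b - on_b) - (off_t - on_t)) > qrsd_tol_ms
    if latency > _FUSION_LATENCY_MS:
        # isoelectric interval: conduction-system capture only
        return BeatClass.S_HBP if not widened else BeatClass.NS_HBP
    # fused to the stimulus: nonselective if the terminal QRS still matches
    # the intrinsic activation, otherwise pure myocardial capture
    if _terminal_similarity(beat, template) >= _TERMINAL_R_MIN:
        return BeatClass.NS_HBP
    return BeatClass.RVP
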