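"""Intrinsic morphology match score (IMS) engine.

A frozen intrinsic 12-lead QRS template is compared with every mapped beat:
per-lead Pearson correlation inside an operator-set independent scoring
interval (ISI), averaged over the 12 leads and expressed as an integer
percentage.  Negative global scores are kept for descriptive statistics and
clamped to 0 only for map display.  Local activation time (LAT) relative to
the pacing stimulus separates captured beats (LAT <= 0) from non-captured or
atrial-capture beats (LAT > 0), which are excluded before any statistics no
matter how well they score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .synthetic_ecg import (
    Beat, BeatClass, LEAD_NAMES, PACED_CLASSES, measure_qrs_bounds,
)

__all__ = [
    "ScoringInterval",
    "Template",
    "IMSResult",
    "detect_qrs_onset",
    "make_template",
    "pearson",
    "score_beat",
    "score_beats",
    "shift_search",
    "compute_lat",
    "filter_captured",
    "DEFAULT_ISI",
    "CAPTURE_LATENCY_TOLERANCE_MS",
]

#: Paced beats must begin within this window after the stimulus to count as
#: captured; the LAT of a captured beat is therefore <= 0.
CAPTURE_LATENCY_TOLERANCE_MS = 40.0


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ScoringInterval:
    """ISI window bounds (ms) relative to the reference QRS onset, half-open."""

    start_ms: float
    end_ms: float

    def __post_init__(self):
        if not self.start_ms < self.end_ms:
            raise ValueError("ISI start must precede its end")

    def n_samples(self, sampling_rate_hz: float) -> int:
        return int(round((self.end_ms - self.start_ms)
                         * sampling_rate_hz / 1000.0))


#: Default ISI: encloses a narrow QRS with a small isoelectric margin.
DEFAULT_ISI = ScoringInterval(-10.0, 110.0)


@dataclass(frozen=True)
class Template:
    """Frozen intrinsic 12-lead reference with its scoring interval."""

    beat: Beat
    qrs_onset_ms: float
    isi: ScoringInterval


def detect_qrs_onset(beat: Beat) -> float:
    """Earliest time (ms) where the cross-lead RMS exceeds 5% of its peak."""
    onset, _ = measure_qrs_bounds(beat.samples, beat.sampling_rate_hz)
    return onset


def make_template(beat: Beat, isi: ScoringInterval | None = None) -> Template:
    """Freeze an intrinsic beat as the matching reference.

    The reference offset is the beat's detected QRS onset.  When no ISI is
    given, the scoring interval is adjusted to enclose the intrinsic QRS
    morphology with a 10 ms margin on each side, the way an operator places
    the ISI lines.  The ISI must lie inside the beat window and span at
    least 10 samples.
    """
    if beat.true_class in PACED_CLASSES or beat.stimulus_time_ms is not None:
        raise ValueError("the template must be an unpaced intrinsic beat")
    if isi is None:
        on, off = measure_qrs_bounds(beat.samples, beat.sampling_rate_hz)
        isi = ScoringInterval(-10.0, (off - on) + 10.0)
    if isi.n_samples(beat.sampling_rate_hz) < 10:
        raise ValueError("ISI spans fewer than 10 samples")
    onset = detect_qrs_onset(beat)
    window_ms = beat.n_samples * 1000.0 / beat.sampling_rate_hz
    if onset + isi.start_ms < 0 or onset + isi.end_ms > window_ms:
        raise ValueError("ISI extends beyond the template beat window")
    return Template(beat, onset, isi)


def pearson(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    A vector with zero variance has no defined correlation; the contract
    here is to score it 0 (the caller flags the lead as degenerate).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(np.clip((xc @ yc) / math.sqrt(sx * sy), -1.0, 1.0))


@dataclass(frozen=True)
class IMSResult:
    """Per-lead and global morphology match of one beat against the template."""

    beat_id: str
    per_lead_scores: tuple
    global_ims_pct: int
    global_ims_display_pct: int
    shift_ms: float
    lat_ms: float | None
    captured: bool
    degenerate_leads: tuple = ()
    true_class: BeatClass = BeatClass.UNKNOWN
    source: str = "lead"


def _template_indices(template: Template) -> tuple[int, int]:
    fs = template.beat.sampling_rate_hz
    i0 = int(round((template.qrs_onset_ms + template.isi.start_ms) * fs / 1000.0))
    i1 = i0 + template.isi.n_samples(fs)
    return i0, i1


def compute_lat(beat: Beat, template: Template | None = None,
                tolerance_ms: float = CAPTURE_LATENCY_TOLERANCE_MS) -> float:
    """LAT (ms) = detected QRS onset - (stimulus time + capture tolerance).

    Captured paced beats begin within the tolerance window and yield
    LAT <= 0; non-captured and atrial-capture beats yield LAT > 0.
    """
    if beat.stimulus_time_ms is None:
        raise ValueError("LAT is defined only for paced beats")
    onset = detect_qrs_onset(beat)
    return onset - (beat.stimulus_time_ms + tolerance_ms)


def score_beat(beat: Beat, template: Template, shift_ms: float = 0.0,
               *, align: str = "onset",
               capture_tolerance_ms: float = CAPTURE_LATENCY_TOLERANCE_MS
               ) -> IMSResult:
    """Score one beat against the template over the ISI window.

    The beat is aligned to the reference by its own detected QRS onset
    (``align="onset"``, the automatic behaviour) or left on its raw window
    timing (``align="none"``); ``shift_ms`` adds a manual shift on top.
    ``IMSResult.shift_ms`` records the total shift applied to the beat.
    """
    fs = template.beat.sampling_rate_hz
    if abs(beat.sampling_rate_hz - fs) > 1e-9:
        raise ValueError("beat and template sampling rates differ")
    if align not in ("onset", "none"):
        raise ValueError("align must be 'onset' or 'none'")

    beat_onset = detect_qrs_onset(beat) if align == "onset" else None
    auto_ms = (template.qrs_onset_ms - beat_onset) if align == "onset" else 0.0
    total_shift = auto_ms + shift_ms
    shift_samp = total_shift * fs / 1000.0

    i0, i1 = _template_indices(template)
    pos = np.arange(i0, i1, dtype=float) - shift_samp
    if pos[0] < 0.0 or pos[-1] > beat.n_samples - 1:
        raise ValueError("ISI extends beyond the beat after alignment")

    ref = template.beat.samples[:, i0:i1]
    # fractional-sample alignment by linear interpolation
    base = np.floor(pos).astype(int)
    frac = pos - base
    nxt = np.minimum(base + 1, beat.n_samples - 1)
    seg = beat.samples[:, base] * (1.0 - frac) + beat.samples[:, nxt] * frac

    refc = ref - ref.mean(axis=1, keepdims=True)
    segc = seg - seg.mean(axis=1, keepdims=True)
    sr = np.einsum("ij,ij->i", refc, refc)
    ss = np.einsum("ij,ij->i", segc, segc)
    cross = np.einsum("ij,ij->i", refc, segc)
    degenerate = (sr == 0.0) | (ss == 0.0)
    denom = np.sqrt(np.where(degenerate, 1.0, sr * ss))
    scores = np.where(degenerate, 0.0, np.clip(cross / denom, -1.0, 1.0))

    global_pct = _round_half_up(100.0 * float(scores.mean()))
    lat = None
    if beat.stimulus_time_ms is not None:
        lat = compute_lat(beat, template, tolerance_ms=capture_tolerance_ms)
    deg_leads = tuple(np.asarray(LEAD_NAMES)[degenerate])
    return IMSResult(
        beat_id=beat.beat_id,
        per_lead_scores=tuple(float(s) for s in scores),
        global_ims_pct=global_pct,
        global_ims_display_pct=max(0, global_pct),
        shift_ms=total_shift,
        lat_ms=lat,
        captured=(lat is None or lat <= 0.0),
        degenerate_leads=deg_leads,
        true_class=beat.true_class,
        source=beat.source,
    )


def score_beats(beats, template: Template, *, strict: bool = True,
                **kwargs) -> list[IMSResult]:
    """Score a list of beats; order preserved.

    With ``strict=False`` a beat that cannot be aligned (no detectable QRS,
    or the ISI leaves the beat window) scores 0% on every lead instead of
    raising -- matching how an unmatchable signal is treated operationally.
    """
    out = []
    for b in beats:
        try:
            out.append(score_beat(b, template, **kwargs))
        except ValueError:
            if strict:
                raise
            lat = None
            if b.stimulus_time_ms is not None:
                try:
                    lat = compute_lat(b, template)
                except ValueError:
                    lat = None
            out.append(IMSResult(
                beat_id=b.beat_id, per_lead_scores=(0.0,) * 12,
                global_ims_pct=0, global_ims_display_pct=0, shift_ms=0.0,
                lat_ms=lat, captured=(lat is None or lat <= 0.0),
                degenerate_leads=tuple(LEAD_NAMES),
                true_class=b.true_class, source=b.source))
    return out


def shift_search(beat: Beat, template: Template, max_shift_ms: float,
                 *, align: str = "onset") -> tuple[float, IMSResult]:
    """Exhaustive manual-shift search mirroring the system's manual matching.

    Integer-sample manual shifts in [-max, +max] are tried on top of the
    automatic alignment; the returned shift is the total alignment shift of
    the best result (ties: smallest \\|manual shift\\|, negative first).
    """
    if max_shift_ms < 0:
        raise ValueError("max_shift_ms must be non-negative")
    fs = template.beat.sampling_rate_hz
    max_samp = int(math.floor(max_shift_ms * fs / 1000.0))
    candidates = sorted(range(-max_samp, max_samp + 1),
                        key=lambda s: (abs(s), s > 0))
    best: IMSResult | None = None
    for s in candidates:
        try:
            res = score_beat(beat, template, shift_ms=s * 1000.0 / fs,
                             align=align)
        except ValueError:
            continue
        if best is None or res.global_ims_pct > best.global_ims_pct:
            best = res
    if best is None:
        raise ValueError("no admissible shift kept the ISI inside the beat")
    return best.shift_ms, best


def filter_captured(results) -> list[IMSResult]:
    """Keep only captured beats (LAT <= 0); order preserved.

    Beats without a stimulus (intrinsic) carry no LAT and are kept.
    """
    return [r for r in results if r.lat_ms is None or r.lat_ms <= 0.0]
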