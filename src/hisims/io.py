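"""CSV/JSON interchange for beats and scores.

Beat CSV (long format): one row per sample with columns
``beat_id, source, true_class, stimulus_time_ms, lead, sample_idx, time_ms,
value_mv``; UTF-8, '.' decimal separator, LF or CRLF.  Scores CSV: one row
per beat with the 12 per-lead coefficients and the global IMS.  Write-then-
read round-trips all fields to within 1e-9.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .morphology import IMSResult
from .synthetic_ecg import LEAD_NAMES, Beat, BeatClass

__all__ = [
    "write_beats", "read_beats", "write_scores", "read_scores",
    "write_manifest", "BeatParseError",
]

_BEAT_COLUMNS = ["beat_id", "source", "true_class", "stimulus_time_ms",
                 "lead", "sample_idx", "time_ms", "value_mv"]
_FLOAT_FMT = "%.10g"


class BeatParseError(ValueError):
    """Malformed beat CSV."""


def write_beats(beats, path) -> None:
    """Write a cohort to the long-format beat CSV."""
    frames = []
    for beat in beats:
        t = beat.times_ms
        n = beat.n_samples
        frames.append(pd.DataFrame({
            "beat_id": np.repeat(beat.beat_id, 12 * n),
            "source": beat.source,
            "true_class": beat.true_class.value,
            "stimulus_time_ms": (np.nan if beat.stimulus_time_ms is None
                                 else beat.stimulus_time_ms),
            "lead": np.repeat(LEAD_NAMES, n),
            "sample_idx": np.tile(np.arange(n), 12),
            "time_ms": np.tile(t, 12),
            "value_mv": beat.samples.reshape(-1),
        }))
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_beats(path) -> list[Beat]:
    """Read a long-format beat CSV back into Beat objects.

    Validates the column set, the 12-lead layout and per-lead sample-index
    monotonicity; errors name the offending beat or row.
    """
    df = pd.read_csv(path)
    missing = set(_BEAT_COLUMNS) - set(df.columns)
    if missing:
        raise BeatParseError(f"missing columns: {sorted(missing)}")
    bad_leads = set(df["lead"].unique()) - set(LEAD_NAMES)
    if bad_leads:
        raise BeatParseError(f"unknown lead names: {sorted(bad_leads)}")

    beats = []
    for beat_id, grp in df.groupby("beat_id", sort=False):
        leads = grp["lead"].unique()
        if len(leads) != 12:
            raise BeatParseError(
                f"beat {beat_id!r} has {len(leads)} leads, expected 12")
        lengths = grp.groupby("lead")["sample_idx"].count()
        if lengths.nunique() != 1:
            raise BeatParseError(f"beat {beat_id!r}: unequal lead lengths")
        n = int(lengths.iloc[0])
        samples = np.empty((12, n))
        for k, lead in enumerate(LEAD_NAMES):
            sub = grp[grp["lead"] == lead]
            idx = sub["sample_idx"].to_numpy()
            if np.any(np.diff(idx) <= 0):
                row = sub.index[np.argmax(np.diff(idx) <= 0) + 1]
                raise BeatParseError(
                    f"beat {beat_id!r}, lead {lead}: non-monotone "
                    f"sample_idx at csv row {row + 2}")
            samples[k] = sub["value_mv"].to_numpy()
        t = grp[grp["lead"] == LEAD_NAMES[0]]["time_ms"].to_numpy()
        fs = 1000.0 / float(np.median(np.diff(t))) if n > 1 else 1000.0
        stim = grp["stimulus_time_ms"].iloc[0]
        row0 = grp.iloc[0]
        beats.append(Beat(
            beat_id=str(beat_id),
            samples=samples,
            sampling_rate_hz=fs,
            stimulus_time_ms=None if pd.isna(stim) else float(stim),
            true_class=BeatClass(row0["true_class"]),
            source=str(row0["source"]),
        ))
    return beats


_SCORE_BASE = ["beat_id", "source", "true_class"]
_SCORE_TAIL = ["global_ims_pct", "display_pct", "shift_ms", "lat_ms",
               "captured"]


def scores_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"beat_id": r.beat_id, "source": r.source,
               "true_class": r.true_class.value}
        for lead, s in zip(LEAD_NAMES, r.per_lead_scores):
            row[f"score_{lead}"] = s
        row.update(global_ims_pct=r.global_ims_pct,
                   display_pct=r.global_ims_display_pct,
                   shift_ms=r.shift_ms,
                   lat_ms=np.nan if r.lat_ms is None else r.lat_ms,
                   captured=r.captured)
        rows.append(row)
    return pd.DataFrame(rows)


def write_scores(results, path) -> None:
    scores_frame(results).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_scores(path) -> list[IMSResult]:
    df = pd.read_csv(path)
    expected = _SCORE_BASE + [f"score_{l}" for l in LEAD_NAMES] + _SCORE_TAIL
    missing = set(expected) - set(df.columns)
    if missing:
        raise BeatParseError(f"missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        lat = row["lat_ms"]
        out.append(IMSResult(
            beat_id=str(row["beat_id"]),
            per_lead_scores=tuple(float(row[f"score_{l}"]) for l in LEAD_NAMES),
            global_ims_pct=int(row["global_ims_pct"]),
            global_ims_display_pct=int(row["display_pct"]),
            shift_ms=float(row["shift_ms"]),
            lat_ms=None if pd.isna(lat) else float(lat),
            captured=bool(row["captured"]),
            true_class=BeatClass(row["true_class"]),
            source=str(row["source"]),
        ))
    return out


def write_manifest(path, *, config, counts, seed, source) -> None:
    """Cohort manifest: config echo, per-class counts, seed."""
    from dataclasses import asdict

    def _clean(obj):
        if isinstance(obj, dict):
            return {getattr(k, "value", k): _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        return obj

    payload = {
        "config": _clean(asdict(config)),
        "counts": {getattr(k, "value", str(k)): int(v)
                   for k, v in counts.items()},
        "seed": seed,
        "source": source,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
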