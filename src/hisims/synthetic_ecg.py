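"""Synthetic 12-lead single-beat ECG generation.

Builds the beat cohorts the morphology-matching analysis runs on: narrow
intrinsic QRS complexes, selective His-bundle-paced beats (morphology close
to intrinsic), nonselective fusion beats widened by a pseudodelta onset,
right-ventricular myocardial paced beats with a distinct wide morphology,
plus non-captured and atrial-capture beats whose QRS begins long after the
stimulus.

The waveform model is a sum of Gaussian wavelets (Q, R, S deflections) for
each of two source morphologies -- conduction-system (intrinsic) activation
and direct RV myocardial activation -- projected onto the 12 surface leads
through per-lead amplitude weights.  A paced beat is a convex mixture of the
two sources with myocardial fraction ``w`` (w=0 selective, w=1 pure RV
pacing) plus a pseudodelta ramp spanning the fusion delay.

Every cohort derives its beats from a single intrinsic "template donor":
QRS duration and wavelet shape vary within a cohort by small relative
amounts, the way consecutive beats of one patient vary, while donor-level
draws carry the between-patient spread (QRSd 101 +/- 11 ms intrinsic,
124 +/- 14 ms nonselective-paced).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LEAD_NAMES",
    "BeatClass",
    "PACED_CLASSES",
    "LeadBasis",
    "MixingDist",
    "ClassParams",
    "BeatGenConfig",
    "Beat",
    "ConfigError",
    "make_lead_basis",
    "synth_intrinsic_beat",
    "synth_paced_beat",
    "generate_cohort",
    "measure_qrs_bounds",
    "measure_qrsd",
]

LEAD_NAMES = ("I", "II", "III", "aVR", "aVL", "aVF",
              "V1", "V2", "V3", "V4", "V5", "V6")


class BeatClass(str, enum.Enum):
    INTRINSIC = "INTRINSIC"
    S_HBP = "S_HBP"
    NS_HBP = "NS_HBP"
    RVP = "RVP"
    NO_CAPTURE = "NO_CAPTURE"
    ATRIAL_CAPTURE = "ATRIAL_CAPTURE"
    UNKNOWN = "UNKNOWN"


PACED_CLASSES = frozenset({
    BeatClass.S_HBP, BeatClass.NS_HBP, BeatClass.RVP,
    BeatClass.NO_CAPTURE, BeatClass.ATRIAL_CAPTURE,
})

#: Classes the study's summary tables report (captured paced responses).
CAPTURED_PACED_CLASSES = (BeatClass.S_HBP, BeatClass.NS_HBP, BeatClass.RVP)


class ConfigError(ValueError):
    """Invalid generator configuration."""


# ---------------------------------------------------------------------------
# Lead basis
# ---------------------------------------------------------------------------

# Canonical per-lead amplitude weights (mV at unit source amplitude) for a
# normal-axis narrow QRS.  aVL is deliberately low-amplitude: matching is
# hardest on small signals and the engine must cope with that.
_INTRINSIC_WEIGHTS = np.array(
    [0.55, 0.95, 0.40, -0.75, 0.12, 0.70,
     -0.45, 0.60, 0.85, 1.10, 0.95, 0.70])

# RV septal myocardial activation as seen from the stimulation site reached
# by the His lead (few discordant leads) vs. by the roving diagnostic
# catheter (more discordant leads, lower concordance with the intrinsic
# pattern).  The two variants reproduce the source-dependent RVP score
# levels seen when pacing from the two tools.
_MYO_WEIGHTS = {
    "his_lead": np.array(
        [0.80, 0.55, -0.30, -0.65, 0.45, 0.25,
         -0.90, -0.75, 0.50, 0.80, 0.90, 0.85]),
    "catheter": np.array(
        [0.85, 0.30, -0.45, -0.55, 0.50, -0.35,
         -0.95, -0.80, -0.60, 0.40, 0.55, 0.80]),
}


@dataclass(frozen=True)
class LeadBasis:
    """Per-lead projection weights for the two source morphologies."""

    lead_names: tuple[str, ...]
    intrinsic_weights: np.ndarray
    myocardial_weights: np.ndarray

    def __post_init__(self):
        if len(self.lead_names) != 12:
            raise ConfigError("a lead basis needs exactly 12 leads")
        a = np.asarray(self.intrinsic_weights, dtype=float)
        b = np.asarray(self.myocardial_weights, dtype=float)
        if a.shape != (12,) or b.shape != (12,):
            raise ConfigError("weight vectors must have 12 entries")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ConfigError("weights must be finite")
        cos = float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
        if abs(cos) > 0.99:
            raise ConfigError("source weight vectors are collinear")


def make_lead_basis(seed: int, myo_variant: str = "his_lead") -> LeadBasis:
    """Return the 12-lead weights for both sources, lightly perturbed.

    Deterministic in ``seed``; the perturbation (1.5% relative) stands in
    for electrode placement and torso differences without moving the
    calibrated score distributions.
    """
    if myo_variant not in _MYO_WEIGHTS:
        raise ConfigError(f"unknown myocardial weight variant {myo_variant!r}")
    rng = np.random.default_rng(seed)
    a = _INTRINSIC_WEIGHTS * (1.0 + 0.015 * rng.standard_normal(12))
    b = _MYO_WEIGHTS[myo_variant] * (1.0 + 0.015 * rng.standard_normal(12))
    return LeadBasis(LEAD_NAMES, a, b)


# ---------------------------------------------------------------------------
# Wavelet machinery
# ---------------------------------------------------------------------------

# (amplitude, center, width) per deflection, center/width as fractions of a
# nominal duration scale D.  Intrinsic: crisp Q-R-S; myocardial: slurred,
# broad, late-dominant.
INTRINSIC_WAVELETS = ((-0.25, 0.17, 0.055),
                      (1.00, 0.47, 0.100),
                      (-0.35, 0.75, 0.080))
MYO_WAVELETS = ((0.18, 0.08, 0.090),
                (0.90, 0.30, 0.168),
                (-0.45, 0.75, 0.110))


def _wave(t_ms: np.ndarray, wavelets, scale: float, t0_ms: float) -> np.ndarray:
    """Evaluate a wavelet-sum source morphology on a time grid (ms)."""
    s = np.zeros_like(t_ms, dtype=float)
    for amp, c, w in wavelets:
        s += amp * np.exp(-0.5 * ((t_ms - t0_ms - c * scale) / (w * scale)) ** 2)
    return s


def _shape_bounds(wavelets) -> tuple[float, float]:
    """Onset/offset of a unit-scale shape at the 5%-of-peak criterion.

    Returned as fractions of the duration scale; both scale linearly with
    D, so one fine-grid pass fixes the scale needed for any target QRSd.
    """
    t = np.arange(-0.6, 2.2, 0.002)
    s = np.abs(_wave(t, wavelets, 1.0, 0.0))
    thr = 0.05 * s.max()
    above = np.nonzero(s >= thr)[0]
    return float(t[above[0]]), float(t[above[-1]])


def _scaled_shape(t_ms, wavelets, qrsd_ms: float, onset_ms: float) -> np.ndarray:
    """Shape whose 5%-threshold onset and duration hit the requested values."""
    on, off = _shape_bounds(wavelets)
    scale = qrsd_ms / (off - on)
    t0 = onset_ms - on * scale
    return _wave(np.asarray(t_ms, dtype=float), wavelets, scale, t0)


def _jitter_wavelets(wavelets, rel_sd: float, rng) -> tuple:
    if rel_sd <= 0:
        return tuple(wavelets)
    out = []
    for amp, c, w in wavelets:
        out.append((amp * (1.0 + rel_sd * rng.standard_normal()),
                    c * (1.0 + 0.5 * rel_sd * rng.standard_normal()),
                    w * (1.0 + rel_sd * rng.standard_normal())))
    return tuple(out)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixingDist:
    """Myocardial fraction ``w`` drawn from Beta(a, b) rescaled to [lo, hi]."""

    a: float = 2.0
    b: float = 2.0
    lo: float = 0.0
    hi: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.lo <= self.hi <= 1.0):
            raise ConfigError("mixing support must satisfy 0 <= lo <= hi <= 1")
        if self.a <= 0 or self.b <= 0:
            raise ConfigError("Beta shape parameters must be positive")

    def draw(self, rng) -> float:
        if self.hi == self.lo:
            return self.lo
        return self.lo + (self.hi - self.lo) * rng.beta(self.a, self.b)


@dataclass(frozen=True)
class ClassParams:
    """Per-class generator knobs."""

    mixing: MixingDist = MixingDist()
    #: relative SD of the per-beat wavelet-parameter jitter (beat-to-beat
    #: morphology variation on top of the template shape)
    morph_jitter: float = 0.02
    #: relative SD of the intrinsic-part QRS duration vs. the template's
    qrsd_rel_sd: float = 0.03
    #: relative SD of per-beat myocardial lead-weight jitter (pacing-site
    #: variation across the septum; only meaningful for classes with w > 0)
    lead_jitter: float = 0.0

    def __post_init__(self):
        if self.morph_jitter < 0 or self.qrsd_rel_sd < 0 or self.lead_jitter < 0:
            raise ConfigError("jitter SDs must be non-negative")


def _default_class_params() -> dict:
    return {
        BeatClass.INTRINSIC: ClassParams(MixingDist(), 0.02, 0.03),
        BeatClass.S_HBP: ClassParams(MixingDist(2.0, 2.0, 0.0, 0.05), 0.06, 0.04),
        BeatClass.NS_HBP: ClassParams(MixingDist(3.0, 3.0, 0.18, 0.42), 0.05, 0.03),
        BeatClass.RVP: ClassParams(MixingDist(1.0, 1.0, 1.0, 1.0), 0.12, 0.03),
        BeatClass.NO_CAPTURE: ClassParams(MixingDist(), 0.02, 0.03),
        BeatClass.ATRIAL_CAPTURE: ClassParams(MixingDist(), 0.02, 0.03),
    }


@dataclass(frozen=True)
class BeatGenConfig:
    """Study conditions for one simulated cohort.

    Times in ms, voltages in mV, sample indices 0-based, windows half-open.
    """

    sampling_rate_hz: float = 1000.0
    window_ms: float = 450.0
    #: stimulus time within the window for paced beats
    stim_time_ms: float = 100.0
    #: QRS onset within the window for unpaced (intrinsic) beats
    intrinsic_onset_ms: float = 130.0
    #: (mean, SD) of the narrow intrinsic QRS duration, between-patient
    intrinsic_qrsd_ms: tuple[float, float] = (101.0, 11.0)
    #: (mean, SD) of the nonselective paced QRS duration
    ns_qrsd_ms: tuple[float, float] = (124.0, 14.0)
    #: (mean, SD) of the pure myocardial (RVP) QRS duration
    rvp_qrsd_ms: tuple[float, float] = (155.0, 15.0)
    #: (mean, SD) of the stimulus-to-QRS latency of selective capture
    his_latency_ms: tuple[float, float] = (28.0, 4.0)
    noise_sd_mv: float = 0.02
    jitter_ms: float = 1.0
    #: pseudodelta ramp amplitude at w=1, in units of the source amplitude
    pseudodelta_amp: float = 0.40
    myo_variant: str = "his_lead"
    class_params: dict = field(default_factory=_default_class_params)
    seed: int | None = None

    def __post_init__(self):
        if self.sampling_rate_hz <= 0:
            raise ConfigError("sampling_rate_hz must be positive")
        if self.window_ms < 50:
            raise ConfigError("window_ms too short to hold a beat")
        for name in ("intrinsic_qrsd_ms", "ns_qrsd_ms", "rvp_qrsd_ms",
                     "his_latency_ms"):
            mean, sd = getattr(self, name)
            if sd < 0 or mean <= 0:
                raise ConfigError(f"{name}: mean must be > 0 and SD >= 0")
        if self.noise_sd_mv < 0 or self.jitter_ms < 0:
            raise ConfigError("noise/jitter SDs must be non-negative")
        if self.myo_variant not in _MYO_WEIGHTS:
            raise ConfigError(f"unknown myocardial variant {self.myo_variant!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.window_ms * self.sampling_rate_hz / 1000.0))

    def params(self, cls: BeatClass) -> ClassParams:
        return self.class_params[cls]


# ---------------------------------------------------------------------------
# Beat container
# ---------------------------------------------------------------------------

@dataclass
class Beat:
    """One cardiac cycle as a 12 x T matrix of lead voltages (mV)."""

    beat_id: str
    samples: np.ndarray
    sampling_rate_hz: float
    stimulus_time_ms: float | None
    true_class: BeatClass
    source: str  # "catheter" | "lead"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != 12:
            raise ValueError("samples must be a 12 x T matrix")
        if self.samples.shape[1] < 2:
            raise ValueError("a beat needs at least 2 samples per lead")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("voltages must be finite")
        paced = self.true_class in PACED_CLASSES
        if paced and self.stimulus_time_ms is None:
            raise ValueError("paced beats need stimulus_time_ms")
        if self.true_class == BeatClass.INTRINSIC and self.stimulus_time_ms is not None:
            raise ValueError("intrinsic beats carry no stimulus time")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * 1000.0 / self.sampling_rate_hz


# ---------------------------------------------------------------------------
# QRS duration measurement
# ---------------------------------------------------------------------------

_MIN_RUN = 5  # samples that must stay above threshold to open/close the QRS


def measure_qrs_bounds(samples: np.ndarray, sampling_rate_hz: float
                       ) -> tuple[float, float]:
    """QRS onset/offset (ms) on the cross-lead RMS signal.

    Threshold is 5% of the peak RMS, lifted to 1.6x the median RMS when
    baseline noise would otherwise dominate; a crossing only counts when at
    least 5 consecutive samples stay above threshold, so isolated noise
    excursions never open the QRS.
    """
    samples = np.asarray(samples, dtype=float)
    rms = np.sqrt(np.mean(samples ** 2, axis=0))
    peak = rms.max()
    if peak <= 0:
        raise ValueError("no QRS detected: all-zero beat")
    thr = max(0.05 * peak, 1.6 * float(np.median(rms)))
    above = rms >= thr
    if not above.any():
        raise ValueError("no QRS detected: signal never exceeds threshold")
    # indices opening / closing a run of >= _MIN_RUN above-threshold samples
    kernel = np.ones(_MIN_RUN, dtype=int)
    runs = np.convolve(above.astype(int), kernel, mode="valid") == _MIN_RUN
    starts = np.nonzero(runs)[0]
    if starts.size == 0:  # QRS narrower than the run criterion
        idx = np.nonzero(above)[0]
        onset_i, offset_i = idx[0], idx[-1]
    else:
        onset_i = starts[0]
        offset_i = starts[-1] + _MIN_RUN - 1
    dt = 1000.0 / sampling_rate_hz

    # refine both crossings to sub-sample precision by linear interpolation;
    # skip for discontinuous edges (previous sample far below threshold)
    onset = onset_i * dt
    if onset_i > 0 and thr > rms[onset_i - 1] >= 0.25 * thr:
        frac = (thr - rms[onset_i - 1]) / (rms[onset_i] - rms[onset_i - 1])
        onset = (onset_i - 1 + float(np.clip(frac, 0.0, 1.0))) * dt
    offset = (offset_i + 1) * dt
    if offset_i + 1 < rms.size and thr > rms[offset_i + 1] >= 0.25 * thr:
        frac = (rms[offset_i] - thr) / (rms[offset_i] - rms[offset_i + 1])
        offset = (offset_i + float(np.clip(frac, 0.0, 1.0))) * dt
    return onset, offset


def measure_qrsd(beat: Beat) -> float:
    """Measured QRS duration (ms): 5%-of-peak RMS onset to offset."""
    on, off = measure_qrs_bounds(beat.samples, beat.sampling_rate_hz)
    return off - on


# ---------------------------------------------------------------------------
# Beat synthesis
# ---------------------------------------------------------------------------

def _finish_beat(config: BeatGenConfig, basis: LeadBasis, rng,
                 intrinsic_shape, myo_shape, w: float, ramp,
                 *, beat_id, stim, cls, source, meta,
                 lead_jitter: float = 0.0) -> Beat:
    a = basis.intrinsic_weights[:, None]
    b = basis.myocardial_weights[:, None]
    if lead_jitter > 0:
        b = b * (1.0 + lead_jitter * rng.standard_normal((12, 1)))
    samples = np.zeros((12, config.n_samples))
    if intrinsic_shape is not None:
        samples += (1.0 - w) * a * intrinsic_shape[None, :]
    if myo_shape is not None and w > 0:
        samples += w * b * myo_shape[None, :]
    if ramp is not None and w > 0:
        samples += config.pseudodelta_amp * w * b * ramp[None, :]
    if config.noise_sd_mv > 0:
        samples += rng.normal(0.0, config.noise_sd_mv, samples.shape)
    meta = dict(meta)
    meta.setdefault("w", w)
    return Beat(beat_id, samples, config.sampling_rate_hz,
                stim, cls, source, meta)


def _draw_qrsd(config: BeatGenConfig, rng) -> float:
    mean, sd = config.intrinsic_qrsd_ms
    return float(np.clip(rng.normal(mean, sd), 60.0, 160.0))


def synth_intrinsic_beat(config: BeatGenConfig, rng,
                         *, basis: LeadBasis | None = None,
                         beat_id: str = "intrinsic-0000",
                         source: str = "lead") -> Beat:
    """One narrow intrinsic beat; QRSd drawn from the between-patient
    distribution, wavelet shape lightly individualised."""
    if basis is None:
        basis = make_lead_basis(0, config.myo_variant)
    cp = config.params(BeatClass.INTRINSIC)
    qrsd = _draw_qrsd(config, rng)
    wavelets = _jitter_wavelets(INTRINSIC_WAVELETS, cp.morph_jitter, rng)
    onset = config.intrinsic_onset_ms + round(rng.normal(0.0, config.jitter_ms))
    t = np.arange(config.n_samples) * 1000.0 / config.sampling_rate_hz
    shape = _scaled_shape(t, wavelets, qrsd, onset)
    meta = {"wavelets": wavelets, "qrsd_ms": qrsd, "true_onset_ms": onset,
            "paced_latents": _draw_paced_latents(config, qrsd, rng)}
    return _finish_beat(config, basis, rng, shape, None, 0.0, None,
                        beat_id=beat_id, stim=None,
                        cls=BeatClass.INTRINSIC, source=source, meta=meta)


def _draw_paced_latents(config: BeatGenConfig, qrsd: float, rng) -> dict:
    """Patient-level pacing characteristics tied to one template donor.

    The pseudodelta widening and its onset/terminal split are properties of
    a pacing site, near-constant from beat to beat within one patient; only
    their between-patient spread follows the published paced-QRSd SD.
    """
    ns_mean, ns_sd = config.ns_qrsd_ms
    intr_mean, _ = config.intrinsic_qrsd_ms
    # site-level widening around the published mean gap, proportional to the
    # patient's own QRS width; combined with the template's QRSd draw this
    # carries the paced-QRSd spread
    widen = float(np.clip(rng.normal(ns_mean - intr_mean, 0.5), 22.0, 24.0)
                  * qrsd / intr_mean)
    return {
        "ns_widen_ms": widen,
        "ns_onset_frac": float(rng.uniform(0.33, 0.34)),
    }


def _template_meta(template: Beat) -> tuple:
    meta = template.meta
    try:
        return meta["wavelets"], meta["qrsd_ms"]
    except KeyError:  # imported beat: fall back to canonical shape
        return INTRINSIC_WAVELETS, measure_qrsd(template)


def _orth_distortion(shape: np.ndarray, distortion: np.ndarray,
                     t: np.ndarray, win_lo: float, win_hi: float,
                     extra: tuple = ()) -> np.ndarray:
    """Distortion component orthogonalized against the shape.

    Projected out and rescaled over the scoring window [win_lo, win_hi) so
    that mixing ``(1-w)*shape + w*result`` yields a windowed Pearson
    correlation of (1-w)/sqrt((1-w)^2 + w^2) against the clean shape,
    independent of the template geometry.  Components in ``extra`` (e.g.
    the shape's time derivative) are projected out as well, which makes the
    achieved correlation insensitive, to first order, to small residual
    alignment errors.
    """
    win = (t >= win_lo) & (t < win_hi)
    u = shape[win] - shape[win].mean()
    uu = float(u @ u)
    if uu <= 0.0:
        return np.zeros_like(shape)
    e = distortion.astype(float).copy()
    for comp in (shape,) + tuple(extra):
        cw = comp[win] - comp[win].mean()
        cc = float(cw @ cw)
        if cc <= 0.0:
            continue
        ew = e[win] - e[win].mean()
        e = e - (float(cw @ ew) / cc) * comp
    ec = e[win] - e[win].mean()
    norm = math.sqrt(max(float(ec @ ec), 1e-18) / uu)
    return e / norm


def _derived_intrinsic_shape(template: Beat, cp: ClassParams,
                             config: BeatGenConfig, rng, onset_ms: float,
                             t: np.ndarray, qrsd_rel: float | None = None):
    """Intrinsic-source shape re-generated from the template's parameters
    with within-patient jitter; returns (shape, qrsd, wavelets)."""
    wavelets0, qrsd0 = _template_meta(template)
    rel = cp.qrsd_rel_sd if qrsd_rel is None else qrsd_rel
    qrsd = qrsd0 * (1.0 + rel * rng.standard_normal()) if rel > 0 else qrsd0
    qrsd = float(np.clip(qrsd, 55.0, 170.0))
    wavelets = _jitter_wavelets(wavelets0, cp.morph_jitter, rng)
    return _scaled_shape(t, wavelets, qrsd, onset_ms), qrsd, wavelets


def synth_paced_beat(cls: BeatClass, template: Beat, config: BeatGenConfig,
                     rng, *, basis: LeadBasis | None = None,
                     beat_id: str | None = None, source: str = "lead",
                     w_override: float | None = None) -> Beat:
    """One paced beat of the requested response class.

    The intrinsic component reuses the template donor's wavelet parameters
    (within-patient jitter only); the myocardial component is mixed in with
    fraction ``w`` drawn from the class's mixing distribution.  With
    ``w_override=0`` and zero noise/jitter the waveform is exactly the
    template morphology shifted to the paced timing.
    """
    cls = BeatClass(cls)
    if cls not in PACED_CLASSES:
        raise ValueError(f"{cls.value} is not a paced beat class")
    if basis is None:
        basis = make_lead_basis(0, config.myo_variant)
    cp = config.params(cls)
    stim = config.stim_time_ms
    t = np.arange(config.n_samples) * 1000.0 / config.sampling_rate_hz
    if beat_id is None:
        beat_id = f"{cls.value}-0000"

    w = cp.mixing.draw(rng) if w_override is None else float(w_override)
    if not 0.0 <= w <= 1.0:
        raise ValueError("mixing weight must lie in [0, 1]")

    myo_shape = None
    ramp = None
    premix_w = None

    if cls is BeatClass.S_HBP:
        lam_mean, lam_sd = config.his_latency_ms
        lam = round(float(np.clip(rng.normal(lam_mean, lam_sd), 15.0, 35.0)))
        onset = stim + lam
        shape, qrsd, wavelets = _derived_intrinsic_shape(
            template, cp, config, rng, onset, t)
        if w > 0:
            # selective capture leaves the activation sequence intact; the
            # residual dissimilarity is a subtle timing/shape perturbation
            # modelled as an admixture of the shape's time derivative,
            # orthogonalized over the scoring window (so the similarity
            # level is an analytic function of w) and tapered so the QRS
            # onset and the isoelectric latency are untouched
            taper = np.clip((t - onset - 8.0) / 12.0, 0.0, 1.0)
            deriv = np.gradient(shape) * taper
            e = _orth_distortion(shape, deriv, t,
                                 onset - 10.0, onset + qrsd + 10.0)
            # random perturbation direction: advance or delay of the
            # terminal activation are equally likely, and first-order
            # coupling with residual alignment error cancels
            sign = 1.0 if rng.random() < 0.5 else -1.0
            shape = (1.0 - w) * shape + w * sign * e
            premix_w, w = w, 0.0  # premixed: skip the myocardial projection
        true_onset = onset
    elif cls is BeatClass.NS_HBP:
        latents = template.meta.get("paced_latents")
        if latents is None:
            _, qrsd0 = _template_meta(template)
            latents = _draw_paced_latents(config, qrsd0, rng)
        # site-level widening, small beat-to-beat wobble
        widen = float(np.clip(latents["ns_widen_ms"] + rng.normal(0.0, 1.5),
                              6.0, 55.0))
        f_on = latents["ns_onset_frac"]
        delta_on = f_on * widen
        onset = stim + delta_on
        shape, qrsd, wavelets = _derived_intrinsic_shape(
            template, cp, config, rng, onset, t)
        # fused myocardial activation: starts at the stimulus, spans the
        # widened QRS, orthogonalized so the similarity level is analytic
        myo = _jitter_wavelets(MYO_WAVELETS, cp.morph_jitter, rng)
        myo_shape = _scaled_shape(t, myo, qrsd + widen, stim)
        e = _orth_distortion(shape, myo_shape, t,
                             stim - 10.0, stim + qrsd + widen + 10.0,
                             extra=(np.gradient(shape),))
        shape = (1.0 - w) * shape + w * e
        # pseudodelta: fast rise over the fusion delay, fading into the QRS.
        # Its prominence floors at half the configured amplitude: any fused
        # capture shows a pseudodelta, so the detected QRS onset reliably
        # sits at the stimulus rather than at the delayed intrinsic body.
        if delta_on > 0:
            rise = np.clip((t - stim) / max(delta_on, 1.0), 0.0, 1.0)
            fade = np.clip(1.0 - (t - onset) / 25.0, 0.0, 1.0)
            amp = config.pseudodelta_amp * (0.5 + 0.5 * w)
            shape = shape + amp * rise * fade
        # terminal slur: the myocardial wavefront also outlasts the
        # conduction-system activation, extending the measured QRS end by
        # the remaining share of the widening
        delta_end = widen - delta_on
        if delta_end > 1.0:
            body_end = onset + qrsd
            slur = np.exp(-0.5 * ((t - (body_end + 0.55 * delta_end))
                                  / (0.35 * delta_end)) ** 2)
            shape = shape - 0.28 * (0.5 + 0.5 * w) * slur
        premix_w, w = w, 0.0
        myo_shape = None
        true_onset = stim
    elif cls is BeatClass.RVP:
        lat = round(float(np.clip(rng.normal(2.0, 1.5), 0.0, 6.0)))
        onset = stim + lat
        rv_mean, rv_sd = config.rvp_qrsd_ms
        _, qrsd0 = _template_meta(template)
        intr_mean, _ = config.intrinsic_qrsd_ms
        qrsd = float(np.clip(rng.normal(rv_mean, rv_sd) * qrsd0 / intr_mean,
                             110.0, 210.0))
        myo = _jitter_wavelets(MYO_WAVELETS, cp.morph_jitter, rng)
        myo_shape = _scaled_shape(t, myo, qrsd, onset)
        shape = None
        if w < 1.0:  # residual conduction-system contribution
            shape, _, _ = _derived_intrinsic_shape(
                template, cp, config, rng, onset, t)
        true_onset = onset
    elif cls is BeatClass.NO_CAPTURE:
        # intrinsic-timed escape beat well after the ineffective stimulus
        onset = stim + round(rng.uniform(60.0, 180.0))
        shape, qrsd, wavelets = _derived_intrinsic_shape(
            template, cp, config, rng, onset, t)
        w = 0.0
        true_onset = onset
    elif cls is BeatClass.ATRIAL_CAPTURE:
        # stimulus captures the atrium; conducted QRS after a PR-like delay
        onset = stim + round(float(np.clip(rng.normal(160.0, 30.0), 80.0, 200.0)))
        shape, qrsd, wavelets = _derived_intrinsic_shape(
            template, cp, config, rng, onset, t)
        # altered P segment: low-amplitude retro-timed P wave
        shape = shape + 0.04 * np.exp(-0.5 * ((t - (stim + 28.0)) / 12.0) ** 2)
        w = 0.0
        true_onset = onset
    else:  # pragma: no cover
        raise ValueError(f"unknown paced class {cls}")

    meta = {"true_onset_ms": true_onset, "latency_ms": true_onset - stim}
    if premix_w is not None:
        meta["w"] = premix_w
    if shape is not None and cls is not BeatClass.RVP:
        meta["qrsd_ms"] = qrsd
        meta["wavelets"] = wavelets
    return _finish_beat(config, basis, rng, shape, myo_shape, w, ramp,
                        beat_id=beat_id, stim=stim, cls=cls,
                        source=source, meta=meta, lead_jitter=cp.lead_jitter)


def _derive_cohort_intrinsic(template: Beat, config: BeatGenConfig, rng,
                             basis: LeadBasis, beat_id: str, source: str) -> Beat:
    """A further intrinsic beat of the same cohort (within-patient jitter)."""
    cp = config.params(BeatClass.INTRINSIC)
    onset = config.intrinsic_onset_ms + round(rng.normal(0.0, config.jitter_ms))
    t = np.arange(config.n_samples) * 1000.0 / config.sampling_rate_hz
    shape, qrsd, wavelets = _derived_intrinsic_shape(
        template, cp, config, rng, onset, t)
    meta = {"wavelets": wavelets, "qrsd_ms": qrsd, "true_onset_ms": onset}
    return _finish_beat(config, basis, rng, shape, None, 0.0, None,
                        beat_id=beat_id, stim=None,
                        cls=BeatClass.INTRINSIC, source=source, meta=meta)


_COHORT_ORDER = (BeatClass.INTRINSIC, BeatClass.S_HBP, BeatClass.NS_HBP,
                 BeatClass.RVP, BeatClass.NO_CAPTURE, BeatClass.ATRIAL_CAPTURE)


def generate_cohort(config: BeatGenConfig, counts: dict, source: str,
                    seed: int) -> list[Beat]:
    """Generate a labelled cohort of beats, reproducibly for a fixed seed.

    ``counts`` maps class labels (BeatClass or their string names) to
    non-negative beat counts.  The first intrinsic beat doubles as the
    cohort's template donor: every other beat derives its morphology from
    it, the way all beats of one patient share one template.
    """
    if source not in ("catheter", "lead"):
        raise ValueError("source must be 'catheter' or 'lead'")
    counts = {BeatClass(k): int(v) for k, v in counts.items()}
    for cls, n in counts.items():
        if n < 0:
            raise ValueError(f"negative count for {cls.value}")
    rng = np.random.default_rng(seed)
    basis = make_lead_basis(seed, config.myo_variant)

    template = synth_intrinsic_beat(
        config, rng, basis=basis,
        beat_id=f"{source}-INTRINSIC-0000", source=source)

    beats: list[Beat] = []
    for cls in _COHORT_ORDER:
        n = counts.get(cls, 0)
        for i in range(n):
            beat_id = f"{source}-{cls.value}-{i:04d}"
            if cls is BeatClass.INTRINSIC:
                if i == 0:
                    beats.append(template)
                else:
                    beats.append(_derive_cohort_intrinsic(
                        template, config, rng, basis, beat_id, source))
            else:
                beats.append(synth_paced_beat(
                    cls, template, config, rng, basis=basis,
                    beat_id=beat_id, source=source))
    return beats
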