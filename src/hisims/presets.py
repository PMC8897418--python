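"""Calibrated cohort presets.

Two named presets mirror the study's two pacing tools: ``his_lead``
(stimulation from the pacing lead, stable contact, concordant RVP pattern)
and ``catheter`` (roving diagnostic catheter, noisier contact, more
discordant myocardial morphology).  Their mixing/noise parameters were
tuned once against this package's own IMS engine so that cohort score
quartiles reproduce the study's per-class distributions; they are study
conditions, not user dials.
"""

from __future__ import annotations

from .synthetic_ecg import BeatClass, BeatGenConfig, ClassParams, MixingDist

__all__ = ["PRESET_NAMES", "preset_config", "TABLE2_COUNTS"]

PRESET_NAMES = ("his_lead", "catheter")

#: Published per-class beat counts for each pacing tool (the intrinsic
#: reference pool is shared).
TABLE2_COUNTS = {
    "his_lead": {
        BeatClass.INTRINSIC: 354,
        BeatClass.S_HBP: 478,
        BeatClass.NS_HBP: 268,
        BeatClass.RVP: 125,
    },
    "catheter": {
        BeatClass.INTRINSIC: 354,
        BeatClass.S_HBP: 85,
        BeatClass.NS_HBP: 126,
        BeatClass.RVP: 110,
    },
}


def _his_lead_config() -> BeatGenConfig:
    return BeatGenConfig(
        noise_sd_mv=0.006,
        rvp_qrsd_ms=(150.0, 12.0),
        myo_variant="his_lead",
        class_params={
            BeatClass.INTRINSIC: ClassParams(MixingDist(), 0.02, 0.03),
            BeatClass.S_HBP: ClassParams(
                MixingDist(4.5, 1.6, 0.12, 0.30), 0.008, 0.006),
            BeatClass.NS_HBP: ClassParams(
                MixingDist(4.0, 4.0, 0.08, 0.18), 0.02, 0.006),
            BeatClass.RVP: ClassParams(
                MixingDist(1.1, 0.32, 0.58, 1.0), 0.10, 0.03, lead_jitter=0.5),
            BeatClass.NO_CAPTURE: ClassParams(MixingDist(), 0.02, 0.03),
            BeatClass.ATRIAL_CAPTURE: ClassParams(MixingDist(), 0.02, 0.03),
        },
    )


def _catheter_config() -> BeatGenConfig:
    return BeatGenConfig(
        noise_sd_mv=0.008,
        rvp_qrsd_ms=(150.0, 12.0),
        myo_variant="catheter",
        class_params={
            BeatClass.INTRINSIC: ClassParams(MixingDist(), 0.02, 0.03),
            BeatClass.S_HBP: ClassParams(
                MixingDist(2.5, 1.4, 0.08, 0.33), 0.012, 0.008),
            BeatClass.NS_HBP: ClassParams(
                MixingDist(3.0, 3.0, 0.06, 0.18), 0.025, 0.008),
            BeatClass.RVP: ClassParams(
                MixingDist(2.2, 0.30, 0.62, 1.0), 0.12, 0.03, lead_jitter=0.8),
            BeatClass.NO_CAPTURE: ClassParams(MixingDist(), 0.02, 0.03),
            BeatClass.ATRIAL_CAPTURE: ClassParams(MixingDist(), 0.02, 0.03),
        },
    )


def preset_config(name: str) -> BeatGenConfig:
    """Return the calibrated generator configuration for a named preset."""
    if name == "his_lead":
        return _his_lead_config()
    if name == "catheter":
        return _catheter_config()
    raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
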