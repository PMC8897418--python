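import numpy as np
import pytest

from hisims import (
    BeatClass, filter_captured, generate_cohort, make_lead_basis,
    make_template, score_beats, synth_intrinsic_beat,
)
from hisims.presets import TABLE2_COUNTS, preset_config
from hisims.synthetic_ecg import CAPTURED_PACED_CLASSES


@pytest.fixture(scope="session")
def his_config():
    return preset_config("his_lead")


@pytest.fixture(scope="session")
def his_cohort(his_config):
    """Full His-lead study cohort (published class counts) plus a handful
    of non-captured and atrial-capture beats, seed 42."""
    counts = dict(TABLE2_COUNTS["his_lead"])
    counts[BeatClass.NO_CAPTURE] = 10
    counts[BeatClass.ATRIAL_CAPTURE] = 10
    return generate_cohort(his_config, counts, "lead", seed=42)


@pytest.fixture(scope="session")
def his_template(his_cohort):
    intrinsic = [b for b in his_cohort if b.true_class is BeatClass.INTRINSIC]
    return make_template(intrinsic[0])


@pytest.fixture(scope="session")
def his_results(his_cohort, his_template):
    return score_beats(his_cohort, his_template)


@pytest.fixture(scope="session")
def intrinsic_scores(his_results):
    return [r.global_ims_pct for r in his_results
            if r.true_class is BeatClass.INTRINSIC]


@pytest.fixture(scope="session")
def captured_paced(his_results):
    """Captured paced beats of the three reportable response classes."""
    paced = [r for r in his_results if r.true_class is not BeatClass.INTRINSIC]
    return [r for r in filter_captured(paced)
            if r.true_class in CAPTURED_PACED_CLASSES]


@pytest.fixture(scope="session")
def basis():
    return make_lead_basis(0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def clean_template(his_config, basis):
    """Noise-free template for exactness checks."""
    from dataclasses import replace
    from hisims.synthetic_ecg import ClassParams, MixingDist

    cfg = replace(
        his_config, noise_sd_mv=0.0, jitter_ms=0.0,
        class_params={cls: ClassParams(MixingDist(1, 1, 0, 0), 0.0, 0.0)
                      for cls in his_config.class_params})
    beat = synth_intrinsic_beat(cfg, np.random.default_rng(5), basis=basis)
    return cfg, beat, make_template(beat)
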