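"""Scoring-engine behaviour: Pearson correlation, onset detection,
template alignment, LAT computation and capture filtering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hisims import (
    Beat, BeatClass, ScoringInterval, compute_lat, detect_qrs_onset,
    filter_captured, make_template, pearson, score_beat, shift_search,
    synth_intrinsic_beat, synth_paced_beat,
)


def _pearson_oracle(x, y):
    """Direct-summation textbook formula, independent of the engine."""
    n = len(x)
    mx = math.fsum(x) / n
    my = math.fsum(y) / n
    sxy = math.fsum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = math.fsum((a - mx) ** 2 for a in x)
    syy = math.fsum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def _pulse_beat(start=40, stop=120, n=300, stim=None,
                cls=BeatClass.UNKNOWN):
    samples = np.zeros((12, n))
    amps = np.linspace(0.5, 1.5, 12)
    samples[:, start:stop] = amps[:, None]
    return Beat("pulse", samples, 1000.0, stim, cls, "lead")


class TestPearson:
    def test_perfect_and_inverse(self):
        assert pearson([0, 1, 2], [0, 2, 4]) == pytest.approx(1.0)
        assert pearson([0, 1, 2], [2, 1, 0]) == pytest.approx(-1.0)

    def test_textbook_example(self):
        # frozen from the direct-summation formula
        assert pearson([1, 2, 3, 5], [2, 2, 4, 5]) == pytest.approx(
            0.9433700705169153, abs=1e-12)

    def test_matches_direct_sum_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = rng.integers(3, 40)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert pearson(x, y) == pytest.approx(_pearson_oracle(x, y),
                                                  abs=1e-12)

    def test_length_mismatch_and_degenerate(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [1, 2, 3])
        assert pearson([1.0, 1.0, 1.0], [0.0, 1.0, 2.0]) == 0.0


class TestOnsetDetection:
    def test_rectangular_pulse(self):
        assert detect_qrs_onset(_pulse_beat()) == pytest.approx(40.0, abs=0.5)

    def test_shift_equivariance(self):
        a = detect_qrs_onset(_pulse_beat(40, 120))
        b = detect_qrs_onset(_pulse_beat(50, 130))
        assert b - a == pytest.approx(10.0, abs=1e-9)

    def test_all_zero_beat_rejected(self):
        beat = Beat("z", np.zeros((12, 100)), 1000.0, None,
                    BeatClass.UNKNOWN, "lead")
        with pytest.raises(ValueError, match="no QRS"):
            detect_qrs_onset(beat)

    def test_close_to_generator_truth(self, his_config):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            beat = synth_intrinsic_beat(his_config, rng)
            err = detect_qrs_onset(beat) - beat.meta["true_onset_ms"]
            assert abs(err) <= 4.0


class TestTemplate:
    def test_rejects_paced_beat(self, his_config, rng):
        tmpl = synth_intrinsic_beat(his_config, rng)
        paced = synth_paced_beat(BeatClass.S_HBP, tmpl, his_config, rng)
        with pytest.raises(ValueError):
            make_template(paced)

    def test_rejects_inverted_isi(self):
        with pytest.raises(ValueError):
            ScoringInterval(110.0, -10.0)

    def test_rejects_isi_outside_window(self, his_config, rng):
        beat = synth_intrinsic_beat(his_config, rng)
        with pytest.raises(ValueError, match="beyond"):
            make_template(beat, ScoringInterval(-10.0, 1000.0))

    def test_default_isi_encloses_qrs(self, his_template):
        from hisims import measure_qrsd
        qrsd = measure_qrsd(his_template.beat)
        assert his_template.isi.start_ms == -10.0
        assert his_template.isi.end_ms == pytest.approx(qrsd + 10.0)

    def test_window_choice_changes_fusion_scores(self, his_config, rng,
                                                 basis):
        # an ISI covering only half the QRS sees different morphology
        tmpl_beat = synth_intrinsic_beat(his_config, rng, basis=basis)
        full = make_template(tmpl_beat)
        half = make_template(tmpl_beat, ScoringInterval(-10.0, 50.0))
        beat = synth_paced_beat(BeatClass.NS_HBP, tmpl_beat, his_config,
                                rng, basis=basis)
        assert (score_beat(beat, full).global_ims_pct
                != score_beat(beat, half).global_ims_pct)


class TestScoreBeat:
    def test_self_match_is_100(self, his_template):
        res = score_beat(his_template.beat, his_template)
        assert res.global_ims_pct == 100
        assert all(s == pytest.approx(1.0) for s in res.per_lead_scores)

    def test_negated_beat_scores_minus_100_displayed_0(self, his_template):
        beat = his_template.beat
        neg = Beat(beat.beat_id, -beat.samples, beat.sampling_rate_hz,
                   None, beat.true_class, beat.source, beat.meta)
        res = score_beat(neg, his_template)
        assert res.global_ims_pct == -100
        assert res.global_ims_display_pct == 0

    def test_scale_invariance(self, his_cohort, his_template):
        beat = his_cohort[400]
        scaled = Beat(beat.beat_id, 3.7 * beat.samples,
                      beat.sampling_rate_hz, beat.stimulus_time_ms,
                      beat.true_class, beat.source, beat.meta)
        a = score_beat(beat, his_template)
        b = score_beat(scaled, his_template)
        assert a.per_lead_scores == pytest.approx(b.per_lead_scores)

    def test_pearson_symmetry_between_beats(self, rng):
        # two beats with identical QRS timing: scoring one against the
        # other's template compares identical windows, so the per-lead
        # coefficients are symmetric
        def beat_with_structure(seed, name):
            r = np.random.default_rng(seed)
            samples = np.zeros((12, 300))
            wave = np.sin(np.linspace(0, np.pi, 80)) \
                + 0.3 * r.normal(size=80)
            samples[:, 40:120] = np.linspace(0.5, 1.5, 12)[:, None] * wave
            return Beat(name, samples, 1000.0, None, BeatClass.UNKNOWN,
                        "lead")

        b1 = beat_with_structure(1, "a")
        b2 = beat_with_structure(2, "b")
        isi = ScoringInterval(-5.0, 80.0)
        r12 = score_beat(b1, make_template(b2, isi), align="none")
        r21 = score_beat(b2, make_template(b1, isi), align="none")
        assert r12.per_lead_scores == pytest.approx(r21.per_lead_scores,
                                                    abs=1e-12)

    def test_degenerate_lead_scored_zero_and_flagged(self, his_template):
        beat = his_template.beat
        samples = beat.samples.copy()
        samples[4] = 0.0  # flatten aVL
        flat = Beat("flat", samples, beat.sampling_rate_hz, None,
                    beat.true_class, beat.source, beat.meta)
        res = score_beat(flat, his_template)
        assert res.per_lead_scores[4] == 0.0
        assert "aVL" in res.degenerate_leads

    def test_bounds(self, his_results):
        for r in his_results:
            assert -100 <= r.global_ims_pct <= 100
            assert 0 <= r.global_ims_display_pct <= 100
            assert all(abs(s) <= 1.0 for s in r.per_lead_scores)


class TestShiftSearch:
    def test_recovers_known_delay(self, clean_template):
        _, tmpl_beat, template = clean_template
        delayed = Beat("d", np.roll(tmpl_beat.samples, 8, axis=1),
                       tmpl_beat.sampling_rate_hz, None,
                       tmpl_beat.true_class, tmpl_beat.source)
        best, res = shift_search(delayed, template, 20.0)
        assert best == pytest.approx(-8.0, abs=0.6)
        assert res.global_ims_pct == 100

    def test_zero_budget_equals_plain_scoring(self, his_cohort,
                                              his_template):
        beat = his_cohort[500]
        _, res = shift_search(beat, his_template, 0.0)
        assert res.global_ims_pct == score_beat(beat,
                                                his_template).global_ims_pct

    def test_never_worse_than_unshifted(self, his_cohort, his_template):
        ns = [b for b in his_cohort
              if b.true_class is BeatClass.NS_HBP][:50]
        for beat in ns:
            _, best = shift_search(beat, his_template, 10.0)
            assert (best.global_ims_pct
                    >= score_beat(beat, his_template).global_ims_pct)


class TestLatAndCapture:
    def test_lat_arithmetic(self):
        beat = _pulse_beat(start=160, stop=240, stim=100.0)
        assert compute_lat(beat, tolerance_ms=40.0) == pytest.approx(
            20.0, abs=0.5)

    def test_unpaced_beat_rejected(self, his_template):
        with pytest.raises(ValueError):
            compute_lat(his_template.beat)

    def test_captured_classes_have_nonpositive_lat(self, his_results):
        for r in his_results:
            if r.true_class in (BeatClass.S_HBP, BeatClass.NS_HBP,
                                BeatClass.RVP):
                assert r.lat_ms <= 0.0

    def test_filter_is_order_preserving_and_empty_safe(self, his_results):
        assert filter_captured([]) == []
        kept = filter_captured(his_results)
        ids = [r.beat_id for r in his_results if r.lat_ms is None
               or r.lat_ms <= 0]
        assert [r.beat_id for r in kept] == ids

    def test_high_scoring_non_captured_beat_still_excluded(self,
                                                           his_results):
        nc = [r for r in his_results
              if r.true_class is BeatClass.NO_CAPTURE]
        assert nc, "cohort contains non-captured beats"
        # intrinsic-timed escape beats match the template almost perfectly,
        # yet every one is excluded on timing grounds
        assert all(r.global_ims_pct >= 95 for r in nc)
        assert all(r.lat_ms > 0 for r in nc)
        kept_ids = {r.beat_id for r in filter_captured(his_results)}
        assert all(r.beat_id not in kept_ids for r in nc)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(-5, 5), min_size=3, max_size=30),
       st.floats(0.1, 10.0))
def test_pearson_scale_shift_invariance(values, scale):
    x = np.asarray(values)
    y = np.sin(np.arange(len(values)))
    if np.ptp(x) == 0:
        assert pearson(x, y) == 0.0
    elif np.ptp(x * scale) > 1e-6:  # keep clear of cancellation loss
        assert pearson(x * scale + 1.0, y) == pytest.approx(
            pearson(x, y), abs=1e-7)
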