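"""Generator determinism, generator/analyzer consistency, parameter recovery."""

from dataclasses import replace

import numpy as np
import pytest

from cprqual import (
    Pause,
    SyntheticConfig,
    ValidationError,
    classify_depth,
    detect_pauses,
    generate_attempt,
    generate_cohort,
    minute_summaries,
    nfr_series,
    reference_cohort,
    reference_configs,
)


def test_same_seed_same_record():
    cfg = SyntheticConfig(attempt_id="S", depth_noise_sd_mm=1.0, rate_noise_sd=2.0, seed=42)
    assert generate_attempt(cfg) == generate_attempt(cfg)


def test_different_seed_different_record():
    cfg = SyntheticConfig(attempt_id="S", depth_noise_sd_mm=1.0, seed=1)
    assert generate_attempt(cfg) != generate_attempt(
        SyntheticConfig(attempt_id="S", depth_noise_sd_mm=1.0, seed=2)
    )


def test_noise_free_attempt_is_exactly_on_baseline():
    cfg = SyntheticConfig(attempt_id="NF", depth_baseline_mm=45.0, rate_baseline=110.0)
    rec = generate_attempt(cfg)
    summ = minute_summaries(rec)
    assert all(s.mean_depth == pytest.approx(45.0, abs=1e-9) for s in summ)
    assert all(s.rate == pytest.approx(110.0, rel=1e-9) for s in summ)
    assert classify_depth(summ).label == "good"


def test_noise_free_decay_matches_config_depth_function():
    """Analyzer minute means equal the configured depth model at event times."""
    cfg = SyntheticConfig(
        attempt_id="D",
        depth_baseline_mm=44.0,
        depth_decay_onset_min=6,
        depth_decay_slope_mm_per_min=-1.5,
        rate_baseline=108.0,
    )
    rec = generate_attempt(cfg)
    summ = minute_summaries(rec)
    times = np.asarray(rec.times)
    for s in summ:
        sel = times[(times >= 60 * (s.minute - 1)) & (times < 60 * s.minute)]
        expected = np.mean([cfg.depth_mean(t) for t in sel])
        assert s.mean_depth == pytest.approx(expected, abs=1e-9)


def test_scheduled_pauses_recovered_and_nfr_matches_construction():
    pauses = (
        Pause(0.0, 10.0, "assessment"),
        Pause(100.0, 20.0, "defibrillation"),
        Pause(400.0, 8.0, "rhythm_check"),
    )
    cfg = SyntheticConfig(attempt_id="P", pause_schedule=pauses, rate_baseline=120.0)
    rec = generate_attempt(cfg)
    detected = detect_pauses(rec)
    assert len(detected) == len(pauses)
    # each detected pause covers its scheduled one, overshooting by less than
    # one inter-compression interval (compressions resume exactly at pause end)
    dt = 60.0 / 120.0
    for d, p in zip(detected, pauses):
        assert d.end == pytest.approx(p.end_s, abs=1e-9)
        assert p.start_s - dt <= d.start <= p.start_s + 1e-9
    total = sum(p.duration_s for p in pauses)
    assert nfr_series(rec).overall_nfr == pytest.approx(total / 720.0, abs=dt * 3 / 720.0)


def test_infeasible_schedule_errors():
    with pytest.raises(ValidationError):
        generate_attempt(
            SyntheticConfig(attempt_id="X", pause_schedule=(Pause(0.0, 720.0),))
        )
    with pytest.raises(ValidationError):
        SyntheticConfig(attempt_id="X", pause_schedule=(Pause(0.0, 10.0), Pause(5.0, 10.0)))


def test_cohort_attempts_are_independent():
    base = reference_configs()
    alt = list(base)
    alt[3] = replace(alt[3], seed=alt[3].seed + 1)
    c1, c2 = generate_cohort(base), generate_cohort(alt)
    assert c1[3] != c2[3]
    for i in (0, 1, 2, 4, 10, 18):
        assert c1[i] == c2[i]


def test_duplicate_ids_rejected():
    cfgs = [SyntheticConfig(attempt_id="A"), SyntheticConfig(attempt_id="A")]
    with pytest.raises(ValidationError):
        generate_cohort(cfgs)


def test_reference_cohort_stable_across_calls():
    assert reference_cohort() == reference_cohort()


class TestDecayOnsetRecovery:
    """Simulation: does the classifier find the configured fatigue onset?"""

    @staticmethod
    def _recovered_onsets(baseline, slope, noise, onset, n_seeds):
        seeds = np.random.SeedSequence(987654321).generate_state(n_seeds)
        onsets = []
        for s in seeds:
            cfg = SyntheticConfig(
                attempt_id="R",
                depth_baseline_mm=baseline,
                depth_noise_sd_mm=noise,
                depth_decay_onset_min=onset,
                depth_decay_slope_mm_per_min=slope,
                rate_baseline=110.0,
                seed=int(s),
            )
            lab = classify_depth(minute_summaries(generate_attempt(cfg)))
            onsets.append(lab.onset_minute if lab.label == "decay" else None)
        return onsets

    def test_steep_decay_recovered_exactly(self):
        # slope -2 mm/min drops the onset minute's mean ~0.2 mm below the
        # criterion and the next minute far below it
        onsets = self._recovered_onsets(40.8, -2.0, 0.5, onset=8, n_seeds=200)
        exact = sum(o == 8 for o in onsets) / len(onsets)
        assert exact >= 0.95

    @pytest.mark.parametrize("onset", [3, 8])
    @pytest.mark.parametrize("slope,noise", [(-1.0, 1.0), (-2.0, 1.0), (-1.0, 0.5)])
    def test_recovery_within_one_minute(self, onset, slope, noise):
        onsets = self._recovered_onsets(40.8, slope, noise, onset=onset, n_seeds=200)
        within = sum(o is not None and abs(o - onset) <= 1 for o in onsets) / len(onsets)
        assert within >= 0.95
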