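import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tfstest.staircase import (
    IllegalStateError, RunResult, StaircaseConfig, StaircaseError,
    StaircaseState, is_valid, run, threshold_from_reversals, update,
)

from reference_staircase import reference_track


def replay(cfg: StaircaseConfig, responses):
    """Feed a fixed response sequence to the package engine."""
    state = StaircaseState(cfg)
    for correct in responses:
        if state.terminated:
            break
        update(state, correct)
    return state


class TestUpdate:
    def test_two_correct_steps_harder(self, af_config):
        state = replay(af_config, [True, True])
        assert state.value == pytest.approx(280.0)  # 200 * 1.4

    def test_single_correct_waits(self, af_config):
        state = replay(af_config, [True])
        assert state.value == 200.0
        assert state.n_consecutive_correct == 1

    def test_incorrect_steps_easier_and_resets_counter(self, af_config):
        state = replay(af_config, [True, False])
        assert state.value == pytest.approx(200.0 / 1.4)
        assert state.n_consecutive_correct == 0

    def test_floor_clamp(self):
        cfg = StaircaseConfig.tfs_af(start_value=32.0)
        state = replay(cfg, [False])  # 32/1.4 = 22.86 -> clamped to 30
        assert state.value == 30.0
        assert state.clamped_at_floor == 1

    def test_ipd_track_divides_toward_harder(self, lf_config):
        state = replay(lf_config, [True, True])
        assert state.value == pytest.approx(180.0 / 1.95)

    def test_ceiling_clamp_on_ipd(self, lf_config):
        state = replay(lf_config, [False])
        assert state.value == 180.0  # cannot exceed the 180-deg ceiling

    def test_update_after_termination_raises(self, af_config):
        rng = np.random.default_rng(0)
        state = StaircaseState(af_config)
        while not state.terminated:
            update(state, bool(rng.random() < 0.5))
        with pytest.raises(IllegalStateError):
            update(state, True)


class TestThresholdFromReversals:
    @pytest.mark.parametrize("reversals,expected", [
        ([400.0] * 6, 400.0),
        ([200.0, 800.0] * 3, 400.0),
        # eight reversals: the first two are ignored
        ([100.0, 1000.0] + [400.0] * 6, 400.0),
    ])
    def test_geometric_mean_of_last_six(self, reversals, expected):
        assert threshold_from_reversals(reversals) == pytest.approx(expected)

    def test_too_few_reversals_raises(self):
        with pytest.raises(StaircaseError):
            threshold_from_reversals([400.0] * 5)


class TestIsValid:
    def test_identical_values_valid(self):
        assert is_valid([250.0] * 6)

    def test_large_spread_invalid(self):
        # SD of log10([100]*3 + [1000]*3) = 0.5477 > 0.2
        assert not is_valid([100.0] * 3 + [1000.0] * 3)

    def test_limit_is_inclusive(self):
        vals = [100.0] * 3 + [300.0] * 3
        sd = float(np.std(np.log10(vals), ddof=1))
        assert is_valid(vals, sd_limit=sd)
        assert not is_valid(vals, sd_limit=np.nextafter(sd, 0.0))

    def test_uses_sample_sd(self):
        vals = [100.0, 100.0, 100.0, 100.0, 100.0, 200.0]
        # population SD of the logs is 0.1121 but sample SD is 0.1229
        assert is_valid(vals, sd_limit=0.123)
        assert not is_valid(vals, sd_limit=0.122)

    def test_nonpositive_rejected(self):
        with pytest.raises(StaircaseError):
            is_valid([100.0] * 5 + [-1.0])


class TestRun:
    def test_always_correct_hits_safety_cap(self, af_config):
        res = run(af_config, lambda v: True, rng=0)
        assert res.aborted and not res.valid
        assert res.threshold is None
        assert res.n_trials == af_config.max_trials
        assert "safety cap" in res.abort_reason

    def test_deterministic_responder_matches_reference_trace(self, af_config):
        """'Correct iff value <= 400 Hz' has no randomness: the engine must
        reproduce the independent transcription's trace exactly."""
        responder = lambda v: v <= 400.0
        res = run(af_config, responder, rng=0)

        # replay through the reference transcription
        state_values = [r.value for r in res.trial_log]
        responses = [v <= 400.0 for v in state_values]
        ref = reference_track(responses, start=200.0, factors=(1.4, 1.2, 1.1),
                              n_up=2, harder="increase", floor=30.0)
        assert ref["terminated"]
        assert [x[1] for x in ref["log"]] == state_values
        assert tuple(ref["reversals"]) == res.reversal_values
        expected_thr = float(np.exp(np.mean(np.log(ref["reversals"][-6:]))))
        assert res.threshold == pytest.approx(expected_thr)

    def test_guessing_responder_drifts_to_floor(self, af_config):
        """Pure guessing cannot sustain 2-up progress: the track drifts well
        below the 200-Hz start and a sizable share of runs pin at the 30-Hz
        floor."""
        thresholds, pinned = [], 0
        for seed in range(200):
            gen = np.random.default_rng(seed)
            res = run(af_config, lambda v: bool(gen.random() < 0.5), rng=seed)
            if res.threshold is not None:
                thresholds.append(res.threshold)
                pinned += res.clamped_at_floor > 0
        assert len(thresholds) > 150
        assert np.median(thresholds) < 100.0
        assert np.percentile(thresholds, 25) < 45.0
        assert pinned / len(thresholds) > 0.2

    def test_tfs_lf_track_matches_reference(self, lf_config):
        responder = lambda phi: phi >= 40.0
        res = run(lf_config, responder, rng=0)
        values = [r.value for r in res.trial_log]
        ref = reference_track([v >= 40.0 for v in values], start=180.0,
                              factors=(1.95, 1.56, 1.25), n_up=2,
                              harder="decrease", ceiling=180.0)
        assert [x[1] for x in ref["log"]] == values
        assert tuple(ref["reversals"]) == res.reversal_values

    def test_seed_reproducibility(self, af_config):
        def make_responder(seed):
            gen = np.random.default_rng(seed)
            return lambda v: bool(gen.random() < 0.6)
        a = run(af_config, make_responder(3), rng=3)
        b = run(af_config, make_responder(3), rng=3)
        assert a.trial_log == b.trial_log
        assert a.threshold == b.threshold


class TestOracleEquivalence:
    @pytest.mark.parametrize("harder,factors,start,floor,ceiling", [
        ("increase", (1.4, 1.2, 1.1), 200.0, 30.0, None),
        ("decrease", (1.95, 1.56, 1.25), 180.0, None, 180.0),
    ])
    def test_engine_equals_reference_on_bernoulli_responders(
            self, harder, factors, start, floor, ceiling):
        """Trial-for-trial equality of the engine and the independent
        transcription across 200 seeded stochastic runs."""
        for seed in range(200):
            gen = np.random.default_rng(seed)
            p = 0.4 + 0.4 * (seed % 7) / 6.0
            responses = [bool(x) for x in gen.random(400) < p]

            cfg = StaircaseConfig(
                tracked_variable="frequency" if harder == "increase" else "ipd",
                harder_direction=harder, step_factors=factors,
                start_value=start, floor=floor, ceiling=ceiling)
            state = replay(cfg, responses)
            ref = reference_track(responses, start=start, factors=factors,
                                  n_up=2, harder=harder, floor=floor,
                                  ceiling=ceiling)

            got = [(r.trial, r.value, r.correct, r.reversal, r.factor)
                   for r in state.trial_log]
            assert got == ref["log"], f"divergence at seed {seed}"
            assert state.reversal_values == ref["reversals"]


class TestRunProperties:
    @pytest.mark.parametrize("seed", range(0, 40, 4))
    def test_bounds_reversal_count_and_threshold_rule(self, af_config, seed):
        gen = np.random.default_rng(seed)
        res = run(af_config, lambda v: bool(gen.random() < 0.65), rng=seed)
        if res.aborted:
            return
        values = [r.value for r in res.trial_log]
        assert all(v >= 30.0 for v in values)
        assert len(res.reversal_values) == 8
        assert res.threshold == pytest.approx(
            threshold_from_reversals(res.reversal_values, 6))
        assert res.valid == is_valid(res.reversal_values, 0.2)

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.booleans(), min_size=1, max_size=300))
    def test_arbitrary_response_sequences_respect_invariants(self, responses):
        cfg = StaircaseConfig.tfs_af()
        state = replay(cfg, responses)
        values = [r.value for r in state.trial_log]
        assert all(v >= cfg.floor for v in values)
        assert len(state.reversal_values) <= cfg.total_reversals
        # a logged reversal implies a direction change happened on that trial
        n_marked = sum(r.reversal for r in state.trial_log)
        assert n_marked == len(state.reversal_values)

    def test_config_validation(self):
        with pytest.raises(StaircaseError):
            StaircaseConfig(step_factors=(1.0, 1.2, 1.1))
        with pytest.raises(StaircaseError):
            StaircaseConfig(start_value=20.0, floor=30.0)
        with pytest.raises(StaircaseError):
            StaircaseConfig(total_reversals=4, reversals_for_threshold=6)

    def test_run_log_csv_round_trip(self, af_config, tmp_path):
        import pandas as pd
        gen = np.random.default_rng(1)
        res = run(af_config, lambda v: bool(gen.random() < 0.6), rng=1)
        path = res.write_log_csv(tmp_path / "log.csv")
        df = pd.read_csv(path, float_precision="round_trip")
        assert len(df) == res.n_trials
        assert list(df.columns) == ["trial", "value", "target", "response",
                                    "correct", "reversal", "factor"]
        assert df["value"].tolist() == [r.value for r in res.trial_log]
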