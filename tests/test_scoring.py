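"""D-score pipeline: trimming, exclusion, error treatments, bands, invariances.

The reference oracle here follows the published eight-step procedure one
trial at a time with plain Python lists and the statistics module, staying
independent of the vectorized production path it checks.
"""

import math
import statistics
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gviat import Band, ScoringOptions, classify_band, cohort_summary, compute_d
from gviat.scoring import (
    ScoringError,
    apply_error_treatment,
    fast_response_exclusion,
    trim_trials,
)
from gviat.session_io import Session, Trial

from conftest import random_critical_session


# ---------------------------------------------------------------- oracle


def naive_d(session, task, error_treatment="builtin"):
    """Step-literal reference: returns (excluded, d) following Steps 1-8."""
    # Step 1: critical blocks only; Step 2: drop latencies > 10,000 ms
    kept = [
        t
        for t in session.trials
        if t.block in (3, 4, 6, 7) and not t.latency_ms > 10_000
    ]
    # Step 3: participant exclusion on fast trials
    fast = [t for t in kept if t.latency_ms < 300]
    if len(fast) / len(kept) > 0.10:
        return True, None
    # error treatment
    effective = {}
    for t in kept:
        effective[id(t)] = t.latency_ms
    if error_treatment == "penalty600":
        for block in (3, 4, 6, 7):
            correct = [t.latency_ms for t in kept if t.block == block and t.first_correct]
            mean_correct = sum(correct) / len(correct)
            for t in kept:
                if t.block == block and not t.first_correct:
                    effective[id(t)] = mean_correct + 600.0
    lat = {b: [effective[id(t)] for t in kept if t.block == b] for b in (3, 4, 6, 7)}
    # Step 4: pooled sample SDs; Step 5: block means
    sd1 = statistics.stdev(lat[3] + lat[6])
    sd2 = statistics.stdev(lat[4] + lat[7])
    means = {b: sum(v) / len(v) for b, v in lat.items()}
    # Steps 6-8: incompatible minus compatible, standardize, average
    if session.version == 1:
        diff1, diff2 = means[6] - means[3], means[7] - means[4]
    else:
        diff1, diff2 = means[3] - means[6], means[4] - means[7]
    return False, (diff1 / sd1 + diff2 / sd2) / 2.0


# ---------------------------------------------------------------- trimming


class TestTrim:
    def test_boundaries_and_practice_blocks(self, make_session):
        session = make_session(
            {1: [500.0], 3: [10_500.0, 10_000.0, 800.0], 4: [700.0], 6: [900.0], 7: [950.0]}
        )
        trimmed = trim_trials(session)
        latencies = sorted(t.latency_ms for t in trimmed.trials)
        assert 10_500.0 not in latencies  # strictly greater than the limit: dropped
        assert 10_000.0 in latencies  # exactly at the limit: retained
        assert all(t.block != 1 for t in trimmed.trials)

    def test_sub_300_trials_survive_trimming(self, make_session):
        session = make_session({3: [150.0, 800.0], 4: [700.0], 6: [900.0], 7: [950.0]})
        trimmed = trim_trials(session)
        assert 150.0 in [t.latency_ms for t in trimmed.trials]


class TestFastExclusion:
    @pytest.mark.parametrize(
        "n_fast, expected_fraction, expected_excluded",
        [(15, 15 / 144, True), (14, 14 / 144, False), (0, 0.0, False)],
    )
    def test_ten_percent_rule_is_strict(
        self, make_session, n_fast, expected_fraction, expected_excluded
    ):
        latencies = [250.0] * n_fast + [800.0] * (144 - n_fast)
        session = make_session(
            {3: latencies[:24], 4: latencies[24:72], 6: latencies[72:96], 7: latencies[96:]}
        )
        fraction, excluded = fast_response_exclusion(trim_trials(session))
        assert fraction == pytest.approx(expected_fraction)
        assert excluded is expected_excluded

    def test_no_scorable_trials_is_an_error(self, make_session):
        empty = Session(participant_id="P1", version=1, trials=[])
        with pytest.raises(ScoringError, match="no scorable trials"):
            fast_response_exclusion(empty)


class TestErrorTreatment:
    def test_builtin_is_identity(self, make_session):
        session = make_session({3: [(1250.0, False), (800.0, True)]})
        treated = apply_error_treatment(session, ScoringOptions(error_treatment="builtin"))
        assert [t.latency_ms for t in treated.trials] == [1250.0, 800.0]

    def test_penalty600_uses_block_correct_mean(self, make_session):
        session = make_session(
            {3: [(700.0, True), (900.0, True), (1250.0, False)], 4: [(400.0, True)]}
        )
        treated = apply_error_treatment(session, ScoringOptions(error_treatment="penalty600"))
        by_block = {b: [t.latency_ms for t in treated.block_trials(b)] for b in (3, 4)}
        assert by_block[3] == [700.0, 900.0, 1400.0]  # (700+900)/2 + 600
        assert by_block[4] == [400.0]

    def test_penalty600_all_correct_is_noop(self, make_session):
        session = make_session({3: [700.0, 900.0], 4: [400.0]})
        treated = apply_error_treatment(session, ScoringOptions(error_treatment="penalty600"))
        assert [t.latency_ms for t in treated.trials] == [700.0, 900.0, 400.0]

    def test_block_without_correct_trials_named(self, make_session):
        session = make_session({6: [(700.0, False), (900.0, False)]})
        with pytest.raises(ScoringError, match="block 6"):
            apply_error_treatment(session, ScoringOptions(error_treatment="penalty600"))


# ---------------------------------------------------------------- compute_d

HAND_BLOCKS = {
    3: [600.0, 700.0, 800.0, 900.0],
    6: [900.0, 1000.0, 1100.0, 1200.0],
    4: [700.0, 800.0, 900.0, 1000.0],
    7: [1000.0, 1100.0, 1200.0, 1300.0],
}


class TestComputeD:
    def test_hand_worked_example(self, task, make_session):
        result = compute_d(make_session(HAND_BLOCKS, version=1), task)
        assert result.block_means == {3: 750.0, 6: 1050.0, 4: 850.0, 7: 1150.0}
        assert result.pooled_sd_1 == pytest.approx(200.0)  # sqrt(280000/7)
        assert result.pooled_sd_2 == pytest.approx(200.0)
        assert result.d == pytest.approx(1.5)
        assert result.band is Band.strong
        assert result.trials_used == {3: 4, 4: 4, 6: 4, 7: 4}

    def test_version_symmetry(self, task, make_session):
        # same phase-labelled latencies under version 2: B3/B4 now incompatible
        swapped = {3: HAND_BLOCKS[6], 6: HAND_BLOCKS[3], 4: HAND_BLOCKS[7], 7: HAND_BLOCKS[4]}
        result = compute_d(make_session(swapped, version=2), task)
        assert result.d == pytest.approx(1.5)

    def test_antisymmetry(self, task, make_session):
        swapped = {3: HAND_BLOCKS[6], 6: HAND_BLOCKS[3], 4: HAND_BLOCKS[7], 7: HAND_BLOCKS[4]}
        result = compute_d(make_session(swapped, version=1), task)
        assert result.d == pytest.approx(-1.5)

    def test_empty_block_named(self, task, make_session):
        blocks = {b: v for b, v in HAND_BLOCKS.items() if b != 7}
        with pytest.raises(ScoringError, match="block 7"):
            compute_d(make_session(blocks, version=1), task)

    def test_degenerate_latencies_rejected(self, task, make_session):
        flat = {b: [800.0, 800.0] for b in (3, 4, 6, 7)}
        with pytest.raises(ScoringError, match="degenerate"):
            compute_d(make_session(flat, version=1), task)

    def test_excluded_participant_carries_reason_and_no_d(self, task, make_session):
        latencies = [250.0] * 30 + [800.0] * 114
        session = make_session(
            {3: latencies[:24], 4: latencies[24:72], 6: latencies[72:96], 7: latencies[96:]}
        )
        result = compute_d(session, task)
        assert result.excluded and result.d is None and result.band is None
        assert "300" in result.exclusion_reason


class TestOracleAndInvariances:
    @pytest.mark.parametrize("treatment", ["builtin", "penalty600"])
    def test_matches_step_literal_oracle(self, task, treatment):
        rng = np.random.default_rng(2024)
        options = ScoringOptions(error_treatment=treatment)
        for _ in range(200):
            session = random_critical_session(rng)
            excluded, d_ref = naive_d(session, task, treatment)
            result = compute_d(session, task, options)
            assert result.excluded == excluded
            if not excluded:
                assert result.d == pytest.approx(d_ref, abs=1e-12)

    def test_affine_invariance(self, task, make_session):
        base = compute_d(make_session(HAND_BLOCKS, version=1), task).d
        shifted = {b: [x + 137.0 for x in v] for b, v in HAND_BLOCKS.items()}
        scaled = {b: [x * 3.5 for x in v] for b, v in HAND_BLOCKS.items()}
        assert compute_d(make_session(shifted, version=1), task).d == pytest.approx(base)
        assert compute_d(make_session(scaled, version=1), task).d == pytest.approx(base)

    def test_antisymmetry_on_random_sessions(self, task):
        rng = np.random.default_rng(7)
        for _ in range(20):
            session = random_critical_session(rng)
            # keep every latency inside (300, 10000) so no trial drops out
            trials = [
                replace(t, latency_ms=float(np.clip(t.latency_ms, 301.0, 9_999.0)))
                for t in session.trials
            ]
            session = Session("P1", session.version, trials)
            mirrored = Session(
                "P1",
                session.version,
                [
                    replace(t, block={3: 6, 6: 3, 4: 7, 7: 4}[t.block])
                    for t in session.trials
                ],
            )
            d = compute_d(session, task).d
            d_mirror = compute_d(mirrored, task).d
            assert d_mirror == pytest.approx(-d, abs=1e-12)


class TestBands:
    @pytest.mark.parametrize(
        "d, band",
        [
            (0.10, Band.null),
            (-0.40, Band.null),
            (0.20, Band.mild),
            (0.49, Band.mild),
            (0.50, Band.moderate),
            (0.79, Band.moderate),
            (0.80, Band.strong),
            (2.0, Band.strong),
        ],
    )
    def test_boundaries_go_to_the_upper_band(self, d, band):
        assert classify_band(d) is band

    def test_non_finite_rejected(self):
        with pytest.raises(ScoringError):
            classify_band(float("nan"))

    @given(st.floats(min_value=-5, max_value=5, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_partition_is_total(self, d):
        assert classify_band(d) in list(Band)


class TestCohortSummary:
    def test_band_counts_and_percentages(self):
        import pandas as pd

        ds = [0.1, 0.3, 0.6, 0.9]
        frame = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(4)],
                "excluded": [False] * 4,
                "d": ds,
                "band": [classify_band(d).value for d in ds],
            }
        )
        summary = cohort_summary(frame)
        assert summary["band_counts"] == {"null": 1, "mild": 1, "moderate": 1, "strong": 1}
        assert summary["band_percentages"] == {
            "null": 25.0, "mild": 25.0, "moderate": 25.0, "strong": 25.0
        }

    def test_excluded_participants_kept_out_of_percentages(self, task, small_cohort):
        from gviat import score_cohort

        cohort, _ = small_cohort
        scores = score_cohort(cohort)
        summary = cohort_summary(scores)
        assert summary["n_total"] == 20
        assert summary["n_scored"] + summary["n_excluded"] == 20
        if summary["n_scored"]:
            assert sum(summary["band_percentages"].values()) == pytest.approx(100.0, abs=0.3)
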