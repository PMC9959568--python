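"""Sniffin' Sticks scoring: staircase dynamics, forced choice, TDI, classes."""

import numpy as np
import pytest

from olfmap.errors import ParameterError, StaircaseIncompleteError
from olfmap.olfaction import (
    OlfactoryCutoffs,
    SubjectOlfactoryProfile,
    classify_olfactory,
    compose_tdi,
    run_threshold_staircase,
    score_forced_choice,
    simulate_subject,
)


class ScriptedOracle:
    """Replays a fixed response script (stateful deterministic respondent)."""

    def __init__(self, script):
        self.script = list(script)
        self.k = 0

    def __call__(self, step):
        r = self.script[self.k]
        self.k += 1
        return r


def test_staircase_threshold_oracle_brackets_threshold():
    """A subject detecting steps <= 10 reverses between 10 and 11; the score
    is the mean of the last four reversals, 10.5."""
    trace = run_threshold_staircase(lambda s: s <= 10)
    assert trace.reversal_levels == [10, 11, 10, 11, 10, 11, 10]
    assert trace.t_score == pytest.approx(10.5)


def test_staircase_ceiling_perfect_subject():
    """Always-correct responses saturate the score at the most dilute step."""
    trace = run_threshold_staircase(lambda s: True, start_step=16)
    assert len(trace.reversal_levels) == 7
    assert trace.t_score == 16.0
    assert all(step == 16 for step, _ in trace.presentations)


def test_staircase_floor_never_completes():
    with pytest.raises(StaircaseIncompleteError) as exc:
        run_threshold_staircase(lambda s: False)
    assert len(exc.value.trace.presentations) == 100
    assert exc.value.trace.reversal_levels == []


def test_staircase_score_is_mean_of_last_four_reversals():
    """Property over random stochastic respondents: 7 reversals, score =
    mean of the last 4 reversal levels, always within [1, 16]."""
    rng = np.random.default_rng(42)
    completed = 0
    for _ in range(50):
        p_by_step = rng.uniform(0.2, 1.0, size=17)

        def oracle(step, p=p_by_step, r=rng):
            return bool(r.random() < p[step])

        try:
            trace = run_threshold_staircase(oracle, max_presentations=400)
        except StaircaseIncompleteError:
            continue
        completed += 1
        assert len(trace.reversal_levels) == 7
        assert trace.t_score == pytest.approx(
            float(np.mean(trace.reversal_levels[-4:]))
        )
        assert 1 <= trace.t_score <= 16
    assert completed >= 30


def test_staircase_two_in_a_row_required_on_ascent():
    """A single correct followed by a miss must not register a reversal."""
    # descend 16..13 missing, one hit at 12, miss, then hits at 11 onward
    script = [False] * 4 + [True, False] + [True] * 30
    trace = run_threshold_staircase(ScriptedOracle(script))
    assert trace.reversal_levels[0] == 11


def test_forced_choice_counts():
    assert score_forced_choice([True] * 16) == 16
    assert score_forced_choice([False] * 16) == 0
    assert score_forced_choice([True, False] * 8) == 8
    with pytest.raises(ParameterError):
        score_forced_choice([True] * 15)


def test_tdi_composition():
    assert compose_tdi(5.86, 10.24, 10.86) == pytest.approx(26.96)
    assert compose_tdi(1, 0, 0) == 1
    assert compose_tdi(16, 16, 16) == 48
    with pytest.raises(ParameterError):
        compose_tdi(0.5, 8, 8)
    with pytest.raises(ParameterError):
        compose_tdi(8, 17, 8)


def test_olfactory_classification_monotone_and_boundary():
    cut = OlfactoryCutoffs()
    assert classify_olfactory(48, "TDI", cut) == "normosmic"
    assert classify_olfactory(cut.tdi - 0.25, "TDI", cut) == "hyposmic"
    assert classify_olfactory(cut.tdi, "TDI", cut) == "normosmic"
    # monotone in score
    labels = [classify_olfactory(s, "D", cut) for s in range(0, 17)]
    switch = labels.index("normosmic")
    assert all(l == "hyposmic" for l in labels[:switch])
    assert all(l == "normosmic" for l in labels[switch:])
    with pytest.raises(ParameterError):
        classify_olfactory(10, "Z", cut)


def test_anosmia_range_warns_but_reports_hyposmic():
    with pytest.warns(UserWarning, match="anosmia"):
        assert classify_olfactory(12.0, "TDI") == "hyposmic"


def test_simulated_subject_reproducible_and_validated():
    prof = SubjectOlfactoryProfile(8.0, 2.0, 0.8, 0.7, seed=7)
    o1, d1, i1 = simulate_subject(prof)
    o2, d2, i2 = simulate_subject(prof)
    assert d1 == d2 and i1 == i2
    assert [o1(s) for s in range(1, 17)] == [o2(s) for s in range(1, 17)]
    with pytest.raises(ParameterError):
        simulate_subject(SubjectOlfactoryProfile(8, 2, 0.2, 0.7))
    with pytest.raises(ParameterError):
        simulate_subject(SubjectOlfactoryProfile(8, 2, 0.8, 0.1))


def test_simulated_subject_step_function_limit():
    """Zero psychometric slope: certain detection at or past the latent
    threshold rank, chance guessing below."""
    prof = SubjectOlfactoryProfile(9.0, 0.0, 1.0, 1.0, seed=0)
    oracle, d, i = simulate_subject(prof)
    assert sum(d) == 16
    # ranks >= 9 correspond to steps <= 8: always correct there
    assert all(oracle(s) for s in range(1, 9) for _ in range(3))


def test_identification_at_chance_matches_binomial_mean():
    """At p = 1/4 the mean identification count over many seeded subjects
    approaches the binomial expectation 4 (within 3 standard errors)."""
    counts = []
    for seed in range(500):
        _, _, i_resp = simulate_subject(
            SubjectOlfactoryProfile(8, 2, 1 / 3, 0.25, seed=seed)
        )
        counts.append(sum(i_resp))
    se = np.sqrt(16 * 0.25 * 0.75 / 500)
    assert abs(np.mean(counts) - 4.0) < 3 * se


def test_better_sensitivity_never_lowers_expected_threshold_score():
    """Lowering the latent threshold (better sensitivity) does not decrease
    the Monte-Carlo mean staircase score."""
    def mean_t(latent):
        scores = []
        for seed in range(60):
            oracle, _, _ = simulate_subject(
                SubjectOlfactoryProfile(latent, 1.5, 0.9, 0.9, seed=seed)
            )
            try:
                scores.append(
                    run_threshold_staircase(oracle, max_presentations=400).t_score
                )
            except StaircaseIncompleteError:
                scores.append(1.0)  # floor: no measurable threshold
        return float(np.mean(scores))

    t_sensitive, t_mid, t_poor = mean_t(4.0), mean_t(8.0), mean_t(12.0)
    assert t_sensitive >= t_mid >= t_poor
    assert t_sensitive - t_poor > 2.0  # clearly separated, not a tie
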