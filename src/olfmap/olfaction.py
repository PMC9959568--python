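"""Sniffin' Sticks scoring: threshold staircase, forced-choice counts, TDI.

The threshold (T) test is a single adaptive staircase over 16 n-butanol
dilution steps, indexed 1-16 with 16 the most dilute pen. The staircase
starts at the most dilute pen and presents triplets in increasing order of
concentration (step index decreasing) until the subject identifies the
target twice in a row at one step — the first reversal. The direction then
flips toward weaker concentrations; from there a single miss reverses the
direction again (and two-in-a-row successes reverse it during ascending
runs). The procedure stops after seven reversals and the T score is the
arithmetic mean of the last four reversal levels, so better sensitivity
(detection of more dilute pens) yields a higher score on the 1-16 scale.

Boundary behaviour: the staircase clips at steps 1 and 16. A descending
(toward-dilute) run clipped at step 16 records a reversal there — the
subject detects even the weakest stimulus, so the score saturates at the
ceiling of 16. A clipped ascending run at step 1 records nothing: a subject
who cannot detect the strongest stimulus has no measurable threshold and
the staircase eventually hits its presentation cap (non-completion).

Discrimination (D) and identification (I) are 16-trial forced-choice tests
(3 and 4 alternatives respectively) scored as the number of correct
responses; TDI is the sum of the three subtest scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import ndtr

from .errors import ParameterError, StaircaseIncompleteError

MIN_STEP = 1
MAX_STEP = 16
N_REVERSALS = 7
N_FORCED_CHOICE = 16

#: Chance rates of the two forced-choice tasks (3- and 4-alternative).
CHANCE_D = 1.0 / 3.0
CHANCE_I = 1.0 / 4.0

#: TDI at or below this value would conventionally be called anosmia; the
#: two-class output of this package still reports it as hyposmic.
ANOSMIA_TDI = 16.0


@dataclass(frozen=True)
class OlfactoryCutoffs:
    """Normosmia/hyposmia cut-offs (score below cut-off => hyposmic).

    The TDI default follows common clinical usage for adults; the subtest
    defaults are package choices scaled to a weight-excess population and
    are configurable — no shipped analysis depends on their exact values.
    """

    t: float = 4.5
    d: float = 9.5
    i: float = 10.75
    tdi: float = 30.75

    def for_test(self, test: str) -> float:
        try:
            return {"T": self.t, "D": self.d, "I": self.i, "TDI": self.tdi}[test]
        except KeyError:
            raise ParameterError(f"unknown olfactory test {test!r}") from None


@dataclass
class StaircaseTrace:
    """Full record of one threshold staircase run."""

    presentations: list[tuple[int, bool]] = field(default_factory=list)
    reversal_levels: list[int] = field(default_factory=list)
    t_score: float = float("nan")


def run_threshold_staircase(
    respond: Callable[[int], bool],
    start_step: int = MAX_STEP,
    max_presentations: int = 100,
) -> StaircaseTrace:
    """Run the single-staircase threshold procedure against a response oracle.

    ``respond(step)`` returns whether the subject identified the target pen
    at that dilution step; it may be stateful. Raises
    :class:`StaircaseIncompleteError` (with the partial trace attached) if
    seven reversals are not reached within ``max_presentations``.
    """
    if not (MIN_STEP <= start_step <= MAX_STEP):
        raise ParameterError(f"start_step out of range [1, 16]: {start_step}")
    trace = StaircaseTrace()
    step = start_step
    ascending = True  # toward stronger concentration (decreasing step)
    consecutive = 0

    while len(trace.reversal_levels) < N_REVERSALS:
        if len(trace.presentations) >= max_presentations:
            raise StaircaseIncompleteError(
                f"staircase did not complete {N_REVERSALS} reversals within "
                f"{max_presentations} presentations",
                trace=trace,
            )
        correct = bool(respond(step))
        trace.presentations.append((step, correct))
        if ascending:
            if correct:
                consecutive += 1
                if consecutive == 2:
                    trace.reversal_levels.append(step)
                    ascending = False
                    consecutive = 0
                    step = min(step + 1, MAX_STEP)
            else:
                consecutive = 0
                step = max(step - 1, MIN_STEP)
        else:  # descending phase: toward more dilute
            if correct:
                if step == MAX_STEP:
                    # ceiling: detection of the weakest pen is a reversal
                    trace.reversal_levels.append(MAX_STEP)
                    ascending = True
                else:
                    step += 1
            else:
                trace.reversal_levels.append(step)
                ascending = True
                step = max(step - 1, MIN_STEP)

    trace.t_score = float(np.mean(trace.reversal_levels[-4:]))
    return trace


def score_forced_choice(responses: Sequence[bool]) -> int:
    """Count correct responses of a 16-trial forced-choice test."""
    responses = list(responses)
    if len(responses) != N_FORCED_CHOICE:
        raise ParameterError(
            f"expected {N_FORCED_CHOICE} responses, got {len(responses)}"
        )
    return int(sum(bool(r) for r in responses))


def compose_tdi(t: float, d: float, i: float) -> float:
    """TDI composite score: sum of threshold, discrimination, identification."""
    if not (MIN_STEP <= t <= MAX_STEP):
        raise ParameterError(f"t score out of range [1, 16]: {t}")
    for name, val in (("d", d), ("i", i)):
        if not (0 <= val <= 16):
            raise ParameterError(f"{name} count out of range [0, 16]: {val}")
    return float(t) + float(d) + float(i)


def classify_olfactory(
    score: float, test: str, cutoffs: OlfactoryCutoffs | None = None
) -> str:
    """Classify a score as ``"normosmic"`` or ``"hyposmic"``.

    Scores in the conventional anosmia range (TDI <= 16) are still reported
    as hyposmic — this package emits two classes only — with a warning.
    """
    cutoffs = cutoffs or OlfactoryCutoffs()
    cutoff = cutoffs.for_test(test)
    if test == "TDI" and score <= ANOSMIA_TDI:
        warnings.warn(
            f"TDI {score} lies in the anosmia range (<= {ANOSMIA_TDI}); "
            "reported as hyposmic",
            stacklevel=2,
        )
    return "hyposmic" if score < cutoff else "normosmic"


@dataclass(frozen=True)
class SubjectOlfactoryProfile:
    """Latent description of a simulated respondent.

    ``latent_threshold`` and ``psychometric_slope`` are in concentration-rank
    units (rank = 17 - dilution step, so stronger pens have higher rank);
    a lower threshold means better sensitivity. ``p_discrimination`` and
    ``p_identification`` are per-trial success probabilities bounded below
    by the chance rates 1/3 and 1/4.
    """

    latent_threshold: float
    psychometric_slope: float
    p_discrimination: float
    p_identification: float
    seed: int = 0


def simulate_subject(
    profile: SubjectOlfactoryProfile,
) -> tuple[Callable[[int], bool], list[bool], list[bool]]:
    """Build a seeded respondent: a stochastic threshold oracle plus 16
    discrimination and 16 identification responses.

    The threshold oracle answers correctly with probability
    ``1/3 + (2/3) * Phi((rank(step) - latent_threshold) / slope)`` — chance
    guessing plus a cumulative-normal psychometric function. A zero slope
    degenerates to a step function (certain detection at or above the
    latent threshold, pure guessing below).
    """
    if not (CHANCE_D <= profile.p_discrimination <= 1):
        raise ParameterError(
            f"p_discrimination must lie in [1/3, 1], got {profile.p_discrimination}"
        )
    if not (CHANCE_I <= profile.p_identification <= 1):
        raise ParameterError(
            f"p_identification must lie in [1/4, 1], got {profile.p_identification}"
        )
    if profile.psychometric_slope < 0:
        raise ParameterError("psychometric_slope must be >= 0")

    rng = np.random.default_rng(profile.seed)

    def p_correct(step: int) -> float:
        rank = (MAX_STEP + 1) - step
        if profile.psychometric_slope == 0:
            detect = 1.0 if rank >= profile.latent_threshold else 0.0
        else:
            detect = float(
                ndtr((rank - profile.latent_threshold) / profile.psychometric_slope)
            )
        return CHANCE_D + (1 - CHANCE_D) * detect

    def oracle(step: int) -> bool:
        return bool(rng.random() < p_correct(step))

    d_responses = list(rng.random(N_FORCED_CHOICE) < profile.p_discrimination)
    i_responses = list(rng.random(N_FORCED_CHOICE) < profile.p_identification)
    return oracle, [bool(x) for x in d_responses], [bool(x) for x in i_responses]
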