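"""Simulate a Sniffin' Sticks session for one synthetic respondent.

A latent psychometric profile drives a stochastic response oracle; the
adaptive threshold staircase is run against it and the full TDI composite
is assembled from the three subtests.
"""

from olfmap import (
    SubjectOlfactoryProfile,
    classify_olfactory,
    compose_tdi,
    run_threshold_staircase,
    score_forced_choice,
    simulate_subject,
)

profile = SubjectOlfactoryProfile(
    latent_threshold=9.0,      # concentration rank where detection reaches ~50%
    psychometric_slope=1.5,
    p_discrimination=0.70,
    p_identification=0.75,
    seed=11,
)
oracle, d_responses, i_responses = simulate_subject(profile)

trace = run_threshold_staircase(oracle)
print(f"presentations: {len(trace.presentations)}")
print(f"reversal levels: {trace.reversal_levels}")
print(f"T score (mean of last 4 reversals): {trace.t_score:.2f}")

d = score_forced_choice(d_responses)
i = score_forced_choice(i_responses)
tdi = compose_tdi(trace.t_score, d, i)
print(f"D = {d}/16, I = {i}/16, TDI = {tdi:.2f}")
print(f"TDI class at default cut-offs: {classify_olfactory(tdi, 'TDI')}")
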