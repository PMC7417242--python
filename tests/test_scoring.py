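"""Event scoring, tail probabilities and the largest-compatible-TRC search."""

import numpy as np
import pytest

from kinrecruit import (
    NullSummary,
    ScoreWeights,
    SibshipComposition,
    build_cohort,
    build_weights,
    confidence_trc_search,
    draw_sample,
    expected_composition,
    score_composition,
    tail_probability,
)
from kinrecruit.scoring import _accept_at


def null_from_exact(trc, n=168, s=6, iterations=100_000):
    """NullSummary built from the exact expectation (noise-free weights)."""
    k = trc // s
    mean = expected_composition(k * s, k, s, n)
    return NullSummary(mean_c=mean, se_c=np.zeros_like(mean), iterations=iterations,
                       sample_size=n, cohort_size=k * s, family_size=s)


EMPIRICAL = SibshipComposition.from_counts({1: 89, 2: 20, 3: 10, 4: 1, 5: 1})


def test_weights_reciprocal_rule():
    mean = np.array([0.0, 10.0, 0.5, 0.0])
    null = NullSummary(mean_c=mean, se_c=np.zeros(4), iterations=10_000,
                       sample_size=10, cohort_size=100, family_size=3)
    w = build_weights(null)
    assert w.weights[2] == 2          # round(1 / 0.5)
    assert w.weights[3] == 1000       # capped: never observed in the null


def test_weights_monotone_rarity():
    """Rarer (larger) events never score less under an exact null."""
    w = build_weights(null_from_exact(5910))
    assert w.weights[2] < w.weights[3] < w.weights[4] <= w.weights[5] <= w.weights[6]


def test_score_zero_iff_no_events():
    w = ScoreWeights({2: 3, 3: 10})
    singles = SibshipComposition.from_counts({1: 12})
    assert score_composition(singles, w) == 0
    one_pair = SibshipComposition.from_counts({1: 3, 2: 1})
    assert score_composition(one_pair, w) == 3


def test_score_additive_over_disjoint_compositions():
    w = ScoreWeights({2: 3, 3: 10, 4: 40})
    a = SibshipComposition.from_counts({2: 2, 3: 1})
    b = SibshipComposition.from_counts({1: 5, 4: 2})
    merged = SibshipComposition.from_counts({1: 5, 2: 2, 3: 1, 4: 2})
    assert score_composition(merged, w) == score_composition(a, w) + score_composition(b, w)


def test_tail_probability_limits(small_cohort):
    w = build_weights(null_from_exact(720))
    low = tail_probability(0, small_cohort, 168, w, iterations=2000, seed=1)
    assert low.tail_probability == pytest.approx(1.0, abs=1e-3)
    high = tail_probability(np.inf, small_cohort, 168, w, iterations=2000, seed=1)
    assert high.tail_probability == pytest.approx(1 / 2001)


def test_tail_probability_monotone_in_score(small_cohort):
    w = build_weights(null_from_exact(720))
    tails = [
        tail_probability(s, small_cohort, 168, w, iterations=2000, seed=3).tail_probability
        for s in (0, 50, 200, 10_000)
    ]
    assert all(a >= b for a, b in zip(tails, tails[1:]))


def test_tail_probability_increases_with_smaller_cohort():
    """Smaller pools make kin clumping likelier, so the empirical score is less rare."""
    w = build_weights(null_from_exact(5910))
    emp_score = score_composition(EMPIRICAL, w)
    tails = []
    for trc in (720, 5910, 19_440):
        cohort = build_cohort(trc, 6)
        tails.append(
            tail_probability(emp_score, cohort, 168, w, iterations=4000, seed=5).tail_probability
        )
    assert tails[0] >= tails[1] >= tails[2]


def test_search_accepts_its_own_generating_cohort(rng):
    """A typical null draw is not rejected at the TRC that produced it."""
    t0 = 1200
    comp = draw_sample(build_cohort(t0, 6), 168, rng)
    ok, tail = _accept_at(t0, comp, 168, 6, 0.05, iterations=2000, seed=9, cap=1000)
    assert ok and tail >= 0.05
    res = confidence_trc_search(comp, 168, iterations=2000, seed=9,
                                lower=600, upper=6000)
    assert res.t_star >= t0 - 6


def test_search_collapses_as_alpha_approaches_one():
    res = confidence_trc_search(EMPIRICAL, 168, alpha=0.999, iterations=2000,
                                seed=2, lower=168, upper=6000)
    strict = confidence_trc_search(EMPIRICAL, 168, alpha=0.05, iterations=2000,
                                   seed=2, lower=168, upper=6000)
    assert res.t_star <= strict.t_star


def test_search_monotone_acceptance_along_trace():
    res = confidence_trc_search(EMPIRICAL, 168, iterations=2000, seed=4,
                                lower=720, upper=6000)
    assert res.at_boundary is None
    # tail probabilities decrease as the candidate TRC grows
    trace = sorted(res.trace)
    tails = [t for _, t in trace]
    assert all(a >= b - 0.05 for a, b in zip(tails, tails[1:]))


def test_cohesive_arrivals_score_extreme():
    """Families arriving intact score above the null's 95th percentile."""
    null = null_from_exact(5910)
    w = build_weights(null)
    cohort = build_cohort(5910, 6)
    thresh = tail_probability(
        score_composition(SibshipComposition.from_counts({6: 28}), w),
        cohort, 168, w, iterations=4000, seed=6,
    )
    assert thresh.tail_probability < 0.05
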