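"""Sibship-event scoring against a Monte-Carlo null, and the confidence-TRC search.

A sample's sibship composition is condensed into a single score

    score = sum_{k >= 2} c_k * w_k

with weights inversely proportional to how often events of size ``k``
occur under the null: ``w_k = round(1 / max(mean_c_k, 1 / iterations))``,
capped (default 1000) for events never seen in the null and forced
nondecreasing in ``k`` so a rarer, larger event never scores less.  The
empirical score's rarity is its upper-tail probability among random
draws, with add-one smoothing so the estimate is never exactly zero.

The confidence search inverts the test: it finds the largest TRC size
(multiple of the family size, by bisection) whose null still produces the
empirical score with probability >= alpha — the cohort size at which the
observed kin clumping would no longer be surprising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort_sampling import (
    NullSummary,
    SibshipComposition,
    composition_counts,
    null_summary,
)
from .demography import RecruitCohort, build_cohort

__all__ = [
    "ScoreWeights",
    "ScoreResult",
    "ConfidenceSearch",
    "build_weights",
    "score_composition",
    "tail_probability",
    "confidence_trc_search",
]


@dataclass(frozen=True)
class ScoreWeights:
    """Integer weight per event size ``k >= 2`` (singletons score 0)."""

    weights: dict[int, int]
    cap: int = 1000

    def __post_init__(self) -> None:
        ks = sorted(self.weights)
        if any(k < 2 for k in ks):
            raise ValueError("weights are defined for event sizes k >= 2 only")
        vals = [self.weights[k] for k in ks]
        if any(v < 0 for v in vals):
            raise ValueError("weights must be nonnegative")
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("weights must be nondecreasing in k")

    def as_vector(self, s: int) -> np.ndarray:
        """Weight vector indexed 0..s; unspecified sizes inherit the last
        specified weight below them (keeps monotone rarity)."""
        vec = np.zeros(s + 1, dtype=np.int64)
        last = 0
        for k in range(2, s + 1):
            last = self.weights.get(k, last)
            vec[k] = last
        return vec


def build_weights(null: NullSummary, cap: int = 1000) -> ScoreWeights:
    """Reciprocal-frequency weights from a Monte-Carlo null.

    ``w_k = round(1 / max(mean_c_k, 1 / iterations))`` clipped at ``cap``;
    a running maximum over ``k`` enforces monotone rarity (Monte-Carlo
    noise on near-zero means could otherwise invert the order).
    """
    if len(null.mean_c) < 3:
        raise ValueError("null summary carries no event sizes k >= 2")
    if cap < 1:
        raise ValueError("cap must be >= 1")
    floor = 1.0 / null.iterations
    weights: dict[int, int] = {}
    running = 0
    for k in range(2, len(null.mean_c)):
        w = int(round(1.0 / max(float(null.mean_c[k]), floor)))
        w = min(w, cap)
        running = max(running, w)
        weights[k] = running
    return ScoreWeights(weights=weights, cap=cap)


def score_composition(
    comp: SibshipComposition, weights: ScoreWeights
) -> int:
    """Total score ``sum_{k>=2} c_k * w_k`` of a composition."""
    s = len(comp.counts) - 1
    vec = weights.as_vector(s)
    return int(np.dot(comp.counts, vec))


@dataclass(frozen=True)
class ScoreResult:
    """Score of the empirical composition and its null-tail probability."""

    score: float
    tail_probability: float
    iterations: int
    trc_size: int
    seed: int | None = None


def tail_probability(
    emp_score: float,
    cohort: RecruitCohort,
    n: int,
    weights: ScoreWeights,
    iterations: int = 100_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ScoreResult:
    """Upper-tail probability of ``emp_score`` under the cohort's null.

    ``P = (1 + #{draws with score >= emp_score}) / (iterations + 1)``
    (add-one smoothing).
    """
    if iterations < 1000:
        raise ValueError("tail probability needs >= 1000 iterations")
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = composition_counts(cohort, n, iterations, rng)
    vec = weights.as_vector(cohort.family_size)
    scores = counts @ vec
    hits = int((scores >= emp_score).sum())
    return ScoreResult(
        score=float(emp_score),
        tail_probability=(hits + 1) / (iterations + 1),
        iterations=iterations,
        trc_size=cohort.size,
        seed=seed,
    )


@dataclass(frozen=True)
class ConfidenceSearch:
    """Result of the largest-compatible-TRC bisection.

    ``t_star`` is the largest cohort size (multiple of the family size
    within the bounds) whose null yields the empirical score with
    probability >= ``alpha``; ``at_boundary`` flags searches that never
    bracketed the acceptance transition.
    """

    t_star: int
    alpha: float
    lower: int
    upper: int
    at_boundary: str | None
    iterations: int
    seed: int | None
    trace: tuple[tuple[int, float], ...] = field(default=())


def _accept_at(
    trc: int,
    emp: SibshipComposition,
    n: int,
    s: int,
    alpha: float,
    iterations: int,
    seed: int | None,
    cap: int,
) -> tuple[bool, float]:
    """Tail probability of the empirical score at one candidate TRC.

    Weights are rebuilt from that TRC's own null (the same scoring system
    applied at every cohort size), with a deterministic per-TRC stream.
    """
    rng = np.random.default_rng([seed if seed is not None else 0, trc])
    cohort = build_cohort(trc, s)
    counts = composition_counts(cohort, n, iterations, rng)
    mean = counts.mean(axis=0)
    null = NullSummary(
        mean_c=mean,
        se_c=np.zeros_like(mean),
        iterations=iterations,
        sample_size=n,
        cohort_size=cohort.size,
        family_size=s,
    )
    weights = build_weights(null, cap=cap)
    vec = weights.as_vector(s)
    emp_score = score_composition(emp, weights)
    scores = counts @ vec
    tail = (int((scores >= emp_score).sum()) + 1) / (iterations + 1)
    return tail >= alpha, tail


def confidence_trc_search(
    emp: SibshipComposition,
    n: int,
    s: int = 6,
    alpha: float = 0.05,
    iterations: int = 20_000,
    seed: int | None = None,
    lower: int | None = None,
    upper: int = 30_000,
    cap: int = 1000,
) -> ConfidenceSearch:
    """Largest TRC whose null is compatible with the empirical composition.

    Bisection over multiples of ``s`` between ``lower`` (default: the
    smallest cohort that can hold the sample) and ``upper``; acceptance is
    ``P(null score >= empirical score) >= alpha`` and is monotone
    nonincreasing in the TRC size throughout the sparse regime (cohort
    well above the sample size), so the bisection brackets the transition
    to within one family.  Very near the lower bound a clumped empirical
    composition can be *infeasible* (a cohort of exactly ``n`` is drawn
    whole, all families intact) and the search then reports the
    ``"lower"`` boundary flag instead of a bracket; pass a ``lower`` bound
    in the feasible regime to avoid this.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if lower is None:
        lower = ((n + s - 1) // s) * s
    lower = max(lower, s)
    if upper < lower:
        raise ValueError("upper bound below lower bound")
    lo = lower // s
    hi = upper // s
    trace: list[tuple[int, float]] = []

    ok_lo, tail_lo = _accept_at(lo * s, emp, n, s, alpha, iterations, seed, cap)
    trace.append((lo * s, tail_lo))
    if not ok_lo:
        return ConfidenceSearch(lo * s, alpha, lower, upper, "lower", iterations, seed, tuple(trace))
    ok_hi, tail_hi = _accept_at(hi * s, emp, n, s, alpha, iterations, seed, cap)
    trace.append((hi * s, tail_hi))
    if ok_hi:
        return ConfidenceSearch(hi * s, alpha, lower, upper, "upper", iterations, seed, tuple(trace))

    while hi - lo > 1:
        mid = (lo + hi) // 2
        ok, tail = _accept_at(mid * s, emp, n, s, alpha, iterations, seed, cap)
        trace.append((mid * s, tail))
        if ok:
            lo = mid
        else:
            hi = mid
    return ConfidenceSearch(lo * s, alpha, lower, upper, None, iterations, seed, tuple(trace))
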