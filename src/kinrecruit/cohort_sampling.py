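"""Monte-Carlo subsampling of light-trap-sized cohorts from a family-structured TRC.

A light-trap catch is modelled as ``n`` recruits drawn uniformly *without
replacement* from the total recruiting cohort.  The quantity of interest is
the sibship composition of the draw: ``c_k`` counts the families that
contributed exactly ``k`` members to the sample (``c_2`` = sibling pairs,
``c_3`` = triplets, ...).  Because every family has the same size ``s``,
the vector ``(c_0, ..., c_s)`` follows the multivariate hypergeometric
symmetry and the expected composition has the closed form

    E[c_k] = K * C(s, k) * C(N - s, n - k) / C(N, n),

the scaled hypergeometric pmf, which serves as the exact oracle for the
Monte-Carlo sampler.

The sampler itself runs a partial Fisher-Yates shuffle per draw (numba
kernel fed with uniforms from a seedable numpy Generator), so 10^5 draws
of 168 from cohorts of ~5 * 10^4 take seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.stats import hypergeom

from .demography import RecruitCohort

__all__ = [
    "SibshipComposition",
    "NullSummary",
    "draw_sample",
    "composition_counts",
    "null_summary",
    "expected_composition",
]


class SamplingError(ValueError):
    """Requested sample is infeasible for the cohort."""


@dataclass(frozen=True)
class SibshipComposition:
    """Counts ``c_k`` of families with exactly ``k`` sampled members.

    ``counts[k]`` is ``c_k`` for ``k = 0..s`` (``counts[0]`` is unused and
    kept at 0: families absent from the sample are not tracked).  The
    conservation identity ``sum_k k * c_k == n`` holds for every draw.
    """

    counts: np.ndarray
    sample_size: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 1 or (c < 0).any():
            raise ValueError("counts must be a 1-d nonnegative vector")
        ks = np.arange(len(c))
        if int((ks * c).sum()) != self.sample_size:
            raise ValueError("composition violates sum_k k*c_k == n")

    def count(self, k: int) -> int:
        """Number of families with exactly ``k`` sampled members."""
        if k >= len(self.counts):
            return 0
        return int(self.counts[k])

    @classmethod
    def from_counts(cls, counts: dict[int, int], sample_size: int | None = None):
        """Build from a ``{k: c_k}`` mapping (k >= 1)."""
        s = max(counts) if counts else 1
        vec = np.zeros(s + 1, dtype=np.int64)
        for k, c in counts.items():
            if k < 1:
                raise ValueError("event sizes must be >= 1")
            vec[k] = c
        n = int((np.arange(s + 1) * vec).sum())
        if sample_size is not None and sample_size != n:
            raise ValueError("sample_size inconsistent with counts")
        return cls(counts=vec, sample_size=n)


@dataclass(frozen=True)
class NullSummary:
    """Per-event-size Monte-Carlo mean and standard error of the null.

    ``mean_c[k]`` / ``se_c[k]`` summarize ``c_k`` over the draws; the seed
    and iteration count are recorded so every downstream number is
    traceable to its randomness source.
    """

    mean_c: np.ndarray
    se_c: np.ndarray
    iterations: int
    sample_size: int
    cohort_size: int
    family_size: int
    seed: int | None = None

    def mean(self, k: int) -> float:
        return float(self.mean_c[k]) if k < len(self.mean_c) else 0.0

    def se(self, k: int) -> float:
        return float(self.se_c[k]) if k < len(self.se_c) else 0.0


@njit(cache=True)
def _tally_compositions(n_families, s, n, u):  # pragma: no cover - jitted
    """Tally c_k for each row of uniforms ``u`` (iters x n).

    A single label array is partially Fisher-Yates shuffled per iteration;
    positions [0, n) after the swaps are a uniform without-replacement
    sample.  Family hit-counts are reset via the touched labels only, so
    each iteration costs O(n), independent of cohort size.
    """
    big_n = n_families * s
    labels = np.empty(big_n, dtype=np.int64)
    for i in range(big_n):
        labels[i] = i // s
    hits = np.zeros(n_families, dtype=np.int64)
    iters = u.shape[0]
    out = np.zeros((iters, s + 1), dtype=np.int64)
    for it in range(iters):
        for i in range(n):
            j = i + int(u[it, i] * (big_n - i))
            tmp = labels[i]
            labels[i] = labels[j]
            labels[j] = tmp
        for i in range(n):
            hits[labels[i]] += 1
        for i in range(n):
            fam = labels[i]
            if hits[fam] > 0:
                out[it, hits[fam]] += 1
                hits[fam] = 0
    return out


def composition_counts(
    cohort: RecruitCohort,
    n: int,
    iterations: int,
    rng: np.random.Generator,
    chunk: int = 20_000,
) -> np.ndarray:
    """Raw per-draw compositions: an ``(iterations, s + 1)`` count matrix.

    Row ``t`` holds ``c_0..c_s`` for draw ``t`` (``c_0`` always 0).
    """
    if n < 0 or n > cohort.size:
        raise SamplingError(f"cannot draw {n} from a cohort of {cohort.size}")
    if iterations < 1:
        raise SamplingError("iterations must be >= 1")
    blocks = []
    done = 0
    while done < iterations:
        m = min(chunk, iterations - done)
        u = rng.random((m, n))
        blocks.append(_tally_compositions(cohort.n_families, cohort.family_size, n, u))
        done += m
    return np.concatenate(blocks, axis=0)


def draw_sample(
    cohort: RecruitCohort, n: int, rng: np.random.Generator
) -> SibshipComposition:
    """One uniform without-replacement draw of ``n`` recruits, tallied."""
    counts = composition_counts(cohort, n, iterations=1, rng=rng)[0]
    return SibshipComposition(counts=counts, sample_size=n)


def null_summary(
    cohort: RecruitCohort,
    n: int,
    iterations: int = 100_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> NullSummary:
    """Monte-Carlo null of the sibship composition for samples of size ``n``.

    Either a ``seed`` (recorded in the summary) or an explicit generator may
    be given; results are reproducible for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = composition_counts(cohort, n, iterations, rng)
    mean = counts.mean(axis=0)
    se = counts.std(axis=0, ddof=1) / np.sqrt(iterations) if iterations > 1 else np.zeros_like(mean)
    return NullSummary(
        mean_c=mean,
        se_c=se,
        iterations=iterations,
        sample_size=n,
        cohort_size=cohort.size,
        family_size=cohort.family_size,
        seed=seed,
    )


def expected_composition(N: int, K: int, s: int, n: int) -> np.ndarray:
    """Exact expected composition ``E[c_k]`` for ``k = 0..s``.

    ``E[c_k] = K * hypergeom.pmf(k; N, s, n)``: the number of members a
    given family contributes to the sample is hypergeometric, and the
    expectation is additive over the ``K`` exchangeable families.
    """
    if K < 0 or s < 1 or N != K * s:
        raise ValueError("require N == K * s with K >= 0, s >= 1")
    if not 0 <= n <= N:
        raise ValueError(f"sample size {n} outside [0, {N}]")
    ks = np.arange(s + 1)
    return K * hypergeom.pmf(ks, N, s, n)
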