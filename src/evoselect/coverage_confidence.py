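"""Coupon-collector coverage confidence for saturation-mutagenesis libraries.

How many clones must be picked so that, with a stated confidence, every one of
m equally likely variant types (531 single substitutions for a 59-codon
window) is present at least once?  The question is answered two ways: a
Monte Carlo simulation of the draw-until-complete process, and an exact
inclusion-exclusion formula that serves as an analytic oracle,

    P(all m types seen in n draws) = sum_{k=0..m} (-1)^k C(m,k) (1 - k/m)^n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln


@dataclass
class CompletionDistribution:
    """Completion times of repeated draw-until-complete trials."""

    n_types: int
    draws_to_complete: np.ndarray
    n_trials: int
    seed: int

    def __post_init__(self) -> None:
        draws = np.asarray(self.draws_to_complete)
        if self.n_trials <= 0 or draws.size != self.n_trials:
            raise ValueError("n_trials must match the number of recorded trials")
        if draws.min(initial=self.n_types) < self.n_types:
            raise ValueError("a trial completed in fewer draws than types")
        self.draws_to_complete = draws

    def empirical_cdf(self, n_draws: int) -> float:
        """Fraction of trials complete within ``n_draws`` draws."""
        return float(np.mean(self.draws_to_complete <= n_draws))

    def quantile(self, level: float) -> int:
        """Smallest n such that at least ``level`` of trials completed by n."""
        k = math.ceil(level * self.n_trials)
        return int(np.partition(self.draws_to_complete, k - 1)[k - 1])


def simulate_completion_draws(
    n_types: int, n_trials: int, seed: int, batch_size: int = 1 << 14
) -> CompletionDistribution:
    """Monte Carlo completion times for the uniform coupon-collector process.

    Each trial draws uniform types until all ``n_types`` have been seen and
    records the number of draws.  The waiting time between the (i-1)-th and
    i-th *new* type is geometric with success probability (m-i+1)/m,
    independent across i, so each trial is sampled as a sum of m geometric
    variates — identical in distribution to the literal draw loop but
    vectorisable.  Reproducible for a fixed seed.
    """
    if n_types < 1:
        raise ValueError(f"n_types must be >= 1, got {n_types}")
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    rng = np.random.default_rng(seed)
    p_new = np.arange(n_types, 0, -1, dtype=float) / n_types
    out = np.empty(n_trials, dtype=np.int64)
    done = 0
    while done < n_trials:
        b = min(batch_size, n_trials - done)
        out[done : done + b] = rng.geometric(p_new, size=(b, n_types)).sum(axis=1)
        done += b
    return CompletionDistribution(
        n_types=n_types, draws_to_complete=out, n_trials=n_trials, seed=seed
    )


def exact_completion_cdf(n_types: int, n_draws: int) -> float:
    """Exact P(all types seen) by inclusion-exclusion.

    Terms are computed in log space via log-gamma and accumulated with
    compensated summation (``math.fsum``); the result is clamped to [0, 1].
    The alternating sum is well conditioned whenever n is comfortably above m
    (terms decay geometrically); with n close to m the true probability is
    tiny and the cancellation error of the alternating sum dominates, so
    results below a small floor are recomputed with the numerically stable
    (all-nonnegative) distinct-types Markov-chain recursion instead.
    """
    m = n_types
    if m < 1:
        raise ValueError(f"n_types must be >= 1, got {m}")
    if n_draws < 0:
        raise ValueError(f"n_draws must be >= 0, got {n_draws}")
    if n_draws < m:
        return 0.0
    log_cm = gammaln(m + 1)
    terms = [1.0]  # k = 0
    for k in range(1, m):  # k = m gives (1 - k/m)^n = 0 for n >= m >= 1
        log_term = (
            log_cm
            - gammaln(k + 1)
            - gammaln(m - k + 1)
            + n_draws * math.log((m - k) / m)
        )
        if log_term < -745.0:  # below float64 underflow; later terms smaller
            break
        terms.append((-1.0) ** k * math.exp(log_term))
    p = min(1.0, max(0.0, math.fsum(terms)))
    # Each term carries ~1e-16 relative error, so the sum is meaningless once
    # it falls below the largest term's magnitude times a safety factor; such
    # cases (n close to m, vanishing probability) go to the stable recursion.
    noise_floor = max(abs(t) for t in terms) * 1e-11
    if p < noise_floor:
        p = _completion_cdf_markov(m, n_draws)
    return p


def _completion_cdf_markov(m: int, n_draws: int) -> float:
    """P(all types seen) by powering the distinct-types-seen chain.

    All terms are nonnegative, so this is stable in the deep lower tail
    where inclusion-exclusion cancels catastrophically; cost O(n*m).
    """
    state = np.zeros(m + 1)
    state[0] = 1.0
    j = np.arange(m + 1, dtype=float)
    stay = j / m
    for _ in range(n_draws):
        nxt = state * stay
        nxt[1:] += state[:-1] * (1.0 - stay[:-1])
        state = nxt
    return float(state[m])


def confidence_threshold(
    n_types: int,
    level: float,
    method: str = "exact",
    n_trials: int = 1_000_000,
    seed: int | None = None,
    distribution: CompletionDistribution | None = None,
) -> int:
    """Minimum draws n with completion probability >= ``level``.

    ``method="monte_carlo"`` uses the empirical trial fraction (strict
    ">= level" on the count of completed trials, ties broken toward smaller
    n); ``method="exact"`` bisects :func:`exact_completion_cdf`.  A
    pre-computed :class:`CompletionDistribution` may be passed to avoid
    re-simulation.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if n_types < 1:
        raise ValueError(f"n_types must be >= 1, got {n_types}")
    if method in ("monte_carlo", "mc"):
        if distribution is None:
            if seed is None:
                raise ValueError("monte_carlo method requires a seed")
            distribution = simulate_completion_draws(n_types, n_trials, seed)
        elif distribution.n_types != n_types:
            raise ValueError("distribution was simulated for a different n_types")
        return distribution.quantile(level)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    lo, hi = n_types, max(n_types, 2)
    while exact_completion_cdf(n_types, hi) < level:
        lo, hi = hi, hi * 2
    while lo < hi:
        mid = (lo + hi) // 2
        if exact_completion_cdf(n_types, mid) >= level:
            hi = mid
        else:
            lo = mid + 1
    return lo


def asymptotic_threshold(n_types: int, level: float) -> float:
    """Gumbel (extreme-value) approximation m*(ln m - ln(-ln level))."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    return n_types * (math.log(n_types) - math.log(-math.log(level)))


@dataclass(frozen=True)
class CoverageReport:
    """Completion probability of a library and verdicts at requested levels."""

    n_types: int
    n_colonies: int
    probability: float
    meets_level: dict[float, bool]


def coverage_report(
    n_types: int, n_colonies: int, levels: tuple[float, ...] = (0.90, 0.95)
) -> CoverageReport:
    """Exact probability that ``n_colonies`` draws cover all types, with
    pass/fail flags against each requested confidence level."""
    if n_colonies < 0:
        raise ValueError(f"n_colonies must be >= 0, got {n_colonies}")
    p = exact_completion_cdf(n_types, n_colonies)
    return CoverageReport(
        n_types=n_types,
        n_colonies=n_colonies,
        probability=p,
        meets_level={lvl: p >= lvl for lvl in levels},
    )
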