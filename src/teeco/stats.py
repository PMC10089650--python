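"""Shared statistical machinery: exact tests, Bonferroni, seeded permutations.

Conventions used throughout the package:

* two-sided Fisher p-values follow the probability-mass rule (sum of
  hypergeometric probabilities of tables at least as extreme as observed);
* permutation p-values are ``(r + 1) / (n_perm + 1)`` with ``r`` the number
  of null statistics >= the observed one, so a finite run never reports 0;
* every stochastic routine takes an explicit integer seed, and per-unit
  child generators are derived by hashing ``(seed, unit name)`` so results
  do not depend on iteration order.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class EnrichmentResult:
    """Observed/expected/ratio/p/q for one unit (subfamily, class, gene set)."""

    unit: str
    observed: float
    expected_mean: float
    ratio: float
    p: float
    q: float = 1.0
    test: str = "permutation"
    p_perm: float | None = None  # permutation companion when test == fisher
    extra: dict = field(default_factory=dict)


def rng_for(seed: int, *names) -> np.random.Generator:
    """Deterministic child generator keyed by (seed, *names).

    Names are hashed with SHA-256 (never Python's salted ``hash``), so the
    stream for a given unit is stable across processes and input order.
    """
    keys = [
        int.from_bytes(hashlib.sha256(str(n).encode()).digest()[:8], "big")
        for n in names
    ]
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *keys])


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher's exact test p-value for a 2x2 count table."""
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("table must be 2x2 with nonnegative integer counts")
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def _u_from_ranks(rank_sum_x: float, n_x: int) -> float:
    return rank_sum_x - n_x * (n_x + 1) / 2.0


def mann_whitney_u(x, y, exact_max_n: int = 20) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact by enumeration for small samples.

    For ``n_x + n_y <= exact_max_n`` the null distribution of U is built by
    enumerating every assignment of the pooled midranks to the x-group (ties
    handled naturally); otherwise the tie-corrected normal approximation is
    used. The two-sided p is ``min(1, 2 * min(P(U <= u), P(U >= u)))``.
    Returns ``(U_x, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n_x, n_y = x.size, y.size
    n = n_x + n_y
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    u_obs = _u_from_ranks(ranks[:n_x].sum(), n_x)

    if n <= exact_max_n:
        us = np.fromiter(
            (
                _u_from_ranks(sum(ranks[i] for i in combo), n_x)
                for combo in itertools.combinations(range(n), n_x)
            ),
            dtype=float,
        )
        eps = 1e-9
        p_le = np.mean(us <= u_obs + eps)
        p_ge = np.mean(us >= u_obs - eps)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return float(u_obs), float(p)

    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def bonferroni(pvals) -> np.ndarray:
    """Bonferroni-adjusted q-values: ``q_i = min(1, m * p_i)``."""
    p = np.asarray(pvals, dtype=float)
    return np.minimum(1.0, p * p.size)


def permutation_pvalue(observed: float, null_values) -> tuple[float, float, float]:
    """(p, null_mean, ratio) with p = (#{null >= observed} + 1) / (n + 1).

    The enrichment ratio observed/mean(null) is ``inf`` when the null mean is
    zero and the observation positive, and ``nan`` when both are zero.
    """
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("need at least one permutation")
    p = (float(np.sum(null >= observed)) + 1.0) / (null.size + 1.0)
    mean = float(null.mean())
    if mean > 0:
        ratio = observed / mean
    else:
        ratio = float("inf") if observed > 0 else float("nan")
    return p, mean, ratio


def place_uniform(rng: np.random.Generator, lengths, chrom_length: int, n_perm: int) -> np.ndarray:
    """Uniform per-chromosome re-placement preserving element lengths.

    Returns an ``(n_perm, n_elements)`` array of start positions; element i
    keeps its length, so starts are drawn from ``[0, L - len_i]``. This is
    the randomizer every permutation test in the package shares.
    """
    lengths = np.asarray(lengths, dtype=np.int64)
    if (lengths > chrom_length).any():
        raise ValueError("element longer than chromosome")
    high = chrom_length - lengths + 1  # exclusive upper bound per element
    return rng.integers(0, high[None, :], size=(n_perm, lengths.size))
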