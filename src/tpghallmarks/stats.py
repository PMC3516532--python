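"""Statistical primitives shared by all analysis stages.

Empirical permutation p-values use the add-one convention
p = (1 + #{null >= observed}) / (N + 1), which never returns zero from a
finite number of permutations.  Two-sided empirical p-values double the
smaller tail and cap at 1, matching separate over/under calls downstream.
Z-normalization uses the population standard deviation because it is applied
to a full gene universe rather than a sample.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats as sps

from .models import EnrichmentResult


def empirical_pvalue(observed: float, null_values: Sequence[float] | np.ndarray,
                     tail: str = "ge") -> float:
    """Permutation p-value of ``observed`` against a sampled null.

    ``tail`` is 'ge' (null >= observed counts as extreme), 'le', or
    'two_sided' (double the smaller one-sided p, capped at 1).  Ties count
    as extreme in both directions.
    """
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("null_values must be non-empty")
    n = null.size
    p_ge = (1 + int(np.count_nonzero(null >= observed))) / (n + 1)
    p_le = (1 + int(np.count_nonzero(null <= observed))) / (n + 1)
    if tail == "ge":
        return p_ge
    if tail == "le":
        return p_le
    if tail == "two_sided":
        return min(1.0, 2.0 * min(p_ge, p_le))
    raise ValueError(f"unknown tail {tail!r}")


def benjamini_hochberg(p_values: Sequence[float] | np.ndarray,
                       q: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns (reject flags, q-values).  Q-values are p * m / rank with a
    cumulative minimum applied from the largest rank down, so they are
    monotone in p; a hypothesis is rejected iff its q-value is <= q.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    qvals_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    qvals_sorted = np.minimum(qvals_sorted, 1.0)
    qvals = np.empty(m)
    qvals[order] = qvals_sorted
    reject = qvals <= q
    return reject, qvals


def zscore_normalize(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Normalize to zero mean and unit population standard deviation."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    sd = x.std()  # population SD: normalizing a full universe, not a sample
    if sd == 0:
        raise ValueError("degenerate spread: constant input")
    return (x - x.mean()) / sd


def fold_enrichment_binomial(k: int, n: int, p0: float) -> EnrichmentResult:
    """Enrichment of k/n successes against background proportion p0.

    The fold is the ratio of proportions (k/n)/p0 and the p-value is the
    exact binomial tail: upper when the set is enriched (fold >= 1), lower
    otherwise.  A true odds ratio is not used; the fold matches the
    ratio-of-percentages arithmetic this statistic is reported with.
    """
    if n == 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    prop = k / n
    fold = prop / p0
    if fold >= 1.0:
        p = float(sps.binom.sf(k - 1, n, p0))  # P(X >= k)
        direction = "over"
    else:
        p = float(sps.binom.cdf(k, n, p0))  # P(X <= k)
        direction = "under"
    p = min(1.0, max(p, np.nextafter(0, 1)))
    return EnrichmentResult(observed=prop * 100.0, null_mean=p0 * 100.0,
                            fold=fold, p_value=p, direction=direction)


def odds_ratio_2x2(table: np.ndarray) -> float:
    """Sample odds ratio ad/bc (inf when bc = 0)."""
    (a, b), (c, d) = np.asarray(table, dtype=float)
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 count table.

    Returns (odds ratio, p).  The two-sided p sums all hypergeometric
    tables (at fixed margins) whose probability does not exceed the
    observed table's.  Zero margins leave the test undefined.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("undefined test: zero margin")
    res = sps.fisher_exact(t, alternative="two-sided")
    return odds_ratio_2x2(t), float(res.pvalue)
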