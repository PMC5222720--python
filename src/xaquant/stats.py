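"""Shared hypothesis tests: rank-sum, Fisher's exact, rank correlation.

The two-sample Wilcoxon rank-sum (Mann-Whitney) test is exact — full
enumeration of rank assignments with midranks for ties — when the combined
sample size is at most ``EXACT_LIMIT``, and a tie-corrected normal
approximation (scipy) otherwise.  Contingency comparisons use the
hypergeometric exact test for 2×2 tables, a full-enumeration
Freeman-Halton extension for small r×c tables, and chi-square with a
warning for larger ones.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.special
import scipy.stats

EXACT_LIMIT = 20  # combined n at or below which the rank-sum test enumerates


@dataclass
class RankSumResult:
    statistic: float  # Mann-Whitney U for the first sample
    p_value: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    method: str  # "exact" or "normal"


def rank_sum_test(a, b) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact by enumeration of all C(n_a + n_b, n_a) rank assignments (with
    average ranks for ties) when the combined size is <= 20; otherwise the
    tie-corrected normal approximation without continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"each group needs >= 2 defined values (got {len(a)} and {len(b)})"
        )
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pooled)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0

    if n_a + n_b <= EXACT_LIMIT:
        combos = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(n_a + n_b), n_a)),
            dtype=np.intp,
        ).reshape(-1, n_a)
        u_all = ranks[combos].sum(axis=1) - n_a * (n_a + 1) / 2.0
        center = n_a * n_b / 2.0
        p = float(np.mean(np.abs(u_all - center) >= np.abs(u_obs - center) - 1e-9))
        method = "exact"
    else:
        res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "normal"
    return RankSumResult(
        statistic=float(u_obs),
        p_value=min(p, 1.0),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        n_a=n_a,
        n_b=n_b,
        method=method,
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2×2 table (hypergeometric)."""
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 expects a 2×2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("contingency table has a zero margin; p = 1", stacklevel=2)
        return 1.0
    return float(scipy.stats.fisher_exact(table, alternative="two-sided")[1])


def _table_log_prob(table: np.ndarray, log_fact: np.ndarray) -> float:
    """Log conditional probability of an r×c table given its margins."""
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    return (
        log_fact[row].sum()
        + log_fact[col].sum()
        - log_fact[n]
        - log_fact[table].sum()
    )


def _enumerate_tables(row_sums, col_sums):
    """Yield all nonnegative integer tables with the given margins."""
    def fill(rows_left, col_remaining):
        if len(rows_left) == 1:
            yield [list(col_remaining)]
            return
        target = rows_left[0]

        def row_options(remaining, cols):
            if len(cols) == 1:
                if 0 <= remaining <= cols[0]:
                    yield [remaining]
                return
            for v in range(min(remaining, cols[0]) + 1):
                for rest in row_options(remaining - v, cols[1:]):
                    yield [v] + rest

        for row in row_options(target, list(col_remaining)):
            new_remaining = [c - v for c, v in zip(col_remaining, row)]
            for rest in fill(rows_left[1:], new_remaining):
                yield [row] + rest

    yield from fill(list(row_sums), list(col_sums))


def fisher_exact_rxc(table) -> float:
    """Exact Freeman-Halton p for an r×c table by full enumeration.

    Two-sided in the standard sense: the p-value sums the conditional
    probabilities of all margin-compatible tables no more probable than
    the observed one.
    """
    table = np.asarray(table, dtype=np.int64)
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        warnings.warn("contingency table has a zero margin; p = 1", stacklevel=2)
        return 1.0
    n = int(table.sum())
    log_fact = scipy.special.gammaln(np.arange(n + 1) + 1.0)
    lp_obs = _table_log_prob(table, log_fact)
    total = 0.0
    for cand in _enumerate_tables(row_sums, col_sums):
        lp = _table_log_prob(np.asarray(cand, dtype=np.int64), log_fact)
        if lp <= lp_obs + 1e-9:
            total += math.exp(lp)
    return float(min(total, 1.0))


def compare_contingency(table, exact_limit: int = 30) -> dict:
    """Compare category counts between groups (rows = groups).

    2×2 tables use the hypergeometric exact test; larger tables are exact
    by enumeration when the grand total is <= ``exact_limit`` and fall
    back to chi-square with a warning otherwise.  Zero-margin tables give
    p = 1 with a warning.
    """
    table = np.asarray(table, dtype=np.int64)
    if (table < 0).any():
        raise ValueError("contingency counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("contingency table has a zero margin; p = 1", stacklevel=2)
        return {"p_value": 1.0, "method": "degenerate"}
    if table.shape == (2, 2):
        return {"p_value": fisher_exact_2x2(table), "method": "fisher_exact"}
    if table.sum() <= exact_limit:
        return {"p_value": fisher_exact_rxc(table), "method": "freeman_halton"}
    warnings.warn(
        f"table total {table.sum()} exceeds exact limit {exact_limit}; "
        "using chi-square approximation",
        stacklevel=2,
    )
    chi2 = scipy.stats.chi2_contingency(table)
    return {"p_value": float(chi2.pvalue), "method": "chi2"}


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks; NaN when degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    return float(scipy.stats.spearmanr(x, y).statistic)
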