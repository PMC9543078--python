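"""Binomial intervals and contingency-table tests for outcome summaries.

Clopper-Pearson is the exact (conservative) binomial interval prescribed by
SWGDAM guidance for reporting match/exclusion rates; the Wilson score
interval is reported alongside as a narrower, near-nominal alternative. A
Pearson chi-squared test compares outcome distributions between comparison
modes, and a Fisher exact test (Monte-Carlo beyond 2x2) is available for
sparse tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma
from typing import Optional, Sequence

import numpy as np
import scipy.stats as st


class StatsError(ValueError):
    """Invalid counts, table, or confidence level."""


def _check_xn(x: int, n: int, level: float) -> None:
    if n < 1:
        raise StatsError(f"n must be >= 1, got {n}")
    if not 0 <= x <= n:
        raise StatsError(f"x must lie in [0, n], got x={x}, n={n}")
    if not 0.0 < level < 1.0:
        raise StatsError(f"level must be in (0, 1), got {level}")


def clopper_pearson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial interval from Beta quantiles.

    lo is the alpha/2 quantile of Beta(x, n-x+1) (exactly 0 when x = 0);
    hi is the 1-alpha/2 quantile of Beta(x+1, n-x) (exactly 1 when x = n).
    Returned as fractions.
    """
    _check_xn(x, n, level)
    alpha = 1.0 - level
    lo = 0.0 if x == 0 else float(st.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(st.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def wilson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval, clipped to [0, 1], returned as fractions.

    z is the exact normal quantile (1.959964 at 95%), not the rounded 1.96.
    """
    _check_xn(x, n, level)
    z = float(st.norm.ppf(1 - (1 - level) / 2))
    p = x / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    # at x = 0 (x = n) the score bound is analytically exact at 0 (1)
    lo = 0.0 if x == 0 else float(max(0.0, center - half))
    hi = 1.0 if x == n else float(min(1.0, center + half))
    return lo, hi


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float
    degenerate: bool = False  # zero rows/columns were dropped


def pearson_chi2(table: Sequence[Sequence[int]]) -> Chi2Result:
    """Pearson chi-squared test of independence, no continuity correction.

    Expected counts come from the row/column margins. All-zero rows or
    columns contribute nothing: they are dropped, the degrees of freedom
    reduced accordingly, and the result flagged degenerate.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise StatsError(f"table must be at least 2x2, got shape {obs.shape}")
    if (obs < 0).any():
        raise StatsError("table entries must be non-negative")
    if obs.sum() <= 0:
        raise StatsError("table must have a positive grand total")
    row_ok = obs.sum(axis=1) > 0
    col_ok = obs.sum(axis=0) > 0
    degenerate = not (row_ok.all() and col_ok.all())
    obs = obs[np.ix_(row_ok, col_ok)]
    r, c = obs.shape
    df = (r - 1) * (c - 1)
    if df == 0:
        return Chi2Result(statistic=0.0, df=0, p_value=1.0, degenerate=True)
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    statistic = float(((obs - expected) ** 2 / expected).sum())
    p = float(st.chi2.sf(statistic, df))
    return Chi2Result(statistic=statistic, df=df, p_value=p, degenerate=degenerate)


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    method: str  # "exact" or "monte_carlo"
    mc_se: Optional[float] = None  # standard error of the Monte-Carlo p


def _table_log_prob_part(table: np.ndarray) -> float:
    # log P(table | margins) up to the margin-dependent constant
    return -sum(lgamma(v + 1) for v in table.ravel())


def fisher_exact(
    table: Sequence[Sequence[int]],
    mc_draws: int = 100_000,
    seed: Optional[int] = None,
) -> FisherResult:
    """Two-sided Fisher exact test for an R x C count table.

    2x2 tables are tested exactly (sum of hypergeometric probabilities no
    larger than the observed table's). Larger tables use a Monte-Carlo
    estimate over margin-preserving tables, obtained by permuting column
    labels against row labels; the add-one estimator
    p = (1 + #{prob <= observed}) / (B + 1) is reported with its standard
    error. A table with a zero margin admits only one configuration, so
    p = 1.
    """
    obs = np.asarray(table, dtype=np.int64)
    if obs.ndim != 2 or (obs < 0).any():
        raise StatsError("table must be a 2-D array of non-negative integers")
    row_m, col_m = obs.sum(axis=1), obs.sum(axis=0)
    if (row_m == 0).any() or (col_m == 0).any():
        return FisherResult(p_value=1.0, method="exact")
    if obs.shape == (2, 2):
        p = float(st.fisher_exact(obs, alternative="two-sided")[1])
        return FisherResult(p_value=min(p, 1.0), method="exact")

    rng = np.random.default_rng(seed)
    n = int(obs.sum())
    row_labels = np.repeat(np.arange(obs.shape[0]), row_m)
    col_labels = np.repeat(np.arange(obs.shape[1]), col_m)
    obs_lp = _table_log_prob_part(obs)
    eps = 1e-9
    hits = 0
    flat_bins = obs.shape[0] * obs.shape[1]
    for _ in range(mc_draws):
        perm = rng.permutation(col_labels)
        flat = row_labels * obs.shape[1] + perm
        t = np.bincount(flat, minlength=flat_bins)
        if _table_log_prob_part(t) <= obs_lp + eps:
            hits += 1
    p = (1 + hits) / (mc_draws + 1)
    se = float(np.sqrt(p * (1 - p) / mc_draws))
    return FisherResult(p_value=p, method="monte_carlo", mc_se=se)


def outcome_summary(
    counts: Sequence[int], labels: Sequence[str] = ("cannot_exclude", "inconclusive", "exclude"),
    level: float = 0.95,
) -> dict:
    """Percentage and both CI methods (as percentages, 2 d.p. on display)
    for each outcome count over their total."""
    counts = [int(c) for c in counts]
    if len(counts) != len(labels):
        raise StatsError("counts and labels must align")
    n = sum(counts)
    if n < 1:
        raise StatsError("total count must be >= 1")
    out: dict = {"n_pairs": n, "level": level, "outcomes": {}}
    for label, x in zip(labels, counts):
        cp = clopper_pearson(x, n, level)
        wi = wilson(x, n, level)
        out["outcomes"][label] = {
            "count": x,
            "percentage": round(100 * x / n, 2),
            "clopper_pearson_pct": [round(100 * cp[0], 2), round(100 * cp[1], 2)],
            "wilson_pct": [round(100 * wi[0], 2), round(100 * wi[1], 2)],
        }
    return out
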