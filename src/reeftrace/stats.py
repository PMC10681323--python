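"""Nonparametric statistical toolkit.

Thin, contract-checked wrappers over scipy for the standard tests
(chi-squared goodness of fit, Spearman, Mann-Whitney, Kruskal-Wallis,
2x2 Fisher), plus hand-built routines where scipy has no equivalent:
the Dunn post-hoc Z comparisons and the Freeman-Halton extension of the
Fisher exact test to 2x3 tables by full enumeration.

Conventions follow the R ecosystem the field reports in: the
Mann-Whitney statistic is the rank-sum ``W`` of the first sample
(identical to scipy's U1; the classical U of the second sample is
``n1*n2 - W``), and Spearman reports both the tie-corrected rho and the
``S = sum(d^2)`` statistic on mid-ranks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    df: Optional[int] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 and not math.isnan(self.p_value):
            raise ConfigurationError(f"p-value {self.p_value} outside [0, 1]")


def chi_square_gof(observed: Sequence[float], expected_prop: Sequence[float]) -> TestResult:
    """Chi-squared goodness of fit against expected proportions."""
    obs = np.asarray(observed, dtype=float)
    prop = np.asarray(expected_prop, dtype=float)
    if obs.shape != prop.shape:
        raise ConfigurationError("observed and expected proportions differ in length")
    if (obs < 0).any():
        raise ConfigurationError("counts must be non-negative")
    if not math.isclose(prop.sum(), 1.0, abs_tol=1e-9):
        raise ConfigurationError("expected proportions must sum to 1")
    exp = obs.sum() * prop
    if (exp == 0).any():
        raise ConfigurationError("an expected count of zero is not allowed")
    stat, p = sps.chisquare(obs, exp)
    return TestResult("chi-squared goodness of fit", float(stat), float(p), df=len(obs) - 1)


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Tie-corrected Spearman rank correlation (two-sided).

    rho is the Pearson correlation of mid-ranks; ``extras['S']`` is the
    sum of squared rank differences on the same mid-ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ConfigurationError("spearman requires equal-length vectors of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ConfigurationError("spearman undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    s = float(((rx - ry) ** 2).sum())
    return TestResult("Spearman rank correlation", float(rho), float(p), extras={"S": s})


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided two-sample Mann-Whitney test.

    Statistic reported as the rank-sum ``W`` (R convention, = U of the
    first sample). Uses the exact null for small tie-free samples and
    the tie-corrected normal approximation otherwise; two samples whose
    pooled values are all identical compare equal (p = 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ConfigurationError("mann_whitney_u requires two non-empty samples")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return TestResult("Mann-Whitney U", float(len(a) * len(b) / 2.0), 1.0)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return TestResult(
        "Mann-Whitney U",
        float(res.statistic),
        float(min(1.0, res.pvalue)),
        extras={"U": float(len(a) * len(b) - res.statistic)},
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis rank-sum test with tie correction, df = k - 1."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ConfigurationError("kruskal_wallis requires >= 2 non-empty groups")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:  # all values tied across all groups
        return TestResult("Kruskal-Wallis rank sum", 0.0, 1.0, df=df)
    stat, p = sps.kruskal(*groups)
    return TestResult("Kruskal-Wallis rank sum", float(stat), float(p), df=df)


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    adjustment: str = "none",
) -> TestResult:
    """Dunn (1964) pairwise post-hoc comparisons on pooled mid-ranks.

    Z for groups i, j is the mean-rank difference over its standard
    error with the usual tie correction; two-sided p per pair, with
    optional Bonferroni adjustment over the k(k-1)/2 pairs. Empty
    groups are excluded. The returned statistic is the largest |Z|.
    """
    if adjustment not in ("none", "bonferroni"):
        raise ConfigurationError(f"unknown adjustment {adjustment!r}")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [str(i + 1) for i in range(len(arrays))]
    kept = [(l, g) for l, g in zip(labels, arrays) if len(g) > 0]
    if len(kept) < 2:
        raise ConfigurationError("dunn_posthoc requires >= 2 non-empty groups")
    labels = [l for l, _ in kept]
    arrays = [g for _, g in kept]

    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, start = [], [], 0
    for g in arrays:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n - 1))) if n > 1 else 0.0
    base_var = n * (n + 1) / 12.0 - tie_term

    m = len(arrays) * (len(arrays) - 1) // 2
    pairs = {}
    max_abs_z = 0.0
    for i, j in itertools.combinations(range(len(arrays)), 2):
        se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        if adjustment == "bonferroni":
            p = min(1.0, m * p)
        pairs[(labels[i], labels[j])] = {"z": float(z), "p": float(p)}
        max_abs_z = max(max_abs_z, abs(z))

    overall_p = min(v["p"] for v in pairs.values())
    return TestResult(
        "Dunn post-hoc",
        max_abs_z,
        float(overall_p),
        extras={"pairs": pairs, "adjustment": adjustment},
    )


def fisher_exact(table: Sequence[Sequence[int]]) -> TestResult:
    """Exact probability test on a 2x2 or 2x3 contingency table.

    p is the total null probability of all tables with the observed
    margins whose probability does not exceed the observed table's
    (two-sided, Freeman-Halton rule). 2x2 tables delegate to scipy;
    wider tables are fully enumerated, which is exact and fast for the
    small tables in scope.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] not in (2, 3):
        raise ConfigurationError("fisher_exact supports 2x2 and 2x3 tables")
    if (t < 0).any():
        raise ConfigurationError("counts must be non-negative")
    if t.sum() == 0 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        # a zero margin forces a degenerate (single-table) distribution
        return TestResult("Fisher exact", 0.0, 1.0)
    if t.shape[1] == 2:
        _, p = sps.fisher_exact(t, alternative="two-sided")
        return TestResult("Fisher exact", 0.0, float(p))

    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = int(t.sum())

    def log_prob(first_row: tuple[int, ...]) -> float:
        cells = list(first_row) + [c - f for c, f in zip(col, first_row)]
        logp = (
            sum(math.lgamma(r + 1) for r in row)
            + sum(math.lgamma(c + 1) for c in col)
            - math.lgamma(n + 1)
            - sum(math.lgamma(x + 1) for x in cells)
        )
        return logp

    obs_lp = log_prob(tuple(t[0]))
    total = 0.0
    # enumerate all first rows consistent with the margins
    for a in range(min(row[0], col[0]) + 1):
        for b in range(min(row[0] - a, col[1]) + 1):
            c = row[0] - a - b
            if c < 0 or c > col[2]:
                continue
            lp = log_prob((a, b, c))
            if lp <= obs_lp + 1e-9:
                total += math.exp(lp)
    return TestResult("Fisher exact (2x3 enumeration)", 0.0, float(min(1.0, total)))
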