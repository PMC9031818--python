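"""Phylogenetic Pearson correlation between two traits under Brownian motion.

For traits x, y on the tips of a tree with BM covariance C, the evolutionary
cross-products are GLS residual forms

    s_xy = dx' C^{-1} dy / (n - 1),   dx = x - âx·1, dy = y - ây·1,

with âx, ây the GLS root-state estimates, and the phylogenetic Pearson
correlation is r = s_xy / sqrt(s_xx · s_yy).  This equals the ordinary
correlation-through-the-origin of the phylogenetically independent
contrasts of x and y.  Computed over a posterior tree sample, the per-tree
r values form a sample from the posterior of r; the headline estimate is
their mean, the 95% interval the equal-tail quantiles, and the p value the
two-sided Student-t test applied to the posterior-mean r with n - 2 degrees
of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phylo_signal import (
    SignalError,
    _as_matrix,
    _solver,
    validate_trait_table,
)
from .trees import prune, tip_labels, vcv


def phylo_pearson(
    x: Sequence[float],
    y: Sequence[float],
    C,
    pseudo_inverse: bool = False,
) -> float:
    """Phylogenetic Pearson r of two aligned trait vectors on one tree."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise SignalError("trait vectors must have equal length")
    n = len(x)
    Cm = _as_matrix(C)
    solve = _solver(Cm, pseudo_inverse)
    ones = np.ones(n)
    ci1 = solve(ones)
    denom = ci1.sum()
    dx = x - (ci1 @ x) / denom
    dy = y - (ci1 @ y) / denom
    ci_dx = solve(dx)
    ci_dy = solve(dy)
    sxx = dx @ ci_dx / (n - 1)
    syy = dy @ ci_dy / (n - 1)
    if sxx <= 0 or syy <= 0:
        raise SignalError("zero evolutionary variance in a trait")
    sxy = dx @ ci_dy / (n - 1)
    r = sxy / np.sqrt(sxx * syy)
    return float(np.clip(r, -1.0, 1.0))


def correlation_test(r_mean: float, n: int) -> float:
    """Two-sided p for H0: rho = 0, via the t transform with n-2 df."""
    if n < 3:
        raise SignalError("need at least 3 tips")
    if abs(r_mean) >= 1.0:
        warnings.warn(
            "|r| = 1: p value is the degenerate limit 0", stacklevel=2
        )
        return 0.0
    df = n - 2
    t = r_mean * np.sqrt(df / (1.0 - r_mean**2))
    return float(2.0 * stats.t.sf(abs(t), df))


@dataclass
class CorrelationResult:
    """Posterior summary of phylogenetic r for one trait pair."""

    pair: tuple[str, str]
    r_values: np.ndarray  # per-tree r
    df: int  # n - 2

    @property
    def r_mean(self) -> float:
        return float(np.mean(self.r_values))

    @property
    def interval(self) -> tuple[float, float]:
        lo, hi = np.quantile(self.r_values, [0.025, 0.975])
        return float(lo), float(hi)

    @property
    def p(self) -> float:
        return correlation_test(self.r_mean, self.df + 2)


def correlate_over_sample(
    trait_x: str,
    trait_y: str,
    table: pd.DataFrame,
    trees,
    pseudo_inverse: bool = False,
) -> CorrelationResult:
    """Phylogenetic r of a trait pair over every tree of a sample.

    Per-tree r propagates phylogenetic uncertainty; the p value is computed
    from the posterior-mean r.  Trees are pruned to the trait table's
    language set; missing tips are fatal.
    """
    validate_trait_table(table)
    tips = [str(t) for t in table.index]
    x = table[trait_x].to_numpy(dtype=float)
    y = table[trait_y].to_numpy(dtype=float)
    rs = np.empty(len(trees))
    for j, tree in enumerate(trees):
        subtree = tree
        if set(tip_labels(tree)) != set(tips):
            subtree = prune(tree, tips)
        cov = vcv(subtree, tip_order=tips)
        rs[j] = phylo_pearson(x, y, cov, pseudo_inverse=pseudo_inverse)
    return CorrelationResult(
        pair=(trait_x, trait_y), r_values=rs, df=len(tips) - 2
    )


def correlation_results_frame(
    results: Sequence[CorrelationResult],
) -> pd.DataFrame:
    """Long per-tree table: ``pair, tree_index, r``."""
    rows = []
    for res in results:
        name = f"{res.pair[0]}~{res.pair[1]}"
        for j, r in enumerate(res.r_values):
            rows.append({"pair": name, "tree_index": j, "r": r})
    return pd.DataFrame(rows)


def correlation_summary_frame(
    results: Sequence[CorrelationResult],
) -> pd.DataFrame:
    """Summary table: ``pair, r_mean, ci_low, ci_high, p, df``."""
    rows = []
    for res in results:
        lo, hi = res.interval
        rows.append(
            {
                "pair": f"{res.pair[0]}~{res.pair[1]}",
                "r_mean": res.r_mean,
                "ci_low": lo,
                "ci_high": hi,
                "p": res.p,
                "df": res.df,
            }
        )
    return pd.DataFrame(rows)
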