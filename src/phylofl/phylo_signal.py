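"""Blomberg's K and the tip-randomization test for phylogenetic signal.

Given a continuous trait x over n tips and the BM covariance C of a rooted
dated tree, the two-step procedure is:

1. a permutation test against the null of no phylogenetic structure: the
   GLS mean-squared error MSE = d'C^{-1}d/(n-1) (d = x - â1, â the GLS
   root-state estimate) is compared with its distribution under random
   reassignment of trait values to tips; low MSE means the data fit the
   tree better than chance;
2. Blomberg's K = (MSE0/MSE) / E_BM[MSE0/MSE], the observed ratio of
   ordinary to GLS mean squared error scaled by its Brownian-motion
   expectation (tr(C) - n/(1'C^{-1}1))/(n-1).  K = 1 when trait variation
   matches BM on the tree, K < 1 for weaker signal, K > 1 for trait values
   more clumped by clade than BM predicts.

Both steps are repeated over every tree of a posterior sample and the
distribution of K (mean, sd) and the worst-case permutation p are reported,
propagating phylogenetic uncertainty.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .trees import PhyloCovariance, prune, tip_labels, vcv


class SignalError(ValueError):
    """Raised for degenerate inputs to the signal machinery."""


def validate_trait_table(table: pd.DataFrame) -> None:
    """Check a trait table: unique language ids, no missing values."""
    if table.index.has_duplicates:
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise SignalError(f"duplicate language ids: {dups}")
    if table.isna().any().any():
        bad = table.index[table.isna().any(axis=1)].tolist()
        raise SignalError(f"missing trait values for: {bad}")


def _as_matrix(C) -> np.ndarray:
    if isinstance(C, PhyloCovariance):
        return C.matrix
    return np.asarray(C, dtype=float)


def _solver(C: np.ndarray, pseudo_inverse: bool = False):
    """Return a function b -> C^{-1} b (Cholesky, or pinv fallback)."""
    if pseudo_inverse:
        Cinv = np.linalg.pinv(C, hermitian=True)
        return lambda b: Cinv @ b
    try:
        factor = cho_factor(C)
    except np.linalg.LinAlgError as exc:
        raise SignalError(
            "singular BM covariance matrix (zero-length terminal "
            "branches?); enable pseudo_inverse to proceed"
        ) from exc
    return lambda b: cho_solve(factor, b)


def gls_mean(x: Sequence[float], C, pseudo_inverse: bool = False) -> float:
    """GLS estimate of the root state: â = (1'C^{-1}1)^{-1} 1'C^{-1}x."""
    x = np.asarray(x, dtype=float)
    Cm = _as_matrix(C)
    solve = _solver(Cm, pseudo_inverse)
    ci1 = solve(np.ones(len(x)))
    return float(ci1 @ x / ci1.sum())


def _k_stats(x: np.ndarray, Cm: np.ndarray, solve):
    """(MSE0, MSE, expected ratio) for Blomberg's K."""
    n = len(x)
    ones = np.ones(n)
    ci1 = solve(ones)
    denom = ci1.sum()  # 1'C^{-1}1
    ahat = ci1 @ x / denom
    d = x - ahat
    mse0 = d @ d / (n - 1)
    mse = d @ solve(d) / (n - 1)
    expected = (np.trace(Cm) - n / denom) / (n - 1)
    return mse0, mse, expected


def blomberg_k(x: Sequence[float], C, pseudo_inverse: bool = False) -> float:
    """Blomberg's K of a trait on a tree's BM covariance."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise SignalError("need at least 3 tips")
    if np.ptp(x) == 0:
        raise SignalError("zero variance: trait is constant across tips")
    Cm = _as_matrix(C)
    solve = _solver(Cm, pseudo_inverse)
    mse0, mse, expected = _k_stats(x, Cm, solve)
    return float((mse0 / mse) / expected)


def signal_test(
    x: Sequence[float],
    C,
    n_perm: int = 999,
    rng: Optional[np.random.Generator] = None,
    pseudo_inverse: bool = False,
) -> float:
    """Tip-randomization p value for phylogenetic signal.

    The statistic is the GLS MSE (lower = better fit to the tree).  Trait
    values are shuffled across tips ``n_perm`` times and

        p = (1 + #{MSE_perm <= MSE_obs}) / (n_perm + 1),

    so p is never 0 and ties count against rejection (conservative).
    """
    if n_perm < 1:
        raise SignalError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    x = np.asarray(x, dtype=float)
    n = len(x)
    Cm = _as_matrix(C)
    solve = _solver(Cm, pseudo_inverse)

    ones = np.ones(n)
    ci1 = solve(ones)
    denom = ci1.sum()

    def mse_times_nm1(X: np.ndarray) -> np.ndarray:
        # rows of X are trait vectors; d'C^{-1}d = x'C^{-1}x - (1'C^{-1}x)^2/denom
        S = solve(X.T)  # (n, m)
        q = np.einsum("ij,ij->j", X.T, S)
        u = ci1 @ X.T  # 1'C^{-1}x per column
        return q - u**2 / denom

    obs = mse_times_nm1(x[None, :])[0]
    perms = rng.permuted(np.tile(x, (n_perm, 1)), axis=1)
    perm_stats = mse_times_nm1(perms)
    n_le = int(np.sum(perm_stats <= obs + 1e-12 * max(abs(obs), 1.0)))
    return (1 + n_le) / (n_perm + 1)


@dataclass
class KResult:
    """Per-tree and aggregated phylogenetic-signal results for one trait."""

    trait: str
    k_values: np.ndarray
    p_values: np.ndarray
    n_perm: int
    seed: int

    @property
    def mean_k(self) -> float:
        return float(np.mean(self.k_values))

    @property
    def sd_k(self) -> float:
        return float(np.std(self.k_values, ddof=1)) if len(self.k_values) > 1 else 0.0

    @property
    def max_p(self) -> float:
        return float(np.max(self.p_values))


def _trait_stream_key(trait: str) -> int:
    # stable across runs and platforms, unlike hash()
    return zlib.crc32(trait.encode("utf-8"))


def signal_over_sample(
    trait: str,
    table: pd.DataFrame,
    trees,
    n_perm: int = 999,
    seed: int = 0,
    pseudo_inverse: bool = False,
) -> KResult:
    """K and permutation p for one trait over every tree of a sample.

    Each (trait, tree) pair draws from its own deterministic random
    substream of ``seed``, so results do not depend on iteration order.
    Every tree is pruned to the trait table's language set; a missing tip
    is fatal.
    """
    validate_trait_table(table)
    tips = [str(t) for t in table.index]
    x = table[trait].to_numpy(dtype=float)
    tkey = _trait_stream_key(trait)
    ks = np.empty(len(trees))
    ps = np.empty(len(trees))
    for j, tree in enumerate(trees):
        subtree = tree
        if set(tip_labels(tree)) != set(tips):
            subtree = prune(tree, tips)
        cov = vcv(subtree, tip_order=tips)
        ks[j] = blomberg_k(x, cov, pseudo_inverse=pseudo_inverse)
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(tkey, j))
        )
        ps[j] = signal_test(
            x, cov, n_perm=n_perm, rng=rng, pseudo_inverse=pseudo_inverse
        )
    return KResult(
        trait=trait, k_values=ks, p_values=ps, n_perm=n_perm, seed=seed
    )


def k_results_frame(results: Sequence[KResult]) -> pd.DataFrame:
    """Long per-tree table: ``trait, tree_index, K, p``."""
    rows = []
    for r in results:
        for j, (k, p) in enumerate(zip(r.k_values, r.p_values)):
            rows.append({"trait": r.trait, "tree_index": j, "K": k, "p": p})
    return pd.DataFrame(rows)


def k_summary_frame(results: Sequence[KResult]) -> pd.DataFrame:
    """Summary table: ``trait, mean_K, sd_K, max_p, n_perm, seed``."""
    return pd.DataFrame(
        [
            {
                "trait": r.trait,
                "mean_K": r.mean_k,
                "sd_K": r.sd_k,
                "max_p": r.max_p,
                "n_perm": r.n_perm,
                "seed": r.seed,
            }
            for r in results
        ]
    )
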