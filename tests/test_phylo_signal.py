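"""Blomberg's K, the GLS mean, and the tip-randomization test."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest

import phylofl as pf
from phylofl.phylo_signal import SignalError

from conftest import pic_contrasts

X_WORKED = np.array([1.0, 2.0, 4.0])


class TestGlsMean:
    def test_worked_value(self, worked_cov):
        assert pf.gls_mean(X_WORKED, worked_cov) == pytest.approx(
            18 / 7, abs=1e-12)

    def test_reduces_to_ols_on_star_tree(self):
        C = 2.5 * np.eye(5)
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        assert pf.gls_mean(x, C) == pytest.approx(x.mean(), abs=1e-12)

    def test_constant_trait_recovered_exactly(self, worked_cov):
        assert pf.gls_mean(np.full(3, 7.3), worked_cov) == pytest.approx(
            7.3, abs=1e-12)

    def test_singular_matrix_raises_unless_pinv(self):
        C = np.ones((3, 3))
        with pytest.raises(SignalError, match="singular"):
            pf.gls_mean(X_WORKED, C)
        # pseudo-inverse fallback is available but off by default
        pf.gls_mean(X_WORKED, C, pseudo_inverse=True)


class TestBlombergK:
    def test_worked_value(self, worked_cov):
        # observed ratio 1659/784, BM expectation 12/7
        assert pf.blomberg_k(X_WORKED, worked_cov) == pytest.approx(
            1.234375, abs=1e-9)

    def test_star_tree_gives_exactly_one(self):
        rng = np.random.default_rng(4)
        C = 3.0 * np.eye(12)
        for _ in range(5):
            x = rng.standard_normal(12)
            assert pf.blomberg_k(x, C) == pytest.approx(1.0, abs=1e-10)

    def test_affine_invariance(self, worked_cov):
        k = pf.blomberg_k(X_WORKED, worked_cov)
        assert pf.blomberg_k(-2.5 * X_WORKED + 7, worked_cov) == (
            pytest.approx(k, abs=1e-10))

    def test_clade_constant_data_exceeds_one(self):
        # two clades, trait constant within each: maximal clumping
        tree = pf.tree_from_newick(
            "((A:1,B:1,C:1):3,(D:1,E:1,F:1):3);")
        cov = pf.vcv(tree, tip_order=["A", "B", "C", "D", "E", "F"])
        x = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        assert pf.blomberg_k(x, cov) > 1.0

    def test_constant_trait_rejected(self, worked_cov):
        with pytest.raises(SignalError, match="variance"):
            pf.blomberg_k(np.ones(3), worked_cov)

    def test_matches_pic_decomposition(self):
        """GLS residual form equals the sum of squared PIC contrasts."""
        for seed in (1, 2, 3):
            tree = pf.yule_tree(6, seed=seed)
            cov = pf.vcv(tree)
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(6)
            contrasts = pic_contrasts(
                tree, dict(zip(cov.tip_order, x)))
            from scipy.linalg import cho_factor, cho_solve

            f = cho_factor(cov.matrix)
            ci1 = cho_solve(f, np.ones(6))
            d = x - ci1 @ x / ci1.sum()
            mse_ratio = (d @ d) / (d @ cho_solve(f, d))
            pic_ratio = (d @ d) / (contrasts @ contrasts)
            assert mse_ratio == pytest.approx(pic_ratio, abs=1e-8)


class TestSignalTest:
    def test_clumped_data_minimal_p(self):
        tree = pf.tree_from_newick(
            "((A:0.05,B:0.05):3,(C:0.05,D:0.05):3);")
        cov = pf.vcv(tree, tip_order=["A", "B", "C", "D"])
        x = np.array([0.0, 0.01, 1.0, 1.01])
        rng = np.random.default_rng(0)
        p = pf.signal_test(x, cov, n_perm=999, rng=rng)
        # only the 8/24 relabelings preserving the clade split fit as well
        assert p < 0.5
        assert p >= 1 / 1000

    def test_tie_convention_constant_groups(self, worked_cov):
        # all permutations give an identical statistic -> p = 1
        x = np.array([5.0, 5.0, 5.0])
        p = pf.signal_test(x, worked_cov, n_perm=99,
                           rng=np.random.default_rng(1))
        assert p == 1.0

    def test_p_never_zero(self):
        tree = pf.yule_tree(16, seed=2)
        cov = pf.vcv(tree)
        x = pf.simulate_bm(
            tree, pf.BMSpec(rates=[[1.0]], root=[0.0], seed=3)
        ).loc[list(cov.tip_order)].to_numpy().ravel()
        p = pf.signal_test(x, cov, n_perm=199,
                           rng=np.random.default_rng(4))
        assert p >= 1 / 200

    def test_exhaustive_small_example(self):
        """p agrees with exhaustive enumeration of all tip relabelings."""
        import itertools

        from scipy.linalg import cho_factor, cho_solve

        tree = pf.tree_from_newick("((A:1,B:1):2,(C:1,D:1):2);")
        cov = pf.vcv(tree, tip_order=["A", "B", "C", "D"])
        x = np.array([0.0, 0.1, 2.0, 2.1])
        f = cho_factor(cov.matrix)
        ci1 = cho_solve(f, np.ones(4))

        def mse(v):
            d = v - ci1 @ v / ci1.sum()
            return d @ cho_solve(f, d)

        obs = mse(x)
        perms = [mse(np.array(p)) for p in itertools.permutations(x)]
        exact = sum(m <= obs + 1e-12 for m in perms) / len(perms)
        # exact proportion: clade-respecting relabelings fit equally well
        assert exact == pytest.approx(8 / 24)
        ps = [
            pf.signal_test(x, cov, n_perm=1999,
                           rng=np.random.default_rng(s))
            for s in range(3)
        ]
        assert np.mean(ps) == pytest.approx(exact, abs=0.05)


@pytest.fixture(scope="module")
def sample():
    trees = [pf.yule_tree(20, seed=s) for s in (10, 11, 12)]
    table = pd.DataFrame(
        {
            "FLVu": pf.simulate_bm(
                trees[0], pf.BMSpec(rates=[[1.0]], root=[0.0], seed=1)
            ).iloc[:, 0]
        }
    )
    return trees, table


class TestSignalOverSample:
    def test_determinism_under_seed(self, sample):
        trees, table = sample
        r1 = pf.signal_over_sample("FLVu", table, trees, n_perm=99, seed=5)
        r2 = pf.signal_over_sample("FLVu", table, trees, n_perm=99, seed=5)
        assert np.array_equal(r1.k_values, r2.k_values)
        assert np.array_equal(r1.p_values, r2.p_values)
        assert r1.mean_k == r2.mean_k and r1.max_p == r2.max_p

    def test_generating_tree_k_near_one_iid_low(self):
        tree = pf.yule_tree(48, seed=21)
        cov = pf.vcv(tree)
        rng = np.random.default_rng(0)
        spec = pf.BMSpec(rates=[[1.0]], root=[0.0])
        # sd(K) ~ 0.55 on this tree, so 400 replicates put the +/-0.1
        # band at ~3.6 standard errors
        k_bm = np.mean([
            pf.blomberg_k(
                pf.simulate_bm(tree, spec, rng=rng)
                .loc[list(cov.tip_order)].to_numpy().ravel(), cov)
            for _ in range(400)
        ])
        k_iid = np.mean([
            pf.blomberg_k(rng.standard_normal(48), cov)
            for _ in range(100)
        ])
        assert 0.9 < k_bm < 1.1
        assert k_iid < 0.5

    def test_missing_tip_is_fatal(self, sample):
        trees, table = sample
        bad = table.copy()
        bad.index = ["ZZZ"] + list(table.index[1:])
        with pytest.raises(Exception, match="ZZZ"):
            pf.signal_over_sample("FLVu", bad, trees, n_perm=9, seed=0)

    def test_missing_values_rejected(self, sample):
        trees, table = sample
        bad = table.copy()
        bad.iloc[0, 0] = np.nan
        with pytest.raises(SignalError, match="missing"):
            pf.signal_over_sample("FLVu", bad, trees, n_perm=9, seed=0)


class TestAgainstReferenceImplementations:
    def test_k_matches_picante(self, tmp_path):
        """Cross-check K against the R picante package on one fixture."""
        tree = pf.yule_tree(8, seed=13)
        cov = pf.vcv(tree)
        rng = np.random.default_rng(14)
        x = rng.standard_normal(8)
        ours = pf.blomberg_k(x, cov)
        nwk = tmp_path / "t.nwk"
        pf.write_trees([tree], nwk, format="newick")
        vals = ";".join(
            f"{lbl}={float(v)!r}" for lbl, v in zip(cov.tip_order, x))
        rcode = (
            "suppressMessages(library(picante));"
            f"tr <- read.tree('{nwk}');"
            f"kv <- strsplit('{vals}', ';')[[1]];"
            "parts <- strsplit(kv, '=');"
            "x <- as.numeric(sapply(parts, `[`, 2));"
            "names(x) <- sapply(parts, `[`, 1);"
            "cat(format(Kcalc(x[tr$tip.label], tr), digits=15))"
        )
        out = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True,
            check=True)
        theirs = float(out.stdout.strip())
        assert ours == pytest.approx(theirs, rel=1e-10)
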