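# phylofl

Phylogenetic analysis of the functional load of phonological
contrasts: how much work a contrast (vowel length, consonant manner,
consonant place) does in keeping word forms distinct, whether that
workload evolves along a language family tree, and whether different
contrasts trade off against each other once shared descent is
controlled for.

## The problem

Languages differ in how heavily they lean on particular phonological
contrasts. The **functional load** of a contrast φ in language Λ is
the information lost when the contrast is erased from the language's
analysis domain — here the tonic (first) vowel plus a single
intervocalic post-tonic consonant of each word:

    fl(φ, Λ) = H(S) − H(S_φ̄)          (unnormalized, bits)
    fnorm(φ, Λ) = fl(φ, Λ) / H(S)      (normalized)

where `S` is the distribution of (tonic vowel, post-tonic consonant)
string types, `H` is Shannon entropy, and `S_φ̄` is the same
distribution after merging the phoneme sets that φ distinguishes.
Six variables result: FLVu/FLVn (vowel length), FLCu/FLCn (consonant
manner), FLPu/FLPn (consonant place).

Related languages are not independent samples, so both questions are
asked phylogenetically, on a dated family tree `t` whose Brownian-
motion covariance is `C[i,j]` = shared root-to-tip path length:

- **Signal** (study 1): Blomberg's
  `K = (MSE₀/MSE) / [(tr C − n/(1ᵀC⁻¹1)) / (n−1)]`, calibrated so
  K = 1 under Brownian motion, with significance from a tip-
  randomization permutation test on the GLS mean squared error.
- **Trade-off** (study 2): the phylogenetic Pearson correlation
  `r = dₓᵀC⁻¹d_y / √(dₓᵀC⁻¹dₓ · d_yᵀC⁻¹d_y)` (d = deviations from
  the GLS mean; identical to the correlation of independent contrasts
  through the origin), with p from the t transform on n − 2 df,
  aggregated over a sample of trees.

A negative FLV–FLC correlation with a null FLV–FLP correlation is the
trade-off signature: length and manner compete for the same
disambiguation work; place is a control that should not.

## Worked example

The hand-checkable 3-tip tree `((A:1,B:1):1,C:2)` with
x = (1, 2, 4), y = (3, 1, 2):

```python
>>> import numpy as np, phylofl as pf
>>> tree = pf.tree_from_newick("((A:1,B:1):1,C:2);")
>>> cov = pf.vcv(tree, tip_order=["A", "B", "C"])
>>> cov.matrix
array([[2., 1., 0.],
       [1., 2., 0.],
       [0., 0., 2.]])
>>> pf.gls_mean(np.array([1., 2., 4.]), cov)        # 18/7
2.5714285714285716
>>> pf.blomberg_k(np.array([1., 2., 4.]), cov)      # 1659/784 ÷ 12/7
1.2343750000000004
>>> pf.phylo_pearson(np.array([1., 2., 4.]), np.array([3., 1., 2.]), cov)
-0.4677071733467427
```

Functional load on a four-type toy profile (one bit carried entirely
by vowel length):

```python
>>> prof = pf.DomainProfile("L", {("a", "t"): 1, ("aː", "t"): 1,
...                               ("a", "d"): 1, ("aː", "d"): 1})
>>> res = pf.functional_load(
...     prof, pf.ContrastSpec.make("FLV", [{"a", "aː"}], "vowel"))
>>> res.fl, res.fl_norm
(1.0, 0.5)
```

The `examples/` scripts walk through each capability end to end,
including a full synthetic study (`examples/04_tradeoff_study.py`)
that evolves a vowel-length/consonant-manner trade-off on a simulated
tree, rebuilds lexicons, recomputes FL from raw wordforms, and runs
both studies via `pf.run_all`. The same pipeline is available from
the shell as `phylofl run-all --trees ... --lexicons ...
--segment-tables ... --out ...` (see `phylofl --help`).

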