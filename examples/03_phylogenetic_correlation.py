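"""Phylogenetic Pearson correlation between two evolving traits.

An ordinary correlation across related languages is confounded by
shared descent.  The phylogenetic Pearson correlation removes that
confound by whitening both traits with the inverse Brownian-motion
covariance of the tree (equivalently, by correlating independent
contrasts through the origin), and its significance comes from the
usual t transform on n - 2 degrees of freedom.
"""

import numpy as np

import phylofl as pf

# Worked 3-tip example from the hand computation: r = -0.467707.
tree = pf.tree_from_newick("((A:1,B:1):1,C:2);")
cov = pf.vcv(tree, tip_order=["A", "B", "C"])
x = np.array([1.0, 2.0, 4.0])
y = np.array([3.0, 1.0, 2.0])
print(f"3-tip worked example: r = {pf.phylo_pearson(x, y, cov):.6f}")

# Recovery: traits evolved with BM increment correlation -0.5 on a
# 90-tip tree.  The naive Pearson r fluctuates widely run to run; the
# phylogenetic r averages to the generating value.
tree = pf.yule_tree(90, seed=20)
cov = pf.vcv(tree)
order = list(cov.tip_order)
spec = pf.BMSpec(rates=[[1.0, -0.5], [-0.5, 1.0]], root=[0.0, 0.0])
rng = np.random.default_rng(20)
phylo_rs, naive_rs = [], []
for _ in range(200):
    xy = pf.simulate_bm(tree, spec, rng=rng).loc[order].to_numpy()
    phylo_rs.append(pf.phylo_pearson(xy[:, 0], xy[:, 1], cov))
    naive_rs.append(np.corrcoef(xy[:, 0], xy[:, 1])[0, 1])
print(f"generating increment correlation: -0.5")
print(f"mean phylogenetic r over 200 replicates: {np.mean(phylo_rs):+.3f}"
      f" (sd {np.std(phylo_rs):.3f})")
print(f"mean naive r over 200 replicates:        {np.mean(naive_rs):+.3f}"
      f" (sd {np.std(naive_rs):.3f})")

# The pipeline entry point: aggregate over a tree sample (here of
# size one) and attach a p value via the t transform.
traits = pf.simulate_bm(tree, spec, rng=np.random.default_rng(21))
res = pf.correlate_over_sample(
    traits.columns[0], traits.columns[1], traits, [tree])
print(f"\nsingle-sample analysis: r = {res.r_mean:+.3f}, "
      f"p = {res.p:.4f}, df = {res.df}")
print("The phylogenetic estimate is centred on the generating value and"
      "\nmuch less dispersed than the naive correlation.")
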