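"""End-to-end synthetic study: evolve a trade-off, then detect it.

A latent preference evolves by Brownian motion along a simulated
family tree; each tip language builds its lexicon from a mixture that
trades vowel-length contrasts against consonant-manner contrasts
(mixing weight = logistic of the latent value), while consonant place
varies independently.  The pipeline then recomputes functional loads
from the raw wordforms and runs both studies:

  study 1 -- phylogenetic signal (Blomberg's K + permutation test)
  study 2 -- phylogenetic correlations between FL variables
"""

import pathlib
import tempfile

import phylofl as pf

workdir = pathlib.Path(tempfile.mkdtemp(prefix="phylofl_demo_"))
tree = pf.yule_tree(40, seed=7)
lexicons, thetas = pf.evolve_tradeoff(tree, bm_seed=8)
pf.write_trees([tree], workdir / "trees.nwk", format="newick")
pf.lexicon.write_lexicons(lexicons, workdir / "lexicons.tsv")
pf.lexicon.write_segment_table(
    pf.tradeoff_segment_table(), workdir / "segments.csv")
print(f"simulated {len(lexicons)} languages; "
      f"theta range {thetas.min():.3f}..{thetas.max():.3f}")

cfg = pf.RunConfig(
    trees=str(workdir / "trees.nwk"),
    tree_format="newick",
    lexicons=str(workdir / "lexicons.tsv"),
    segment_tables=str(workdir / "segments.csv"),
    n_perm=999,
    seed=0,
    out_dir=str(workdir / "out"),
)
results = pf.run_all(cfg)
print("\nstudy 1 (signal):")
print(results["study1"].to_string(index=False))
print("\nstudy 2 (correlation):")
print(results["study2"].to_string(index=False))
print(f"\nfull CSV outputs in {workdir / 'out'}")
print("\nExpected pattern: strong signal in FLV/FLC (the trade-off is"
      "\nclade-structured), a significant negative FLV-FLC correlation,"
      "\nand a much weaker FLV-FLP correlation (place is independent of"
      "\nthe trade-off; residual association reflects the shared-entropy"
      "\nestimation noise discussed in docs/methods.md).")
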