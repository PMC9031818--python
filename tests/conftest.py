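import numpy as np
import pytest

import phylofl as pf


@pytest.fixture(scope="session")
def worked_tree():
    """Three-tip tree used in all hand-computed matrix examples."""
    return pf.tree_from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def worked_cov(worked_tree):
    return pf.vcv(worked_tree, tip_order=["A", "B", "C"])


@pytest.fixture(scope="session")
def tradeoff_table():
    return pf.tradeoff_segment_table()


@pytest.fixture(scope="session")
def rich_table():
    """Inventory with several vowel pairs, glides, and a digraph consonant."""
    S = pf.Segment
    return pf.SegmentTable(
        [
            S("a", "vowel", length="short", length_partner="aː"),
            S("aː", "vowel", length="long", length_partner="a"),
            S("i", "vowel", length="short", length_partner="iː"),
            S("iː", "vowel", length="long", length_partner="i"),
            S("u", "vowel", length="short", length_partner="uː"),
            S("uː", "vowel", length="long", length_partner="u"),
            S("p", "consonant", place="bilabial", manner="stop"),
            S("t", "consonant", place="apical", manner="stop"),
            S("d", "consonant", place="apical", manner="voiced"),
            S("n", "consonant", place="apical", manner="nasal"),
            S("nt", "consonant", place="apical", manner="prestopped"),
            S("k", "consonant", place="velar", manner="stop"),
            S("w", "consonant", place="labiovelar", manner="glide"),
            S("j", "consonant", place="palatal", manner="glide"),
        ]
    )


def pic_contrasts(tree, values):
    """Independent PIC oracle: Felsenstein pruning on a binary tree.

    ``values`` maps tip label -> trait value.  Returns the n-1
    standardized contrasts.
    """
    out = []

    def rec(node):
        if node.is_leaf():
            return values[node.taxon.label], node.edge.length or 0.0
        children = node.child_nodes()
        assert len(children) == 2, "PIC oracle needs a binary tree"
        (x1, v1), (x2, v2) = (rec(ch) for ch in children)
        out.append((x1 - x2) / np.sqrt(v1 + v2))
        xa = (x1 / v1 + x2 / v2) / (1 / v1 + 1 / v2)
        va = (node.edge.length or 0.0) + v1 * v2 / (v1 + v2)
        return xa, va

    rec(tree.seed_node)
    return np.array(out)
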