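"""Shared fixtures and small generators used across the test modules."""

from __future__ import annotations

import numpy as np
import pytest
from skbio import TreeNode

from pockettree.alignments import Alignment, SwapGroup, make_seed

# --- hand-written PDB fixtures -------------------------------------------

MINI_PDB = """\
HEADER    MINIMAL TWO-RESIDUE FIXTURE
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      12.560   6.351  -6.512  1.00  0.00           C
ATOM      3  N   GLY A   2      13.104   7.134  -3.504  1.00  0.00           N
ATOM      4  CA  GLY A   2      14.560   7.351  -3.512  1.00  0.00           C
END
"""

# one atom with altlocs A (occupancy 0.4) and B (occupancy 0.6)
ALTLOC_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA AALA A   1      12.560   6.351  -6.512  0.40  0.00           C
ATOM      3  CA BALA A   1      12.660   6.451  -6.612  0.60  0.00           C
END
"""

# equal-occupancy altlocs: tie broken toward 'A'
ALTLOC_TIE_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA AALA A   1      12.560   6.351  -6.512  0.50  0.00           C
ATOM      3  CA BALA A   1      12.660   6.451  -6.612  0.50  0.00           C
END
"""


@pytest.fixture
def mini_pdb() -> str:
    return MINI_PDB


# --- alignment fixtures ----------------------------------------------------


@pytest.fixture
def toy_seed():
    """3-row seed, no gaps, designated columns 2, 5, 7."""
    aln = Alignment(
        ids=["r1", "r2", "r3"],
        rows=["AKCDEFGH", "AKCDEFGH", "TKCDEWGH"],
    )
    return make_seed(aln, designated_columns=(2, 5, 7))


@pytest.fixture
def swap_seed():
    """Two subfamilies whose hinge residues occupy the same three pocket
    slots in opposite sequential order (the swapped-loop situation).

    Subfamily A rows carry F-W-L across the group columns in natural
    order; subfamily B rows carry the structurally equivalent residues in
    reversed sequential order, declared via the group permutation.
    """
    aln = Alignment(
        ids=["A1", "A2", "B1", "B2"],
        rows=["GFWLG", "GFWLG", "GLWFG", "GLWFG"],
    )
    grp = SwapGroup(
        columns=(2, 3, 4),
        permutations={"fungal": (4, 3, 2)},
        members={"human": frozenset({"A1", "A2"}), "fungal": frozenset({"B1", "B2"})},
    )
    return make_seed(aln, designated_columns=(2, 3, 4), swap_groups=[grp])


# --- random tree generator --------------------------------------------------


def random_binary_tree(n_leaves: int, rng: np.random.Generator) -> TreeNode:
    """Random rooted binary tree with uniform branch lengths in [0.05, 1]."""
    nodes = [TreeNode(name=f"L{i}", length=float(rng.uniform(0.05, 1.0)))
             for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.05, 1.0)))
        parent.append(nodes[i])
        parent.append(nodes[j])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = None
    return root


def additive_matrix(tree: TreeNode):
    """(ids, matrix) of leaf-to-leaf path lengths."""
    ids = sorted(leaf.name for leaf in tree.tips())
    dm = tree.tip_tip_distances(endpoints=ids)
    return list(dm.ids), np.asarray(dm.data, dtype=float)
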