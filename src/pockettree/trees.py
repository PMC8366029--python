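"""Distance matrices and neighbor-joining binding-site trees.

Trees built from a pocket-only reduced alignment are *binding-site trees*:
they group sequences by binding-cavity similarity, not by evolutionary
history, but are constructed with ordinary phylogenetic machinery —
corrected pairwise distances followed by neighbor joining.  Branch lengths
are in substitutions per site.

The tree container is :class:`skbio.TreeNode`; this module only adds the
distance models, the NJ agglomeration with the tie/clamping conventions
documented below, and Newick round-trip helpers.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .alignments import GAP, Alignment, ReducedAlignment

DISTANCE_MODELS = ("p", "poisson")
GAP_RULES = ("pairwise_deletion", "complete_deletion")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances plus per-pair comparable-site counts."""

    ids: list[str]
    data: np.ndarray
    model: str
    comparable_sites: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.data) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.data < 0):
            raise ValueError("distances must be nonnegative")
        if self.comparable_sites is None:
            self.comparable_sites = np.full((n, n), -1, dtype=int)

    def index(self, seq_id: str) -> int:
        try:
            return self.ids.index(seq_id)
        except ValueError:
            raise KeyError(f"id {seq_id!r} not in distance matrix") from None

    def between(self, a: str, b: str) -> float:
        return float(self.data[self.index(a), self.index(b)])

    def to_tsv(self) -> str:
        lines = ["\t".join([""] + self.ids)]
        for i, sid in enumerate(self.ids):
            lines.append("\t".join([sid] + [f"{v:.6f}" for v in self.data[i]]))
        return "\n".join(lines) + "\n"


def _encode(rows: list[str]) -> np.ndarray:
    arr = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
    return arr.reshape(len(rows), -1)


def pairwise_distance(
    aln: ReducedAlignment | Alignment,
    model: str = "poisson",
    gap_rule: str = "pairwise_deletion",
    max_distance: float = 5.0,
) -> DistanceMatrix:
    """Pairwise p- or Poisson-corrected distances.

    p = mismatches / comparable sites, where comparable sites are the
    columns where both rows are non-gap (``pairwise_deletion``) or, under
    ``complete_deletion``, the columns with no gap in any row.  The Poisson
    correction d = −ln(1 − p) is capped at ``max_distance`` for saturated
    pairs (p close to or at 1), with a warning listing them.

    Raises ``ValueError`` naming the pair if a pair has zero comparable
    sites.
    """
    if model not in DISTANCE_MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {DISTANCE_MODELS}")
    if gap_rule not in GAP_RULES:
        raise ValueError(f"unknown gap rule {gap_rule!r}; choose from {GAP_RULES}")
    ids, rows = list(aln.ids), list(aln.rows)
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences")

    X = _encode(rows)
    gap_byte = ord(GAP)
    nongap = X != gap_byte
    if gap_rule == "complete_deletion":
        keep = nongap.all(axis=0)
        if not keep.any():
            raise ValueError("complete deletion removed every column")
        X, nongap = X[:, keep], nongap[:, keep]
    width = X.shape[1]

    n = len(ids)
    comparable = np.zeros((n, n), dtype=int)
    p = np.zeros((n, n), dtype=float)
    for i in range(n):
        both = nongap[i] & nongap[i + 1:]
        comp = both.sum(axis=1)
        mism = ((X[i] != X[i + 1:]) & both).sum(axis=1)
        comparable[i, i + 1:] = comp
        comparable[i + 1:, i] = comp
        with np.errstate(invalid="ignore", divide="ignore"):
            pv = np.where(comp > 0, mism / np.maximum(comp, 1), np.nan)
        p[i, i + 1:] = pv
        p[i + 1:, i] = pv
    np.fill_diagonal(comparable, width)

    zero_pairs = [
        (ids[i], ids[j])
        for i in range(n) for j in range(i + 1, n)
        if comparable[i, j] == 0
    ]
    if zero_pairs:
        raise ValueError(f"pairs with zero comparable sites: {zero_pairs}")

    if model == "p":
        d = p.copy()
    else:
        d = np.zeros_like(p)
        off = ~np.eye(n, dtype=bool)
        with np.errstate(divide="ignore"):
            d[off] = -np.log(np.maximum(1.0 - p[off], 0.0))
        # pairs sharing (almost) no residues carry no usable signal: cap them
        sat_thresh = 1.0 - 1.0 / max(width, 1)
        saturated = (p >= sat_thresh) & (p > 0) & off
        d[saturated] = max_distance
        d = np.minimum(np.where(np.isfinite(d), d, max_distance), max_distance)
        if saturated.any():
            pairs = [
                (ids[i], ids[j])
                for i in range(n) for j in range(i + 1, n) if saturated[i, j]
            ]
            shown = ", ".join(f"{a}/{b}" for a, b in pairs[:5])
            more = f" (+{len(pairs) - 5} more)" if len(pairs) > 5 else ""
            warnings.warn(
                f"{len(pairs)} saturated pair(s) capped at {max_distance}: "
                f"{shown}{more}",
                stacklevel=2,
            )
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry

    return DistanceMatrix(ids=ids, data=d, model=model, comparable_sites=comparable)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Classic neighbor joining (Q-criterion agglomeration).

    Conventions: ties in the Q matrix are broken toward the lowest index
    pair; a negative limb length is clamped to 0 with the deficit moved to
    the sibling limb; the final join leaves an unrooted trifurcation (or,
    for two leaves, a single edge split d/2 : d/2).  The returned tree is
    tagged ``tree.rooted = False``.
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least 2 ids")
    D = dm.data.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=sid) for sid in dm.ids]

    if n == 2:
        half = float(D[0, 1]) / 2.0
        root = TreeNode()
        for node in nodes:
            node.length = half
            root.append(node)
        root.rooted = False
        return root

    active = list(range(n))
    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index tie break: first occurrence of the minimum in row-major order
        flat = int(np.argmin(Q))
        ai, aj = divmod(flat, k)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]

        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (k - 2))
        lj = dij - li
        # clamp negatives, transferring the deficit to the sibling limb
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)

        parent = TreeNode()
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        parent.append(nodes[i])
        parent.append(nodes[j])

        # distances from the new node to the remaining ones
        du = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = du
        D[:, i] = du
        D[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    root = TreeNode()
    if len(active) == 3:
        a, b, c = active
        la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
        lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
        lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
        for node_idx, length in ((a, la), (b, lb), (c, lc)):
            nodes[node_idx].length = float(max(length, 0.0))
            root.append(nodes[node_idx])
    else:  # two clusters left (possible when starting from n == 3 joined once)
        a, b = active
        half = float(D[a, b]) / 2.0
        for node_idx in (a, b):
            nodes[node_idx].length = half
            root.append(nodes[node_idx])
    root.rooted = False
    return root


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Optional midpoint rooting (delegates to scikit-bio)."""
    rooted = tree.root_at_midpoint()
    rooted.rooted = True
    return rooted


# ---------------------------------------------------------------------------
# Newick I/O


def write_newick(tree: TreeNode) -> str:
    """Serialize to Newick; labels containing spaces are quoted."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


def read_newick(text: str) -> TreeNode:
    """Parse Newick text; raises ``ValueError`` on malformed input."""
    if text.count("(") != text.count(")"):
        # report the position of the first unmatched parenthesis
        depth = 0
        pos = len(text)
        for k, ch in enumerate(text):
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
            if depth < 0:
                pos = k
                break
        raise ValueError(f"unbalanced parentheses in Newick (near position {pos})")
    try:
        tree = TreeNode.read(io.StringIO(text), format="newick",
                             convert_underscores=False)
    except Exception as exc:
        raise ValueError(f"Newick parse error: {exc}") from exc
    return tree


def tree_leaf_distances(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (for additivity checks)."""
    ids = sorted(leaf.name for leaf in tree.tips())
    skdm = tree.tip_tip_distances(endpoints=ids)
    return DistanceMatrix(
        ids=list(skdm.ids), data=np.asarray(skdm.data, dtype=float), model="path"
    )


def leaf_distance_rank(dm: DistanceMatrix, query: str) -> list[tuple[str, float]]:
    """All other ids ordered by ascending distance to ``query``; ties broken
    lexicographically by id."""
    qi = dm.index(query)
    pairs = [
        (sid, float(dm.data[qi, k]))
        for k, sid in enumerate(dm.ids)
        if sid != query
    ]
    return sorted(pairs, key=lambda t: (t[1], t[0]))


def bootstrap_trees(
    aln: Alignment,
    n_replicates: int,
    seed: int,
    model: str = "poisson",
    gap_rule: str = "pairwise_deletion",
) -> list[TreeNode]:
    """Column-resampling bootstrap NJ trees (meant for full-length
    alignments; support values on short pocket profiles are uninformative)."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_replicates):
        cols = rng.integers(0, aln.width, size=aln.width)
        rows = ["".join(r[c] for c in cols) for r in aln.rows]
        boot = Alignment(ids=list(aln.ids), rows=rows)
        out.append(nj_tree(pairwise_distance(boot, model=model, gap_rule=gap_rule)))
    return out
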