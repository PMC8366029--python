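"""Annotation handling, EC-class clustering on trees, and label propagation.

Enzyme sequences carry EC numbers, substrate names, evidence flags and
organism tags.  A sequence annotated as the generic EC 1.1.1.1, as an
incomplete EC (1.1.1.-), or with more than one EC is treated as
promiscuous/unspecific and excluded from class-specific statistics and
votes.  Uncharacterized sequences inherit substrate hypotheses from their
nearest pocket-profile neighbors; tagged subsets (e.g. thermophiles) can be
ranked by pocket distance from a query of interest.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .alignments import Alignment, ReducedAlignment
from .trees import DistanceMatrix, pairwise_distance

PROMISCUOUS = "promiscuous"

#: EC annotations treated as unspecific by default
DEFAULT_PROMISCUOUS_ECS = frozenset({"1.1.1.1", "1.1.1.-"})

EC_PATTERN = re.compile(r"^\d+\.\d+\.\d+\.(\d+|-|\*)$")

REQUIRED_COLUMNS = ("id", "ec", "substrate", "evidence", "organism", "tags")


@dataclass
class AnnotationRecord:
    ec_numbers: list[str]
    substrate: str = ""
    evidence: bool = False
    organism: str = ""
    tags: frozenset[str] = frozenset()


@dataclass
class AnnotationTable:
    records: dict[str, AnnotationRecord]

    def __post_init__(self):
        for sid, rec in self.records.items():
            for ec in rec.ec_numbers:
                if not EC_PATTERN.match(ec):
                    raise ValueError(f"malformed EC number {ec!r} for id {sid!r}")

    def __contains__(self, sid: str) -> bool:
        return sid in self.records

    def __getitem__(self, sid: str) -> AnnotationRecord:
        return self.records[sid]

    def ids(self) -> list[str]:
        return list(self.records)

    def tagged(self, tag: str) -> list[str]:
        return [sid for sid, r in self.records.items() if tag in r.tags]


def load_annotations(tsv: str) -> AnnotationTable:
    """Parse an annotations TSV with columns id, ec, substrate, evidence,
    organism, tags; multi-valued cells are semicolon-separated."""
    df = pd.read_csv(io.StringIO(tsv), sep="\t", dtype=str).fillna("")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotations table missing columns: {missing}")
    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"].unique())
        raise ValueError(f"duplicate annotation ids: {dupes}")

    records: dict[str, AnnotationRecord] = {}
    for row in df.itertuples(index=False):
        ecs = [e.strip() for e in str(row.ec).split(";") if e.strip()]
        tags = frozenset(t.strip() for t in str(row.tags).split(";") if t.strip())
        evidence = str(row.evidence).strip().lower() in ("yes", "true", "1", "y")
        records[row.id] = AnnotationRecord(
            ec_numbers=ecs,
            substrate=str(row.substrate),
            evidence=evidence,
            organism=str(row.organism),
            tags=tags,
        )
    return AnnotationTable(records=records)


def classify_promiscuity(
    ann: AnnotationTable,
    promiscuous_ecs: frozenset[str] = DEFAULT_PROMISCUOUS_ECS,
) -> dict[str, str]:
    """Label each id with its specific EC, or ``promiscuous``.

    An id is specific only if it carries exactly one EC number and that EC
    is not in the promiscuous set; anything else (no EC, several ECs, a
    generic/incomplete EC) is promiscuous/unspecific.
    """
    labels: dict[str, str] = {}
    for sid, rec in ann.records.items():
        ecs = set(rec.ec_numbers)
        if len(ecs) == 1 and not (ecs & promiscuous_ecs):
            labels[sid] = next(iter(ecs))
        else:
            labels[sid] = PROMISCUOUS
    return labels


# ---------------------------------------------------------------------------
# clustering quality of annotation classes on a tree


@dataclass
class ClassStats:
    leaf_count: int
    blocks: int
    best_purity: float


@dataclass
class ClassSummary:
    per_class: dict[str, ClassStats]
    single_block_fraction: float


def _adjacency(tree: TreeNode) -> tuple[dict[int, list[int]], dict[int, str]]:
    """Undirected adjacency over node ids plus leaf-name lookup."""
    nodes = list(tree.traverse(include_self=True))
    index = {id(n): k for k, n in enumerate(nodes)}
    adj: dict[int, list[int]] = {k: [] for k in range(len(nodes))}
    names: dict[int, str] = {}
    for node in nodes:
        k = index[id(node)]
        if node.is_tip():
            names[k] = node.name
        for child in node.children:
            c = index[id(child)]
            adj[k].append(c)
            adj[c].append(k)
    return adj, names


def _count_blocks(
    adj: dict[int, list[int]],
    names: dict[int, str],
    in_class: set[str],
    eligible: set[str],
    root: int,
) -> int:
    """Number of maximal subtrees (seen from ``root``) whose eligible leaves
    all belong to the class.  ``root`` must not itself head a pure subtree."""
    n_class: dict[int, int] = {}
    n_other: dict[int, int] = {}

    order: list[tuple[int, int]] = []
    stack = [(root, -1)]
    seen = set()
    while stack:
        node, parent = stack.pop()
        seen.add(node)
        order.append((node, parent))
        for nb in adj[node]:
            if nb != parent:
                stack.append((nb, node))

    for node, parent in reversed(order):
        c = o = 0
        if node in names:
            name = names[node]
            if name in eligible:
                if name in in_class:
                    c = 1
                else:
                    o = 1
        for nb in adj[node]:
            if nb != parent:
                c += n_class[nb]
                o += n_other[nb]
        n_class[node], n_other[node] = c, o

    pure = {node for node, _ in order if n_class[node] > 0 and n_other[node] == 0}
    blocks = 0
    for node, parent in order:
        if node in pure and (parent == -1 or parent not in pure):
            blocks += 1
    return blocks


def class_clustering(
    tree: TreeNode,
    labels: dict[str, str],
    ignore_promiscuous: bool = True,
) -> ClassSummary:
    """How well each specific EC class clusters on the tree.

    For each class, ``blocks`` is the minimal number of maximal subtrees
    (in the unrooted sense) containing only that class — 1 means the class
    is monophyletic.  Promiscuous leaves are ignored when
    ``ignore_promiscuous`` (they may sit inside a class clade without
    breaking it).  ``best_purity`` is the best fraction of a clade's
    eligible leaves belonging to the class.
    """
    leaves = [leaf.name for leaf in tree.tips()]
    missing = [l for l in leaves if l not in labels]
    if missing:
        raise ValueError(f"leaves missing from labels: {missing}")

    eligible = {
        l for l in leaves if not (ignore_promiscuous and labels[l] == PROMISCUOUS)
    }
    classes = sorted({labels[l] for l in eligible})

    adj, names = _adjacency(tree)
    name_to_node = {v: k for k, v in names.items()}

    per_class: dict[str, ClassStats] = {}
    for cls in classes:
        in_class = {l for l in eligible if labels[l] == cls}
        outside = sorted(eligible - in_class)
        if not outside:
            per_class[cls] = ClassStats(
                leaf_count=len(in_class), blocks=1, best_purity=1.0
            )
            continue
        root = name_to_node[outside[0]]  # a leaf that can never head a pure subtree
        blocks = _count_blocks(adj, names, in_class, eligible, root)

        # best purity over rooted clades of the tree as given
        best = 0.0
        for node in tree.traverse(include_self=True):
            tips = [t.name for t in node.tips(include_self=True)]
            elig = [t for t in tips if t in eligible]
            if not elig:
                continue
            purity = sum(1 for t in elig if t in in_class) / len(elig)
            best = max(best, purity)
        per_class[cls] = ClassStats(
            leaf_count=len(in_class), blocks=blocks, best_purity=best
        )

    frac = (
        sum(1 for s in per_class.values() if s.blocks == 1) / len(per_class)
        if per_class else 1.0
    )
    return ClassSummary(per_class=per_class, single_block_fraction=frac)


def is_monophyletic(tree: TreeNode, leaf_set: set[str]) -> bool:
    """True iff some edge of the (unrooted) tree splits ``leaf_set`` exactly
    from the remaining leaves."""
    all_leaves = {leaf.name for leaf in tree.tips()}
    if leaf_set == all_leaves:
        return True
    for node in tree.traverse(include_self=False):
        below = {t.name for t in node.tips(include_self=True)}
        if below == leaf_set or (all_leaves - below) == leaf_set:
            return True
    return False


# ---------------------------------------------------------------------------
# label propagation and tagged-neighbor ranking


@dataclass
class Prediction:
    query: str
    predicted: str
    neighbors: list[tuple[str, float, str]]  # (id, distance, label)
    tie: bool = False
    promiscuous_neighbors: list[tuple[str, float]] = field(default_factory=list)


def _distances(ra: ReducedAlignment | Alignment | DistanceMatrix) -> DistanceMatrix:
    if isinstance(ra, DistanceMatrix):
        return ra
    return pairwise_distance(ra)


def predict_labels(
    ra: ReducedAlignment | Alignment | DistanceMatrix,
    labels: dict[str, str],
    queries: list[str],
    k: int = 1,
) -> dict[str, Prediction]:
    """k-nearest-neighbor substrate/EC propagation on pocket distances.

    Voters are labeled, non-promiscuous sequences; promiscuous neighbors
    are excluded from the vote but reported.  Class ties are broken toward
    the class with smaller mean supporting distance, then toward the class
    of the lexicographically smallest supporting neighbor id.
    """
    dm = _distances(ra)
    voters = [
        sid for sid in dm.ids
        if sid not in queries and labels.get(sid) not in (None, PROMISCUOUS)
    ]
    if not voters:
        raise ValueError("no eligible (labeled, non-promiscuous) neighbors")

    out: dict[str, Prediction] = {}
    for q in queries:
        qi = dm.index(q)
        ranked = sorted(
            ((sid, float(dm.data[qi, dm.index(sid)])) for sid in voters),
            key=lambda t: (t[1], t[0]),
        )
        top = ranked[:k]
        prom = sorted(
            (
                (sid, float(dm.data[qi, dm.index(sid)]))
                for sid in dm.ids
                if sid != q and labels.get(sid) == PROMISCUOUS
            ),
            key=lambda t: (t[1], t[0]),
        )[:k]

        votes: dict[str, list[tuple[str, float]]] = {}
        for sid, d in top:
            votes.setdefault(labels[sid], []).append((sid, d))
        best_count = max(len(v) for v in votes.values())
        contenders = [c for c, v in votes.items() if len(v) == best_count]
        tie = len(contenders) > 1
        winner = min(
            contenders,
            key=lambda c: (
                float(np.mean([d for _, d in votes[c]])),
                min(sid for sid, _ in votes[c]),
            ),
        )
        out[q] = Prediction(
            query=q,
            predicted=winner,
            neighbors=[(sid, d, labels[sid]) for sid, d in top],
            tie=tie,
            promiscuous_neighbors=prom,
        )
    return out


def predict_by_clade(
    tree: TreeNode,
    labels: dict[str, str],
    queries: list[str],
) -> dict[str, Prediction]:
    """Clade-mode label propagation, mirroring a visual branch reading.

    Each query inherits the dominant class of the smallest enclosing clade
    of the tree that contains at least one labeled, non-promiscuous leaf;
    class ties are broken toward the lexicographically smallest class.
    Supporting leaves are reported without distances.
    """
    out: dict[str, Prediction] = {}
    for q in queries:
        node = tree.find(q)
        cur = node.parent
        while cur is not None:
            support: dict[str, list[str]] = {}
            for t in cur.tips():
                lab = labels.get(t.name)
                if t.name not in queries and lab not in (None, PROMISCUOUS):
                    support.setdefault(lab, []).append(t.name)
            if support:
                winner = min(support, key=lambda c: (-len(support[c]), c))
                out[q] = Prediction(
                    query=q,
                    predicted=winner,
                    neighbors=[
                        (sid, float("nan"), winner)
                        for sid in sorted(support[winner])
                    ],
                    tie=len([c for c in support
                             if len(support[c]) == len(support[winner])]) > 1,
                )
                break
            cur = cur.parent
        else:
            raise ValueError(f"no labeled leaf anywhere around query {q!r}")
    return out


def nearest_tagged(
    ra: ReducedAlignment | Alignment | DistanceMatrix,
    query: str,
    tag: str,
    ann: AnnotationTable,
    n: int = 5,
) -> list[tuple[str, float, str]]:
    """The ``n`` tag-carrying sequences closest to ``query`` by pocket
    distance, as (id, distance, organism) tuples; ties broken by id."""
    dm = _distances(ra)
    tagged = [sid for sid in ann.tagged(tag) if sid in dm.ids and sid != query]
    if not ann.tagged(tag):
        raise ValueError(f"tag {tag!r} not present in the annotation table")
    if not tagged:
        raise ValueError(f"no sequence carrying tag {tag!r} is in the alignment")
    qi = dm.index(query)
    ranked = sorted(
        ((sid, float(dm.data[qi, dm.index(sid)])) for sid in tagged),
        key=lambda t: (t[1], t[0]),
    )
    return [(sid, d, ann[sid].organism) for sid, d in ranked[:n]]


def annotation_coverage(ann: AnnotationTable, universe_reaction_count: int) -> float:
    """Percentage of the family's known reactions backed by experimental
    evidence: 100 × (distinct evidence-backed ECs) / universe, to 1 decimal."""
    evidence_ecs = {
        ec
        for rec in ann.records.values()
        if rec.evidence
        for ec in rec.ec_numbers
    }
    if universe_reaction_count < len(evidence_ecs):
        raise ValueError(
            "universe_reaction_count smaller than the evidence-backed count"
        )
    if universe_reaction_count <= 0:
        raise ValueError("universe_reaction_count must be positive")
    return round(100.0 * len(evidence_ecs) / universe_reaction_count, 1)
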