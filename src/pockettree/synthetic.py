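"""Synthetic fixtures with known ground truth.

Two generators make every other module testable without any database
download:

* :func:`make_toy_structure` — PDB text for a toy protein whose
  binding-pocket membership is known by construction: designated residues
  get one side-chain atom placed inside the distance cutoff of a small
  het ligand, all other residues stay well outside (cutoff + 2 Å).

* :func:`simulate_families` — an enzyme superfamily alignment in which
  each family carries a characteristic residue signature at a few pocket
  columns over a shared, noisily conserved background.  This emulates the
  structure the binding-site-tree analysis assumes — pocket residues carry
  the substrate-specificity signal — with a per-family pseudo-EC as ground
  truth.  It deliberately omits indels and tree-structured evolution.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignments import AMINO_ACIDS, Alignment, ReducedAlignment
from .classify import (
    AnnotationRecord,
    AnnotationTable,
    class_clustering,
    classify_promiscuity,
)
from .trees import nj_tree, pairwise_distance

# ---------------------------------------------------------------------------
# toy structures


@dataclass
class ToyStructureSpec:
    n_residues: int = 10
    pocket_members: tuple[int, ...] = (3, 7)
    cutoff_A: float = 5.0
    ligand_code: str = "LIG"
    seed: int = 0

    def __post_init__(self):
        self.pocket_members = tuple(sorted(self.pocket_members))
        if self.cutoff_A <= 0:
            raise ValueError("cutoff_A must be > 0")
        if any(not 1 <= m <= self.n_residues for m in self.pocket_members):
            raise ValueError("pocket_members must be residue numbers 1..n_residues")


_RESNAMES = ("ALA", "GLY", "SER", "THR", "VAL", "LEU", "ILE", "PHE", "TYR", "TRP")


def _atom_line(
    serial: int, name: str, resname: str, chain: str, resnum: int,
    xyz: tuple[float, float, float], element: str, hetatm: bool = False,
) -> str:
    record = "HETATM" if hetatm else "ATOM  "
    x, y, z = xyz
    return (
        f"{record}{serial:5d}  {name:<3s}{resname:>4s} {chain}{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def make_toy_structure(spec: ToyStructureSpec) -> str:
    """PDB text with known pocket membership (see module docstring).

    Residues sit on a ring far outside the cutoff around a 4-atom ligand
    at the origin; each pocket member additionally gets a CB atom at
    cutoff − 0.5 Å from a ligand atom.  Deterministic per seed.
    """
    if spec.cutoff_A <= 1.5:
        raise ValueError(
            "cutoff too small to place member atoms outside the ligand cluster"
        )
    rng = np.random.default_rng(spec.seed)
    ring_radius = spec.cutoff_A + 4.2
    member_radius = spec.cutoff_A - 0.5

    lines = [f"HEADER    SYNTHETIC TOY STRUCTURE SEED={spec.seed}"]
    serial = 1
    members = set(spec.pocket_members)
    jitter = rng.uniform(-0.05, 0.05, size=spec.n_residues)
    for num in range(1, spec.n_residues + 1):
        theta = 2.0 * np.pi * (num - 1) / spec.n_residues + jitter[num - 1]
        base = np.array([np.cos(theta), np.sin(theta), 0.0])
        resname = _RESNAMES[(num - 1) % len(_RESNAMES)]
        n_xyz = tuple(ring_radius * base + np.array([0.0, 0.0, 0.3]))
        ca_xyz = tuple((ring_radius + 1.0) * base)
        lines.append(_atom_line(serial, "N", resname, "A", num, n_xyz, "N"))
        serial += 1
        lines.append(_atom_line(serial, "CA", resname, "A", num, ca_xyz, "C"))
        serial += 1
        if num in members:
            cb_xyz = tuple(member_radius * base)
            lines.append(_atom_line(serial, "CB", resname, "A", num, cb_xyz, "C"))
            serial += 1
    lines.append("TER")
    lig_num = spec.n_residues + 100
    for name, elem, xyz in (
        ("C1", "C", (0.0, 0.0, 0.0)),
        ("C2", "C", (0.8, 0.0, 0.0)),
        ("O1", "O", (0.0, 0.8, 0.0)),
        ("N1", "N", (0.0, 0.0, 0.8)),
    ):
        lines.append(
            _atom_line(serial, name, spec.ligand_code, "A", lig_num, xyz, elem,
                       hetatm=True)
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# simulated enzyme families


@dataclass
class FamilySimSpec:
    """Parameters of the planted-signature family simulation.

    Pocket columns come first in the generated alignment (columns
    1..profile_width are the designated ones), followed by
    ``background_width`` non-pocket columns.  Signature positions default
    to ``n_signature_columns`` pocket columns drawn per seed, with one
    distinct residue per family at each.
    """

    n_families: int = 3
    seqs_per_family: int = 20
    profile_width: int = 21
    background_width: int = 180
    n_signature_columns: int = 6
    signature_positions: dict[int, dict[int, str]] | None = None
    within_family_mutation_rate: float = 0.05
    background_rate: float = 0.2
    seed: int = 42

    def __post_init__(self):
        for name in ("within_family_mutation_rate", "background_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.signature_positions is not None:
            for fam, sig in self.signature_positions.items():
                bad = [c for c in sig if not 1 <= c <= self.profile_width]
                if bad:
                    raise ValueError(
                        f"signature columns {bad} of family {fam} outside the "
                        f"pocket profile (1..{self.profile_width})"
                    )


@dataclass
class SyntheticFamilySet:
    alignment: Alignment
    annotations: AnnotationTable
    truth: dict[str, str]  # id -> family pseudo-EC
    designated_columns: tuple[int, ...]

    def reduced(self) -> ReducedAlignment:
        cols = self.designated_columns
        return ReducedAlignment(
            ids=list(self.alignment.ids),
            rows=["".join(r[c - 1] for c in cols) for r in self.alignment.rows],
            column_sources=cols,
        )


def _mutate(ch: str, rate: float, rng: np.random.Generator) -> str:
    if rate > 0 and rng.random() < rate:
        others = AMINO_ACIDS.replace(ch, "")
        return others[rng.integers(0, len(others))]
    return ch


def simulate_families(spec: FamilySimSpec) -> SyntheticFamilySet:
    """Simulate families with planted pocket signatures (see class docs).

    Each sequence is the family's signature residues at the signature
    columns (each independently mutated away with
    ``within_family_mutation_rate``) plus a shared consensus at all other
    columns (mutated with ``background_rate``).  Family k is annotated
    with pseudo-EC ``9.9.9.k`` and experimental evidence.
    """
    import warnings as _warnings

    if spec.n_families < 2:
        _warnings.warn(
            "fewer than 2 families: classification benchmarks are degenerate",
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    width = spec.profile_width + spec.background_width

    consensus = "".join(
        AMINO_ACIDS[rng.integers(0, 20)] for _ in range(width)
    )

    sig = spec.signature_positions
    if sig is None:
        cols = sorted(
            rng.choice(
                np.arange(1, spec.profile_width + 1),
                size=min(spec.n_signature_columns, spec.profile_width),
                replace=False,
            ).tolist()
        )
        sig = {}
        for fam in range(1, spec.n_families + 1):
            sig[fam] = {}
        for c in cols:
            # one distinct residue per family at this column
            residues = rng.choice(
                list(AMINO_ACIDS), size=spec.n_families, replace=False
            )
            for fam in range(1, spec.n_families + 1):
                sig[fam][c] = str(residues[fam - 1])

    ids: list[str] = []
    rows: list[str] = []
    truth: dict[str, str] = {}
    records: dict[str, AnnotationRecord] = {}
    for fam in range(1, spec.n_families + 1):
        fam_sig = sig.get(fam, {})
        ec = f"9.9.9.{fam}"
        for s in range(1, spec.seqs_per_family + 1):
            sid = f"F{fam}_S{s:02d}"
            chars = []
            for col in range(1, width + 1):
                if col in fam_sig:
                    chars.append(
                        _mutate(fam_sig[col], spec.within_family_mutation_rate, rng)
                    )
                else:
                    chars.append(_mutate(consensus[col - 1], spec.background_rate, rng))
            ids.append(sid)
            rows.append("".join(chars))
            truth[sid] = ec
            records[sid] = AnnotationRecord(
                ec_numbers=[ec],
                substrate=f"compound-{fam}",
                evidence=True,
                organism=f"Synthetica familia {fam}",
                tags=frozenset(),
            )

    return SyntheticFamilySet(
        alignment=Alignment(ids=ids, rows=rows),
        annotations=AnnotationTable(records=records),
        truth=truth,
        designated_columns=tuple(range(1, spec.profile_width + 1)),
    )


# ---------------------------------------------------------------------------
# pocket-vs-full benchmark


@dataclass
class BenchmarkResult:
    pocket_accuracy: float
    full_accuracy: float
    pocket_monophyly_fraction: float
    full_monophyly_fraction: float


def holdout_accuracy(
    aln: Alignment | ReducedAlignment, truth: dict[str, str]
) -> float:
    """Hold-one-out nearest-neighbor accuracy on pairwise pocket distances.

    Each sequence is predicted from its nearest neighbor (ties broken by
    id) among all the others; returns the fraction predicted correctly.
    """
    dm = pairwise_distance(aln)
    correct = 0
    for i, sid in enumerate(dm.ids):
        ranked = sorted(
            ((other, float(dm.data[i, k])) for k, other in enumerate(dm.ids)
             if other != sid),
            key=lambda t: (t[1], t[0]),
        )
        if truth[ranked[0][0]] == truth[sid]:
            correct += 1
    return correct / len(dm.ids)


def benchmark_pocket_vs_full(sim: SyntheticFamilySet) -> BenchmarkResult:
    """Compare pocket-only vs full-length classification on one simulation.

    Runs extract → distances → NJ → class clustering, plus hold-one-out
    nearest-neighbor prediction, on (a) the designated pocket columns only
    and (b) all columns, returning the four summary metrics.
    """
    reduced = sim.reduced().to_alignment()
    full = sim.alignment
    labels = classify_promiscuity(sim.annotations)

    accuracies = {}
    monophyly = {}
    for key, aln in (("pocket", reduced), ("full", full)):
        accuracies[key] = holdout_accuracy(aln, sim.truth)
        tree = nj_tree(pairwise_distance(aln))
        summary = class_clustering(tree, labels)
        monophyly[key] = summary.single_block_fraction

    return BenchmarkResult(
        pocket_accuracy=accuracies["pocket"],
        full_accuracy=accuracies["full"],
        pocket_monophyly_fraction=monophyly["pocket"],
        full_monophyly_fraction=monophyly["full"],
    )
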