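"""Alignments: seed alignments with swap groups, pocket-column extraction,
and profile alignment of new sequences onto a frozen seed.

The central object is the :class:`SeedAlignment`: a curated multiple
sequence alignment whose columns are frozen, carrying (i) per-reference
maps from ungapped residue positions to columns, (ii) the ordered list of
*designated* columns that make up the substrate-binding-pocket profile,
and (iii) *swap groups* — sets of columns whose residues occupy
structurally equivalent pocket slots in a different sequential order in
different subfamilies (e.g. a loop that places its hinge residues in
swapped order).  Extracting the designated columns with the per-subfamily
permutation applied yields the :class:`ReducedAlignment`, the pocket
profile from which binding-site trees are built.

All column and position indices in public interfaces are 1-based.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from Bio import SeqIO

from .structures import PocketDefinition

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
# extended alphabet: ambiguity/rare codes (B, Z, J, X, U, O) are accepted in
# rows but carry no profile score
_VALID_ROW = frozenset("ABCDEFGHIJKLMNOPQRSTUVWXYZ" + GAP)
_VALID_SEQ = frozenset("ABCDEFGHIJKLMNOPQRSTUVWXYZ")


@dataclass
class Alignment:
    """An aligned set of sequences: equal-length gapped rows, unique ids."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")
        self.rows = [r.upper() for r in self.rows]
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            w0 = len(self.rows[0])
            bad = next(i for i, r in zip(self.ids, self.rows) if len(r) != w0)
            raise ValueError(f"rows have unequal lengths (offending id: {bad!r})")
        for sid, row in zip(self.ids, self.rows):
            extra = set(row) - _VALID_ROW
            if extra:
                raise ValueError(
                    f"invalid characters {sorted(extra)} in row {sid!r}"
                )

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence id {seq_id!r} not in alignment") from None

    def __len__(self) -> int:
        return len(self.ids)


def read_alignment(text: str) -> Alignment:
    """Read an aligned FASTA string. Ragged rows raise, naming the offender."""
    try:
        records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    except ValueError as exc:
        raise ValueError(f"not valid FASTA: {exc}") from exc
    if not records:
        raise ValueError("no FASTA records found")
    ids = [r.id for r in records]
    rows = [str(r.seq).upper() for r in records]
    return Alignment(ids=ids, rows=rows)


def write_alignment(aln: Alignment) -> str:
    """Canonical aligned FASTA: one line per sequence."""
    return "".join(f">{i}\n{r}\n" for i, r in zip(aln.ids, aln.rows))


@dataclass
class SwapGroup:
    """Columns whose residues sit in structurally equivalent pocket slots in a
    different sequential order in some subfamilies.

    ``columns`` lists the group's columns in their *structural* slot order
    (the order used in the reduced alignment).  For each subfamily tag,
    ``permutations[tag]`` gives, slot by slot, the alignment column that
    holds the residue occupying that structural slot in members of the tag.
    Tags absent from ``permutations`` use the identity (``columns`` as is).
    """

    columns: tuple[int, ...]
    permutations: dict[str, tuple[int, ...]] = field(default_factory=dict)
    members: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        self.columns = tuple(self.columns)
        if len(self.columns) < 2:
            raise ValueError("a swap group needs at least 2 columns")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("swap group columns must be distinct")
        self.permutations = {t: tuple(p) for t, p in self.permutations.items()}
        for tag, perm in self.permutations.items():
            if sorted(perm) != sorted(self.columns):
                raise ValueError(
                    f"permutation for tag {tag!r} is not a bijection on the "
                    f"group columns"
                )
        self.members = {t: frozenset(m) for t, m in self.members.items()}
        seen: set[str] = set()
        for tag, ids in self.members.items():
            if seen & ids:
                raise ValueError(
                    f"ids {sorted(seen & ids)} appear in more than one subfamily"
                )
            seen |= ids

    def source_column(self, slot_column: int, seq_id: str) -> int:
        """Alignment column supplying structural slot ``slot_column`` for ``seq_id``."""
        if slot_column not in self.columns:
            raise KeyError(f"column {slot_column} not in swap group")
        i = self.columns.index(slot_column)
        for tag, ids in self.members.items():
            if seq_id in ids:
                return self.permutations.get(tag, self.columns)[i]
        return slot_column

    def tag_of(self, seq_id: str) -> str | None:
        for tag, ids in self.members.items():
            if seq_id in ids:
                return tag
        return None


@dataclass
class SeedAlignment:
    """A frozen, curated alignment plus the bookkeeping to reduce it.

    ``reference_maps`` maps each reference sequence id to a dict
    (1-based ungapped position -> 1-based column).  ``references``
    optionally records which structure (pdb id, chain) each reference row
    corresponds to, so pocket definitions can find their reference row.
    """

    alignment: Alignment
    reference_maps: dict[str, dict[int, int]] = field(default_factory=dict)
    designated_columns: tuple[int, ...] = ()
    swap_groups: list[SwapGroup] = field(default_factory=list)
    references: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        self.designated_columns = tuple(self.designated_columns)
        if list(self.designated_columns) != sorted(set(self.designated_columns)):
            raise ValueError("designated_columns must be strictly increasing")
        for c in self.designated_columns:
            if not 1 <= c <= self.alignment.width:
                raise ValueError(
                    f"designated column {c} outside alignment width "
                    f"{self.alignment.width}"
                )
        for ref_id in self.reference_maps:
            if ref_id not in self.alignment.ids:
                raise ValueError(f"reference id {ref_id!r} not in alignment")

    def reference_for_structure(self, structure_id: str) -> str:
        """Reference row id declared for a structure id; falls back to the
        single reference when only one map exists."""
        for ref_id, meta in self.references.items():
            if meta.get("pdb_id", "").upper() == structure_id.upper():
                return ref_id
        if len(self.reference_maps) == 1:
            return next(iter(self.reference_maps))
        raise KeyError(
            f"no reference row declared for structure {structure_id!r}"
        )


def build_reference_map(row: str) -> dict[int, int]:
    """Ungapped 1-based position -> 1-based column, from a gapped row."""
    out: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            pos += 1
            out[pos] = col
    return out


def make_seed(
    alignment: Alignment,
    reference_ids: list[str] | None = None,
    designated_columns: tuple[int, ...] = (),
    swap_groups: list[SwapGroup] | None = None,
    references: dict[str, dict[str, str]] | None = None,
) -> SeedAlignment:
    """Build a SeedAlignment, deriving reference maps from row content."""
    ref_ids = reference_ids if reference_ids is not None else list(alignment.ids)
    maps = {rid: build_reference_map(alignment.row(rid)) for rid in ref_ids}
    return SeedAlignment(
        alignment=alignment,
        reference_maps=maps,
        designated_columns=designated_columns,
        swap_groups=list(swap_groups or []),
        references=dict(references or {}),
    )


def column_of(seed: SeedAlignment, ref_id: str, position: int) -> int:
    """Alignment column (1-based) holding ungapped ``position`` of ``ref_id``."""
    if ref_id not in seed.reference_maps:
        raise KeyError(f"{ref_id!r} is not a reference sequence")
    refmap = seed.reference_maps[ref_id]
    if position not in refmap:
        raise ValueError(
            f"position {position} outside ungapped length of {ref_id!r} "
            f"(1..{len(refmap)})"
        )
    return refmap[position]


def designate_pocket_columns(
    seed: SeedAlignment,
    pocket: PocketDefinition,
    struct_map: dict[int | str, int],
    ref_id: str | None = None,
) -> SeedAlignment:
    """Designate the alignment columns corresponding to a pocket definition.

    Each pocket residue number is sent through ``struct_map`` (author
    numbering -> dense sequence index of the reference chain) and then
    through the reference row's position->column map.  Idempotent: re-running
    with the same pocket yields an equal seed.
    """
    rid = ref_id or seed.reference_for_structure(pocket.structure_id)
    unmappable = []
    cols = []
    for p in pocket.positions:
        key: int | str = p.number if not p.insertion_code else f"{p.number}{p.insertion_code}"
        if key not in struct_map:
            unmappable.append(key)
            continue
        seq_pos = struct_map[key]
        try:
            cols.append(column_of(seed, rid, seq_pos))
        except ValueError:
            unmappable.append(key)
    if unmappable:
        raise ValueError(
            f"pocket positions not mappable onto reference {rid!r}: {unmappable}"
        )
    return replace(seed, designated_columns=tuple(sorted(set(cols))))


@dataclass
class ReducedAlignment:
    """Pocket-columns-only alignment: the substrate-binding-site profile."""

    ids: list[str]
    rows: list[str]
    column_sources: tuple[int, ...]
    swap_applied: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        k = len(self.column_sources)
        if k < 1:
            raise ValueError("a reduced alignment needs at least one column")
        for sid, row in zip(self.ids, self.rows):
            if len(row) != k:
                raise ValueError(f"row {sid!r} has length {len(row)}, expected {k}")

    @property
    def width(self) -> int:
        return len(self.column_sources)

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence id {seq_id!r} not in reduced alignment") from None

    def to_alignment(self) -> Alignment:
        return Alignment(ids=list(self.ids), rows=list(self.rows))

    def __len__(self) -> int:
        return len(self.ids)


def extract_pocket(
    seed: SeedAlignment, subject_ids: list[str] | None = None
) -> ReducedAlignment:
    """Concatenate each row's characters at the designated columns.

    For rows belonging to a permuted subfamily of a swap group, the group's
    columns are read in the subfamily's permuted order, so structurally
    equivalent residues land in the same reduced column across subfamilies.
    """
    if not seed.designated_columns:
        raise ValueError("seed has no designated columns")
    ids = subject_ids if subject_ids is not None else list(seed.alignment.ids)

    out_rows: list[str] = []
    swap_applied: dict[str, bool] = {}
    for sid in ids:
        row = seed.alignment.row(sid)
        chars = []
        applied = False
        for col in seed.designated_columns:
            src = col
            for grp in seed.swap_groups:
                if col in grp.columns:
                    src = grp.source_column(col, sid)
                    if src != col:
                        applied = True
                    break
            chars.append(row[src - 1])
        out_rows.append("".join(chars))
        swap_applied[sid] = applied

    return ReducedAlignment(
        ids=list(ids),
        rows=out_rows,
        column_sources=seed.designated_columns,
        swap_applied=swap_applied,
    )


def filter_by_length(
    sequences: dict[str, str], min_len: int = 250, max_len: int = 600
) -> dict[str, str]:
    """Admission pre-filter on ungapped sequence length (bounds inclusive)."""
    return {
        sid: s for sid, s in sequences.items()
        if min_len <= len(s.replace(GAP, "")) <= max_len
    }


# ---------------------------------------------------------------------------
# profile alignment of a new sequence onto the frozen seed


@dataclass
class ProfileAlignmentResult:
    """A new row gapped to seed width, plus insertions the seed cannot hold."""

    gapped_row: str
    insertions: list[tuple[int, str]]  # (column after which inserted, substring)
    score: float


def _profile_scores(seed: SeedAlignment, pseudocount: float = 0.1) -> np.ndarray:
    """Per-column log-odds scores, shape (width, 20).

    Column frequencies over the 20 residues (gaps ignored) with a Laplace
    pseudocount, log2 odds against a uniform background.
    """
    aln = seed.alignment
    idx = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    counts = np.zeros((aln.width, 20), dtype=float)
    for row in aln.rows:
        for c, ch in enumerate(row):
            if ch in idx:
                counts[c, idx[ch]] += 1
    counts += pseudocount
    freqs = counts / counts.sum(axis=1, keepdims=True)
    return np.log2(freqs * 20.0)


def profile_align(
    seed: SeedAlignment,
    new_seq: str,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> ProfileAlignmentResult:
    """Globally align an ungapped sequence against the seed's column profile.

    The seed columns are frozen: the result is a gapped row of exactly seed
    width.  Residues that do not fit any column are reported as insertions
    (position = seed column after which they occur, 0 for an N-terminal
    insertion) and are *not* added as new columns.  Scoring is per-column
    log-odds with affine gap penalties, charged also at the ends (global).
    Ties are broken deterministically: match preferred over either gap
    state, column-skip preferred over insertion.

    Raises ``ValueError`` on invalid characters.
    """
    new_seq = new_seq.upper().replace(GAP, "")
    if not new_seq:
        raise ValueError("new sequence is empty")
    bad = set(new_seq) - _VALID_SEQ
    if bad:
        raise ValueError(f"invalid sequence characters: {sorted(bad)}")

    S = _profile_scores(seed)  # (W, 20)
    idx = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    W = seed.alignment.width
    m = len(new_seq)
    NEG = -np.inf

    # DP over (i: seq prefix, j: column prefix); states M (residue in column),
    # X (residue inserted, consumes seq only), Y (column skipped, gap in row).
    # A gap of length L costs gap_open + gap_extend * L, also at the ends.
    M = np.full((m + 1, W + 1), NEG)
    X = np.full((m + 1, W + 1), NEG)  # residue inserted (consumes seq only)
    Y = np.full((m + 1, W + 1), NEG)  # column skipped (gap in the new row)
    # traceback pointers: predecessor state 0=M, 1=X, 2=Y
    ptr_M = np.zeros((m + 1, W + 1), dtype=np.int8)
    ptr_X = np.zeros((m + 1, W + 1), dtype=np.int8)
    ptr_Y = np.zeros((m + 1, W + 1), dtype=np.int8)

    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = -gap_open - gap_extend * i
        ptr_X[i, 0] = 0 if i == 1 else 1
    for j in range(1, W + 1):
        Y[0, j] = -gap_open - gap_extend * j
        ptr_Y[0, j] = 0 if j == 1 else 2

    def emit(i: int, j: int) -> float:
        ch = new_seq[i - 1]
        if ch not in idx:  # 'X' unknown residue: neutral score
            return 0.0
        return float(S[j - 1, idx[ch]])

    def best_of(m_val, x_val, y_val):
        # tie preference: M, then Y (column skip), then X (insertion)
        best, p = m_val, 0
        if y_val > best:
            best, p = y_val, 2
        if x_val > best:
            best, p = x_val, 1
        return best, p

    for i in range(m + 1):
        for j in range(W + 1):
            if i > 0 and j > 0:
                best, p = best_of(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
                M[i, j] = best + emit(i, j)
                ptr_M[i, j] = p
            if i > 0 and j > 0:
                best, p = best_of(
                    M[i - 1, j] - gap_open - gap_extend,
                    X[i - 1, j] - gap_extend,
                    Y[i - 1, j] - gap_open - gap_extend,
                )
                if best > X[i, j]:
                    X[i, j], ptr_X[i, j] = best, p
            if j > 0 and i > 0:
                best, p = best_of(
                    M[i, j - 1] - gap_open - gap_extend,
                    X[i, j - 1] - gap_open - gap_extend,
                    Y[i, j - 1] - gap_extend,
                )
                if best > Y[i, j]:
                    Y[i, j], ptr_Y[i, j] = best, p

    finals = (M[m, W], X[m, W], Y[m, W])
    score, state = best_of(*finals)
    score = float(score)

    # traceback
    i, j = m, W
    row_chars: list[str] = [GAP] * W
    inserted: list[tuple[int, str]] = []  # (column, residue), collected reversed
    while i > 0 or j > 0:
        if state == 0:  # M: residue i in column j
            row_chars[j - 1] = new_seq[i - 1]
            state = int(ptr_M[i, j])
            i, j = i - 1, j - 1
        elif state == 1:  # X: residue i inserted after column j
            inserted.append((j, new_seq[i - 1]))
            state = int(ptr_X[i, j])
            i = i - 1
        else:  # Y: column j skipped
            state = int(ptr_Y[i, j])
            j = j - 1

    # group contiguous inserted residues per anchor column
    insertions: list[tuple[int, str]] = []
    for col, ch in reversed(inserted):
        if insertions and insertions[-1][0] == col:
            insertions[-1] = (col, insertions[-1][1] + ch)
        else:
            insertions.append((col, ch))

    return ProfileAlignmentResult(
        gapped_row="".join(row_chars), insertions=insertions, score=score
    )


# ---------------------------------------------------------------------------
# seed config I/O


def seed_from_config(alignment: Alignment, config: dict) -> SeedAlignment:
    """Assemble a SeedAlignment from an alignment plus a config mapping.

    Config schema::

        references: [{id, pdb_id, chain}]
        designated_columns: [int, ...]            # 1-based
        swap_groups:
          - columns: [int, ...]                   # structural slot order
            permutations: {tag: [int, ...]}
            members: {tag: [ids]}
    """
    refs = {r["id"]: {"pdb_id": r.get("pdb_id", ""), "chain": r.get("chain", "")}
            for r in config.get("references", [])}
    groups = [
        SwapGroup(
            columns=tuple(g["columns"]),
            permutations={t: tuple(p) for t, p in g.get("permutations", {}).items()},
            members={t: frozenset(m) for t, m in g.get("members", {}).items()},
        )
        for g in config.get("swap_groups", [])
    ]
    return make_seed(
        alignment,
        reference_ids=list(refs) or None,
        designated_columns=tuple(config.get("designated_columns", [])),
        swap_groups=groups,
        references=refs,
    )


def load_seed_config(text: str) -> dict:
    """Parse a YAML/JSON seed config string."""
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("seed config must be a mapping")
    return cfg
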