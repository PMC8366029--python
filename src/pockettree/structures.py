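"""Protein structures: PDB parsing, ligand selection and binding-pocket detection.

A binding pocket is defined operationally: every polymer residue with at
least one heavy atom within a distance cutoff (default 5.0 Å) of any heavy
atom of a chosen bound ligand.  Residues are reported in author numbering so
that pocket definitions can be compared against numbering used in the
structural literature; a separate dense 1-based sequence index is available
through :func:`structure_to_sequence_map` for placing pocket positions onto
alignment rows.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.PDBData import protein_letters_3to1
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

logger = logging.getLogger(__name__)

#: het codes never treated as ligands or pocket members
WATER_CODES = frozenset({"HOH", "WAT", "DOD"})

#: common monatomic ions (reported as context, never as pocket positions)
METAL_CODES = frozenset(
    {"ZN", "MG", "CA", "MN", "FE", "CU", "NI", "CO", "NA", "K", "CD", "HG"}
)


@dataclass(frozen=True)
class Atom:
    """A single atom with coordinates in Å."""

    name: str
    element: str
    coords: tuple[float, float, float]
    is_hetero: bool = False
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self):
        if not self.element:
            raise ValueError(f"atom {self.name!r} has an empty element symbol")
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r} has non-finite coordinates")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass
class Residue:
    """A residue identified by (chain, author number, insertion code)."""

    chain_id: str
    number: int
    insertion_code: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)

    @property
    def label(self) -> str:
        return f"{self.number}{self.insertion_code}"

    @property
    def one_letter(self) -> str:
        """1-letter code for standard amino acids, 'X' otherwise."""
        return protein_letters_3to1.get(self.name.upper(), "X")

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coords for a in self.atoms if a.is_heavy]
        return np.asarray(pts, dtype=float).reshape(-1, 3)


@dataclass
class StructureModel:
    """First model of a structure: polymer chains plus het (non-polymer) residues."""

    id: str
    chains: dict[str, list[Residue]]
    het_residues: list[Residue] = field(default_factory=list)
    title: str = ""

    def chain(self, chain_id: str) -> list[Residue]:
        if chain_id not in self.chains:
            raise KeyError(
                f"chain {chain_id!r} not in structure {self.id!r}; "
                f"available: {sorted(self.chains)}"
            )
        return self.chains[chain_id]

    def het_codes(self) -> list[str]:
        return sorted({r.name for r in self.het_residues})

    def metals(self) -> list[Residue]:
        """Monatomic metal het residues (context only, never pocket members)."""
        return [r for r in self.het_residues if r.name.strip() in METAL_CODES]


@dataclass(frozen=True)
class PocketPosition:
    number: int
    provenance: str  # "distance" | "literature"
    insertion_code: str = ""


@dataclass
class PocketDefinition:
    """Designated substrate-binding residue positions on a reference chain.

    ``positions`` are author residue numbers on ``chain_id`` of
    ``structure_id``, each tagged with how it was obtained: ``distance``
    (heavy-atom cutoff criterion) or ``literature`` (transcribed from a
    published list).
    """

    structure_id: str
    chain_id: str
    cutoff_A: float
    ligand_code: str
    positions: list[PocketPosition]

    def __post_init__(self):
        if self.cutoff_A <= 0:
            raise ValueError("cutoff_A must be > 0")
        if not self.positions:
            raise ValueError("no pocket found: position list is empty")
        nums = [(p.number, p.insertion_code) for p in self.positions]
        if nums != sorted(nums):
            raise ValueError("pocket positions must be ordered by residue number")
        if len(set(nums)) != len(nums):
            raise ValueError("duplicate pocket positions")

    @property
    def numbers(self) -> list[int]:
        return [p.number for p in self.positions]

    def to_json(self) -> str:
        return json.dumps(
            {
                "structure_id": self.structure_id,
                "chain_id": self.chain_id,
                "cutoff_A": self.cutoff_A,
                "ligand_code": self.ligand_code,
                "positions": [
                    {"number": p.number, "provenance": p.provenance,
                     **({"insertion_code": p.insertion_code} if p.insertion_code else {})}
                    for p in self.positions
                ],
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "PocketDefinition":
        d = json.loads(text)
        return cls(
            structure_id=d["structure_id"],
            chain_id=d["chain_id"],
            cutoff_A=d["cutoff_A"],
            ligand_code=d["ligand_code"],
            positions=[
                PocketPosition(
                    number=p["number"],
                    provenance=p["provenance"],
                    insertion_code=p.get("insertion_code", ""),
                )
                for p in d["positions"]
            ],
        )


# ---------------------------------------------------------------------------
# parsing


def _pick_altloc(atoms: list) -> "object":
    """Altloc rule: highest occupancy wins; ties broken toward altloc 'A',
    then lexicographically."""
    def rank(a):
        occ = a.get_occupancy()
        occ = 0.0 if occ is None else occ
        alt = a.get_altloc()
        return (-occ, alt != "A", alt)

    return min(atoms, key=rank)


def parse_pdb(text: str, structure_id: str = "structure") -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Polymer residues and het residues (ligands, ions, waters, cofactors)
    are separated.  Alternate locations are collapsed to a single atom
    (highest occupancy, ties toward altloc 'A').  Hydrogens are kept and
    can be excluded downstream via :attr:`Atom.is_heavy`.

    Raises
    ------
    ValueError
        If the text contains no ATOM/HETATM record, or a coordinate field
        is malformed (the underlying parser reports the line number).
    """
    if not any(line.startswith(("ATOM", "HETATM")) for line in text.splitlines()):
        raise ValueError("no ATOM or HETATM records found in input")

    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure(structure_id, io.StringIO(text))
    except PDBConstructionException as exc:  # message names the line number
        raise ValueError(f"PDB parse error: {exc}") from exc

    model = next(structure.get_models())
    chains: dict[str, list[Residue]] = {}
    hets: list[Residue] = []

    for bio_chain in model:
        for bio_res in bio_chain:
            hetfield, resseq, icode = bio_res.get_id()
            atoms: list[Atom] = []
            for bio_atom in bio_res:
                if bio_atom.is_disordered():
                    bio_atom = _pick_altloc(bio_atom.disordered_get_list())
                x, y, z = bio_atom.get_coord()
                elem = (bio_atom.element or bio_atom.get_name()[:1]).strip()
                atoms.append(
                    Atom(
                        name=bio_atom.get_name(),
                        element=elem,
                        coords=(float(x), float(y), float(z)),
                        is_hetero=(hetfield.strip() != ""),
                        altloc=bio_atom.get_altloc().strip(),
                        occupancy=float(bio_atom.get_occupancy() or 1.0),
                    )
                )
            res = Residue(
                chain_id=bio_chain.id,
                number=int(resseq),
                insertion_code=icode.strip(),
                name=bio_res.get_resname().strip(),
                atoms=atoms,
            )
            if hetfield.strip() == "":
                chains.setdefault(bio_chain.id, []).append(res)
            else:
                hets.append(res)

    return StructureModel(id=structure_id, chains=chains, het_residues=hets)


# ---------------------------------------------------------------------------
# ligand selection and pocket detection


def select_ligand(
    model: StructureModel,
    het_code: str,
    chain_id: str | None = None,
    copy_index: int | None = None,
) -> list[Atom]:
    """Heavy atoms of one copy of the het residue ``het_code``.

    With several copies and no ``chain_id``/``copy_index`` selector, the
    first copy by (chain, residue number) is used and a warning is logged.
    ``copy_index`` is 1-based over the copies in that order.
    """
    het_code = het_code.strip().upper()
    if het_code in WATER_CODES:
        raise ValueError(f"{het_code!r} is water and cannot be selected as a ligand")

    copies = sorted(
        (r for r in model.het_residues if r.name.upper() == het_code),
        key=lambda r: (r.chain_id, r.number, r.insertion_code),
    )
    if chain_id is not None:
        copies = [r for r in copies if r.chain_id == chain_id]
    if not copies:
        raise KeyError(
            f"het code {het_code!r} not found"
            + (f" on chain {chain_id!r}" if chain_id else "")
            + f"; available het codes: {model.het_codes()}"
        )
    if copy_index is not None:
        if not 1 <= copy_index <= len(copies):
            raise IndexError(
                f"copy_index {copy_index} out of range (1..{len(copies)})"
            )
        chosen = copies[copy_index - 1]
    else:
        chosen = copies[0]
        if len(copies) > 1:
            logger.warning(
                "%d copies of %s present; using chain %s residue %d",
                len(copies), het_code, chosen.chain_id, chosen.number,
            )

    heavy = [a for a in chosen.atoms if a.is_heavy]
    if not heavy:
        raise ValueError(f"ligand {het_code!r} has no heavy atoms")
    return heavy


def pocket_residues(
    model: StructureModel,
    ligand_atoms: list[Atom],
    cutoff_A: float = 5.0,
    chain_id: str | None = None,
    ligand_code: str = "LIG",
) -> PocketDefinition:
    """All polymer residues with a heavy atom within ``cutoff_A`` of the ligand.

    Euclidean distances between atom centers; heavy atoms on both sides;
    waters, ions and other het residues never count.  Result positions carry
    ``provenance="distance"`` and are ordered by residue number.

    Raises ``ValueError`` ("no pocket found") when no residue qualifies.
    """
    if not ligand_atoms:
        raise ValueError("ligand atom list is empty")
    if cutoff_A <= 0:
        raise ValueError("cutoff_A must be > 0")

    lig = np.asarray([a.coords for a in ligand_atoms if a.is_heavy], dtype=float)
    if lig.size == 0:
        raise ValueError("ligand has no heavy atoms")

    chain_ids = [chain_id] if chain_id is not None else sorted(model.chains)
    if chain_id is not None and chain_id not in model.chains:
        raise KeyError(f"chain {chain_id!r} not in structure {model.id!r}")

    hits: list[tuple[str, Residue]] = []
    cutoff2 = cutoff_A * cutoff_A
    for cid in chain_ids:
        for res in model.chains[cid]:
            pts = res.heavy_coords()
            if pts.size == 0:
                continue
            d2 = ((pts[:, None, :] - lig[None, :, :]) ** 2).sum(axis=2)
            if (d2 <= cutoff2).any():
                hits.append((cid, res))

    if not hits:
        raise ValueError(
            f"no pocket found: no residue within {cutoff_A} Å of the ligand"
        )

    hit_chains = sorted({cid for cid, _ in hits})
    positions = [
        PocketPosition(number=r.number, provenance="distance",
                       insertion_code=r.insertion_code)
        for _, r in sorted(hits, key=lambda cr: (cr[1].number, cr[1].insertion_code))
    ]
    return PocketDefinition(
        structure_id=model.id,
        chain_id=",".join(hit_chains),
        cutoff_A=cutoff_A,
        ligand_code=ligand_code,
        positions=positions,
    )


def structure_to_sequence_map(
    model: StructureModel, chain_id: str
) -> dict[int | str, int]:
    """Map author residue numbering to dense 1-based sequence indices.

    Keys are the integer residue number, or ``f"{number}{icode}"`` for
    residues carrying an insertion code.  Indices follow the order of
    resolved residues in the chain, so gaps in author numbering simply skip
    numbers while the sequence index stays dense.
    """
    mapping: dict[int | str, int] = {}
    for idx, res in enumerate(model.chain(chain_id), start=1):
        key: int | str = res.number if not res.insertion_code else res.label
        if key in mapping:
            raise ValueError(
                f"duplicate residue identifier {key!r} on chain {chain_id!r}"
            )
        mapping[key] = idx
    return mapping
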