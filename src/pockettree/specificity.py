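"""Specificity-determining positions between enzyme subfamilies.

Given two groups of rows from a pocket profile, each position gets:

* a **harmony score** in [0, 1] — overlap of the two per-column residue
  distributions, 1 for identical distributions and 0 for disjoint
  supports, realized as 1 − JSD (Jensen–Shannon divergence, base 2);
* a **permutation Z-score** — the observed harmony standardized against a
  group-label-permutation null; strongly negative Z means the position
  separates the groups far more than chance, and positions with
  Z < −3 (default) are flagged as specificity-determining candidates;
* a **relief weight** in [−1, 1] — nearest-hit/nearest-miss feature
  weight on pocket Hamming distances;
* **two-sample-logo enrichments** — per-residue frequency differences with
  Fisher exact p-values, as plot-ready data.

The gap symbol participates in all distributions: an indel can itself be a
specificity signal in pocket columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import fisher_exact

from .alignments import AMINO_ACIDS, GAP, ReducedAlignment

#: 21-letter alphabet: the 20 residues plus the gap symbol
ALPHABET = AMINO_ACIDS + GAP
_SYM_INDEX = {s: k for k, s in enumerate(ALPHABET)}

DEFAULT_Z_THRESHOLD = -3.0

#: Residue volumes in Å³ (standard compilation of amino-acid volumes).
RESIDUE_VOLUMES: dict[str, float] = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "K": 168.6, "L": 162.9, "M": 166.7, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}


def residue_volume(code: str) -> float:
    """Volume (Å³) of a standard residue; raises ``KeyError`` otherwise."""
    code = code.upper()
    if code not in RESIDUE_VOLUMES:
        raise KeyError(f"unknown residue code {code!r}")
    return RESIDUE_VOLUMES[code]


@dataclass
class GroupProfile:
    """Per-position residue frequency distributions of one subfamily."""

    label: str
    frequencies: np.ndarray  # (width, 21), rows sum to 1
    n: int

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.n < 1:
            raise ValueError("group must contain at least one sequence")
        if not np.allclose(self.frequencies.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("per-position frequencies must sum to 1")

    @property
    def width(self) -> int:
        return self.frequencies.shape[0]

    def distribution(self, position: int) -> dict[str, float]:
        """Distribution at a 1-based position as a symbol -> frequency dict
        (zero entries omitted)."""
        row = self.frequencies[position - 1]
        return {s: float(row[k]) for s, k in _SYM_INDEX.items() if row[k] > 0}


def _encode_rows(rows: list[str]) -> np.ndarray:
    out = np.empty((len(rows), len(rows[0]) if rows else 0), dtype=np.int8)
    for i, row in enumerate(rows):
        for j, ch in enumerate(row):
            out[i, j] = _SYM_INDEX.get(ch, _SYM_INDEX[GAP])
    return out


def _freqs(X: np.ndarray) -> np.ndarray:
    """(width, 21) relative frequencies of an encoded row block."""
    n, w = X.shape
    out = np.zeros((w, len(ALPHABET)), dtype=float)
    for k in range(len(ALPHABET)):
        out[:, k] = (X == k).sum(axis=0)
    return out / n


def group_frequencies(
    ra: ReducedAlignment, group_ids: list[list[str]] | dict[str, list[str]]
) -> list[GroupProfile]:
    """Per-position frequency profiles for two or more disjoint groups.

    No pseudocount is applied: exact support disjointness between groups
    must remain detectable (it is what drives harmony to 0).
    """
    if isinstance(group_ids, dict):
        items = list(group_ids.items())
    else:
        items = [(f"group{k + 1}", ids) for k, ids in enumerate(group_ids)]
    if len(items) < 2:
        raise ValueError("need at least two groups")

    seen: set[str] = set()
    for label, ids in items:
        if not ids:
            raise ValueError(f"group {label!r} is empty")
        overlap = seen & set(ids)
        if overlap:
            raise ValueError(f"groups overlap on ids: {sorted(overlap)}")
        seen |= set(ids)

    profiles = []
    for label, ids in items:
        rows = [ra.row(sid) for sid in ids]
        X = _encode_rows(rows)
        profiles.append(GroupProfile(label=label, frequencies=_freqs(X), n=len(ids)))
    return profiles


# ---------------------------------------------------------------------------
# harmony (distribution overlap)


def _entropy2(p: np.ndarray) -> np.ndarray:
    """Base-2 entropy along the last axis, with 0·log 0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log2(p), 0.0)
    return -t.sum(axis=-1)


def _harmony_rows(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    """1 − JSD(base 2) for each row pair of two (width, 21) arrays."""
    m = 0.5 * (fa + fb)
    jsd = _entropy2(m) - 0.5 * (_entropy2(fa) + _entropy2(fb))
    return 1.0 - np.clip(jsd, 0.0, 1.0)


def _as_vector(p: dict[str, float] | np.ndarray) -> np.ndarray:
    if isinstance(p, dict):
        v = np.zeros(len(ALPHABET))
        for s, x in p.items():
            if s.upper() not in _SYM_INDEX:
                raise KeyError(f"unknown symbol {s!r}")
            v[_SYM_INDEX[s.upper()]] = x
        return v
    v = np.asarray(p, dtype=float)
    if v.shape != (len(ALPHABET),):
        raise ValueError(f"distribution must have length {len(ALPHABET)}")
    return v


def harmony_score(
    pA: dict[str, float] | np.ndarray, pB: dict[str, float] | np.ndarray
) -> float:
    """Overlap of two residue distributions: 1 − Jensen–Shannon divergence
    (base 2).  1 iff identical, 0 iff the supports are disjoint; symmetric
    and continuous in both arguments."""
    va, vb = _as_vector(pA), _as_vector(pB)
    for name, v in (("pA", va), ("pB", vb)):
        if np.any(v < 0) or not np.isclose(v.sum(), 1.0, atol=1e-6):
            raise ValueError(f"{name} is not a normalized distribution")
    return float(_harmony_rows(va[None, :], vb[None, :])[0])


# ---------------------------------------------------------------------------
# permutation Z-scores


@dataclass
class PositionResult:
    position: int  # 1-based
    harmony: float
    z: float
    flagged: bool
    relief: float | None = None
    enrichment: list[tuple[str, str, float, float]] = field(default_factory=list)


@dataclass
class SpecificityReport:
    positions: list[PositionResult]
    z_threshold: float
    n_permutations: int
    seed: int | None

    def flagged_positions(self) -> list[int]:
        return [p.position for p in self.positions if p.flagged]

    def to_tsv(self) -> str:
        lines = ["position\tharmony\tz\trelief\tflagged\ttop_enrichment"]
        for p in self.positions:
            top = (
                f"{p.enrichment[0][0]}:{p.enrichment[0][1]}"
                if p.enrichment else ""
            )
            relief = f"{p.relief:.4f}" if p.relief is not None else ""
            lines.append(
                f"{p.position}\t{p.harmony:.4f}\t{p.z:.4f}\t{relief}"
                f"\t{int(p.flagged)}\t{top}"
            )
        return "\n".join(lines) + "\n"


def position_zscores(
    ra: ReducedAlignment,
    group_a: list[str],
    group_b: list[str],
    n_perm: int = 1000,
    seed: int = 0,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> SpecificityReport:
    """Per-position harmony Z-scores against a group-label-permutation null.

    For each position, z = (observed harmony − mean permuted harmony) / sd,
    with sd = 0 mapped to z = 0.  Low harmony (strong between-group
    separation) gives negative z; positions with z below ``z_threshold``
    are flagged.  Fully reproducible for a given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 sequences")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap on ids: {sorted(overlap)}")

    rows = [ra.row(sid) for sid in list(group_a) + list(group_b)]
    X = _encode_rows(rows)
    n_a = len(group_a)
    n = X.shape[0]

    onehot = np.zeros((n, X.shape[1], len(ALPHABET)), dtype=float)
    rows_idx = np.arange(n)[:, None]
    cols_idx = np.arange(X.shape[1])[None, :]
    onehot[rows_idx, cols_idx, X] = 1.0

    def harmony_for(idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
        fa = onehot[idx_a].mean(axis=0)
        fb = onehot[idx_b].mean(axis=0)
        return _harmony_rows(fa, fb)

    observed = harmony_for(np.arange(n_a), np.arange(n_a, n))

    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, X.shape[1]), dtype=float)
    for t in range(n_perm):
        order = rng.permutation(n)
        perms[t] = harmony_for(order[:n_a], order[n_a:])

    mean = perms.mean(axis=0)
    sd = perms.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (observed - mean) / sd, 0.0)

    positions = [
        PositionResult(
            position=w + 1,
            harmony=float(observed[w]),
            z=float(z[w]),
            flagged=bool(z[w] < z_threshold),
        )
        for w in range(X.shape[1])
    ]
    return SpecificityReport(
        positions=positions,
        z_threshold=z_threshold,
        n_permutations=n_perm,
        seed=seed,
    )


def flag_positions(
    z_scores: list[float] | np.ndarray, threshold: float = DEFAULT_Z_THRESHOLD
) -> list[int]:
    """1-based positions whose z lies below the threshold."""
    return [k + 1 for k, zv in enumerate(np.asarray(z_scores)) if zv < threshold]


# ---------------------------------------------------------------------------
# relief weights


def relief_weights(
    ra: ReducedAlignment, group_a: list[str], group_b: list[str]
) -> np.ndarray:
    """Nearest-hit/nearest-miss per-position weights in [−1, 1].

    For each sequence, the nearest *hit* (same group, excluding itself) and
    the nearest *miss* (other group) are found by Hamming distance on the
    pocket columns (ties broken toward the lexicographically smallest id).
    The weight of position k is the mean over sequences of
    [mismatch_k(miss) − mismatch_k(hit)]: positions that consistently agree
    within a group and differ between groups approach +1.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 sequences")
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")

    ids = sorted(group_a) + sorted(group_b)
    rows = {sid: ra.row(sid) for sid in ids}
    width = ra.width
    in_a = set(group_a)

    def hamming(x: str, y: str) -> int:
        return sum(a != b for a, b in zip(x, y))

    acc = np.zeros(width, dtype=float)
    for sid in ids:
        same = sorted(group_a if sid in in_a else group_b)
        other = sorted(group_b if sid in in_a else group_a)
        hit = min(
            (s for s in same if s != sid),
            key=lambda s: (hamming(rows[sid], rows[s]), s),
        )
        miss = min(other, key=lambda s: (hamming(rows[sid], rows[s]), s))
        for k in range(width):
            acc[k] += (rows[sid][k] != rows[miss][k]) - (rows[sid][k] != rows[hit][k])
    return acc / len(ids)


# ---------------------------------------------------------------------------
# two-sample logo


@dataclass
class Enrichment:
    position: int  # 1-based
    residue: str
    group: str  # label of the group the residue is enriched in
    delta_f: float
    p_value: float


def two_sample_logo(
    profile_a: GroupProfile,
    profile_b: GroupProfile,
    alpha: float = 0.05,
) -> list[Enrichment]:
    """Per-position residue enrichments between two groups.

    For every position and symbol, Δf = fA − fB; symbols whose 2×2 count
    table (symbol vs rest, group A vs B) passes a two-sided Fisher exact
    test at ``alpha`` are reported, assigned to the group where they are
    more frequent, with height |Δf|.  Plot-ready data, not an image.
    """
    if profile_a.n < 2 or profile_b.n < 2:
        raise ValueError("each group needs n >= 2 for enrichment testing")
    if profile_a.width != profile_b.width:
        raise ValueError("profiles have different widths")

    out: list[Enrichment] = []
    for w in range(profile_a.width):
        fa = profile_a.frequencies[w]
        fb = profile_b.frequencies[w]
        for k, sym in enumerate(ALPHABET):
            delta = fa[k] - fb[k]
            if delta == 0:
                continue
            ca = int(round(fa[k] * profile_a.n))
            cb = int(round(fb[k] * profile_b.n))
            table = [[ca, profile_a.n - ca], [cb, profile_b.n - cb]]
            _, p = fisher_exact(table, alternative="two-sided")
            if p < alpha:
                out.append(
                    Enrichment(
                        position=w + 1,
                        residue=sym,
                        group=profile_a.label if delta > 0 else profile_b.label,
                        delta_f=float(delta),
                        p_value=float(p),
                    )
                )
    out.sort(key=lambda e: (e.position, -abs(e.delta_f), e.residue))
    return out


def logo_tsv(enrichments: list[Enrichment]) -> str:
    lines = ["position\tresidue\tgroup\tdelta_f\tp"]
    for e in enrichments:
        lines.append(
            f"{e.position}\t{e.residue}\t{e.group}\t{e.delta_f:.4f}\t{e.p_value:.3e}"
        )
    return "\n".join(lines) + "\n"
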