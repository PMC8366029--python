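# Methods

## The binding-site-tree model

The package rests on one modelling assumption: among the few hundred
positions of an enzyme's sequence, the one-to-two dozen residues lining
the substrate-binding cavity carry most of the information about
substrate specificity. A tree computed from only those alignment columns
("binding-site tree" or "binding-cavity similarity tree") therefore
groups sequences by binding-pocket similarity. Such a tree is *not* an
evolutionary history: similar pockets can arise independently in distant
lineages, one lineage can diversify its specificity, and with only
~20 columns bootstrap support values carry little meaning (the package
consequently offers bootstrapping only for full-length alignments). The
tree is a hypothesis-generation device — sequences co-clustering with
annotated enzymes are *candidates* for sharing their substrate, to be
confirmed experimentally.

## Pocket detection

A pocket residue is any polymer residue with at least one heavy atom
within `cutoff_A` (default 5.0 Å, Euclidean, atom centers) of any heavy
atom of the selected ligand. Conventions chosen where the operational
definition leaves room:

* heavy atoms only on both sides — hydrogen positions are unreliable or
  absent at typical crystallographic resolution, and heavy-atom contact
  cutoffs are the standard convention;
* alternate locations collapse to the highest-occupancy atom, ties
  broken toward altloc `A`;
* waters and metal ions never count as pocket residues; metals (e.g. the
  catalytic zinc of ADHs) are exposed separately as context;
* residues are reported in author numbering so that results can be read
  against the structural literature; a dense 1-based index is used to
  map onto alignment rows;
* no solvent-accessibility or binding-energy filtering: the criterion is
  purely geometric. mmCIF input is not supported, only PDB format.

Pocket definitions record per-position provenance: `distance` for
cutoff-derived positions, `literature` for positions transcribed from
published lists whose derivation cannot be re-run. The packaged AOx
(19 positions, 1NAA/ABL) and AmDH (20 positions, 1C1D chain A) lists are
transcriptions; the AmDH list mixes structural and literature criteria in
its source, so it is marked `literature` throughout.

## Seed alignments and swap groups

The curated seed alignment is a frozen object: its columns never change.
New sequences are added by global dynamic programming against a
position-specific profile of the seed (per-column residue frequencies,
Laplace pseudocount 0.1, log₂-odds against a uniform background; affine
gaps, open 11 / extend 1, charged at the ends). Residues that fit no
column are *reported* as insertions, never inserted as columns. Ties in
the traceback prefer a match over either gap state and a column skip over
an insertion, making results deterministic. The pseudocount and gap
parameters are configurable; the defaults are conventional protein-search
values and the contract (optimal score under the stated scoring,
seed frozen) is what the tests pin down, not the particular constants.

Swap groups encode a curational fact that no purely sequential alignment
can express: in some subfamilies a loop places its pocket residues in a
different sequential order, so structurally equivalent residues live in
*different* columns per subfamily. A swap group lists the columns in
structural-slot order and, per subfamily, the permutation saying which
column supplies each slot. Extraction applies the permutation, so the
reduced alignment is structurally consistent across subfamilies. Swap
groups are declared in the seed configuration — they come from manual
structural curation and are not inferred automatically.

An optional admission filter on ungapped length (default 250–600
residues, inclusive) mirrors the usual practice of restricting a family
to sequences with the full expected domain architecture.

## Distances and trees

On the reduced alignment, `p` is the mismatch fraction over comparable
sites. With `pairwise_deletion` (the default) comparable sites are the
columns where both sequences are non-gap; `complete_deletion` first drops
every column containing any gap, which on a 19–21-column profile is
usually too destructive — hence the default. The Poisson correction
`d = −ln(1 − p)` is the default model; saturated pairs (p ≥ 1 − 1/width,
i.e. sharing at most about one residue) carry no usable signal and are
set to a configurable ceiling (default 5.0 substitutions/site) with a
warning. Maximum-likelihood tree search and rate heterogeneity are out
of scope by design: the binding-site-tree idea is distance-agnostic, and
classic neighbor joining on corrected distances is cheap, deterministic
and sufficient for grouping.

Neighbor joining follows the standard Q-criterion agglomeration with two
pinned conventions: ties in Q resolve to the lowest index pair, and a
negative limb length is clamped to zero with the deficit moved to the
sibling limb (total path lengths preserved). On additive matrices the
algorithm reproduces the generating tree's leaf-to-leaf path lengths
exactly (tested to 1e-9 on random trees up to 12 leaves). Trees are
`skbio.TreeNode` objects; Newick serialization quotes labels containing
spaces and round-trips branch lengths to six decimals.

## Annotation handling and label propagation

EC strings must match `d+.d+.d+.(d+|-|*)`. The promiscuity rule: a
sequence is *specific* only if it carries exactly one EC that is not in
the promiscuous set (default `{1.1.1.1, 1.1.1.-}` — the generic and the
incomplete ADH codes); anything else, including multiple ECs or no EC,
is treated as promiscuous/unspecific and excluded from class statistics
and votes (but reported alongside predictions).

Label propagation is k-nearest-neighbor on pocket distances (default
k = 1). Distance-based propagation is the default because NJ topology on
very short profiles can be unstable while the distances themselves are
not; a clade mode (`predict_by_clade`) instead assigns the dominant class
of the smallest annotated enclosing clade, mirroring how one reads a
published tree figure. Tie-breaks are fixed everywhere (smaller mean
distance, then lexicographic id/class) so results are reproducible. The
choice of k and the vote rule are package decisions — nearest-neighbor
transfer is the minimal model consistent with "co-clustering sequences
share specificity".

Class clustering on a tree reports, per specific EC class, the number of
maximal pure subtrees in the unrooted sense (1 ⇔ monophyletic, verified
against brute-force bipartition enumeration on small trees), with
promiscuous leaves ignored by default so that an unspecific enzyme inside
an otherwise clean clade does not break it.

Annotation coverage is `100 × distinct evidence-backed ECs / universe`,
reported to one decimal — with 40 evidence-backed of 55 known reactions
this yields 72.7%.

## Specificity scoring

*Harmony.* Per-column subfamily distributions over 21 symbols (20
residues + gap; a gap can itself be a specificity signal) are compared
with `1 − JSD` (Jensen–Shannon divergence, base 2): 1 for identical
distributions, 0 for disjoint supports, symmetric and continuous. The
published Sequence Harmony score satisfies the same boundary/symmetry
contract but its exact formula differs; numeric agreement with that tool
is not promised, only the contract, and no pseudocount is applied so
that exact disjointness stays detectable.

*Z-scores.* The observed harmony of each position is standardized
against a null built by shuffling group labels (`n_perm ≥ 100`, default
1000, one RNG seeded per run; permutations are label shuffles without
replacement). Strong separation means low harmony, hence negative z;
positions with z below the threshold (default −3) are flagged. A zero
permutation standard deviation (constant columns) maps to z = 0, never
flagged. Under a true null, fewer than 2% of positions reach |z| > 3
(calibration test: 20 replicates of 30+30 sequences, 1000 permutations).

*Relief weights.* For each sequence, the nearest same-group ("hit") and
other-group ("miss") rows by Hamming distance on the pocket columns
(ties toward the lexicographically smallest id); the weight of a column
is the mean of `[differs from miss] − [differs from hit]`, in [−1, 1].
Note the hand-checkable boundary case: identical groups give all-zero
weights only when every row also has an exact duplicate within its own
group — otherwise the nearest miss (an exact copy in the other group) is
closer than the nearest hit and weights go negative, which is the
formula's intended behavior.

*Two-sample logo.* Per position and symbol, Δf between groups with a
two-sided Fisher exact test on the 2×2 count table; significant symbols
are reported as plot-ready enrichment records (no image rendering).
Fisher was chosen over t/binomial approximations for validity at the
small group sizes typical of curated subfamilies; no multiple-testing
correction is applied by default (an optional Bonferroni flag exists in
the report tooling) because the scan is meant as a candidate triage, not
a confirmatory test.

*Residue volumes.* The embedded table gives residue volumes in Å³ for
the 20 standard residues, with Met = 166.7 and Leu = 162.9 — the values
used when interpreting pocket-size effects such as the Met/Leu contrast
between xylitol- and iditol-preferring dehydrogenases.

## Synthetic data

`make_toy_structure` places residues as 2–3-atom stubs on a ring far
outside the cutoff around a 4-atom het ligand at the origin; designated
pocket members get one extra atom at cutoff − 0.5 Å from a ligand atom,
all other atoms stay beyond cutoff + 2 Å. Only distances matter to
consumers; the geometry makes pocket membership exact by construction
and every generator is a pure function of its seed.

`simulate_families` plants, at a few pocket columns (default 6 of 21),
one distinct residue per family; every other column carries a shared
consensus. Each sequence mutates signature residues with probability
0.05 and background residues with probability 0.2 (defaults); residue
draws are uniform over the 20 amino acids. Defaults — 3 families ×
20 sequences, 21 pocket + 180 background columns — give an alignment of
the scale of a ~200-column family profile. The generator deliberately
omits indels, tree-structured descent and realistic amino-acid
composition: passing benchmarks show the *pipeline* extracts planted
pocket signal correctly, not that real families are this clean. The
pocket-vs-full benchmark raises the background rate (0.45) to emulate
families whose full-length similarity is dominated by noise, where
pocket-only classification should match or beat full-length
classification — averaged over 20 seeds in the acceptance checks.

## Problem sizes and determinism

The shipped verification uses 100 random additive matrices (≤ 12
leaves), 100 synthetic structures, 20 permutation-null replicates at
1000 permutations, 20 benchmark seeds and 60-sequence simulations —
sizes at which every check runs in seconds while still exercising the
asymptotic behavior that matters (NJ consistency, calibration, oracle
agreement). All randomness flows from explicit integer seeds; reruns are
bit-reproducible.

## Known limitations

* PDB input only; no mmCIF, no structural superposition, no automatic
  swap-group inference (these require manual curation or external tools).
* No de-novo multiple alignment: the seed must come from an external
  aligner plus curation; `profile_align` only adds sequences to it.
* No ML/Bayesian tree inference, no rate heterogeneity; branch supports
  are not computed for pocket profiles on purpose.
* Harmony is a JSD surrogate for the published Sequence Harmony score —
  same contract, different numbers.
* k-NN label transfer knows nothing about chemistry; it propagates
  whatever the annotations say, including their errors.
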