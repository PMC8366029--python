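# pockettree

Classify large enzyme superfamilies by their **substrate-binding-pocket
residues** instead of their full-length sequences.

## The problem

Families such as the zinc-dependent alcohol dehydrogenases (ADHs,
EC 1.1.1.\*), long-chain alcohol oxidases (AOx) or amine dehydrogenases
(AmDH) contain up to millions of database sequences but only a few
hundred experimentally characterized members. For enzyme-engineering work
one needs to pick, from that ocean, a handful of candidate sequences (and
candidate mutation sites) likely to act on a desired substrate. Substrate
specificity is determined largely by the one-to-two dozen residues lining
the binding cavity, not by the whole chain — so a tree built from *only
those residue columns* (a **binding-site tree**) groups enzymes by
binding-cavity similarity, and uncharacterized sequences co-clustering
with annotated ones can be hypothesized to share their substrate.

`pockettree` implements that workflow end to end for people doing enzyme
family triage:

1. **structures** — parse a ligand-bound PDB structure and select every
   residue with a heavy atom within a cutoff (default 5 Å) of the
   ligand's heavy atoms; map author residue numbers to dense sequence
   positions.
2. **alignments** — maintain a frozen, curated seed alignment; mark the
   pocket columns; extract the pocket-only *reduced alignment*, honouring
   **swap groups** (columns whose residues occupy structurally equivalent
   pocket slots in a different sequential order in different subfamilies,
   as happens at the human/yeast ADH loop); profile-align new sequences
   onto the seed without ever changing its columns.
3. **trees** — p- or Poisson-corrected pairwise distances
   (d = −ln(1 − p)) with pairwise or complete gap deletion, classic
   neighbor joining, Newick I/O, nearest-neighbor ranking.
4. **classify** — EC/substrate annotation handling with a promiscuity
   rule (EC 1.1.1.1, incomplete ECs, or multiple ECs ⇒ unspecific),
   clustering quality of EC classes on a tree, k-NN label propagation to
   unannotated sequences, and ranking of tagged (e.g. thermophile)
   neighbors of a query.
5. **specificity** — specificity-determining position scoring between
   subfamilies: per-column **harmony** (1 − Jensen–Shannon divergence;
   1 = identical distributions, 0 = disjoint), permutation **Z-scores**
   (positions with Z < −3 flagged), relief-style nearest-hit/nearest-miss
   weights, two-sample-logo enrichments with Fisher exact tests, and a
   residue-volume table for interpreting size effects
   (e.g. Met 166.7 Å³ vs Leu 162.9 Å³).
6. **synthetic** — generators with known ground truth: toy ligand-bound
   structures with pocket membership fixed by construction, and simulated
   enzyme families carrying planted pocket signatures over a noisy
   conserved background.

Packaged reference data: the published 19-position AOx pocket (structure
1NAA, inhibitor ABL, 5 Å) and the 20-position AmDH pocket (1C1D chain A).

## Worked example

```python
import pockettree as pt
from pockettree.synthetic import holdout_accuracy

# simulate a 3-family superfamily with planted pocket signatures
sim = pt.simulate_families(pt.FamilySimSpec(seed=11))
ra = sim.reduced()                       # 21 pocket columns only

# hold-one-out substrate classification on pocket distances
acc = holdout_accuracy(ra.to_alignment(), sim.truth)

# binding-site tree and EC-class clustering
labels = pt.classify_promiscuity(sim.annotations)
tree = pt.nj_tree(pt.pairwise_distance(ra.to_alignment()))
summary = pt.class_clustering(tree, labels)

# specificity-determining positions between two families
fam1 = [s for s in ra.ids if sim.truth[s] == "9.9.9.1"]
fam2 = [s for s in ra.ids if sim.truth[s] == "9.9.9.2"]
report = pt.position_zscores(ra, fam1, fam2, n_perm=1000, seed=17)
```

Output:

```
sequences: 60 | pocket columns: 21
hold-one-out accuracy: 1.000
  9.9.9.1: 20 leaves, 1 block(s), best purity 1.00
  9.9.9.2: 20 leaves, 1 block(s), best purity 1.00
  9.9.9.3: 20 leaves, 1 block(s), best purity 1.00
flagged positions (z < -3): [3, 8, 10, 12, 15, 16]
strongest signal: position 3, harmony 0.000, z = -37.53
```

Reading: every simulated family forms a single monophyletic block on the
binding-site tree (`1 block(s)`), each held-out sequence is assigned its
correct family by its nearest pocket neighbor, and the permutation test
flags exactly the planted signature columns — position 3 separates the
two families perfectly (harmony 0, i.e. disjoint residue distributions),
far beyond what label shuffling produces (z ≈ −38).

The same steps are available from the shell:

```bash
pockettree pocket --pdb 1naa.pdb --ligand ABL --cutoff 5.0 -o pocket.json
pockettree extract --msa seed.fasta --config seed.yaml -o pocket.fasta
pockettree tree --pocket pocket.fasta -o tree.nwk
pockettree classify --pocket pocket.fasta --ann ann.tsv --queries ids.txt
pockettree nearest --pocket pocket.fasta --ann ann.tsv --query CpSADH --tag thermophile
pockettree specificity --pocket pocket.fasta --group-a a.txt --group-b b.txt --perms 1000 --seed 17
```

## Documentation

See `docs/methods.md` for the model assumptions, parameter defaults,
numerical conventions and known limitations.
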