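"""Packaged pocket-definition fixtures.

Published binding-pocket position lists for two of the enzyme families
this package targets, transcribed from the structural literature:

* long-chain alcohol oxidase family (AOx): the 19 residues of the
  cellobiose dehydrogenase flavoprotein 1NAA with a heavy atom within
  5 Å of its bound inhibitor ABL;
* amine dehydrogenase family (AmDH): the 20 substrate-binding/specificity
  residues of chain A of the phenylalanine dehydrogenase structure 1C1D.

These are data, not computation: the distance criterion can be re-run on
the corresponding PDB entries with :func:`pockettree.pocket_residues`
whenever the coordinate files are at hand.
"""

from importlib import resources

from ..structures import PocketDefinition


def _load(name: str) -> PocketDefinition:
    text = resources.files(__package__).joinpath(name).read_text()
    return PocketDefinition.from_json(text)


def aox_pocket_definition() -> PocketDefinition:
    """The 19-position AOx pocket (1NAA / inhibitor ABL, 5 Å)."""
    return _load("aox_1naa_pocket.json")


def amdh_pocket_definition() -> PocketDefinition:
    """The 20-position AmDH pocket (1C1D chain A)."""
    return _load("amdh_1c1d_pocket.json")
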