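"""Frozen functional-group fragment catalogue.

The fragment block of the fragprint representation counts occurrences of
the substructures below. The catalogue is frozen in-repo (rather than
delegating to a toolkit's built-in descriptor set) so that feature vectors
are reproducible across toolkit versions; bump ``CATALOGUE_VERSION``
whenever an entry is added, removed or reordered.
"""

from __future__ import annotations

from rdkit import Chem

CATALOGUE_VERSION = "1.0"

# (name, SMARTS). Ordering is part of the feature contract — do not reorder.
CATALOGUE: tuple[tuple[str, str], ...] = (
    # azo family — the defining motifs of the chemical space
    ("azo", "[NX2]=[NX2]"),
    ("aryl_azo", "c[NX2]=[NX2]c"),
    ("azoxy", "[NX2]=[N+]([O-])"),
    ("hydrazine", "[NX3][NX3]"),
    ("hydrazone", "[NX3][NX2]=[CX3]"),
    ("azide", "N=[N+]=[N-]"),
    # nitrogen groups
    ("nitro", "[$([NX3](=O)=O),$([NX3+](=O)[O-])]"),
    ("nitroso", "[NX2]=[OX1]"),
    ("amine_primary", "[NX3;H2;!$(NC=O);!$(NN)]"),
    ("amine_secondary", "[NX3;H1;!$(NC=O);!$(NN)]"),
    ("amine_tertiary", "[NX3;H0;!$(NC=O);!$(N=O);!$(NN)]"),
    ("aniline_n", "[NX3][c]"),
    ("aryl_amine_primary", "[NX3H2][c]"),
    ("dimethylamino", "[NX3]([CH3])[CH3]"),
    ("ammonium_quaternary", "[NX4+]"),
    ("imine", "[CX3]=[NX2]"),
    ("amidine", "[NX3][CX3]=[NX2]"),
    ("guanidine", "[NX3][CX3](=[NX2])[NX3]"),
    ("nitrile", "[NX1]#[CX2]"),
    ("isocyanate", "[NX2]=[CX2]=[OX1]"),
    ("isothiocyanate", "[NX2]=[CX2]=[SX1]"),
    ("n_oxide", "[#7+][OX1-]"),
    ("hydroxylamine", "[NX3][OX2H]"),
    # oxygen groups
    ("alcohol_aliphatic", "[OX2H][CX4]"),
    ("phenol", "[OX2H][c]"),
    ("ether", "[OD2]([#6])[#6]"),
    ("aryl_methoxy", "[OX2H0](c)[CH3]"),
    ("vinyl_ether", "[OX2][CX3]=[CX3]"),
    ("acetal", "[CX4]([OX2])[OX2]"),
    ("epoxide", "C1OC1"),
    ("carbonyl", "[CX3]=[OX1]"),
    ("aldehyde", "[CX3H1](=O)[#6]"),
    ("ketone", "[#6][CX3](=O)[#6]"),
    ("carboxylic_acid", "[CX3](=O)[OX2H1]"),
    ("ester", "[CX3](=O)[OX2H0][#6]"),
    ("anhydride", "[CX3](=O)[OX2][CX3](=O)"),
    ("acyl_halide", "[CX3](=O)[F,Cl,Br,I]"),
    ("amide", "[NX3][CX3](=[OX1])"),
    ("urea", "[NX3][CX3](=[OX1])[NX3]"),
    ("carbamate", "[NX3][CX3](=[OX1])[OX2]"),
    # sulfur groups
    ("thiol", "[SX2H]"),
    ("thioether", "[SX2]([#6])[#6]"),
    ("thiocarbonyl", "[CX3]=[SX1]"),
    ("sulfoxide", "[#16X3]=[OX1]"),
    ("sulfone", "[SX4](=O)(=O)"),
    ("sulfonamide", "[SX4](=O)(=O)[NX3]"),
    ("sulfonate", "[SX4](=O)(=O)[OX2]"),
    # halogens
    ("fluoro", "[F]"),
    ("chloro", "[Cl]"),
    ("bromo", "[Br]"),
    ("iodo", "[I]"),
    ("aryl_fluoro", "c[F]"),
    ("aryl_chloro", "c[Cl]"),
    ("aryl_bromo", "c[Br]"),
    ("aryl_iodo", "c[I]"),
    ("trifluoromethyl", "[CX4](F)(F)F"),
    ("alkyl_chloride", "[CX4][Cl]"),
    # hydrocarbon features
    ("alkene", "[CX3]=[CX3]"),
    ("alkyne", "[CX2]#[CX2]"),
    ("terminal_alkyne", "[CX2]#[CX1H]"),
    ("benzene", "c1ccccc1"),
    ("naphthalene", "c1ccc2ccccc2c1"),
    # nitrogen heteroaryl rings (frequent azoheteroarene partners)
    ("pyridine", "n1ccccc1"),
    ("pyrimidine", "c1cncnc1"),
    ("pyrazine", "c1cnccn1"),
    ("pyridazine", "c1ccnnc1"),
    ("pyrrole", "[nH]1cccc1"),
    ("imidazole", "c1cnc[nH]1"),
    ("pyrazole", "c1cc[nH]n1"),
    ("triazole_123", "c1c[nH]nn1"),
    ("triazole_124", "c1nc[nH]n1"),
    ("tetrazole", "c1nnn[nH]1"),
    ("indole", "c1ccc2c(c1)cc[nH]2"),
    ("quinoline", "c1ccc2c(c1)cccn2"),
    # O/S heteroaryl rings
    ("furan", "o1cccc1"),
    ("thiophene", "s1cccc1"),
    ("oxazole", "o1cncc1"),
    ("isoxazole", "o1nccc1"),
    ("thiazole", "s1cncc1"),
    ("isothiazole", "s1nccc1"),
    # saturated heterocycles
    ("morpholine", "O1CCNCC1"),
    ("piperidine", "N1CCCCC1"),
    ("piperazine", "N1CCNCC1"),
    ("pyrrolidine", "N1CCCC1"),
    # phosphorus / boron
    ("phosphoryl", "[PX4]=[OX1]"),
    ("boronic", "[BX3]([OX2])[OX2]"),
)


def compiled_catalogue() -> list[tuple[str, Chem.Mol]]:
    """Parse every SMARTS once; raises if any entry is malformed."""
    out = []
    for name, smarts in CATALOGUE:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"unparseable SMARTS in catalogue: {name!r} = {smarts!r}")
        out.append((name, patt))
    return out
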