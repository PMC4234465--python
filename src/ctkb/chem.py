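"""Structure purging and canonical keys.

Compound records arriving from different sources often describe the same
molecule with cosmetic differences: co-crystallized water, counterions,
isotope labels, stereo annotations, or the same unit repeated (salts and
simple polymer dumps).  Purging strips all of these so that records of the
same parent molecule collapse onto one canonical graph, whose canonical
SMILES then serves as the merge key.

The purge deliberately erases stereochemistry and isotope composition:
entity resolution here is at the level of the constitutional skeleton,
matching how heterogeneous source databases actually disagree.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem, RDLogger
from rdkit.Chem import rdmolops

RDLogger.DisableLog("rdApp.*")  # parse diagnostics are surfaced as Diagnostic objects


@dataclass
class PurgeRules:
    """Configuration of the structure-purging pass.

    ion_max_heavy_atoms
        A disconnected component with non-zero net formal charge and at most
        this many heavy atoms is treated as a counterion and removed, provided
        a larger neutral component survives.  Default 6 covers the common
        pharma counterions (Na+, Cl-, K+, Br-, mesylate, acetate...).
    counterions
        Extra components removed by identity (canonical SMILES), charged or
        not — e.g. neutral co-formers a deployment wants gone.
    """

    ion_max_heavy_atoms: int = 6
    counterions: tuple[str, ...] = ()
    remove_water: bool = True
    remove_ions: bool = True
    dedupe_components: bool = True
    clear_isotopes: bool = True
    clear_stereo: bool = True

    def counterion_keys(self) -> set[str]:
        keys = set()
        for smi in self.counterions:
            m = Chem.MolFromSmiles(smi)
            if m is not None:
                keys.add(Chem.MolToSmiles(m))
        return keys


DEFAULT_RULES = PurgeRules()


def _is_water(frag: Chem.Mol) -> bool:
    heavy = [a for a in frag.GetAtoms() if a.GetAtomicNum() != 1]
    return (
        len(heavy) == 1
        and heavy[0].GetAtomicNum() == 8
        and heavy[0].GetFormalCharge() == 0
        and all(a.GetAtomicNum() in (1, 8) for a in frag.GetAtoms())
    )


def _strip_labels(mol: Chem.Mol, rules: PurgeRules) -> Chem.Mol:
    mol = Chem.Mol(mol)
    for atom in mol.GetAtoms():
        if rules.clear_isotopes:
            atom.SetIsotope(0)
        if rules.clear_stereo:
            atom.SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)
    if rules.clear_stereo:
        for bond in mol.GetBonds():
            bond.SetStereo(Chem.BondStereo.STEREONONE)
            if bond.GetBondDir() != Chem.BondDir.NONE:
                bond.SetBondDir(Chem.BondDir.NONE)
    return mol


def purge_structure(mol: Chem.Mol, rules: PurgeRules = DEFAULT_RULES) -> Chem.Mol:
    """Apply the purging rules to a molecule, returning a new molecule.

    Rules, in order: clear isotope labels and stereo flags; drop free water
    components; drop small charged components (counterions) when a larger
    neutral-or-organic component remains; keep a single copy of identical
    components (repeating units).  If every component would be removed, the
    largest original component is kept instead, so the result is never empty.

    Raises ``ValueError`` on a molecule with no atoms.
    """
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError("cannot purge an empty molecule")

    mol = _strip_labels(mol, rules)
    frags = list(rdmolops.GetMolFrags(mol, asMols=True, sanitizeFrags=False))
    counterion_keys = rules.counterion_keys()

    def heavy(f: Chem.Mol) -> int:
        return sum(1 for a in f.GetAtoms() if a.GetAtomicNum() != 1)

    def net_charge(f: Chem.Mol) -> int:
        return sum(a.GetFormalCharge() for a in f.GetAtoms())

    largest = max(frags, key=lambda f: (heavy(f), f.GetNumAtoms()))
    max_heavy = heavy(largest)

    kept: list[Chem.Mol] = []
    for f in frags:
        if rules.remove_water and _is_water(f):
            continue
        key = Chem.MolToSmiles(f)
        if key in counterion_keys and heavy(f) < max_heavy:
            continue
        if (
            rules.remove_ions
            and net_charge(f) != 0
            and heavy(f) <= rules.ion_max_heavy_atoms
            and heavy(f) < max_heavy
        ):
            continue
        kept.append(f)

    if not kept:
        kept = [largest]

    if rules.dedupe_components:
        seen: set[str] = set()
        unique: list[Chem.Mol] = []
        for f in kept:
            key = Chem.MolToSmiles(f)
            if key not in seen:
                seen.add(key)
                unique.append(f)
        kept = unique

    out = kept[0]
    for f in kept[1:]:
        out = Chem.CombineMols(out, f)
    out = Chem.Mol(out)
    Chem.SanitizeMol(out, catchErrors=True)
    try:
        # isotope clearing can leave explicit hydrogens behind (e.g. 2H)
        out = Chem.RemoveHs(out)
    except Exception:
        pass
    return out


def canonical_key(mol: Chem.Mol) -> str:
    """Canonical line notation (canonical SMILES) of a purged molecule.

    Two molecules whose purged graphs are identical up to atom ordering get
    byte-identical keys.  Raises ``ValueError`` if canonicalization fails.
    """
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError("cannot canonicalize an empty molecule")
    smi = Chem.MolToSmiles(mol)
    if not smi:
        raise ValueError("canonicalization produced no output")
    return smi


def mol_from_molblock(text: str) -> Chem.Mol | None:
    """Parse a V2000 molfile block; ``None`` on failure.

    V3000 blocks are rejected explicitly (out of the supported dialect).
    """
    lines = text.splitlines()
    if len(lines) > 3 and "V3000" in lines[3]:
        raise ValueError("V3000 molfiles are not supported; supply V2000")
    return Chem.MolFromMolBlock(text, sanitize=True, removeHs=False)


def mol_from_smiles(smiles: str) -> Chem.Mol | None:
    return Chem.MolFromSmiles(smiles)


def mol_to_molblock(mol: Chem.Mol) -> str:
    """Write a V2000 molfile block for a molecule."""
    return Chem.MolToMolBlock(mol, kekulize=True)


def key_for_structure_text(text: str, rules: PurgeRules = DEFAULT_RULES) -> str | None:
    """Convenience: molblock → purged canonical key, ``None`` when unparseable."""
    mol = mol_from_molblock(text)
    if mol is None or mol.GetNumAtoms() == 0:
        return None
    return canonical_key(purge_structure(mol, rules))
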