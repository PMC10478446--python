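"""Molecular graphs with pKa-augmented atom features, plus chemistry utilities.

Atom feature layout (76 columns)
--------------------------------
Columns 0-73 are the canonical atom featurization used with attention-based
message-passing backbones:

====================  =====  ==============================================
block                 width  encoding
====================  =====  ==============================================
element type           43    one-hot over 42 common elements + "other"
heavy-atom degree      11    one-hot 0..10
implicit valence        7    one-hot 0..6
formal charge           1    integer value
radical electrons       1    integer value
hybridization           5    one-hot SP, SP2, SP3, SP3D, SP3D2
aromaticity             1    flag
total attached H        5    one-hot 0..4
====================  =====  ==============================================

Columns 74-75 are the two microscopic-pKa channels: the acidic and basic
microscopic pKa of the atom, each affinely rescaled to [0, 1]. An acidic
pKa is only ever assigned to a non-carbon atom bearing at least one
hydrogen; a basic pKa only to a nitrogen without a positive formal charge.
Atoms with no assigned site carry sentinels chosen at the non-ionizable end
of each scale: 1.0 on the acidic channel (low values mean stronger acids)
and 0.0 on the basic channel (high values mean stronger bases).

Bond features (12 columns): bond type one-hot (single/double/triple/
aromatic), conjugation flag, ring membership flag, stereo one-hot (6).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

ATOM_FDIM = 76
BOND_FDIM = 12
PKA_LO = -10.0  # lower clip of the micro-pKa normalization, pKa units
PKA_HI = 20.0
ACID_SENTINEL = 1.0  # "maximally non-acidic" on the normalized scale
BASE_SENTINEL = 0.0  # "maximally non-basic"
FEATURIZATION_VERSION = "canonical74+pka2/v1"

_ELEMENTS = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg",
]  # 42 named; slot 43 is "other"

_HYBRIDIZATIONS = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]

_BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]

_STEREOS = [
    Chem.BondStereo.STEREONONE,
    Chem.BondStereo.STEREOANY,
    Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOE,
    Chem.BondStereo.STEREOCIS,
    Chem.BondStereo.STEREOTRANS,
]


def _one_hot(value, choices, other: bool = False) -> list[float]:
    vec = [0.0] * (len(choices) + (1 if other else 0))
    if value in choices:
        vec[choices.index(value)] = 1.0
    elif other:
        vec[-1] = 1.0
    return vec


def base_atom_features(atom: Chem.Atom) -> np.ndarray:
    """The 74-dimensional pKa-free atom feature vector (layout in module docs)."""
    feats = (
        _one_hot(atom.GetSymbol(), _ELEMENTS, other=True)
        + _one_hot(atom.GetDegree(), list(range(11)))
        + _one_hot(atom.GetImplicitValence(), list(range(7)))
        + [float(atom.GetFormalCharge())]
        + [float(atom.GetNumRadicalElectrons())]
        + _one_hot(atom.GetHybridization(), _HYBRIDIZATIONS)
        + [1.0 if atom.GetIsAromatic() else 0.0]
        + _one_hot(min(atom.GetTotalNumHs(), 4), list(range(5)))
    )
    return np.asarray(feats, dtype=np.float64)


def bond_features(bond: Chem.Bond) -> np.ndarray:
    feats = (
        _one_hot(bond.GetBondType(), _BOND_TYPES)
        + [1.0 if bond.GetIsConjugated() else 0.0]
        + [1.0 if bond.IsInRing() else 0.0]
        + _one_hot(bond.GetStereo(), _STEREOS)
    )
    return np.asarray(feats, dtype=np.float64)


# ---------------------------------------------------------------------------
# Microscopic pKa annotation
# ---------------------------------------------------------------------------

@dataclass
class PkaAnnotation:
    """Optional acidic/basic microscopic pKa per atom index, raw and normalized."""

    acidic: dict[int, float] = field(default_factory=dict)
    basic: dict[int, float] = field(default_factory=dict)

    def normalized(self, lo: float = PKA_LO, hi: float = PKA_HI) -> tuple[dict[int, float], dict[int, float]]:
        return (
            {i: normalize_pka(v, lo, hi) for i, v in self.acidic.items()},
            {i: normalize_pka(v, lo, hi) for i, v in self.basic.items()},
        )


def assign_pka_sites(mol: Chem.Mol) -> dict[int, tuple[bool, bool]]:
    """Per-atom (acidic_eligible, basic_eligible) flags.

    Acidic sites: non-carbon atoms carrying at least one hydrogen.
    Basic sites: nitrogen atoms without a positive formal charge.
    """
    out = {}
    for atom in mol.GetAtoms():
        acidic = atom.GetSymbol() != "C" and atom.GetTotalNumHs() >= 1
        basic = atom.GetSymbol() == "N" and atom.GetFormalCharge() <= 0
        out[atom.GetIdx()] = (acidic, basic)
    return out


def normalize_pka(value: float, lo: float = PKA_LO, hi: float = PKA_HI) -> float:
    """Clip to [lo, hi], then map affinely onto [0, 1]."""
    if not math.isfinite(value):
        raise ValueError("pKa must be finite")
    if not lo < hi:
        raise ValueError("lo must be < hi")
    return (min(max(value, lo), hi) - lo) / (hi - lo)


# Functional-group micro-pKa lookup used by the rule-based provider. Values
# are textbook-typical constants for each group, not predictions; the point
# is internally consistent, deterministic annotation for modeling and tests.
_ACID_RULES: list[tuple[str, int, float]] = [
    # (SMARTS, index of the ionizable atom within the match, pKa)
    ("[CX3](=O)[OX2H1]", 2, 4.2),     # carboxylic acid O-H
    ("[c][OX2H1]", 1, 10.0),          # phenol O-H
    ("[CX4][OX2H1]", 1, 15.5),        # aliphatic alcohol O-H
    ("[SX2H1]", 0, 10.5),             # thiol
    ("[SX4](=O)(=O)[NX3H1,NX3H2]", 3, 10.1),  # sulfonamide N-H
    ("[CX3](=O)[NX3H1,NX3H2]", 2, 17.0),      # amide N-H (very weak acid)
    ("[nX3H1]", 0, 16.5),             # pyrrole-type aromatic N-H
]

_BASE_RULES: list[tuple[str, int, float]] = [
    ("[NX3;H2,H1,H0;!$(N-C=O);!$(N-S(=O)=O);!$(N-a);!$(N=*);!$([N+])][CX4]", 0, 10.5),  # aliphatic amine
    ("[NX3;H2,H1;!$(N-C=O);!$(N-S(=O)=O)]c", 0, 4.6),   # aniline-type N
    ("[nX2]", 0, 5.2),                                  # pyridine-type aromatic N
    ("[NX2]=[CX3]", 0, 6.0),                            # imine-type N
]


def rule_based_pka(mol: Chem.Mol) -> PkaAnnotation:
    """Functional-group lookup surrogate for a microscopic-pKa predictor.

    Matches a short SMARTS table of common ionizable groups and assigns each
    matched atom a typical group pKa, gated by the site-eligibility rules
    (:func:`assign_pka_sites`). Where several rules hit the same atom the
    strongest site wins (lowest acidic pKa, highest basic pKa).
    """
    sites = assign_pka_sites(mol)
    ann = PkaAnnotation()
    for smarts, pos, pka in _ACID_RULES:
        patt = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(patt):
            idx = match[pos]
            if sites[idx][0]:
                ann.acidic[idx] = min(ann.acidic.get(idx, math.inf), pka)
    for smarts, pos, pka in _BASE_RULES:
        patt = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(patt):
            idx = match[pos]
            if sites[idx][1]:
                ann.basic[idx] = max(ann.basic.get(idx, -math.inf), pka)
    return ann


def table_pka_provider(table: dict[str, PkaAnnotation]):
    """Provider backed by a precomputed {canonical smiles: annotation} table."""

    def provider(mol: Chem.Mol) -> PkaAnnotation:
        smi = Chem.MolToSmiles(mol)
        return table.get(smi, PkaAnnotation())

    return provider


# ---------------------------------------------------------------------------
# Graphs
# ---------------------------------------------------------------------------

@dataclass
class MolecularGraph:
    """Heavy-atom molecular graph with attributed nodes and undirected bonds."""

    smiles: str
    atom_features: np.ndarray  # (n_atoms, 76)
    bonds: np.ndarray          # (n_bonds, 2) undirected atom-index pairs
    bond_features: np.ndarray  # (n_bonds, 12)

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]


def mol_to_graph(
    smiles: str,
    pka: PkaAnnotation | None = None,
    pka_provider=rule_based_pka,
    lo: float = PKA_LO,
    hi: float = PKA_HI,
) -> MolecularGraph:
    """Build the attributed graph for one molecule.

    ``pka`` overrides the provider when given. Annotation indices must refer
    to the molecule's canonical atom ordering.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"parse_error: {smiles!r}")
    n = mol.GetNumAtoms()
    if pka is None:
        pka = pka_provider(mol)
    if pka.acidic and max(pka.acidic) >= n or pka.basic and max(pka.basic) >= n:
        raise ValueError("pKa annotation index out of range")
    acid_norm, base_norm = pka.normalized(lo, hi)

    feats = np.empty((n, ATOM_FDIM), dtype=np.float64)
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        feats[i, :74] = base_atom_features(atom)
        feats[i, 74] = acid_norm.get(i, ACID_SENTINEL)
        feats[i, 75] = base_norm.get(i, BASE_SENTINEL)

    bonds, bfeats = [], []
    for bond in mol.GetBonds():
        bonds.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        bfeats.append(bond_features(bond))
    bonds_arr = np.asarray(bonds, dtype=np.int64).reshape(-1, 2)
    bfeats_arr = (
        np.asarray(bfeats, dtype=np.float64).reshape(-1, BOND_FDIM)
        if bfeats
        else np.zeros((0, BOND_FDIM))
    )
    return MolecularGraph(smiles, feats, bonds_arr, bfeats_arr)


# ---------------------------------------------------------------------------
# Fingerprints and similarity
# ---------------------------------------------------------------------------

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def ecfp4(smiles: str):
    """2048-bit ECFP4 (Morgan radius 2, i.e. diameter 4) fingerprint."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"parse_error: {smiles!r}")
    return _MORGAN.GetFingerprint(mol)


def tanimoto(a, b) -> float:
    """Bit-set Tanimoto |a&b|/|a|b|; 0 by convention when both are empty."""
    if a.GetNumOnBits() == 0 and b.GetNumOnBits() == 0:
        return 0.0
    return float(DataStructs.TanimotoSimilarity(a, b))


def max_similarity_to_set(query, ref_set) -> float:
    """Maximum Tanimoto similarity of one fingerprint against a collection."""
    if not ref_set:
        raise ValueError("reference set is empty")
    return max(tanimoto(query, ref) for ref in ref_set)


# ---------------------------------------------------------------------------
# Scaffold splitting & dissimilarity-prioritized sampling
# ---------------------------------------------------------------------------

@dataclass
class SplitAssignment:
    train: list[int]
    valid: list[int]
    test: list[int]
    scaffold_of: dict[int, str]

    def partitions(self) -> dict[str, list[int]]:
        return {"train": self.train, "valid": self.valid, "test": self.test}


def murcko_scaffold(smiles: str) -> str:
    """Bemis-Murcko framework SMILES; empty string for acyclic molecules."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"parse_error: {smiles!r}")
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol)


def scaffold_split(
    smiles_list: list[str],
    ratio: tuple[float, float, float] = (8, 1, 1),
    seed: int = 0,
) -> SplitAssignment:
    """Deterministic scaffold-coherent train/valid/test split.

    Molecules sharing a Bemis-Murcko framework are assigned as one group
    (acyclic molecules form a single shared bucket), so no scaffold leaks
    across partitions. Groups go largest-first into train, then valid, then
    test until each partition reaches its target size; the seed shuffles
    groups before the (stable) size sort, breaking ties among equal-sized
    groups reproducibly.
    """
    scaffold_of = {i: murcko_scaffold(s) for i, s in enumerate(smiles_list)}
    groups: dict[str, list[int]] = {}
    for i, sc in scaffold_of.items():
        groups.setdefault(sc, []).append(i)

    rng = np.random.default_rng(seed)
    keys = sorted(groups)
    rng.shuffle(keys)
    keys.sort(key=lambda k: len(groups[k]), reverse=True)  # stable: shuffle breaks ties

    n = len(smiles_list)
    total = float(sum(ratio))
    n_train = n * ratio[0] / total
    n_valid = n * ratio[1] / total
    train: list[int] = []
    valid: list[int] = []
    test: list[int] = []
    for k in keys:
        if len(train) < n_train:
            train.extend(groups[k])
        elif len(valid) < n_valid:
            valid.extend(groups[k])
        else:
            test.extend(groups[k])
    return SplitAssignment(sorted(train), sorted(valid), sorted(test), scaffold_of)


def dissimilarity_prioritized_sample(
    pool: list[str], ref_set: list[str], n: int
) -> list[str]:
    """The n pool molecules least similar to a reference set.

    Each pool molecule is scored by its maximum ECFP4 Tanimoto similarity to
    the reference set; molecules are sorted ascending by score (ties broken
    by canonical SMILES) and the first n returned. Growing n gives nested
    prefixes of the same ordering.
    """
    if n > len(pool):
        raise ValueError(f"requested {n} molecules from a pool of {len(pool)}")
    ref_fps = [ecfp4(s) for s in ref_set]
    scored = sorted(
        ((max_similarity_to_set(ecfp4(s), ref_fps), Chem.CanonSmiles(s), s) for s in pool),
        key=lambda t: (t[0], t[1]),
    )
    return [s for _, _, s in scored[:n]]
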