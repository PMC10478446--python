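"""Synthetic molecule libraries with internally consistent RT/logP/logD labels.

Every pipeline stage in this package is testable offline because this
module can generate arbitrarily many valid, standardizable molecules and
label them with a known ground-truth mechanism:

* ``true logP`` comes from a small additive atom/group contribution table
  (documented below) — crude chemistry, but a deterministic function of
  structure that a graph network can in principle recover exactly;
* per-atom microscopic pKa values come from the same functional-group rules
  the featurizer's surrogate provider uses, so features and labels agree;
* ``true logD7.4`` is derived from true logP and the strongest ionizable
  site(s) through the closed-form ionized-fraction correction;
* retention time is an affine function of true logD clipped to a typical
  chromatographic span (0.3-1471.7 s), mirroring the strong empirical
  RT-lipophilicity correlation that motivates transfer learning.

Observed labels add independent Gaussian noise, and a configurable fraction
of molecules carries only one of logD/logP, reproducing the masked
multitask setting. Everything is deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .curation import standardize_structure
from .evalbase import CalLogDInput, Ionization, cal_logd
from .featurize import PkaAnnotation, rule_based_pka

RT_MIN_S = 0.3
RT_MAX_S = 1471.7


@dataclass(frozen=True)
class SynthConfig:
    n_molecules: int = 500
    seed: int = 0
    noise_sd_logp: float = 0.2   # log units
    noise_sd_logd: float = 0.2
    noise_sd_rt: float = 30.0    # seconds
    rt_intercept: float = 600.0  # seconds at logD = 0
    rt_slope: float = 150.0      # seconds per log unit
    label_missingness: float = 0.3  # fraction carrying only one of logD/logP

    def __post_init__(self) -> None:
        if min(self.noise_sd_logp, self.noise_sd_logd, self.noise_sd_rt) < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0.0 <= self.label_missingness < 1.0:
            raise ValueError("label_missingness must lie in [0, 1)")


# Ring systems and branch-form substituents the generator decorates them
# with. Each template marks substitution sites with {0}/{1}; substituent
# fragments are written so their first atom bonds to the ring.
_TEMPLATES: list[str] = [
    "c1ccc({0})cc1",            # benzene
    "c1ccc({0})c({1})c1",
    "c1cc({0})cc({1})c1",
    "c1cc({0})ccn1",            # pyridine
    "c1cc({0})cnc1{1}",
    "c1cc({0})nc({1})c1",
    "C1CCC({0})CC1",            # cyclohexane
    "C1CC({0})CCC1{1}",
    "C1CC({0})CC({1})C1",
    "C1CCNC({0})C1",            # piperidine
    "c1ccc2c(c1)cc({0})[nH]2",  # indole
    "c1cc({0})co1",             # furan
    "c1cc({0})cs1",             # thiophene
    "c1cc({0})c[nH]1",          # pyrrole
    "c1cnc({0})cn1",            # pyrimidine
    "c1ccc2cc({0})ccc2c1",      # naphthalene
    "c1ccc2cc({0})c({1})cc2c1",
    "c1ccc2ncc({0})cc2c1",      # quinoline
    "C1COC({0})CN1",            # morpholine
    "C1CC({0})CN1",             # pyrrolidine
    "C1CC({0})CO1",             # tetrahydrofuran
    "C1CC({0})C1",              # cyclobutane
    "c1ccc(-c2ccc({0})cc2)cc1",     # biphenyl
    "c1cc({0})ccc1-c1ccc({1})cc1",
    "c1ccc(Cc2ccc({0})cc2)cc1",     # diphenylmethane
    "c1cc({0})ccc1Cc1ccc({1})cc1",
    "c1ccc(-c2ccc({0})cn2)cc1",     # phenylpyridine
    "C1CCC(Cc2ccc({0})cc2)CC1",     # cyclohexylmethyl-benzene
    "c1ccc(CC2CCNC({0})C2)cc1",     # benzyl-piperidine
    "c1cc(-c2cc({0})cs2)ccn1",      # pyridyl-thiophene
    "c1cc({0})cc2c1OCC2{1}",        # benzofuran-like bicycle
    "C1CN(Cc2ccc({0})cc2)CCN1{1}",  # benzyl-piperazine
]

_SUBSTITUENTS: list[str] = [
    "", "F", "Cl", "Br", "C", "CC", "CCC", "C(C)C", "C(C)(C)C", "OC", "OCC",
    "C(=O)O",    # carboxylic acid
    "CC(=O)O",
    "N",         # primary amine
    "CN",        # aminomethyl
    "CCN",
    "N(C)C",
    "O",         # hydroxyl / phenol on aromatic rings
    "CO",        # hydroxymethyl
    "CCO",
    "C(N)=O",    # primary amide
    "NC(C)=O",   # acetamido
    "C(=O)OC",   # methyl ester
    "C(C)=O",    # methyl ketone
    "S(N)(=O)=O",  # sulfonamide
    "SC",
    "C#N", "OC(F)(F)F", "C(F)(F)F",
]

# Additive logP contribution table (per heavy atom, by environment) plus
# group corrections. Values are in the spirit of classic fragment schemes;
# they define this package's synthetic ground truth, nothing more.
_ATOM_CONTRIB = {
    ("C", True): 0.30,    # aromatic carbon
    ("C", False): 0.36,   # aliphatic carbon
    ("N", True): -0.50,
    ("N", False): -0.80,
    ("O", True): -0.45,
    ("O", False): -0.40,
    ("S", True): 0.25,
    ("S", False): 0.10,
    ("F", False): 0.20,
    ("Cl", False): 0.70,
    ("Br", False): 0.90,
}
_GROUP_CORRECTIONS: list[tuple[str, float]] = [
    ("[CX3](=O)[OX2H1]", -0.60),        # carboxylic acid
    ("[CX3](=O)[NX3]", -0.70),          # amide
    ("[SX4](=O)(=O)[NX3]", -1.00),      # sulfonamide
    ("[NX3;H2;!$(N-C=O)]", -0.45),      # primary amine extra polarity
    ("[OX2H1]", -0.25),                 # hydroxyl extra polarity
    ("C#N", -0.30),                     # nitrile
]


def gen_library(cfg: SynthConfig) -> list[str]:
    """Seeded deterministic library of unique, standardizable SMILES."""
    rng = np.random.default_rng(cfg.seed)
    seen: set[str] = set()
    out: list[str] = []
    attempts = 0
    while len(out) < cfg.n_molecules and attempts < cfg.n_molecules * 200:
        attempts += 1
        template = _TEMPLATES[rng.integers(len(_TEMPLATES))]
        n_sites = template.count("{")
        subs = [_SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))] for _ in range(n_sites)]
        smi = template.format(*subs).replace("()", "")
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            continue
        seen.add(canon)
        out.append(canon)
    if len(out) < cfg.n_molecules:
        raise RuntimeError("generator exhausted its template space")
    return out


def true_logp(smiles: str) -> float:
    """Ground-truth logP from the additive contribution table."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"parse_error: {smiles!r}")
    total = 0.0
    for atom in mol.GetAtoms():
        total += _ATOM_CONTRIB.get((atom.GetSymbol(), atom.GetIsAromatic()), 0.0)
    for smarts, corr in _GROUP_CORRECTIONS:
        patt = Chem.MolFromSmarts(smarts)
        total += corr * len(mol.GetSubstructMatches(patt))
    return round(total, 4)


def true_logd(smiles: str, ph: float = 7.4) -> tuple[float, PkaAnnotation]:
    """Ground-truth logD at the given pH from true logP and the strongest
    ionizable site(s); returns the per-atom pKa annotation as well."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"parse_error: {smiles!r}")
    ann = rule_based_pka(mol)
    lp = true_logp(smiles)
    acid = min(ann.acidic.values()) if ann.acidic else None
    base = max(ann.basic.values()) if ann.basic else None
    if acid is not None and base is not None:
        ld = cal_logd(CalLogDInput(lp, Ionization.AMPHOTERIC, pka=acid,
                                   pka_basic=base, ph=ph))
    elif acid is not None:
        ld = cal_logd(CalLogDInput(lp, Ionization.ACID, pka=acid, ph=ph))
    elif base is not None:
        ld = cal_logd(CalLogDInput(lp, Ionization.BASE, pka=base, ph=ph))
    else:
        ld = lp
    return ld, ann


@dataclass
class SynthRecord:
    smiles: str
    logd_true: float
    logp_true: float
    rt_true: float
    logd_obs: float | None
    logp_obs: float | None
    rt_obs: float
    pka: PkaAnnotation


def synth_labels(smiles_list: list[str], cfg: SynthConfig) -> list[SynthRecord]:
    """Noisy observed labels (with missingness) on top of the ground truth."""
    rng = np.random.default_rng(cfg.seed + 1)
    records = []
    for smi in smiles_list:
        lp = true_logp(smi)
        ld, ann = true_logd(smi)
        rt = float(np.clip(cfg.rt_intercept + cfg.rt_slope * ld, RT_MIN_S, RT_MAX_S))
        ld_obs = ld + rng.normal(0, cfg.noise_sd_logd) if cfg.noise_sd_logd else ld
        lp_obs = lp + rng.normal(0, cfg.noise_sd_logp) if cfg.noise_sd_logp else lp
        rt_obs = rt + rng.normal(0, cfg.noise_sd_rt) if cfg.noise_sd_rt else rt
        ld_out, lp_out = float(ld_obs), float(lp_obs)
        if rng.random() < cfg.label_missingness:
            if rng.random() < 0.5:
                ld_out = None
            else:
                lp_out = None
        records.append(
            SynthRecord(smi, float(ld), float(lp), rt,
                        ld_out, lp_out, float(rt_obs), ann)
        )
    return records


def generate(cfg: SynthConfig) -> list[SynthRecord]:
    """Library + labels in one call."""
    return synth_labels(gen_library(cfg), cfg)


def check_library(smiles_list: list[str]) -> None:
    """Audit helper: every generated SMILES must survive standardization."""
    for smi in smiles_list:
        standardize_structure(smi)
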