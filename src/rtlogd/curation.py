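"""Curation of raw octanol/buffer endpoint tables into modeling datasets.

Raw distribution-coefficient records pulled from bioactivity databases are
heterogeneous: measurements at the wrong pH, in the wrong solvent system,
untransformed partition coefficients entered as if they were logs, and the
same molecule measured several times. The pipeline here turns such a table
into a clean per-molecule dataset:

1. pH window filter (logD records only; defaults keep 7.2-7.6 inclusive).
2. Solvent filter (logD records only; octanol by default, case-insensitive).
3. Suspect-value flagging against any user-supplied reference predictor
   (flag-and-report only; corrections stay manual for auditability).
4. Structure standardization: salt stripping (largest organic fragment),
   tautomer canonicalization, charge neutralization, canonical SMILES.
5. Duplicate aggregation: replicate measurements whose spread stays within
   a configurable range are averaged; discordant groups are excluded.

Every input record is accounted for: it either contributes provenance to a
surviving curated record or appears in the rejection log with a reason.
"""

from __future__ import annotations

import enum
import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)


class Endpoint(enum.Enum):
    LOGD = "logD"
    LOGP = "logP"
    RT = "RT"


@dataclass(frozen=True)
class EndpointRecord:
    """One measured molecule/endpoint row."""

    smiles: str
    value: float
    endpoint: Endpoint
    ph: float | None = None
    solvent: str | None = None
    method: str | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"endpoint value must be finite, got {self.value}")


@dataclass(frozen=True)
class CurationConfig:
    ph_low: float = 7.2
    ph_high: float = 7.6
    solvent_allowed: frozenset[str] = frozenset({"octanol"})
    agg_max_range: float = 0.5  # max-min spread (log units) tolerated when averaging
    flag_deviation: float = 3.0  # |value - reference| beyond which a record is flagged

    def __post_init__(self) -> None:
        if not self.ph_low < self.ph_high:
            raise ValueError("ph_low must be < ph_high")
        if self.agg_max_range <= 0:
            raise ValueError("agg_max_range must be positive")


@dataclass
class CuratedDataset:
    """Curated records plus a full audit trail.

    ``records`` holds (canonical_smiles, endpoint, value); ``provenance``
    runs parallel to it and lists the source_ids merged into each record.
    """

    records: list[tuple[str, Endpoint, float]] = field(default_factory=list)
    provenance: list[list[str]] = field(default_factory=list)
    rejection_log: list[tuple[EndpointRecord, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_source_records(self) -> int:
        return sum(len(p) for p in self.provenance) + len(self.rejection_log)


def filter_ph_window(
    records: list[EndpointRecord], cfg: CurationConfig
) -> tuple[list[EndpointRecord], list[tuple[EndpointRecord, str]]]:
    """Keep logD records measured inside [ph_low, ph_high] (inclusive).

    Non-logD endpoints pass through untouched; the pH of a retention-time or
    logP record is meaningless for the distribution coefficient.
    """
    kept, rejected = [], []
    for rec in records:
        if rec.endpoint is not Endpoint.LOGD:
            kept.append(rec)
        elif rec.ph is None or not math.isfinite(rec.ph):
            rejected.append((rec, "ph_missing"))
        elif cfg.ph_low <= rec.ph <= cfg.ph_high:
            kept.append(rec)
        else:
            rejected.append((rec, "ph_out_of_window"))
    return kept, rejected


def filter_solvent(
    records: list[EndpointRecord], cfg: CurationConfig
) -> tuple[list[EndpointRecord], list[tuple[EndpointRecord, str]]]:
    """Keep logD records whose organic phase matches the allowed set (case-folded)."""
    allowed = {s.casefold() for s in cfg.solvent_allowed}
    kept, rejected = [], []
    for rec in records:
        if rec.endpoint is not Endpoint.LOGD:
            kept.append(rec)
        elif rec.solvent is not None and rec.solvent.casefold() in allowed:
            kept.append(rec)
        else:
            rejected.append((rec, "solvent_not_allowed"))
    return kept, rejected


def flag_suspect_values(
    records: list[EndpointRecord],
    reference_pred: dict[str, float],
    cfg: CurationConfig,
) -> list[tuple[EndpointRecord, float]]:
    """Flag records deviating from a reference predictor by > flag_deviation.

    Catches untransformed partition coefficients (e.g. 7500 entered where
    log10 of it was meant) and transcription errors. Returns (record,
    reference) pairs for manual review; nothing is auto-corrected. Records
    without a reference prediction are skipped with a warning.
    """
    flags = []
    for rec in records:
        ref = reference_pred.get(rec.smiles)
        if ref is None:
            logger.warning("no reference prediction for %s; skipped", rec.smiles)
            continue
        if abs(rec.value - ref) > cfg.flag_deviation:
            flags.append((rec, ref))
    return flags


# One shared set of standardizer objects; construction is expensive.
_LARGEST = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_UNCHARGER = rdMolStandardize.Uncharger()
_TAUTOMER = rdMolStandardize.TautomerEnumerator()


def standardize_structure(smiles: str) -> str:
    """Canonical standardized SMILES: salt strip -> tautomer -> neutralize.

    Salt stripping keeps the largest organic fragment (heavy-atom count,
    canonical-SMILES order breaking ties). Neutralization only fires where a
    simple (de)protonation gives a valid valence, so quaternary ammonium
    centres stay charged. The map is idempotent.

    Raises ValueError with reason "parse_error" for unparseable input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"parse_error: {smiles!r}")
    mol = rdMolStandardize.Cleanup(mol)
    mol = _LARGEST.choose(mol)
    mol = _TAUTOMER.Canonicalize(mol)
    mol = _UNCHARGER.uncharge(mol)
    return Chem.MolToSmiles(mol)


def aggregate_duplicates(
    records: list[EndpointRecord], cfg: CurationConfig
) -> CuratedDataset:
    """Merge replicate measurements of the same (canonical SMILES, endpoint).

    Groups whose value spread (max - min) is within ``agg_max_range`` are
    replaced by their arithmetic mean; wider groups are excluded outright as
    discordant. The smiles field is assumed already standardized.
    """
    groups: dict[tuple[str, Endpoint], list[EndpointRecord]] = defaultdict(list)
    for rec in records:
        groups[(rec.smiles, rec.endpoint)].append(rec)

    out = CuratedDataset()
    for (smi, ep), grp in sorted(groups.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
        values = [r.value for r in grp]
        if max(values) - min(values) <= cfg.agg_max_range:
            out.records.append((smi, ep, sum(values) / len(values)))
            out.provenance.append([r.source_id for r in grp])
        else:
            for r in grp:
                out.rejection_log.append((r, "discordant_replicates"))
    return out


def curate(
    records: list[EndpointRecord],
    cfg: CurationConfig | None = None,
    reference_pred: dict[str, float] | None = None,
) -> tuple[CuratedDataset, list[tuple[EndpointRecord, float]]]:
    """Full curation pipeline; returns (dataset, suspect flags).

    Order: pH window -> solvent -> suspect flagging -> structure
    standardization -> duplicate aggregation. Per-record failures land in
    the rejection log; a single bad record never aborts the run.
    """
    cfg = cfg or CurationConfig()
    dataset_rejects: list[tuple[EndpointRecord, str]] = []

    kept, rej = filter_ph_window(records, cfg)
    dataset_rejects.extend(rej)
    kept, rej = filter_solvent(kept, cfg)
    dataset_rejects.extend(rej)

    flags = flag_suspect_values(kept, reference_pred, cfg) if reference_pred else []

    standardized = []
    for rec in kept:
        try:
            canon = standardize_structure(rec.smiles)
        except ValueError:
            dataset_rejects.append((rec, "parse_error"))
            continue
        standardized.append(
            EndpointRecord(canon, rec.value, rec.endpoint, rec.ph, rec.solvent, rec.method, rec.source_id)
        )

    dataset = aggregate_duplicates(standardized, cfg)
    dataset.rejection_log.extend(dataset_rejects)
    return dataset, flags


def filter_counts_summary(dataset: CuratedDataset) -> dict[str, int]:
    """Per-reason rejection counts plus surviving-record count."""
    counts: dict[str, int] = defaultdict(int)
    for _, reason in dataset.rejection_log:
        counts[reason] += 1
    summary = dict(sorted(counts.items()))
    summary["kept"] = len(dataset.records)
    return summary
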