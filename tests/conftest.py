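"""Shared fixtures: a designed curation table and small molecule sets."""

from __future__ import annotations

import pytest

from rtlogd.curation import Endpoint, EndpointRecord
from rtlogd.synthdata import SynthConfig, gen_library


def build_curation_fixture() -> tuple[list[EndpointRecord], dict[str, int]]:
    """A 50-record endpoint table with known per-filter pass/fail composition.

    Returns (records, expected) where expected holds the designed counts:
    10 pH-out-of-window, 3 missing pH, 5 wrong solvent, 2 unparseable,
    6 discordant replicates (two groups of three), 4 concordant duplicates
    (two pairs -> two averaged records) and 20 unique clean records, i.e.
    22 surviving curated records from 50 inputs.
    """
    records: list[EndpointRecord] = []
    mk = lambda smi, val, ph=7.4, solvent="octanol", sid="": EndpointRecord(
        smi, val, Endpoint.LOGD, ph=ph, solvent=solvent, source_id=sid
    )

    clean = [
        "c1ccccc1", "c1ccncc1", "C1CCCCC1", "CCO", "CCN", "CC(=O)O",
        "c1ccc(O)cc1", "c1ccc(Cl)cc1", "c1ccc(F)cc1", "c1ccc(Br)cc1",
        "CC(C)O", "CCCC", "c1ccc(C)cc1", "c1ccc(N)cc1", "CCOC(C)=O",
        "CC(C)N", "c1ccc(CO)cc1", "c1ccc(C#N)cc1", "CCS", "c1cnc2ccccc2c1",
    ]
    for i, smi in enumerate(clean):
        records.append(mk(smi, 1.0 + 0.1 * i, sid=f"clean{i}"))

    for i, ph in enumerate([6.0, 6.5, 7.0, 7.1, 7.19, 7.61, 7.7, 8.0, 9.0, 10.0]):
        records.append(mk("CCCO", 2.0, ph=ph, sid=f"ph{i}"))
    for i in range(3):
        records.append(mk("CCCO", 2.0, ph=None, sid=f"noph{i}"))
    for i, solv in enumerate(["cyclohexane", "water", "DMSO", "hexane", None]):
        records.append(mk("CCCO", 2.0, solvent=solv, sid=f"solv{i}"))
    for i, bad in enumerate(["not_a_smiles", "C1CC"]):
        records.append(mk(bad, 2.0, sid=f"bad{i}"))
    # two discordant replicate groups (spread > 0.5 log units)
    for i, v in enumerate([0.0, 1.0, 2.0]):
        records.append(mk("CCCCCC", v, sid=f"disc_a{i}"))
    for i, v in enumerate([1.0, 1.3, 2.9]):
        records.append(mk("CCCCCO", v, sid=f"disc_b{i}"))
    # two concordant duplicate pairs (spread <= 0.5)
    records.append(mk("CCCCCN", 1.0, sid="dup_a0"))
    records.append(mk("CCCCCN", 1.2, sid="dup_a1"))
    records.append(mk("CCCCCS", 2.0, sid="dup_b0"))
    records.append(mk("CCCCCS", 2.4, sid="dup_b1"))

    expected = {
        "n_input": 50,
        "ph_out_of_window": 10,
        "ph_missing": 3,
        "solvent_not_allowed": 5,
        "parse_error": 2,
        "discordant_replicates": 6,
        "kept": 22,
        "aggregated_values": {"CCCCCN": 1.1, "CCCCCS": 2.2},
    }
    assert len(records) == 50
    return records, expected


@pytest.fixture
def curation_fixture():
    return build_curation_fixture()


@pytest.fixture(scope="session")
def small_library() -> list[str]:
    """60 deterministic synthetic molecules."""
    return gen_library(SynthConfig(n_molecules=60, seed=11))
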