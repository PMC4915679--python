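import numpy as np
import pytest

from orpscan.anchor import Fingerprint, fingerprint_query
from orpscan.classify import (
    assign_family,
    conservation_report,
    orp_group,
    schiff_base_test,
)
from orpscan.config import Thresholds
from orpscan.io import ProteinRecord
from orpscan.references import DEFAULT_SCHEMA, mutate, reference_by_id
from orpscan.search import search_proteome

SCHIFF = DEFAULT_SCHEMA.schiff_position


def _fp(schiff_residue: str) -> Fingerprint:
    residues = dict(DEFAULT_SCHEMA.positions)
    residues[SCHIFF] = schiff_residue
    return Fingerprint(query_id="q", residues=residues)


@pytest.mark.parametrize(
    "residue,expected",
    [("K", "canonical"), ("R", "ORP"), ("L", "ORP"), ("S", "ORP"), ("-", "unassigned")],
)
def test_schiff_base_test(residue, expected):
    assert schiff_base_test(_fp(residue)) == expected


@pytest.mark.parametrize(
    "residue,group",
    [("R", "A"), ("L", "B"), ("I", "B"), ("V", "B"), ("M", "B"), ("F", "B"),
     ("A", "B"), ("S", "unassigned"), ("G", "unassigned"), ("W", "unassigned")],
)
def test_orp_group_rules(residue, group):
    assert orp_group(_fp(residue)) == group


def test_orp_group_rejects_canonical_fingerprint():
    with pytest.raises(ValueError, match="only defined for ORP"):
        orp_group(_fp("K"))


def _call_for(sequence: str, qid: str):
    thresholds = Thresholds()
    (hit,) = search_proteome(
        [ProteinRecord(id=qid, description="", sequence=sequence)],
        thresholds=thresholds,
    )
    fp = fingerprint_query(hit.query)
    return assign_family(hit, fp, thresholds=thresholds)


def test_verbatim_reference_gets_its_family():
    call = _call_for(reference_by_id("BR").sequence, "q_br")
    assert call.family == "BR"
    assert call.orp_group == "n/a"
    assert call.schiff_status == "canonical"


def test_planted_schiff_arginine_is_group_a_orp():
    seq = reference_by_id("SRII").sequence
    seq = seq[: SCHIFF - 1] + "R" + seq[SCHIFF:]
    call = _call_for(seq, "q_orp")
    assert call.family == "ORP"
    assert call.orp_group == "A"
    assert call.class_label == "ORP_A"


def test_divergent_hr_like_assigned_by_nearest_reference():
    rng = np.random.default_rng(8)
    seq = mutate(
        reference_by_id("HR").sequence, 0.40, rng,
        protected=set(DEFAULT_SCHEMA.positions),
    )
    call = _call_for(seq, "q_hr")
    assert call.family == "HR"
    assert call.schiff_status == "canonical"


def test_classification_partition_is_exhaustive_and_disjoint(screen_result):
    for call in screen_result.calls:
        assert call.schiff_status in ("canonical", "ORP", "unassigned")
        assert (call.family == "ORP") == (call.schiff_status == "ORP")
        assert (call.orp_group != "n/a") == (call.family == "ORP")


def test_conservation_report_planted_fractions():
    # 10 group-A-like fingerprints, 9 with D at position 76
    calls = []
    for i in range(10):
        residues = dict(DEFAULT_SCHEMA.positions)
        residues[SCHIFF] = "R"
        residues[76] = "D" if i < 9 else "W"
        fp = Fingerprint(query_id=f"a{i}", residues=residues)
        calls.append(
            assign_family_from_fp(fp)
        )
    report = conservation_report(calls)
    row = report[(report.class_label == "ORP_A") & (report.position == 76)].iloc[0]
    assert row.modal_residue == "D"
    assert row.conservation_fraction == pytest.approx(0.9)
    assert row.n == 10


def assign_family_from_fp(fp: Fingerprint):
    from orpscan.classify import OpsinCall, orp_group, schiff_base_test

    status = schiff_base_test(fp)
    group = orp_group(fp) if status == "ORP" else "n/a"
    return OpsinCall(
        query_id=fp.query_id,
        family="ORP" if status == "ORP" else "SRII",
        orp_group=group,
        fingerprint=fp,
        nearest_reference_id="SRII",
        score=0.0,
        schiff_status=status,
    )


def test_single_sequence_class_fully_conserved():
    fp = Fingerprint(query_id="solo", residues=dict(DEFAULT_SCHEMA.positions))
    report = conservation_report([assign_family_from_fp(fp)])
    assert (report.conservation_fraction == 1.0).all()
    assert (report.n == 1).all()


def test_conservation_report_empty_input_errors():
    with pytest.raises(ValueError, match="at least one"):
        conservation_report([])
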