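import numpy as np
import pytest

from orpscan.config import Thresholds
from orpscan.io import ProteinRecord
from orpscan.references import mutate, reference_by_id, reference_panel
from orpscan.search import (
    build_profile,
    calibrate_profile_gate,
    dipeptide_shuffle,
    opsin_profile_and_gate,
    profile_score,
    search_proteome,
)


@pytest.fixture(scope="module")
def thresholds():
    return Thresholds()


def test_build_profile_rejects_ragged_input():
    with pytest.raises(ValueError, match="ragged"):
        build_profile(["MK", "MKL"])


def test_profile_top_residue_is_shared_residue():
    prof = build_profile(["MKW", "MKW"])
    for col, residue in enumerate("MKW"):
        from orpscan.io import ALPHABET

        assert ALPHABET[int(np.argmax(prof.scores[col, :20]))] == residue


def test_profile_score_monotone_in_counts():
    prof = build_profile(["KAAA", "KAAA", "KAAA", "KAAA"])
    from orpscan.io import ALPHABET

    k, r = ALPHABET.index("K"), ALPHABET.index("R")
    assert prof.scores[0, k] > prof.scores[0, r]


def test_profile_drops_gappy_columns():
    prof = build_profile(["M-K", "M-K", "MW-"])  # middle column 2/3 gaps
    assert list(prof.columns) == [0, 2]


def test_member_outscores_its_shuffles(thresholds):
    prof, _ = opsin_profile_and_gate(thresholds)
    member = reference_by_id("HR").sequence
    s_member = profile_score(prof, member)
    rng = np.random.default_rng(3)
    for _ in range(20):
        assert s_member >= profile_score(prof, dipeptide_shuffle(member, rng))


def test_verbatim_reference_is_perfect_hit(thresholds):
    (hit,) = search_proteome([reference_by_id("BR")], thresholds=thresholds)
    assert hit.best_reference_id == "BR"
    assert hit.alignment.identity == 1.0
    assert hit.alignment.coverage == 1.0
    assert hit.passes_domain_gate


def test_shuffled_references_yield_no_hits(thresholds):
    rng = np.random.default_rng(42)
    panel = reference_panel()
    decoys = [
        ProteinRecord(
            id=f"d{i}", description="", sequence=dipeptide_shuffle(panel[i % 7].sequence, rng)
        )
        for i in range(50)
    ]
    assert search_proteome(decoys, thresholds=thresholds) == []


def test_planted_distant_homolog_recovered_once(thresholds):
    rng = np.random.default_rng(5)
    seq = mutate(reference_by_id("SRI").sequence, 0.60, rng)  # ~40% identity
    hits = search_proteome(
        [ProteinRecord(id="q40", description="", sequence=seq)], thresholds=thresholds
    )
    assert len(hits) == 1
    assert 0.25 <= hits[0].alignment.identity <= 0.55


def test_search_monotone_in_min_identity(thresholds):
    rng = np.random.default_rng(11)
    proteome = [
        ProteinRecord(
            id=f"q{i}",
            description="",
            sequence=mutate(reference_panel()[i % 7].sequence, 0.3 + 0.05 * i, rng),
        )
        for i in range(8)
    ]
    lo = {h.query.id for h in search_proteome(proteome, thresholds=thresholds)}
    stricter = Thresholds(min_identity=0.45)
    hi = {h.query.id for h in search_proteome(proteome, thresholds=stricter)}
    assert hi <= lo


def test_empty_proteome_is_empty_result(thresholds):
    assert search_proteome([], thresholds=thresholds) == []


def test_calibration_is_seed_deterministic(thresholds):
    prof, _ = opsin_profile_and_gate(thresholds)
    srcs = [r.sequence for r in reference_panel()]
    c1 = calibrate_profile_gate(prof, srcs, n_decoys=50, seed=9)
    c2 = calibrate_profile_gate(prof, srcs, n_decoys=50, seed=9)
    assert (c1.mean, c1.sd) == (c2.mean, c2.sd)
    assert c1.cutoff(6) > c1.cutoff(4)  # strict preset is stricter
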