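import itertools

import numpy as np
import pytest
from Bio import Align
from hypothesis import given, settings
from hypothesis import strategies as st

from orpscan.align import (
    AlignmentParams,
    blosum62,
    global_align,
    profile_align,
    semiglobal_align,
)
from oracle_align import brute_force_score

AA = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=0, max_size=25)


def test_identity_alignment_score():
    # three A:A matches at BLOSUM62 +4
    assert global_align("AAA", "AAA").score == 12


def test_empty_vs_kr_pays_one_two_gap():
    aln = global_align("", "KR")
    assert aln.score == -13  # 11 + 2*1
    assert aln.aligned_query == "--"
    assert aln.aligned_subject == "KR"


def test_residue_outside_alphabet_errors():
    with pytest.raises(ValueError, match="outside alphabet"):
        global_align("M1K", "MK")


def test_matches_brute_force_on_short_mixed_pairs():
    params = AlignmentParams()
    for a, b in [("KW", "W"), ("KWK", "WK"), ("AW", "WA"), ("KKWW", "WK")]:
        assert global_align(a, b, params).score == brute_force_score(a, b, params)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(AA, AA)
def test_score_symmetric(a, b):
    assert global_align(a, b).score == global_align(b, a).score


@settings(max_examples=20, deadline=None, derandomize=True)
@given(AA, AA)
def test_alignment_strings_recover_inputs(a, b):
    aln = global_align(a, b)
    assert aln.aligned_query.replace("-", "") == a
    assert aln.aligned_subject.replace("-", "") == b
    assert 0.0 <= aln.identity <= 1.0 and 0.0 <= aln.coverage <= 1.0


def _biopython_score(a: str, b: str, mode: str) -> float:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12  # their open includes the first extend
    aligner.extend_gap_score = -1
    if mode == "global":
        aligner.mode = "global"
    else:
        aligner.mode = "global"
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner.score(a, b)


@pytest.mark.parametrize("mode", ["global", "semiglobal"])
def test_cross_check_against_biopython(mode):
    """Independent implementation check on random realistic pairs."""
    rng = np.random.default_rng(17)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    fn = global_align if mode == "global" else semiglobal_align
    for _ in range(15):
        a = "".join(rng.choice(aas, size=rng.integers(5, 60)))
        b = "".join(rng.choice(aas, size=rng.integers(5, 60)))
        assert fn(a, b).score == _biopython_score(a, b, mode)


def test_semiglobal_end_gaps_free():
    # subject extends past query on both sides: no end-gap penalty
    aln = semiglobal_align("WWW", "AAWWWAA")
    assert aln.score == global_align("WWW", "WWW").score
    assert aln.identity == 1.0


def test_alignment_params_validation():
    with pytest.raises(ValueError, match="symmetric"):
        m = blosum62().copy()
        m[0, 1] += 1
        AlignmentParams(matrix=m)
    with pytest.raises(ValueError, match="gap_extend"):
        AlignmentParams(gap_open=1, gap_extend=2)


def test_profile_align_maps_columns_monotonically():
    # trivial profile strongly favoring the sequence itself
    from orpscan.search import build_profile

    prof = build_profile(["MKWLE", "MKWLE"])
    score, mapping = profile_align(prof.scores, "MKWLE")
    assert list(mapping) == [0, 1, 2, 3, 4]
    assert score > 0
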