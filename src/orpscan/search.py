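"""Homology search: find opsin-domain homologs in a proteome.

The screen replaces BLAST E-values with a decoy-calibrated score gate.  A
position log-odds profile is built from the packaged family alignment; a
query passes the domain gate when its profile alignment score exceeds the
mean plus ``k`` standard deviations of the scores of seed-fixed shuffled
decoys.  ``k = 4`` is the "standard" preset (permissive search intent,
the classical 1e-5 regime), ``k = 6`` the "strict" one (1e-20 regime,
used for the retinal-pathway screen).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .align import AlignmentParams, PairwiseAlignment, profile_align, semiglobal_align
from .config import Thresholds
from .io import ALPHABET, ProteinRecord
from . import references

logger = logging.getLogger(__name__)

PRESETS = {"standard": "gate_sd_standard", "strict": "gate_sd_strict"}


@dataclass(frozen=True)
class ProfileModel:
    """Per-column log-odds scores over the 21-letter alphabet.

    ``columns`` maps each kept profile column to the original alignment
    column it came from (columns over 50% gaps are dropped).
    """

    scores: np.ndarray
    columns: np.ndarray

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class HomologHit:
    """One proteome sequence accepted as an opsin-family homolog."""

    query: ProteinRecord
    best_reference_id: str
    alignment: PairwiseAlignment
    profile_score: float
    passes_domain_gate: bool


def build_profile(
    aligned: dict[str, str] | list[str],
    background: np.ndarray | None = None,
    pseudocount: float = 0.5,
    max_gap_fraction: float = 0.5,
) -> ProfileModel:
    """Build a log-odds profile from equal-length gapped sequences.

    Scores are log2 of (pseudocount-smoothed column frequency / background
    frequency); the background defaults to uniform 1/20.  X scores 0
    everywhere (uninformative).
    """
    rows = list(aligned.values()) if isinstance(aligned, dict) else list(aligned)
    if len(rows) < 2:
        raise ValueError("a profile needs at least two sequences")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("ragged input: aligned sequences must have equal length")
    n_rows, n_cols = len(rows), len(rows[0])
    if background is None:
        background = np.full(20, 1 / 20)

    kept_cols = []
    col_scores = []
    for c in range(n_cols):
        col = [r[c] for r in rows]
        gaps = col.count("-")
        if gaps / n_rows > max_gap_fraction:
            continue
        counts = np.zeros(20)
        for ch in col:
            if ch in ("-", "X"):
                continue
            counts[ALPHABET.index(ch)] += 1
        total = counts.sum()
        freqs = (counts + pseudocount) / (total + 20 * pseudocount)
        scores = np.zeros(21)
        scores[:20] = np.log2(freqs / background)
        kept_cols.append(c)
        col_scores.append(scores)
    return ProfileModel(scores=np.array(col_scores), columns=np.array(kept_cols))


def profile_score(
    profile: ProfileModel, seq: str, params: AlignmentParams | None = None
) -> float:
    """Optimal free-end-gap alignment score of ``seq`` against the profile."""
    score, _ = profile_align(profile.scores, seq, params, semiglobal=True)
    return score


def dipeptide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle the order of non-overlapping dipeptide chunks.

    Preserves dipeptide (hence composition) biases better than a residue
    shuffle, giving a more conservative decoy null.
    """
    chunks = [seq[i : i + 2] for i in range(0, len(seq), 2)]
    order = rng.permutation(len(chunks))
    return "".join(chunks[i] for i in order)


def residue_shuffle(seq: str, rng: np.random.Generator) -> str:
    chars = list(seq)
    rng.shuffle(chars)
    return "".join(chars)


@dataclass(frozen=True)
class GateCalibration:
    """A decoy-score null: cutoff = mean + k_sd * SD of decoy scores."""

    mean: float
    sd: float
    n_decoys: int

    def cutoff(self, k_sd: float) -> float:
        return self.mean + k_sd * self.sd


def calibrate_profile_gate(
    profile: ProfileModel,
    source_sequences: list[str],
    params: AlignmentParams | None = None,
    n_decoys: int = 200,
    seed: int = 2081,
    shuffler=dipeptide_shuffle,
) -> GateCalibration:
    """Score ``n_decoys`` shuffles of the source sequences against the profile."""
    rng = np.random.default_rng(seed)
    scores = []
    for i in range(n_decoys):
        src = source_sequences[i % len(source_sequences)]
        scores.append(profile_score(profile, shuffler(src, rng), params))
    arr = np.array(scores)
    return GateCalibration(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n_decoys=n_decoys)


def calibrate_reference_gate(
    reference: ProteinRecord,
    params: AlignmentParams | None = None,
    n_decoys: int = 200,
    seed: int = 2081,
    shuffler=dipeptide_shuffle,
) -> GateCalibration:
    """Decoy null for single-exemplar screens: shuffles of the reference
    itself, scored by pairwise free-end-gap alignment against it."""
    rng = np.random.default_rng(seed)
    scores = [
        semiglobal_align(shuffler(reference.sequence, rng), reference.sequence, params).score
        for _ in range(n_decoys)
    ]
    arr = np.array(scores)
    return GateCalibration(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n_decoys=n_decoys)


@lru_cache(maxsize=8)
def _default_opsin_gate(gap_open: int, gap_extend: int, n_decoys: int, seed: int):
    aln = references.reference_alignment()
    profile = build_profile(aln)
    params = AlignmentParams(gap_open=gap_open, gap_extend=gap_extend)
    cal = calibrate_profile_gate(
        profile, [r.sequence for r in references.reference_panel()],
        params, n_decoys=n_decoys, seed=seed,
    )
    return profile, cal


def opsin_profile_and_gate(thresholds: Thresholds) -> tuple[ProfileModel, GateCalibration]:
    """The packaged-panel profile and its calibrated gate (cached)."""
    return _default_opsin_gate(
        thresholds.gap_open, thresholds.gap_extend,
        thresholds.n_decoys, thresholds.calibration_seed,
    )


def search_proteome(
    proteome: list[ProteinRecord],
    refs: list[ProteinRecord] | None = None,
    params: AlignmentParams | None = None,
    thresholds: Thresholds | None = None,
    preset: str = "standard",
    profile: ProfileModel | None = None,
    gate: GateCalibration | None = None,
) -> list[HomologHit]:
    """Screen a proteome for opsin-family homologs.

    A sequence is retained when its best free-end-gap alignment against the
    reference panel reaches ``min_identity`` and ``min_coverage`` AND its
    profile score passes the calibrated gate for ``preset``.  Ties between
    references at equal score go to the lexicographically smallest id.
    """
    thresholds = thresholds or Thresholds()
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    refs = refs if refs is not None else references.reference_panel()
    if not refs:
        raise ValueError("reference panel must be non-empty")
    params = params or AlignmentParams(
        gap_open=thresholds.gap_open, gap_extend=thresholds.gap_extend
    )
    if profile is None or gate is None:
        profile, gate = opsin_profile_and_gate(thresholds)
    k_sd = getattr(thresholds, PRESETS[preset])
    cutoff = gate.cutoff(k_sd)

    hits: list[HomologHit] = []
    for rec in proteome:
        best: PairwiseAlignment | None = None
        best_ref = ""
        for ref in sorted(refs, key=lambda r: r.id):
            aln = semiglobal_align(
                rec.sequence, ref.sequence, params, query_id=rec.id, subject_id=ref.id
            )
            if best is None or aln.score > best.score:
                best, best_ref = aln, ref.id
        assert best is not None
        if best.identity < thresholds.min_identity or best.coverage < thresholds.min_coverage:
            continue
        pscore = profile_score(profile, rec.sequence, params)
        if pscore < cutoff:
            logger.debug("%s fails domain gate (%.1f < %.1f)", rec.id, pscore, cutoff)
            continue
        hits.append(
            HomologHit(
                query=rec, best_reference_id=best_ref, alignment=best,
                profile_score=pscore, passes_domain_gate=True,
            )
        )
    return hits
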