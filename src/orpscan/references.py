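"""The packaged opsin and retinal-pathway reference panels.

The panels are SYNTHETIC exemplars, not database sequences: seven
microbial-rhodopsin family representatives (BR, BR2, HR, SRI, SRII, SR3,
MR) built deterministically from a shared 240-residue backbone, plus one
exemplar each of the retinal-biosynthesis genes crtY, brp, crtE, crtB and
crtI.  The opsin exemplars carry the canonical functional residues of the
sensory-rhodopsin-II numbering at their literature positions — the
signaling tetrad Y51/R72/D189/Y199, the retinal pocket
W76/V108/F127/W171/Y174/W178, and the Schiff-base lysine K216 — so that
reference-anchored numbering, fingerprint extraction and the Schiff-base
screen behave exactly as they would on a curated panel.

Everything here is a pure function of fixed seeds: re-importing the module
always yields byte-identical panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

from .io import CANONICAL_AA, ProteinRecord, write_fasta

FAMILIES = ("BR", "BR2", "HR", "SRI", "SRII", "SR3", "MR")
CRT_GENES = ("crtY", "brp", "crtE", "crtB", "crtI")

REFERENCE_LENGTH = 240
_PANEL_SEED = 73
#: Fraction of non-fingerprint positions mutated per non-SRII family.
_FAMILY_DIVERGENCE = 0.30

#: Fingerprint of functionally important positions, 1-based in the
#: packaged SRII exemplar's numbering (which matches the literature
#: sensory-rhodopsin-II numbering by construction).
SIGNALING_POSITIONS = {51: "Y", 72: "R", 189: "D", 199: "Y"}
POCKET_POSITIONS = {76: "W", 108: "V", 127: "F", 171: "W", 174: "Y", 178: "W"}
SCHIFF_POSITION = {216: "K"}

#: Amino-acid frequencies biased toward a membrane-protein composition.
_AA_WEIGHTS = {
    "A": 9.0, "C": 1.0, "D": 4.0, "E": 4.5, "F": 5.5, "G": 7.5, "H": 1.5,
    "I": 6.5, "K": 3.0, "L": 10.5, "M": 2.5, "N": 3.0, "P": 4.0, "Q": 2.5,
    "R": 4.0, "S": 6.0, "T": 6.0, "V": 8.0, "W": 2.5, "Y": 4.5,
}


@dataclass(frozen=True)
class FingerprintSchema:
    """The ordered position set read out for every classified sequence.

    ``positions`` maps a 1-based reference position to its canonical
    residue; ``roles`` tags each as signaling, retinal pocket, or the
    Schiff-base column.
    """

    reference_id: str = "SRII"
    positions: dict[int, str] = field(
        default_factory=lambda: {
            **SIGNALING_POSITIONS, **POCKET_POSITIONS, **SCHIFF_POSITION
        }
    )
    roles: dict[int, str] = field(
        default_factory=lambda: {
            **{p: "signaling" for p in SIGNALING_POSITIONS},
            **{p: "retinal_pocket" for p in POCKET_POSITIONS},
            **{p: "schiff_base" for p in SCHIFF_POSITION},
        }
    )

    def __post_init__(self) -> None:
        if set(self.positions) != set(self.roles):
            raise ValueError("positions and roles must cover the same sites")

    @property
    def ordered_positions(self) -> list[int]:
        return sorted(self.positions)

    @property
    def schiff_position(self) -> int:
        schiff = [p for p, r in self.roles.items() if r == "schiff_base"]
        if len(schiff) != 1:
            raise ValueError("schema must define exactly one Schiff-base column")
        return schiff[0]


DEFAULT_SCHEMA = FingerprintSchema()


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    aas = np.array(list(_AA_WEIGHTS))
    w = np.array(list(_AA_WEIGHTS.values()))
    return "".join(rng.choice(aas, size=length, p=w / w.sum()))


def _impose(seq: str, edits: dict[int, str]) -> str:
    chars = list(seq)
    for pos, aa in edits.items():
        chars[pos - 1] = aa
    return "".join(chars)


def mutate(
    seq: str, rate: float, rng: np.random.Generator,
    protected: set[int] | None = None,
) -> str:
    """Substitute each position with prob. ``rate`` (1-based ``protected`` kept)."""
    protected = protected or set()
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        if (i + 1) in protected:
            continue
        alternatives = [a for a in CANONICAL_AA if a != chars[i]]
        chars[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


@lru_cache(maxsize=None)
def opsin_backbone() -> str:
    """The shared ancestral backbone with canonical fingerprint residues."""
    rng = np.random.default_rng(_PANEL_SEED)
    seq = _random_sequence(rng, REFERENCE_LENGTH)
    return _impose(seq, DEFAULT_SCHEMA.positions)


@lru_cache(maxsize=None)
def reference_panel() -> list[ProteinRecord]:
    """The seven family exemplars (synthetic; see module docstring)."""
    backbone = opsin_backbone()
    fingerprint = set(DEFAULT_SCHEMA.positions)
    records = []
    for k, family in enumerate(FAMILIES):
        if family == "SRII":
            seq = backbone
        else:
            rng = np.random.default_rng([_PANEL_SEED, k + 1])
            seq = mutate(backbone, _FAMILY_DIVERGENCE, rng, protected=fingerprint)
            seq = _impose(seq, DEFAULT_SCHEMA.positions)
        records.append(
            ProteinRecord(
                id=family,
                description=f"synthetic {family} family exemplar",
                sequence=seq,
            )
        )
    return records


def reference_alignment() -> dict[str, str]:
    """The pre-built gapped reference alignment (ungapped by construction:
    the exemplars share one backbone with substitutions only)."""
    return {r.id: r.sequence for r in reference_panel()}


def reference_by_id(ref_id: str) -> ProteinRecord:
    for r in reference_panel():
        if r.id == ref_id:
            return r
    raise KeyError(f"no reference {ref_id!r} in the packaged panel")


def schiff_column(alignment: dict[str, str], schema: FingerprintSchema = DEFAULT_SCHEMA) -> int:
    """Locate the Schiff-base column of an alignment structurally.

    The column is defined as the alignment column holding the schema
    reference's Schiff-base residue (robust to numbering drift: columns
    move with the alignment, printed labels stay at "216").
    """
    row = alignment[schema.reference_id]
    residue_count = 0
    for col, ch in enumerate(row):
        if ch != "-":
            residue_count += 1
            if residue_count == schema.schiff_position:
                return col
    raise ValueError("reference row shorter than the Schiff-base position")


_CRT_LENGTHS = {"crtY": 480, "brp": 400, "crtE": 330, "crtB": 340, "crtI": 500}
_CRT_PRODUCTS = {
    "crtY": "lycopene beta-cyclase CrtY",
    "brp": "beta-carotene 15,15'-dioxygenase Brp (bacterioopsin-related protein)",
    "crtE": "geranylgeranyl pyrophosphate synthase CrtE",
    "crtB": "phytoene synthase CrtB",
    "crtI": "phytoene desaturase CrtI",
}


@lru_cache(maxsize=None)
def crt_panel() -> dict[str, ProteinRecord]:
    """Synthetic exemplars of the five retinal-biosynthesis genes."""
    out = {}
    for k, gene in enumerate(CRT_GENES):
        rng = np.random.default_rng([_PANEL_SEED, 100 + k])
        out[gene] = ProteinRecord(
            id=gene,
            description=f"synthetic exemplar: {_CRT_PRODUCTS[gene]}",
            sequence=_random_sequence(rng, _CRT_LENGTHS[gene]),
        )
    return out


def crt_product(gene: str) -> str:
    return _CRT_PRODUCTS[gene]


def write_reference_panel(path: str | Path, include_crt: bool = False) -> None:
    """Write the packaged panel(s) as FASTA."""
    records = list(reference_panel())
    if include_crt:
        records += list(crt_panel().values())
    write_fasta(records, path)
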