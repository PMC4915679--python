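"""Readers and writers for the external formats of the screen.

Protein FASTA and GFF3 come in; TSV tables (fingerprints, calls, context,
presence/absence), iTOL binary-dataset annotations, Newick (via
:mod:`orpscan.phylo`) and two-column spectra go out.

Coordinate convention: GFF3 is 1-based inclusive on disk.  Internally every
:class:`GeneFeature` is 0-based half-open; the conversion happens here, at
the I/O boundary, and nowhere else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from urllib.parse import quote, unquote

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity/rare codes folded into X: scoring matrices lack them.
_NON_CANONICAL = {"B": "X", "Z": "X", "U": "X", "J": "X", "O": "X"}
ALPHABET = CANONICAL_AA + "X"

#: Opsin-class and pathway columns of the presence/absence matrix, in the
#: order they are rendered on the tree annotation.
MATRIX_COLUMNS = [
    "BR", "BR2", "HR", "SRI", "SRII", "SR3", "MR",
    "ORP_A", "ORP_B", "crtY", "brp",
]


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence: id, free-text description, residues."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid record id {self.id!r}: must be non-empty, no whitespace")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-amino-acid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """An annotated gene.  ``start``/``end`` are 0-based half-open."""

    genome_id: str
    contig: str
    start: int
    end: int
    strand: str
    locus_id: str
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.locus_id}: invalid interval [{self.start}, {self.end})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.locus_id}: strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class SpectrumRecord:
    """An absorbance spectrum: matched wavelength (nm) / absorbance (AU) arrays."""

    wavelengths: np.ndarray
    absorbances: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelengths", np.asarray(self.wavelengths, dtype=float))
        object.__setattr__(self, "absorbances", np.asarray(self.absorbances, dtype=float))
        if self.wavelengths.shape != self.absorbances.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelengths and absorbances must be matched 1-D arrays")
        if self.wavelengths.size and np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    def value_at(self, nm: float) -> float:
        """Absorbance linearly interpolated at ``nm``."""
        return float(np.interp(nm, self.wavelengths, self.absorbances))


def _sanitize_sequence(seq: str, rec_id: str) -> str:
    seq = seq.upper().strip("*")
    if "*" in seq:
        raise ValueError(f"record {rec_id!r}: internal stop codon '*'")
    repl = [c for c in seq if c in _NON_CANONICAL]
    if repl:
        warnings.warn(
            f"record {rec_id!r}: non-canonical residues {sorted(set(repl))} mapped to X",
            stacklevel=3,
        )
        seq = "".join(_NON_CANONICAL.get(c, c) for c in seq)
    return seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read an amino-acid FASTA file.

    Sequences are uppercased, terminal ``*`` stripped and rare/ambiguity
    codes folded to X.  Duplicate ids and empty sequences are errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _sanitize_sequence(str(rec.seq), rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(ProteinRecord(id=rec.id, description=desc, sequence=seq))
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path, width: int = 60) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description) for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def _prevalidate_gff(path: Path) -> None:
    """Line-level sanity pass so coordinate/strand errors carry line numbers."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated columns")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start > end:
                raise ValueError(f"{path}:{lineno}: start {start} > end {end}")
            if cols[6] not in {"+", "-"}:
                raise ValueError(f"{path}:{lineno}: unknown strand {cols[6]!r}")


def read_gff(path: str | Path, genome_id: str | None = None) -> list[GeneFeature]:
    """Read gene features (CDS, else gene rows) from a GFF3 file.

    Returns features sorted by (contig, start), converted to 0-based
    half-open coordinates.  ``locus_id`` comes from the ``locus_tag``
    attribute, falling back to ``ID``; ``product`` from the ``product``
    attribute, else empty.
    """
    import gffutils

    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    _prevalidate_gff(path)
    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    features: list[GeneFeature] = []
    seen: set[str] = set()
    ftypes = ["CDS"] if any(True for _ in db.features_of_type("CDS")) else ["gene"]
    for f in db.features_of_type(ftypes):
        locus = (f.attributes.get("locus_tag") or f.attributes.get("ID") or [f.id])[0]
        if locus in seen:
            raise ValueError(f"duplicate locus id {locus!r} in {path}")
        seen.add(locus)
        product = unquote(",".join(f.attributes.get("product") or [""]))
        features.append(
            GeneFeature(
                genome_id=genome_id, contig=f.seqid,
                start=f.start - 1, end=f.end,  # GFF 1-based inclusive -> 0-based half-open
                strand=f.strand, locus_id=locus, product=product,
            )
        )
    features.sort(key=lambda g: (g.contig, g.start, g.locus_id))
    return features


def write_gff(features: list[GeneFeature], path: str | Path) -> None:
    """Write features as GFF3 CDS rows (coordinates back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(features, key=lambda g: (g.contig, g.start, g.locus_id)):
            attrs = f"ID={g.locus_id};locus_tag={g.locus_id}"
            if g.product:
                # GFF3 reserves , ; = in attribute values
                attrs += f";product={quote(g.product, safe=' ()/-')}"
            fh.write(
                f"{g.contig}\torpscan\tCDS\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t0\t{attrs}\n"
            )


def make_presence_absence_matrix(rows: dict[str, dict[str, int]]) -> pd.DataFrame:
    """Build the genome x {opsin classes, crtY, brp} count matrix.

    ``rows`` maps genome id -> {column -> count}; absent columns are 0.
    """
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(
        index=list(rows), columns=MATRIX_COLUMNS, fill_value=0
    )
    df = df.fillna(0).astype(int).sort_index()
    if (df.values < 0).any():
        raise ValueError("presence/absence counts must be non-negative")
    return df


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="genome")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="genome")


def write_itol_binary(
    matrix: pd.DataFrame,
    path: str | Path,
    label: str = "opsin and retinal pathway complement",
    color: str = "#4d7ea8",
) -> None:
    """Emit an iTOL DATASET_BINARY annotation: counts > 0 encoded as presence.

    One field per matrix column; presence is ``1``, absence ``-1`` (iTOL's
    empty-symbol code).
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("cannot write an iTOL annotation for an empty matrix")
    cols = list(matrix.columns)
    lines = [
        "DATASET_BINARY",
        "SEPARATOR COMMA",
        f"DATASET_LABEL,{label}",
        f"COLOR,{color}",
        "FIELD_SHAPES," + ",".join(["2"] * len(cols)),
        "FIELD_LABELS," + ",".join(cols),
        "FIELD_COLORS," + ",".join([color] * len(cols)),
        "DATA",
    ]
    for genome, row in matrix.iterrows():
        symbols = ["1" if v > 0 else "-1" for v in row.values]
        lines.append(f"{genome}," + ",".join(symbols))
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum_tsv(path: str | Path) -> SpectrumRecord:
    """Read a two-column wavelength/absorbance TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.iloc[0].astype(str).str.contains("[A-Za-z]", regex=True).any():
        df = df.iloc[1:]
    arr = df.astype(float).to_numpy()
    return SpectrumRecord(wavelengths=arr[:, 0], absorbances=arr[:, 1])


def write_spectrum_tsv(spectrum: SpectrumRecord, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("wavelength_nm\tabsorbance_au\n")
        for wl, ab in zip(spectrum.wavelengths, spectrum.absorbances):
            fh.write(f"{wl:.6g}\t{ab:.8g}\n")
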