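"""Run configuration: every tunable threshold of the screen, with defaults.

The configuration is a flat mapping of named thresholds, loadable from a
simple YAML file.  Every rule in the pipeline that involves a cutoff reads
it from here, so a run is fully described by one :class:`Thresholds` plus
the input files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Residues accepted as "hydrophobic" at the Schiff column for group B calls.
#: G and W are deliberately excluded: G occurs at other fingerprint columns
#: in group B and W is aromatic-bulky rather than aliphatic.
DEFAULT_HYDROPHOBIC_SET = "LIVMFA"


@dataclass
class Thresholds:
    """All named cutoffs of the screen.

    Attributes
    ----------
    gap_open, gap_extend:
        Affine gap penalties; a gap of length ``k`` costs
        ``gap_open + k * gap_extend``.
    min_identity, min_coverage:
        Pairwise-alignment filters for a proteome sequence to count as an
        opsin-family homolog.
    gate_sd_standard, gate_sd_strict:
        Decoy-calibrated score gates expressed in standard deviations above
        the mean decoy score.  The "standard" preset stands in for a
        permissive homology search (BLAST-style 1e-5 intent), "strict" for
        a conservative one (1e-20 intent).
    n_decoys, calibration_seed:
        Size and seed of the shuffled-decoy null used for gate calibration.
    anchor_min_identity:
        Below this pairwise identity a query is considered unanchorable to
        the reference numbering.
    adjacency_rank, proximity_rank, taxis_min_neighbors:
        Gene-rank windows for genome-context labels: a transducer at
        ``|rank| <= adjacency_rank`` makes a locus transducer-adjacent; at
        least ``taxis_min_neighbors`` taxis/flagellar genes within
        ``proximity_rank`` make it taxis-operon-proximal.
    spectra_window_nm, min_prominence_sd, noise_region_nm:
        Retinal-band detection: search window, required peak prominence in
        noise-SD units, and the flat region used to estimate noise.
    """

    gap_open: int = 11
    gap_extend: int = 1
    min_identity: float = 0.25
    min_coverage: float = 0.5
    gate_sd_standard: float = 4.0
    gate_sd_strict: float = 6.0
    n_decoys: int = 200
    calibration_seed: int = 2081
    anchor_min_identity: float = 0.15
    hydrophobic_set: str = DEFAULT_HYDROPHOBIC_SET
    adjacency_rank: int = 1
    proximity_rank: int = 10
    taxis_min_neighbors: int = 2
    spectra_window_nm: tuple[float, float] = (480.0, 580.0)
    min_prominence_sd: float = 3.0
    noise_region_nm: tuple[float, float] = (600.0, 800.0)

    def __post_init__(self) -> None:
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if not (0.0 <= self.min_identity <= 1.0 and 0.0 <= self.min_coverage <= 1.0):
            raise ValueError("identity/coverage thresholds must lie in [0, 1]")
        self.spectra_window_nm = tuple(self.spectra_window_nm)  # type: ignore[assignment]
        self.noise_region_nm = tuple(self.noise_region_nm)  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Thresholds":
        """Load thresholds from a flat YAML mapping; absent keys keep defaults."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["spectra_window_nm"] = list(self.spectra_window_nm)
        data["noise_region_nm"] = list(self.noise_region_nm)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


DEFAULT_THRESHOLDS = Thresholds()
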