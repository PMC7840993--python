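"""Kyte-Doolittle hydropathy screening of candidate protein probes.

Dye-based thermal shift assays need probes with a buried hydrophobic
core: intrinsically disordered or floppy regions bind the dye in the
native state and produce high background fluorescence.  A quick,
structure-free screen is the Kyte-Doolittle hydropathy profile — long
low-hydropathy stretches mark candidate problem regions — together with
the grand average of hydropathy (GRAVY) of the construct.

Coordinates are 1-based inclusive, matching protein residue numbering
(constructs like "aa 1-306").  Disorder *prediction* is deliberately
not reimplemented here; the hydropathy screen only flags candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO

import numpy as np
from Bio import SeqIO

from thermoshift.errors import ParseError, ValidationError

__all__ = [
    "KYTE_DOOLITTLE",
    "ProteinSequence",
    "HydropathyProfile",
    "read_fasta",
    "gravy",
    "hydropathy_profile",
    "low_hydropathy_segments",
]

#: Kyte-Doolittle hydropathy scale (positive = hydrophobic).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass
class ProteinSequence:
    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class HydropathyProfile:
    """Sliding-window mean Kyte-Doolittle scores.

    ``positions`` are the 1-based residue indices of the window centers;
    there are ``len(sequence) - window + 1`` scores (no edge padding).
    """

    sequence_id: str
    window: int
    positions: np.ndarray
    scores: np.ndarray
    gravy: float


def read_fasta(source: str | IO[str], permissive: bool = False) -> list[ProteinSequence]:
    """Read protein FASTA records in input order.

    Residues are upper-cased and whitespace-stripped.  Non-standard
    letters raise unless ``permissive`` is set.
    """
    handle = source if hasattr(source, "read") else open(source, "r", encoding="utf-8")
    records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise ParseError("no FASTA records found")
    sequences = []
    for rec in records:
        residues = str(rec.seq).upper().replace(" ", "").replace("*", "")
        bad = sorted(set(residues) - set(KYTE_DOOLITTLE))
        if bad and not permissive:
            raise ParseError(f"record {rec.id!r} contains non-standard residues: {bad}")
        sequences.append(ProteinSequence(id=rec.id, residues=residues))
    return sequences


def _scores(seq: ProteinSequence, permissive: bool) -> np.ndarray:
    if permissive:
        return np.array([KYTE_DOOLITTLE.get(aa, 0.0) for aa in seq.residues])
    unknown = sorted(set(seq.residues) - set(KYTE_DOOLITTLE))
    if unknown:
        raise ValidationError(f"sequence {seq.id!r} contains unknown residues: {unknown}")
    return np.array([KYTE_DOOLITTLE[aa] for aa in seq.residues])


def gravy(seq: ProteinSequence, permissive: bool = False) -> float:
    """Grand average of hydropathy: the window-independent mean of the
    per-residue Kyte-Doolittle values over the full sequence.

    Unknown residues raise, or contribute 0.0 under ``permissive``.
    """
    return float(_scores(seq, permissive).mean())


def hydropathy_profile(
    seq: ProteinSequence,
    window: int = 9,
    permissive: bool = False,
) -> HydropathyProfile:
    """Unweighted sliding-window mean of the Kyte-Doolittle values
    (window must be odd and no longer than the sequence)."""
    if window < 1 or window % 2 == 0:
        raise ValidationError("window must be a positive odd integer")
    if window > len(seq):
        raise ValidationError(f"window {window} exceeds sequence length {len(seq)}")
    values = _scores(seq, permissive)
    kernel = np.ones(window) / window
    scores = np.convolve(values, kernel, mode="valid")
    half = window // 2
    positions = np.arange(half + 1, half + 1 + scores.size)
    return HydropathyProfile(
        sequence_id=seq.id, window=window, positions=positions,
        scores=scores, gravy=float(values.mean()),
    )


def low_hydropathy_segments(
    profile: HydropathyProfile,
    threshold: float = -1.5,
    min_length: int = 10,
) -> list[tuple[int, int, float]]:
    """Maximal runs of at least ``min_length`` consecutive window scores
    below ``threshold``.

    Returns ``(start, end, mean_score)`` triples in 1-based inclusive
    window-center coordinates.
    """
    below = profile.scores < threshold
    segments: list[tuple[int, int, float]] = []
    run_start = None
    for i, flag in enumerate(np.append(below, False)):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            length = i - run_start
            if length >= min_length:
                segments.append((
                    int(profile.positions[run_start]),
                    int(profile.positions[i - 1]),
                    float(profile.scores[run_start:i].mean()),
                ))
            run_start = None
    return segments
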