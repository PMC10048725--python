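"""Nucleotide and overlapping-dinucleotide counting.

Dimers are counted on the provided (plus) strand only, in overlapping
windows at offsets 0..L-2; a window containing any non-ACGT character is
skipped and excluded from the valid-window count W. Reverse-complement
relationships are handled analytically downstream (Chargaff null model,
pair reporting), never by double-strand counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .sequence_io import ChromosomeRecord

BASES = "ACGT"
#: Canonical dimer order used for all 16-vectors: AA, AC, AG, AT, CA, ... TT.
DIMERS = tuple(a + b for a in BASES for b in BASES)
DIMER_INDEX = {d: i for i, d in enumerate(DIMERS)}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# byte -> base code (A=0, C=1, G=2, T=3, other=4)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i

#: index (in DIMERS order) of each dimer's reverse complement
REVCOMP_INDEX = np.empty(16, dtype=np.intp)


def reverse_complement_dimer(dimer: str) -> str:
    """Reverse complement of a dimer (AC -> GT); an involution on the 16 dimers."""
    if dimer not in DIMER_INDEX:
        raise ValueError(f"not a dimer over ACGT: {dimer!r}")
    return _COMPLEMENT[dimer[1]] + _COMPLEMENT[dimer[0]]


for _d in DIMERS:
    REVCOMP_INDEX[DIMER_INDEX[_d]] = DIMER_INDEX[reverse_complement_dimer(_d)]


@dataclass
class CompositionTable:
    """Counts for one chromosome.

    Attributes
    ----------
    mono_counts : 4-vector of A, C, G, T counts (non-ACGT ignored)
    dimer_counts : 16-vector in :data:`DIMERS` order
    valid_windows : number W of length-2 windows with both bases in ACGT
    """

    id: str
    species: str
    length_bp: int
    n_gaps: int
    mono_counts: np.ndarray
    dimer_counts: np.ndarray
    valid_windows: int

    @property
    def gc_content(self) -> float:
        total = self.mono_counts.sum()
        return float((self.mono_counts[1] + self.mono_counts[2]) / total)

    def mono_dict(self) -> dict[str, int]:
        return {b: int(n) for b, n in zip(BASES, self.mono_counts)}

    def dimer_dict(self) -> dict[str, int]:
        return {d: int(n) for d, n in zip(DIMERS, self.dimer_counts)}

    @property
    def dimer_fractions(self) -> np.ndarray:
        """Dimer counts / W; undefined (NaN) when W = 0."""
        if self.valid_windows == 0:
            return np.full(16, np.nan)
        return self.dimer_counts / self.valid_windows


def _codes(sequence: str) -> np.ndarray:
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def count_monomers(record: ChromosomeRecord | str) -> dict[str, int]:
    """Counts of A, C, G, T; any other character is ignored."""
    seq = record if isinstance(record, str) else record.sequence
    codes = _codes(seq)
    counts = np.bincount(codes[codes < 4], minlength=4)
    return {b: int(n) for b, n in zip(BASES, counts)}


def count_dimers(record: ChromosomeRecord | str) -> tuple[dict[str, int], int]:
    """Overlapping dimer counts and the valid-window count W."""
    seq = record if isinstance(record, str) else record.sequence
    codes = _codes(seq)
    if codes.size < 2:
        return {d: 0 for d in DIMERS}, 0
    first, second = codes[:-1], codes[1:]
    valid = (first < 4) & (second < 4)
    idx = first[valid].astype(np.intp) * 4 + second[valid]
    counts = np.bincount(idx, minlength=16)
    return {d: int(n) for d, n in zip(DIMERS, counts)}, int(valid.sum())


def compose(record: ChromosomeRecord) -> CompositionTable:
    """Full composition (mono + dimer counts) of one chromosome."""
    mono = count_monomers(record)
    dimers, w = count_dimers(record)
    return CompositionTable(
        id=record.id,
        species=record.species,
        length_bp=record.length_bp,
        n_gaps=record.n_gaps,
        mono_counts=np.array([mono[b] for b in BASES], dtype=np.int64),
        dimer_counts=np.array([dimers[d] for d in DIMERS], dtype=np.int64),
        valid_windows=w,
    )


def composition_frame(compositions: Iterable[CompositionTable]) -> pd.DataFrame:
    """One row per chromosome: id, species, L, n_gaps, 4 mono, 16 dimer counts, W."""
    rows = []
    for c in compositions:
        row: dict[str, object] = {
            "id": c.id,
            "species": c.species,
            "length_bp": c.length_bp,
            "n_gaps": c.n_gaps,
        }
        row.update({f"n_{b}": int(n) for b, n in zip(BASES, c.mono_counts)})
        row.update({f"C_{d}": int(n) for d, n in zip(DIMERS, c.dimer_counts)})
        row["W"] = c.valid_windows
        row["gc_content"] = c.gc_content
        rows.append(row)
    return pd.DataFrame(rows)


def compositions_from_frame(frame: pd.DataFrame) -> list[CompositionTable]:
    """Inverse of :func:`composition_frame` (round-trips the TSV export)."""
    out = []
    for _, row in frame.iterrows():
        out.append(
            CompositionTable(
                id=str(row["id"]),
                species=str(row.get("species", "")),
                length_bp=int(row["length_bp"]),
                n_gaps=int(row["n_gaps"]),
                mono_counts=np.array([row[f"n_{b}"] for b in BASES], dtype=np.int64),
                dimer_counts=np.array([row[f"C_{d}"] for d in DIMERS], dtype=np.int64),
                valid_windows=int(row["W"]),
            )
        )
    return out


def mono_vector(mono_counts: Mapping[str, int]) -> np.ndarray:
    return np.array([mono_counts[b] for b in BASES], dtype=float)
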