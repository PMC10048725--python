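"""Detection of dinucleotide pairs that moderate structural DNA properties.

A *moderating pair* is a coupled pair of dimer contents whose combined
effect buffers a chromosomal property: either the contents are
significantly correlated and push the property in opposite directions
(``correlated_opposite``), or they are significantly anticorrelated and
push it in the same direction (``anticorrelated_same``). Inputs are the
unexplained significant pair correlations and the per-property lists of
dimers with large significant influence; both may be computed by the
pipeline or supplied as hand-entered TSV tables.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .correlation_stats import SIGNIFICANCE_THRESHOLD, CorrelationRecord

CORRELATED_OPPOSITE = "correlated_opposite"
ANTICORRELATED_SAME = "anticorrelated_same"


@dataclass(frozen=True)
class CoupledPair:
    """One (dimer pair, property) moderation event."""

    pair: tuple[str, str]
    correlation_significance: float
    property_id: int
    property_name: str
    sign_first: int
    sign_second: int
    moderation_type: str


def sign_lists_to_map(sign_table: pd.DataFrame) -> dict[int, dict[str, object]]:
    """Expand a per-property sign table into {property_id: {dimer: +/-1, ...}}.

    ``sign_table`` has columns property_id, property_name, positive,
    negative (the last two space-separated dimer lists, possibly empty).
    """
    out: dict[int, dict[str, object]] = {}
    for _, row in sign_table.iterrows():
        signs: dict[str, int] = {}
        for col, sign in (("positive", +1), ("negative", -1)):
            cell = row.get(col, "")
            if isinstance(cell, str) and cell.strip():
                for dimer in cell.split():
                    signs[dimer] = sign
        out[int(row["property_id"])] = {
            "name": str(row["property_name"]),
            "signs": signs,
        }
    return out


def find_moderating_pairs(
    pairs: Sequence[CorrelationRecord] | pd.DataFrame,
    sign_table: pd.DataFrame | Mapping[int, dict[str, object]],
    threshold: float = SIGNIFICANCE_THRESHOLD,
) -> list[CoupledPair]:
    """Emit moderation events for every (unexplained pair, property) match.

    For each significant pair and each property where BOTH dimers carry a
    large significant influence, a :class:`CoupledPair` is emitted when
    the correlation sign and the influence-sign pattern match the
    moderation rule. Output is sorted by property id, then pair.
    """
    if isinstance(pairs, pd.DataFrame):
        records = [
            ((row["dimer1"], row["dimer2"]), float(row["significance"]))
            for _, row in pairs.iterrows()
        ]
    else:
        records = [(rec.pair, rec.significance) for rec in pairs]
    if isinstance(sign_table, pd.DataFrame):
        properties = sign_lists_to_map(sign_table)
    else:
        properties = dict(sign_table)

    out = []
    for (d1, d2), sig in records:
        if abs(sig) <= threshold:
            continue
        for prop_id in sorted(properties):
            signs = properties[prop_id]["signs"]
            if d1 not in signs or d2 not in signs:
                continue
            s1, s2 = signs[d1], signs[d2]
            if sig > threshold and s1 != s2:
                kind = CORRELATED_OPPOSITE
            elif sig < -threshold and s1 == s2:
                kind = ANTICORRELATED_SAME
            else:
                continue
            out.append(
                CoupledPair(
                    pair=(d1, d2),
                    correlation_significance=sig,
                    property_id=prop_id,
                    property_name=str(properties[prop_id]["name"]),
                    sign_first=s1,
                    sign_second=s2,
                    moderation_type=kind,
                )
            )
    out.sort(key=lambda cp: (cp.property_id, cp.pair))
    return out


def count_by_type(coupled: Sequence[CoupledPair]) -> Counter:
    """Tally of (pair, property) combinations per moderation type."""
    counts = Counter({CORRELATED_OPPOSITE: 0, ANTICORRELATED_SAME: 0})
    counts.update(cp.moderation_type for cp in coupled)
    return counts


def coupled_frame(coupled: Sequence[CoupledPair]) -> pd.DataFrame:
    """TSV-ready report of moderation events."""
    return pd.DataFrame(
        {
            "dimer1": [cp.pair[0] for cp in coupled],
            "dimer2": [cp.pair[1] for cp in coupled],
            "correlation_significance": [cp.correlation_significance for cp in coupled],
            "property_id": [cp.property_id for cp in coupled],
            "property_name": [cp.property_name for cp in coupled],
            "sign_dimer1": [cp.sign_first for cp in coupled],
            "sign_dimer2": [cp.sign_second for cp in coupled],
            "moderation_type": [cp.moderation_type for cp in coupled],
        }
    )


# --- hand-entered table IO -------------------------------------------------

def read_pair_table(path: str | Path) -> pd.DataFrame:
    """Read a pair-correlation TSV (dimer1, dimer2, ..., significance)."""
    frame = pd.read_csv(path, sep="\t")
    needed = {"dimer1", "dimer2", "significance"}
    missing = needed - set(frame.columns)
    if missing:
        raise ValueError(f"pair table missing column(s): {', '.join(sorted(missing))}")
    return frame


def read_sign_table(path: str | Path) -> pd.DataFrame:
    """Read a per-property influence-sign TSV (property_id, property_name, positive, negative)."""
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    needed = {"property_id", "property_name", "positive", "negative"}
    missing = needed - set(frame.columns)
    if missing:
        raise ValueError(f"sign table missing column(s): {', '.join(sorted(missing))}")
    return frame


def _data_path(name: str):
    return resources.files("dinucouple.data").joinpath(name)


def load_reference_pair_table() -> pd.DataFrame:
    """Bundled reference table of unexplained significant pair correlations.

    Published values from the large-scale survey of 2478 eukaryotic
    chromosomes (Chargaff-model significances of pair correlations not
    explained by gene/CDS/length classification).
    """
    with resources.as_file(_data_path("reference_pair_correlations.tsv")) as path:
        return read_pair_table(path)


def load_reference_sign_table() -> pd.DataFrame:
    """Bundled reference table of large significant property influences.

    Published per-property dimer sign lists (influences significant at
    >1 sigma with relative change >= 10%) from the same survey.
    """
    with resources.as_file(_data_path("reference_property_signs.tsv")) as path:
        return read_sign_table(path)
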