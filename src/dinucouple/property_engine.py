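"""Dinucleotide influence on structural DNA properties via a replacement model.

A property model M assigns one numeric value to each of the 16 dimers
(roll, tilt, twist, slide, ... as in DiProDB-style tables). The
chromosomal mean value is the dimer-fraction-weighted average

    V_E = sum_ij M_ij c_ij,          c_ij = C_ij / W.

The influence of a single dimer XY is estimated by notionally removing
its occurrences (-v_XY = -M_XY c_XY) and replacing them with random
dimers drawn from the chromosome's own null model
(+v_random = c_XY sum_ij M_ij p_ij):

    V_M = V_E - v_XY + v_random
    delta = V_E - V_M = c_XY (M_XY - sum_ij M_ij p_ij)

Because both c and p sum to one, delta is invariant under adding a
constant to all model values and scales linearly with the model.
Across chromosomes, mean(delta)/std(delta) is the significance of the
influence (|.| > 1 significant) and |mean delta| / |mean V_E| its
relative size (>= 10% deemed large).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .counts import DIMERS, CompositionTable
from .null_models import ModelKind, dimer_probs

SIGNIFICANCE_THRESHOLD = 1.0
RELATIVE_CHANGE_THRESHOLD = 0.10

#: sentinel for an unbounded significance (zero spread, nonzero mean)
UNBOUNDED = math.inf


@dataclass
class PropertyModel:
    """One dinucleotide property model: 16 values in :data:`DIMERS` order."""

    id: int
    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (16,):
            raise ValueError(f"model {self.id} needs exactly 16 dimer values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"model {self.id} has non-finite values")


@dataclass
class PropertyInfluence:
    """Aggregated influence of one dimer on one property across chromosomes."""

    property_id: int
    property_name: str
    dimer: str
    mean_delta: float
    std_delta: float
    significance: float
    mean_value: float
    relative_change: float

    @property
    def significant(self) -> bool:
        return abs(self.significance) > SIGNIFICANCE_THRESHOLD

    @property
    def large(self) -> bool:
        return self.relative_change >= RELATIVE_CHANGE_THRESHOLD

    @property
    def sign(self) -> int:
        return int(np.sign(self.mean_delta))


def load_property_table(path: str | Path) -> list[PropertyModel]:
    """Read property models from a TSV with columns id, name, AA..TT."""
    frame = pd.read_csv(path, sep="\t")
    missing = [d for d in DIMERS if d not in frame.columns]
    if missing:
        raise ValueError(f"property table missing dimer column(s): {', '.join(missing)}")
    if frame["id"].duplicated().any():
        dup = frame.loc[frame["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicated property model id: {dup}")
    models = []
    for _, row in frame.iterrows():
        values = row[list(DIMERS)].to_numpy()
        try:
            values = values.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric value in property model {row['id']}") from exc
        models.append(PropertyModel(id=int(row["id"]), name=str(row["name"]), values=values))
    return models


def write_property_table(models: Sequence[PropertyModel], path: str | Path) -> None:
    rows = []
    for m in models:
        row = {"id": m.id, "name": m.name}
        row.update({d: v for d, v in zip(DIMERS, m.values)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def chromosome_property_value(model: PropertyModel, fractions: np.ndarray) -> float:
    """Chromosomal mean property value V_E = sum M_ij c_ij."""
    fractions = np.asarray(fractions, dtype=float)
    if np.any(np.isnan(fractions)):
        return float("nan")
    return float(model.values @ fractions)


def replacement_value(
    model: PropertyModel, fractions: np.ndarray, p_model: np.ndarray
) -> pd.DataFrame:
    """Per-dimer replacement bookkeeping for one chromosome.

    Columns: v_xy (the dimer's own contribution), v_random (contribution
    of the same amount of null-random dimers), V_M (property value after
    the replacement) and delta = V_E - V_M.
    """
    fractions = np.asarray(fractions, dtype=float)
    p_model = np.asarray(p_model, dtype=float)
    v_e = chromosome_property_value(model, fractions)
    v_xy = model.values * fractions
    v_random = fractions * float(model.values @ p_model)
    v_m = v_e - v_xy + v_random
    return pd.DataFrame(
        {"dimer": list(DIMERS), "v_xy": v_xy, "v_random": v_random,
         "V_E": v_e, "V_M": v_m, "delta": v_e - v_m}
    )


def replacement_delta(
    model: PropertyModel, fractions: np.ndarray, p_model: np.ndarray
) -> np.ndarray:
    """Closed form of the replacement delta: c_XY (M_XY - sum M p)."""
    fractions = np.asarray(fractions, dtype=float)
    return fractions * (model.values - float(model.values @ np.asarray(p_model, dtype=float)))


def influence_significance(
    model: PropertyModel, deltas: np.ndarray, values: np.ndarray
) -> list[PropertyInfluence]:
    """Aggregate per-chromosome deltas into per-dimer influence statistics.

    ``deltas`` is (n_chromosomes, 16), ``values`` the per-chromosome V_E.
    Requires >= 3 chromosomes. Zero spread with a nonzero mean yields a
    signed unbounded-significance sentinel.
    """
    deltas = np.asarray(deltas, dtype=float)
    values = np.asarray(values, dtype=float)
    if deltas.shape[0] < 3:
        raise ValueError("need at least 3 chromosomes")
    mean_delta = deltas.mean(axis=0)
    std_delta = deltas.std(axis=0, ddof=1)
    mean_value = float(values.mean())
    out = []
    for i, dimer in enumerate(DIMERS):
        # spread below float noise on the mean counts as degenerate
        if std_delta[i] <= abs(mean_delta[i]) * 1e-12:
            std_delta[i] = 0.0
        if std_delta[i] > 0:
            sig = mean_delta[i] / std_delta[i]
        elif mean_delta[i] != 0:
            sig = math.copysign(UNBOUNDED, mean_delta[i])
        else:
            sig = 0.0
        rel = abs(mean_delta[i]) / abs(mean_value) if mean_value != 0 else math.inf
        out.append(
            PropertyInfluence(
                property_id=model.id,
                property_name=model.name,
                dimer=dimer,
                mean_delta=float(mean_delta[i]),
                std_delta=float(std_delta[i]),
                significance=float(sig),
                mean_value=mean_value,
                relative_change=float(rel),
            )
        )
    return out


def property_influences(
    compositions: Sequence[CompositionTable],
    models: Sequence[PropertyModel],
    kind: ModelKind = "binomial",
) -> list[PropertyInfluence]:
    """Replacement-model influence of every dimer on every property.

    The replacement probabilities are each chromosome's own null-model
    dimer probabilities under ``kind``.
    """
    fractions = np.stack([c.dimer_fractions for c in compositions])
    probs = np.stack([dimer_probs(c.mono_counts, kind) for c in compositions])
    influences: list[PropertyInfluence] = []
    for model in models:
        values = fractions @ model.values
        deltas = fractions * (model.values[None, :] - (probs @ model.values)[:, None])
        influences.extend(influence_significance(model, deltas, values))
    return influences


def influences_frame(influences: Sequence[PropertyInfluence]) -> pd.DataFrame:
    """Full per-(property, dimer) diagnostics table."""
    return pd.DataFrame(
        {
            "property_id": [i.property_id for i in influences],
            "property_name": [i.property_name for i in influences],
            "dimer": [i.dimer for i in influences],
            "mean_delta": [i.mean_delta for i in influences],
            "std_delta": [i.std_delta for i in influences],
            "significance": [i.significance for i in influences],
            "mean_value": [i.mean_value for i in influences],
            "relative_change": [i.relative_change for i in influences],
            "significant": [i.significant for i in influences],
            "large": [i.large for i in influences],
        }
    )


def large_influence_table(influences: Sequence[PropertyInfluence]) -> pd.DataFrame:
    """Per-property lists of dimers with significant AND large influence.

    Columns: property_id, property_name, positive (space-separated dimers
    with positive mean delta), negative. Properties with no qualifying
    dimer are omitted. The relative-change boundary (exactly 10%) is
    retained.
    """
    rows: dict[int, dict[str, object]] = {}
    for inf in influences:
        if not (inf.significant and inf.large):
            continue
        row = rows.setdefault(
            inf.property_id,
            {"property_id": inf.property_id, "property_name": inf.property_name,
             "positive": [], "negative": []},
        )
        (row["positive"] if inf.sign > 0 else row["negative"]).append(inf.dimer)
    out = pd.DataFrame(
        [
            {**row, "positive": " ".join(row["positive"]), "negative": " ".join(row["negative"])}
            for row in rows.values()
        ]
    )
    if not out.empty:
        out = out.sort_values("property_id").reset_index(drop=True)
    return out
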