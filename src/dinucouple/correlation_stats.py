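"""Cross-chromosome correlation of dinucleotide contents with Monte-Carlo significance.

Each chromosome contributes one observation per dimer (its normalized
content); Pearson correlation across chromosomes is computed for every
unordered dimer pair. Significance is measured against replicate datasets
sampled from the null model and normalized identically:

    sigma_XY-ZV = (r_empirical - mean_r_model) / std_r_model

with the sample standard deviation (denominator R-1) over replicates.
|sigma| > 1 is deemed significant; the sign splits significant pairs into
correlated and anticorrelated classes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .counts import DIMERS, CompositionTable
from .null_models import (
    ModelKind,
    NullModelSpec,
    Scale,
    normalize_sampled,
    residual_matrix,
    sample_null_counts,
)

SIGNIFICANCE_THRESHOLD = 1.0

#: the 120 distinct unordered dimer pairs, in canonical order
UNORDERED_PAIRS = tuple(itertools.combinations(DIMERS, 2))


@dataclass
class CorrelationRecord:
    """Empirical correlation and null-model significance for one dimer pair."""

    pair: tuple[str, str]
    r_empirical: float
    model_mean: float
    model_std: float
    significance: float

    @property
    def cls(self) -> str:
        return classify_significance(self.significance)


def classify_significance(sig: float) -> str:
    if np.isnan(sig):
        return "undefined"
    if sig > SIGNIFICANCE_THRESHOLD:
        return "correlated"
    if sig < -SIGNIFICANCE_THRESHOLD:
        return "anticorrelated"
    return "none"


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation; NaN (not an exception) on zero variance.

    Observations where either value is NaN are dropped pairwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt((dx * dx).sum())
    sy = np.sqrt((dy * dy).sum())
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.clip((dx * dy).sum() / (sx * sy), -1.0, 1.0))


def correlation_matrix(residuals: np.ndarray) -> pd.DataFrame:
    """16 x 16 Pearson correlation of dimer contents across chromosomes.

    ``residuals`` is (n_chromosomes, 16). NaN observations (undefined
    chromosomes) are dropped pairwise, not globally.
    """
    if residuals.shape[0] < 3:
        raise ValueError("need at least 3 chromosomes")
    frame = pd.DataFrame(residuals, columns=list(DIMERS))
    return frame.corr(method="pearson", min_periods=3)


def pairwise_dimer_correlations(residuals: np.ndarray) -> dict[tuple[str, str], float]:
    """Empirical r for all 120 distinct unordered dimer pairs."""
    corr = correlation_matrix(residuals)
    return {(a, b): float(corr.loc[a, b]) for a, b in UNORDERED_PAIRS}


def null_correlation_distribution(
    spec: NullModelSpec,
    compositions: Sequence[CompositionTable],
    scale: Scale = "per_window",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean and sample std (over replicates) of each pair's null correlation.

    For each replicate, a full synthetic dataset (one sampled count per
    chromosome per dimer) is normalized identically to the empirical data
    and all pairwise correlations are computed.
    """
    sampled = sample_null_counts(spec, compositions)
    normed = normalize_sampled(sampled, compositions, spec.kind, scale)
    reps = np.stack([correlation_matrix(normed[r]).to_numpy() for r in range(spec.replicates)])
    mean = pd.DataFrame(reps.mean(axis=0), index=list(DIMERS), columns=list(DIMERS))
    std = pd.DataFrame(reps.std(axis=0, ddof=1), index=list(DIMERS), columns=list(DIMERS))
    return mean, std


def significance(r_empirical: float, model_mean: float, model_std: float) -> float:
    """Deviation of the empirical correlation from the null, in null-model stds."""
    if model_std == 0 or np.isnan(model_std):
        return float("nan")
    return (r_empirical - model_mean) / model_std


def correlation_records(
    compositions: Sequence[CompositionTable],
    spec: NullModelSpec,
    scale: Scale = "per_window",
) -> list[CorrelationRecord]:
    """Full pairwise analysis: empirical r, null mean/std, significance, class."""
    residuals = residual_matrix(compositions, spec.kind, scale)
    empirical = pairwise_dimer_correlations(residuals)
    mean, std = null_correlation_distribution(spec, compositions, scale)
    records = []
    for a, b in UNORDERED_PAIRS:
        r = empirical[(a, b)]
        m, s = float(mean.loc[a, b]), float(std.loc[a, b])
        records.append(
            CorrelationRecord(
                pair=(a, b),
                r_empirical=r,
                model_mean=m,
                model_std=s,
                significance=significance(r, m, s),
            )
        )
    return records


def records_frame(records: Sequence[CorrelationRecord]) -> pd.DataFrame:
    """TSV-ready report: dimer1, dimer2, r, model mean/std, significance, class."""
    return pd.DataFrame(
        {
            "dimer1": [rec.pair[0] for rec in records],
            "dimer2": [rec.pair[1] for rec in records],
            "r_empirical": [rec.r_empirical for rec in records],
            "model_mean": [rec.model_mean for rec in records],
            "model_std": [rec.model_std for rec in records],
            "significance": [rec.significance for rec in records],
            "class": [rec.cls for rec in records],
        }
    )


def significance_heatmap_frame(records: Sequence[CorrelationRecord], order: Sequence[str] = DIMERS) -> pd.DataFrame:
    """Symmetric 16 x 16 significance matrix (diagonal NaN), rows/cols ordered."""
    mat = pd.DataFrame(np.nan, index=list(order), columns=list(order))
    for rec in records:
        a, b = rec.pair
        mat.loc[a, b] = rec.significance
        mat.loc[b, a] = rec.significance
    return mat
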