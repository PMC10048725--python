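"""Null models for dinucleotide contents.

Two nulls are supported. The *binomial* model predicts each dimer count
from single-base composition, p_XY = p_X p_Y, so any excess it flags is a
genuinely dinucleotide-level bias. The *chargaff* model additionally
enforces intra-strand parity (Chargaff's second rule) by averaging each
dimer's probability with that of its reverse complement,
p^C_XY = (p_XY + p_X'Y')/2.

Expected counts and variances are binomial with sample size n = W, the
number of valid overlapping dimer windows (W = L-1 on a gap-free
sequence): E = W p, sigma^2 = W p (1-p). The normalized content is the
residual C' = C - E, with sigma kept as a quality annotation rather than
subtracted. For cross-chromosome correlations the residual is scaled per
window (C'/W) by default so that chromosome length does not dominate;
raw residuals and z-scores (C-E)/sigma are available as options.

Replicate null datasets are drawn independently per (replicate,
chromosome, dimer) from Binomial(W, p) under the chosen model; the RNG
stream is keyed on (seed, replicate, chromosome id) so adding
chromosomes never reshuffles earlier draws.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .counts import BASES, DIMERS, REVCOMP_INDEX, CompositionTable

ModelKind = Literal["binomial", "chargaff"]
Scale = Literal["per_window", "raw", "zscore"]


@dataclass
class NullModelSpec:
    """Configuration of the null model and its Monte-Carlo replication."""

    kind: ModelKind = "binomial"
    replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("binomial", "chargaff"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates for a standard deviation")


@dataclass
class NormalizedContents:
    """Per-chromosome model probabilities, expectations and residuals.

    All 16-vectors are in :data:`dinucouple.counts.DIMERS` order.
    """

    id: str
    p: np.ndarray
    expected: np.ndarray
    sigma: np.ndarray
    residual: np.ndarray
    scaled_residual: np.ndarray = field(repr=False)


def dimer_probs(mono_counts: Mapping[str, int] | np.ndarray, kind: ModelKind = "binomial") -> np.ndarray:
    """Model probability for each of the 16 dimers.

    binomial: p_XY = p_X p_Y with p_X = n_X / sum(n) (valid bases only).
    chargaff: the binomial probabilities averaged with those of the
    reverse-complement dimer.
    """
    if isinstance(mono_counts, Mapping):
        mono = np.array([mono_counts[b] for b in BASES], dtype=float)
    else:
        mono = np.asarray(mono_counts, dtype=float)
    total = mono.sum()
    if total <= 0:
        raise ValueError("chromosome has no valid (A/C/G/T) bases")
    p_base = mono / total
    p = np.outer(p_base, p_base).ravel()  # row-major matches DIMERS order
    if kind == "chargaff":
        p = 0.5 * (p + p[REVCOMP_INDEX])
    elif kind != "binomial":
        raise ValueError(f"unknown model kind {kind!r}")
    return p


def expectation_and_variance(p: np.ndarray | float, windows: int) -> tuple[np.ndarray, np.ndarray]:
    """Binomial expectation E = W p and std sigma = sqrt(W p (1-p))."""
    p = np.asarray(p, dtype=float)
    expected = windows * p
    sigma = np.sqrt(windows * p * (1.0 - p))
    return expected, sigma


def normalize(composition: CompositionTable, kind: ModelKind = "binomial") -> NormalizedContents:
    """Normalized dinucleotide contents of one chromosome under a null model."""
    p = dimer_probs(composition.mono_counts, kind)
    w = composition.valid_windows
    expected, sigma = expectation_and_variance(p, w)
    residual = composition.dimer_counts - expected
    scaled = residual / w if w > 0 else np.full(16, np.nan)
    return NormalizedContents(
        id=composition.id, p=p, expected=expected, sigma=sigma,
        residual=residual, scaled_residual=scaled,
    )


def residual_matrix(
    compositions: Sequence[CompositionTable],
    kind: ModelKind = "binomial",
    scale: Scale = "per_window",
) -> np.ndarray:
    """(n_chromosomes, 16) matrix of normalized contents on the chosen scale."""
    rows = []
    for comp in compositions:
        norm = normalize(comp, kind)
        rows.append(_scale_residual(norm.residual, norm.sigma, comp.valid_windows, scale))
    return np.asarray(rows)


def _scale_residual(residual: np.ndarray, sigma: np.ndarray, windows: int, scale: Scale) -> np.ndarray:
    if scale == "raw":
        return residual
    if scale == "per_window":
        return residual / windows if windows > 0 else np.full(16, np.nan)
    if scale == "zscore":
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(sigma > 0, residual / sigma, np.nan)
    raise ValueError(f"unknown residual scale {scale!r}")


def _chromosome_rng(seed: int, replicate: int, chrom_id: str) -> np.random.Generator:
    # stable 64-bit key from the chromosome id; SeedSequence mixes the rest
    key = int.from_bytes(
        hashlib.blake2b(chrom_id.encode("utf-8"), digest_size=8).digest(), "big"
    )
    return np.random.default_rng(np.random.SeedSequence([seed, replicate, key]))


def sample_null_counts(
    spec: NullModelSpec, compositions: Sequence[CompositionTable]
) -> np.ndarray:
    """Replicate dimer-count tables drawn from the null model.

    Returns an array of shape (replicates, n_chromosomes, 16); entry
    [r, c, :] is an independent Binomial(W_c, p_.,c) draw, reproducible
    given (seed, r, chromosome id).
    """
    out = np.empty((spec.replicates, len(compositions), 16), dtype=np.int64)
    probs = [dimer_probs(comp.mono_counts, spec.kind) for comp in compositions]
    for r in range(spec.replicates):
        for c, comp in enumerate(compositions):
            rng = _chromosome_rng(spec.seed, r, comp.id)
            out[r, c] = rng.binomial(comp.valid_windows, probs[c])
    return out


def normalize_sampled(
    sampled: np.ndarray,
    compositions: Sequence[CompositionTable],
    kind: ModelKind = "binomial",
    scale: Scale = "per_window",
) -> np.ndarray:
    """Apply the empirical-data normalization to sampled replicate counts.

    ``sampled`` has shape (R, n_chrom, 16); the result has the same shape
    and holds residuals on the chosen scale.
    """
    out = np.empty(sampled.shape, dtype=float)
    for c, comp in enumerate(compositions):
        p = dimer_probs(comp.mono_counts, kind)
        w = comp.valid_windows
        expected, sigma = expectation_and_variance(p, w)
        out[:, c, :] = [
            _scale_residual(rep - expected, sigma, w, scale) for rep in sampled[:, c, :]
        ]
    return out


def normalized_frame(
    compositions: Iterable[CompositionTable], kind: ModelKind = "binomial"
):
    """TSV-ready frame: one row per chromosome x dimer."""
    import pandas as pd

    rows = []
    for comp in compositions:
        norm = normalize(comp, kind)
        for i, dimer in enumerate(DIMERS):
            rows.append(
                {
                    "id": comp.id,
                    "dimer": dimer,
                    "p": norm.p[i],
                    "expected": norm.expected[i],
                    "sigma": norm.sigma[i],
                    "residual": norm.residual[i],
                    "scaled_residual": norm.scaled_residual[i],
                }
            )
    return pd.DataFrame(rows)
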