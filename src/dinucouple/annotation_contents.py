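"""Annotation attributes per chromosome and their relation to dimer contents.

Gene and coding contents are coverage fractions of the gap-corrected
length, c = n / (L - n_gaps), where n is the merged base count of the
feature union (coding content uses the union of mRNA and CDS spans, so
introns inside annotated mRNAs count as coding by default). Enhancer
counts are z-scored within each genome, which deliberately discards
between-genome level differences (annotation effort varies wildly between
model and non-model organisms).

Dimers are then classified by the signs of their significant
correlations with chromosome length versus gene/CDS content: a
*length_class* dimer rises with chromosome length and/or falls with
genic content; a *genic_class* dimer does the opposite; dimers with no
significant signal, or with conflicting signals, stay unclassified.
Significant dimer-pair correlations expected from this classification
(same class and correlated, or different classes and anticorrelated) are
"explained" and filtered out, leaving the pairs whose coupling has no
annotation-level explanation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .correlation_stats import (
    SIGNIFICANCE_THRESHOLD,
    CorrelationRecord,
    pearson,
    significance,
)
from .counts import DIMERS, CompositionTable
from .null_models import NullModelSpec, Scale, normalize_sampled, residual_matrix, sample_null_counts
from .sequence_io import ChromosomeRecord, merged_base_count

logger = logging.getLogger(__name__)

ATTRIBUTES = ("gene_content", "cds_content", "enhancer_norm", "length_bp")

LENGTH_CLASS = "length_class"
GENIC_CLASS = "genic_class"
UNCLASSIFIED = "unclassified"


def gene_cds_content(record: ChromosomeRecord, include_mrna: bool = True) -> tuple[float, float]:
    """Gene and coding coverage fractions of the gap-corrected length.

    Coding bases are the union of mRNA and CDS spans when ``include_mrna``
    (the default; many assemblies annotate mRNA but not CDS), else CDS
    spans alone.
    """
    denom = record.length_bp - record.n_gaps
    if denom <= 0:
        raise ValueError(f"chromosome {record.id} is all gaps")
    ann = record.annotations
    n_genes = merged_base_count(ann.gene_spans)
    coding_spans = list(ann.cds_spans)
    if include_mrna:
        coding_spans += list(ann.mrna_spans)
    n_cds = merged_base_count(coding_spans)
    return n_genes / denom, n_cds / denom


def enhancer_normalize(counts: Sequence[float]) -> tuple[np.ndarray, bool]:
    """Within-genome z-scores of per-chromosome enhancer counts.

    Returns (values, defined). With zero spread the values are all 0 and
    ``defined`` is False; a single-chromosome genome is rejected.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValueError("enhancer normalization needs at least 2 chromosomes")
    mu = counts.mean()
    sd = counts.std(ddof=1)
    if sd == 0:
        return np.zeros_like(counts), False
    return (counts - mu) / sd, True


def count_enhancers(
    record: ChromosomeRecord, extra_span_sets: Sequence[Sequence[tuple[int, int]]] = ()
) -> int:
    """Enhancer count for one chromosome, unioning multiple interval sets.

    Multiple sets (e.g. per cell type) are combined with exact-duplicate
    intervals removed before counting.
    """
    spans = {tuple(s) for s in record.annotations.enhancer_spans}
    for span_set in extra_span_sets:
        spans.update(tuple(s) for s in span_set)
    return len(spans)


def attribute_table(
    records: Sequence[ChromosomeRecord],
    enhancer_counts: Mapping[str, float] | None = None,
    include_mrna: bool = True,
) -> pd.DataFrame:
    """Per-chromosome attributes: gene/CDS content, length, normalized enhancers.

    Enhancer counts default to the records' own enhancer spans; the
    z-score is taken within each genome (grouped by species). Genomes with
    a single chromosome, or with zero spread, get NaN enhancer_norm.
    """
    rows = []
    for rec in records:
        try:
            c_genes, c_cds = gene_cds_content(rec, include_mrna)
        except ValueError:
            logger.warning("excluding all-gap chromosome %s", rec.id)
            continue
        if enhancer_counts is not None:
            enh = float(enhancer_counts.get(rec.id, 0))
        else:
            enh = float(count_enhancers(rec))
        rows.append(
            {
                "id": rec.id,
                "species": rec.species,
                "gene_content": c_genes,
                "cds_content": c_cds,
                "enhancer_count": enh,
                "length_bp": rec.length_bp,
            }
        )
    frame = pd.DataFrame(rows)
    if frame.empty:
        return frame
    frame["enhancer_norm"] = np.nan
    for _, idx in frame.groupby("species").groups.items():
        if len(idx) < 2:
            continue
        values, defined = enhancer_normalize(frame.loc[idx, "enhancer_count"].to_numpy())
        if defined:
            frame.loc[idx, "enhancer_norm"] = values
    return frame


def attribute_dimer_correlations(
    compositions: Sequence[CompositionTable],
    attributes: pd.DataFrame,
    spec: NullModelSpec,
    scale: Scale = "per_window",
    attribute_names: Sequence[str] = ATTRIBUTES,
) -> pd.DataFrame:
    """Significance of each dimer's content against each chromosome attribute.

    The null distribution comes from the same replicate machinery as the
    pair correlations: each attribute is correlated with dimer contents
    sampled from the null model, and the empirical correlation is
    expressed in null-replicate standard deviations. Rows are dimers,
    columns attributes; a constant attribute yields NaN.
    """
    order = {c.id: i for i, c in enumerate(compositions)}
    attrs = attributes[attributes["id"].isin(order)].copy()
    attrs["_pos"] = attrs["id"].map(order)
    attrs = attrs.sort_values("_pos")
    comp_subset = [compositions[i] for i in attrs["_pos"]]

    residuals = residual_matrix(comp_subset, spec.kind, scale)
    sampled = sample_null_counts(spec, comp_subset)
    normed = normalize_sampled(sampled, comp_subset, spec.kind, scale)

    out = pd.DataFrame(index=list(DIMERS), columns=list(attribute_names), dtype=float)
    for attr in attribute_names:
        vec = attrs[attr].to_numpy(dtype=float)
        if np.all(np.isnan(vec)) or np.nanstd(vec) == 0:
            out[attr] = np.nan
            continue
        for d, dimer in enumerate(DIMERS):
            r_emp = pearson(residuals[:, d], vec)
            r_null = np.array(
                [pearson(normed[r, :, d], vec) for r in range(spec.replicates)]
            )
            out.loc[dimer, attr] = significance(
                r_emp, float(np.nanmean(r_null)), float(np.nanstd(r_null, ddof=1))
            )
    return out


@dataclass
class DimerClassification:
    """Three-way class label per dimer plus the supporting significances."""

    classes: dict[str, str]
    significances: pd.DataFrame

    def __getitem__(self, dimer: str) -> str:
        return self.classes[dimer]


def classify_dimers(
    significances: pd.DataFrame, threshold: float = SIGNIFICANCE_THRESHOLD
) -> DimerClassification:
    """Classify dimers by length-vs-genic opposition.

    Evidence for the length class: significant positive correlation with
    chromosome length, or significant anticorrelation with gene or CDS
    content. Evidence for the genic class: the reverse. Both kinds of
    evidence at once (or neither) leaves the dimer unclassified.
    """
    classes = {}
    for dimer in DIMERS:
        sig = significances.loc[dimer]
        s_len = sig.get("length_bp", np.nan)
        s_gene = sig.get("gene_content", np.nan)
        s_cds = sig.get("cds_content", np.nan)

        def _gt(v: float) -> bool:
            return bool(not np.isnan(v) and v > threshold)

        def _lt(v: float) -> bool:
            return bool(not np.isnan(v) and v < -threshold)

        length_evidence = _gt(s_len) or _lt(s_gene) or _lt(s_cds)
        genic_evidence = _lt(s_len) or _gt(s_gene) or _gt(s_cds)
        if length_evidence and genic_evidence:
            logger.warning("dimer %s has conflicting class evidence; unclassified", dimer)
            classes[dimer] = UNCLASSIFIED
        elif length_evidence:
            classes[dimer] = LENGTH_CLASS
        elif genic_evidence:
            classes[dimer] = GENIC_CLASS
        else:
            classes[dimer] = UNCLASSIFIED
    return DimerClassification(classes=classes, significances=significances)


def is_explained(record: CorrelationRecord, classification: DimerClassification) -> bool:
    """Whether a significant pair correlation follows from the classification.

    Explained iff both dimers are classified and either (same class and
    correlated) or (different classes and anticorrelated).
    """
    a, b = record.pair
    ca, cb = classification[a], classification[b]
    if ca == UNCLASSIFIED or cb == UNCLASSIFIED:
        return False
    if record.cls == "correlated":
        return ca == cb
    if record.cls == "anticorrelated":
        return ca != cb
    return False


def filter_explained_pairs(
    records: Sequence[CorrelationRecord], classification: DimerClassification
) -> list[CorrelationRecord]:
    """Significant pairs whose correlation the classification does NOT explain."""
    return [
        rec
        for rec in records
        if rec.cls in ("correlated", "anticorrelated")
        and not is_explained(rec, classification)
    ]


def classification_frame(classification: DimerClassification) -> pd.DataFrame:
    """TSV-ready report: dimer, class, supporting significances."""
    frame = classification.significances.copy()
    frame.insert(0, "dimer", frame.index)
    frame.insert(1, "class", [classification[d] for d in frame.index])
    return frame.reset_index(drop=True)
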