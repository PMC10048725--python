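"""Synthetic multi-chromosome genomes with controllable dinucleotide structure.

Chromosomes are generated by a first-order Markov chain rather than
i.i.d. bases, so that dimer content can be planted independently of base
content — exactly the kind of excess the binomial null model is meant to
detect. The baseline transition matrix T0[x, y] = p_y reproduces the
i.i.d. composition; per-chromosome perturbations add dimer excesses on
top of it:

* a static excess ``dimer_excess[XY] = eps`` shifts the stationary dimer
  probability of XY by approximately +eps on every chromosome;
* a coupling (XY, ZV, rho) draws, per chromosome, a latent pair
  (z1, z2) of standard normals with correlation exactly rho
  (z2 = rho z1 + sqrt(1 - rho^2) w) and shifts XY's dimer probability by
  delta*z1 and ZV's by delta*z2, so the two contents co-vary across
  chromosomes with the requested latent correlation.

A dimer-probability shift eps on XY is realised by adding eps / p_X to
the transition T[X, Y] and renormalizing the rest of row X
proportionally; generation fails up front if any entry leaves (0, 1).
Gap (N) runs, gene/mRNA/CDS intervals and enhancer intervals are placed
uniformly at random; CDS intervals can optionally be regenerated with a
GC-dimer-enriched chain to create annotation-explained couplings.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .counts import BASES, DIMER_INDEX
from .sequence_io import ChromosomeRecord, find_gap_spans, merge_intervals


@dataclass
class SyntheticGenomeSpec:
    """Study conditions for a synthetic genome set.

    Defaults describe the reference recovery experiment: one genome of 40
    chromosomes of 50 kb at ~40% GC, coupling amplitude 0.01 in absolute
    dimer-probability units.
    """

    genomes: int = 1
    chromosomes_per_genome: int = 40
    length: int | Sequence[int] | Callable[[np.random.Generator], int] = 50_000
    base_composition: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    dimer_excess: dict[str, float] = field(default_factory=dict)
    coupling: list[tuple[str, str, float]] = field(default_factory=list)
    coupling_amplitude: float = 0.01
    gene_density: float = 0.0
    cds_fraction: float = 0.5
    cds_gc_dimer_bias: float = 0.0
    enhancers_per_mb: float = 0.0
    gap_rate: float = 0.0
    mean_gap_length: int = 200
    chargaff_parity: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or not np.isclose(comp.sum(), 1.0):
            raise ValueError("base composition must be 4 probabilities summing to 1")
        if np.any(comp <= 0):
            raise ValueError("base composition must be strictly positive")
        for _, _, rho in self.coupling:
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"latent correlation {rho} outside [-1, 1]")


def _chromosome_length(spec: SyntheticGenomeSpec, index: int, rng: np.random.Generator) -> int:
    if callable(spec.length):
        return int(spec.length(rng))
    if isinstance(spec.length, (int, np.integer)):
        return int(spec.length)
    return int(spec.length[index % len(spec.length)])


def perturbed_transition_matrix(
    base: np.ndarray, dimer_shifts: dict[str, float]
) -> np.ndarray:
    """Row-stochastic transition matrix with planted dimer-probability shifts.

    Raises ValueError if any transition probability leaves (0, 1).
    """
    t = np.tile(base, (4, 1)).astype(float)
    for dimer, eps in dimer_shifts.items():
        if eps == 0.0:
            continue
        idx = DIMER_INDEX[dimer]
        x, y = divmod(idx, 4)
        shift = eps / base[x]
        # keep row sum 1: take the shift proportionally from the other entries
        others = [z for z in range(4) if z != y]
        other_mass = sum(base[z] for z in others)
        t[x, y] += shift
        for z in others:
            t[x, z] -= shift * base[z] / other_mass
    if np.any(t <= 0.0) or np.any(t >= 1.0):
        raise ValueError(
            "infeasible transition matrix: a planted shift pushes a probability "
            "outside (0, 1); reduce the excess amplitude"
        )
    return t


def markov_sequence(
    transition: np.ndarray, base: np.ndarray, length: int, rng: np.random.Generator
) -> str:
    """One first-order Markov chain realisation as an ACGT string."""
    if length <= 0:
        return ""
    cum_rows = [np.cumsum(transition[x])[:3].tolist() for x in range(4)]
    uniforms = rng.random(length).tolist()
    start_cum = np.cumsum(base)[:3].tolist()
    state = bisect_right(start_cum, uniforms[0])
    out = bytearray(length)
    base_bytes = [ord(b) for b in BASES]
    out[0] = base_bytes[state]
    for i in range(1, length):
        state = bisect_right(cum_rows[state], uniforms[i])
        out[i] = base_bytes[state]
    return out.decode("ascii")


def _latent_dimer_shifts(
    spec: SyntheticGenomeSpec, rng: np.random.Generator
) -> dict[str, float]:
    """Per-chromosome dimer-probability shifts from static excesses and latents."""
    shifts: dict[str, float] = dict(spec.dimer_excess)
    for d1, d2, rho in spec.coupling:
        z1 = rng.normal()
        z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * rng.normal()
        shifts[d1] = shifts.get(d1, 0.0) + spec.coupling_amplitude * z1
        shifts[d2] = shifts.get(d2, 0.0) + spec.coupling_amplitude * z2
    if spec.chargaff_parity:
        # mirror every planted shift onto the reverse complement, emulating
        # intra-strand parity of real genomes
        from .counts import reverse_complement_dimer

        mirrored = dict(shifts)
        for dimer, eps in shifts.items():
            rc = reverse_complement_dimer(dimer)
            if rc != dimer:
                mirrored[rc] = mirrored.get(rc, 0.0) + eps
        shifts = mirrored
    return shifts


def _place_intervals(
    rng: np.random.Generator, length: int, n: int, mean_width: int
) -> list[tuple[int, int]]:
    spans = []
    for _ in range(n):
        width = max(1, int(rng.exponential(mean_width)))
        width = min(width, length)
        start = int(rng.integers(0, max(1, length - width)))
        spans.append((start, start + width))
    return sorted(spans)


def _insert_gaps(sequence: str, spec: SyntheticGenomeSpec, rng: np.random.Generator) -> str:
    length = len(sequence)
    target = spec.gap_rate * length
    if target < 1:
        return sequence
    seq = bytearray(sequence, "ascii")
    placed = 0
    while placed < target:
        width = max(1, int(rng.exponential(spec.mean_gap_length)))
        start = int(rng.integers(0, max(1, length - width)))
        seq[start : start + width] = b"N" * min(width, length - start)
        placed += min(width, length - start)
    return seq.decode("ascii")


_GC_DIMERS = ("CC", "CG", "GC", "GG")


def _annotate(
    record: ChromosomeRecord,
    spec: SyntheticGenomeSpec,
    transition: np.ndarray,
    base: np.ndarray,
    rng: np.random.Generator,
) -> None:
    length = record.length_bp
    ann = record.annotations
    if spec.gene_density > 0:
        mean_gene = 2_000
        n_genes = max(1, int(spec.gene_density * length / mean_gene))
        genes = merge_intervals(_place_intervals(rng, length, n_genes, mean_gene))
        ann.gene_spans = genes
        ann.gene_strands = ["+" if rng.random() < 0.5 else "-" for _ in genes]
        seq = None
        for start, end in genes:
            width = end - start
            cds_len = max(1, int(spec.cds_fraction * width))
            cds_start = start + int(rng.integers(0, width - cds_len + 1))
            span = (cds_start, cds_start + cds_len)
            ann.cds_spans.append(span)
            ann.cds_strands.append("+")
            ann.mrna_spans.append((start, end))
            ann.mrna_strands.append("+")
            if spec.cds_gc_dimer_bias > 0:
                if seq is None:
                    seq = bytearray(record.sequence, "ascii")
                shifts = {d: spec.cds_gc_dimer_bias for d in _GC_DIMERS}
                t_cds = perturbed_transition_matrix(base, shifts)
                seq[span[0] : span[1]] = markov_sequence(
                    t_cds, base, cds_len, rng
                ).encode("ascii")
        if seq is not None:
            record.sequence = seq.decode("ascii")
    if spec.enhancers_per_mb > 0:
        n_enh = rng.poisson(spec.enhancers_per_mb * length / 1e6)
        ann.enhancer_spans = _place_intervals(rng, length, int(n_enh), 300)


def generate_genomes(spec: SyntheticGenomeSpec) -> list[ChromosomeRecord]:
    """Generate all chromosomes of all genomes, fully reproducible from the seed."""
    base = np.asarray(spec.base_composition, dtype=float)
    # fail fast on clearly infeasible static excesses
    perturbed_transition_matrix(base, dict(spec.dimer_excess))
    records = []
    for g in range(spec.genomes):
        for c in range(spec.chromosomes_per_genome):
            rng = np.random.default_rng(np.random.SeedSequence([spec.seed, g, c]))
            length = _chromosome_length(spec, c, rng)
            shifts = _latent_dimer_shifts(spec, rng)
            transition = perturbed_transition_matrix(base, shifts)
            sequence = markov_sequence(transition, base, length, rng)
            record = ChromosomeRecord(
                id=f"g{g}_chr{c}",
                species=f"synthetic_genome_{g}",
                sequence=sequence,
            )
            _annotate(record, spec, transition, base, rng)
            if spec.gap_rate > 0:
                record.sequence = _insert_gaps(record.sequence, spec, rng)
            record.gap_spans = find_gap_spans(record.sequence)
            records.append(record)
    return records


# --- property-model fixtures -------------------------------------------------

def generate_property_fixture(k: int, seed: int = 0):
    """``k`` toy property models with controlled structure.

    Model 1 is constant (all ones: every replacement delta is exactly 0),
    model 2 an AA indicator (delta reduces to c_AA (1 - p_AA)), and the
    remainder are uniform random in [-1, 1].
    """
    from .property_engine import PropertyModel

    if k < 1:
        raise ValueError("need k >= 1 models")
    rng = np.random.default_rng(seed)
    models = [PropertyModel(id=1, name="constant", values=np.ones(16))]
    if k >= 2:
        indicator = np.zeros(16)
        indicator[DIMER_INDEX["AA"]] = 1.0
        models.append(PropertyModel(id=2, name="AA_indicator", values=indicator))
    for i in range(3, k + 1):
        models.append(
            PropertyModel(id=i, name=f"random_{i}", values=rng.uniform(-1, 1, 16))
        )
    return models[:k]


# --- file export --------------------------------------------------------------

def write_fasta(records: Sequence[ChromosomeRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id} {rec.species}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_genbank(records: Sequence[ChromosomeRecord], path: str | Path) -> None:
    """Write records with gene/mRNA/CDS features as a GenBank flat file."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    from Bio import SeqIO

    out = []
    for rec in records:
        sr = SeqRecord(Seq(rec.sequence), id=rec.id, name=rec.id[:16], description="")
        sr.annotations["molecule_type"] = "DNA"
        sr.annotations["organism"] = rec.species
        ann = rec.annotations
        for spans, strands, ftype in (
            (ann.gene_spans, ann.gene_strands, "gene"),
            (ann.mrna_spans, ann.mrna_strands, "mRNA"),
            (ann.cds_spans, ann.cds_strands, "CDS"),
        ):
            for i, (start, end) in enumerate(spans):
                strand = -1 if (i < len(strands) and strands[i] == "-") else 1
                sr.features.append(
                    SeqFeature(SimpleLocation(start, end, strand), type=ftype)
                )
        out.append(sr)
    SeqIO.write(out, str(path), "genbank")


def write_enhancer_bed(records: Sequence[ChromosomeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            for start, end in rec.annotations.enhancer_spans:
                fh.write(f"{rec.id}\t{start}\t{end}\n")
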