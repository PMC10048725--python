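"""End-to-end orchestration and command-line interface.

Stages communicate through TSV files with documented headers, so each
stage is independently runnable and hand-entered published tables can be
injected mid-pipeline (e.g. ``dinucouple couple`` on transcribed
reference tables). ``run_full_analysis`` chains everything and writes a
manifest recording the configuration, seed and package version.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import click
import pandas as pd

from . import __version__
from .annotation_contents import (
    attribute_dimer_correlations,
    attribute_table,
    classification_frame,
    classify_dimers,
    filter_explained_pairs,
)
from .correlation_stats import correlation_records, records_frame
from .counts import compose, composition_frame, compositions_from_frame
from .coupling_detection import (
    coupled_frame,
    count_by_type,
    find_moderating_pairs,
    read_pair_table,
    read_sign_table,
)
from .null_models import NullModelSpec, normalized_frame
from .property_engine import influences_frame, large_influence_table, load_property_table, property_influences
from .sequence_io import DEFAULT_MIN_LENGTH, filter_short_records, read_bed, read_fasta, read_genbank
from .synthetic_data import (
    SyntheticGenomeSpec,
    generate_genomes,
    generate_property_fixture,
    write_enhancer_bed,
    write_fasta,
    write_genbank,
)
from .property_engine import write_property_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    fasta: list[str] = field(default_factory=list)
    genbank: list[str] = field(default_factory=list)
    enhancer_bed: str | None = None
    property_table: str | None = None
    model_kind: str = "binomial"
    replicates: int = 10
    seed: int = 0
    scale: str = "per_window"
    significance_threshold: float = 1.0
    relative_change_threshold: float = 0.10
    min_length: int = DEFAULT_MIN_LENGTH
    outdir: str = "dinucouple_out"

    def validate(self) -> None:
        if self.significance_threshold <= 0 or self.relative_change_threshold <= 0:
            raise ValueError("thresholds must be positive")
        for path in [*self.fasta, *self.genbank, self.enhancer_bed, self.property_table]:
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)
        if not self.fasta and not self.genbank:
            raise ValueError("no sequence inputs configured")


def load_config(path: str | Path) -> RunConfig:
    """Parse a flat key=value config file (``#`` comments, blank lines ok)."""
    values: dict[str, object] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in ("fasta", "genbank"):
                values.setdefault(key, []).append(value)
            elif key in ("replicates", "seed", "min_length"):
                values[key] = int(value)
            elif key in ("significance_threshold", "relative_change_threshold"):
                values[key] = float(value)
            else:
                values[key] = value
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return RunConfig(**values)  # type: ignore[arg-type]


def _load_records(config: RunConfig):
    records = []
    for path in config.fasta:
        records.extend(read_fasta(path))
    for path in config.genbank:
        records.extend(read_genbank(path))
    return filter_short_records(records, config.min_length)


def _write(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_full_analysis(config: RunConfig) -> dict[str, Path]:
    """Run every stage in order and write the report bundle.

    Outputs (TSV unless noted): composition, normalized contents, pair
    correlations, attribute significances + dimer classification,
    unexplained pairs, property influences + large-influence table,
    coupled (moderating) pairs, and a JSON run manifest. Any stage
    failure aborts with the stage name; partially written outputs of the
    failed run are removed.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    stage = "setup"

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        _write(frame, path)
        written[name] = path

    try:
        stage = "sequence_io"
        t0 = time.perf_counter()
        records = _load_records(config)
        if len(records) < 3:
            raise ValueError("fewer than 3 chromosomes after length filtering")
        logger.info("loaded %d chromosomes [%.1fs]", len(records), time.perf_counter() - t0)

        stage = "counts"
        compositions = [compose(rec) for rec in records]
        emit("composition", composition_frame(compositions))

        stage = "null_models"
        spec = NullModelSpec(kind=config.model_kind, replicates=config.replicates, seed=config.seed)
        emit("normalized_contents", normalized_frame(compositions, spec.kind))

        stage = "correlation_stats"
        t0 = time.perf_counter()
        pair_records = correlation_records(compositions, spec, config.scale)
        emit("pair_correlations", records_frame(pair_records))
        logger.info("pair correlations done [%.1fs]", time.perf_counter() - t0)

        stage = "annotation_contents"
        enhancer_counts = None
        if config.enhancer_bed:
            bed = read_bed(config.enhancer_bed)
            enhancer_counts = {chrom: len(spans) for chrom, spans in bed.items()}
        attrs = attribute_table(records, enhancer_counts)
        attr_sig = attribute_dimer_correlations(compositions, attrs, spec, config.scale)
        classification = classify_dimers(attr_sig, config.significance_threshold)
        emit("attribute_table", attrs)
        emit("dimer_classification", classification_frame(classification))
        unexplained = filter_explained_pairs(pair_records, classification)
        emit("unexplained_pairs", records_frame(unexplained))

        stage = "property_engine"
        if config.property_table:
            models = load_property_table(config.property_table)
            influences = property_influences(compositions, models, spec.kind)
            emit("property_influences", influences_frame(influences))
            large = large_influence_table(influences)
            emit("large_influences", large)

            stage = "coupling_detection"
            coupled = find_moderating_pairs(
                records_frame(unexplained), large, config.significance_threshold
            )
            emit("coupled_pairs", coupled_frame(coupled))
            logger.info("moderation counts: %s", dict(count_by_type(coupled)))

        stage = "manifest"
        manifest = {
            "version": __version__,
            "config": dataclasses.asdict(config),
            "n_chromosomes": len(records),
            "outputs": {k: str(v) for k, v in written.items()},
        }
        path = outdir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written["manifest"] = path
    except Exception as exc:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    return written


# --- CLI ----------------------------------------------------------------------

def _configure_logging(verbose: bool) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
    )


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Log stage progress to stderr.")
def cli(verbose: bool) -> None:
    """Coupled dinucleotide content analysis."""
    _configure_logging(verbose)


def _config_from_options(config_path: str | None, **overrides) -> RunConfig:
    config = load_config(config_path) if config_path else RunConfig()
    for key, value in overrides.items():
        if value in (None, (), []):
            continue
        setattr(config, key, list(value) if isinstance(value, tuple) else value)
    return config


_common = [
    click.option("--config", "config_path", type=click.Path(exists=True), default=None,
                 help="Flat key=value config file; flags override it."),
    click.option("--fasta", multiple=True, type=click.Path(exists=True)),
    click.option("--genbank", multiple=True, type=click.Path(exists=True)),
    click.option("--model-kind", type=click.Choice(["binomial", "chargaff"]), default=None),
    click.option("--replicates", type=int, default=None),
    click.option("--seed", type=int, default=None),
    click.option("--scale", type=click.Choice(["per_window", "raw", "zscore"]), default=None),
    click.option("--min-length", type=int, default=None),
    click.option("--outdir", type=click.Path(), default=None),
]


def _with_common(func):
    for option in reversed(_common):
        func = option(func)
    return func


@cli.command()
@_with_common
def count(config_path, **overrides):
    """Count nucleotides and overlapping dimers per chromosome."""
    config = _config_from_options(config_path, **overrides)
    records = _load_records(config)
    frame = composition_frame(compose(rec) for rec in records)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write(frame, outdir / "composition.tsv")
    click.echo(f"wrote {outdir / 'composition.tsv'} ({len(frame)} chromosomes)")


@cli.command()
@click.option("--composition", type=click.Path(exists=True), required=True,
              help="composition.tsv from the count stage")
@click.option("--model-kind", type=click.Choice(["binomial", "chargaff"]), default="binomial")
@click.option("--out", type=click.Path(), required=True)
def normalize(composition, model_kind, out):
    """Normalize dimer counts against a null model."""
    comps = compositions_from_frame(pd.read_csv(composition, sep="\t"))
    _write(normalized_frame(comps, model_kind), Path(out))
    click.echo(f"wrote {out}")


@cli.command()
@click.option("--composition", type=click.Path(exists=True), required=True)
@click.option("--model-kind", type=click.Choice(["binomial", "chargaff"]), default="binomial")
@click.option("--replicates", type=int, default=10)
@click.option("--seed", type=int, default=0)
@click.option("--scale", type=click.Choice(["per_window", "raw", "zscore"]), default="per_window")
@click.option("--out", type=click.Path(), required=True)
def correlate(composition, model_kind, replicates, seed, scale, out):
    """Pairwise dimer correlations with Monte-Carlo significance."""
    comps = compositions_from_frame(pd.read_csv(composition, sep="\t"))
    spec = NullModelSpec(kind=model_kind, replicates=replicates, seed=seed)
    _write(records_frame(correlation_records(comps, spec, scale)), Path(out))
    click.echo(f"wrote {out}")


@cli.command()
@click.option("--pairs", type=click.Path(exists=True), required=True,
              help="pair-correlation TSV (dimer1, dimer2, significance)")
@click.option("--signs", type=click.Path(exists=True), required=True,
              help="property sign TSV (property_id, property_name, positive, negative)")
@click.option("--out", type=click.Path(), required=True)
def couple(pairs, signs, out):
    """Detect moderating dimer pairs from pair and property-sign tables."""
    coupled = find_moderating_pairs(read_pair_table(pairs), read_sign_table(signs))
    _write(coupled_frame(coupled), Path(out))
    counts = count_by_type(coupled)
    click.echo(
        f"wrote {out}: {counts['correlated_opposite']} correlated_opposite, "
        f"{counts['anticorrelated_same']} anticorrelated_same"
    )


@cli.command()
@click.option("--chromosomes", type=int, default=40)
@click.option("--length", type=int, default=50_000)
@click.option("--seed", type=int, default=0)
@click.option("--coupling", type=(str, str, float), multiple=True,
              help="dimer1 dimer2 rho, e.g. --coupling AA CG -0.8")
@click.option("--gene-density", type=float, default=0.0)
@click.option("--enhancers-per-mb", type=float, default=0.0)
@click.option("--gap-rate", type=float, default=0.0)
@click.option("--property-models", type=int, default=0,
              help="also write a toy property-model table with this many models")
@click.option("--outdir", type=click.Path(), required=True)
def simulate(chromosomes, length, seed, coupling, gene_density, enhancers_per_mb,
             gap_rate, property_models, outdir):
    """Generate a synthetic genome fixture (FASTA + GenBank + BED)."""
    spec = SyntheticGenomeSpec(
        chromosomes_per_genome=chromosomes,
        length=length,
        seed=seed,
        coupling=[tuple(c) for c in coupling],
        gene_density=gene_density,
        enhancers_per_mb=enhancers_per_mb,
        gap_rate=gap_rate,
    )
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    records = generate_genomes(spec)
    write_fasta(records, out / "genome.fasta")
    write_genbank(records, out / "genome.gb")
    write_enhancer_bed(records, out / "enhancers.bed")
    (out / "spec.txt").write_text(
        "".join(f"{f.name}={getattr(spec, f.name)}\n" for f in dataclasses.fields(spec))
    )
    if property_models:
        write_property_table(
            generate_property_fixture(property_models, seed), out / "properties.tsv"
        )
    click.echo(f"wrote {len(records)} chromosomes to {out}")


@cli.command()
@click.option("--composition", type=click.Path(exists=True), required=True)
@click.option("--property-table", type=click.Path(exists=True), required=True)
@click.option("--model-kind", type=click.Choice(["binomial", "chargaff"]), default="binomial")
@click.option("--out", type=click.Path(), required=True)
def properties(composition, property_table, model_kind, out):
    """Replacement-model influence of each dimer on each DNA property."""
    comps = compositions_from_frame(pd.read_csv(composition, sep="\t"))
    models = load_property_table(property_table)
    influences = property_influences(comps, models, model_kind)
    _write(influences_frame(influences), Path(out))
    large = large_influence_table(influences)
    large_path = Path(out).with_name(Path(out).stem + "_large.tsv")
    _write(large, large_path)
    click.echo(f"wrote {out} and {large_path}")


@cli.command()
@_with_common
@click.option("--enhancer-bed", type=click.Path(exists=True), default=None)
@click.option("--property-table", type=click.Path(exists=True), default=None)
def attributes(config_path, **overrides):
    """Per-chromosome attributes, dimer classification, unexplained pairs."""
    overrides.pop("property_table", None)
    config = _config_from_options(config_path, **overrides)
    records = _load_records(config)
    compositions = [compose(rec) for rec in records]
    spec = NullModelSpec(kind=config.model_kind, replicates=config.replicates, seed=config.seed)
    enhancer_counts = None
    if config.enhancer_bed:
        enhancer_counts = {c: len(s) for c, s in read_bed(config.enhancer_bed).items()}
    attrs = attribute_table(records, enhancer_counts)
    sig = attribute_dimer_correlations(compositions, attrs, spec, config.scale)
    classification = classify_dimers(sig, config.significance_threshold)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write(attrs, outdir / "attribute_table.tsv")
    _write(classification_frame(classification), outdir / "dimer_classification.tsv")
    click.echo(f"wrote attribute tables to {outdir}")


@cli.command("run-all")
@_with_common
@click.option("--enhancer-bed", type=click.Path(exists=True), default=None)
@click.option("--property-table", type=click.Path(exists=True), default=None)
def run_all(config_path, **overrides):
    """Run the full pipeline and write the report bundle."""
    config = _config_from_options(config_path, **overrides)
    written = run_full_analysis(config)
    for name, path in written.items():
        click.echo(f"{name}: {path}")


def main() -> None:  # console-script entry point
    cli()


if __name__ == "__main__":
    main()
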