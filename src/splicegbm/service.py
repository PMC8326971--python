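"""Coordinate-level prediction front-end and the command-line interface.

For a genomic coordinate the service enumerates the three non-reference
alleles, maps each to every coding transcript whose Int-50..Int-3 acceptor
window covers the position, featurizes and scores it, and calls
splicing-affecting when the pathogenic probability is at least 0.5.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass
from pathlib import Path

import click
import pandas as pd

from . import features as _feat
from . import model as _model
from .dataset import balance_sample, build_dataset, maf_filter
from .genomic_io import (
    Genome,
    MissingContigError,
    RefMismatchError,
    TranscriptModel,
    VariantRecord,
    acceptor_windows,
    map_variant,
    read_annotation,
    read_variants,
)

log = logging.getLogger(__name__)

OUTPUT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "transcript_id", "int_position",
    "probability", "call",
]
OUTPUT_SCHEMA_VERSION = "splicegbm-predictions-v1"


@dataclass(frozen=True)
class PredictionRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    transcript_id: str
    int_position: int
    probability: float
    call: str


def _predict_variant(
    v: VariantRecord,
    models,
    genome: Genome,
    clf: _model.TrainedClassifier,
    config: _feat.FeatureConfig,
    contexts=None,
) -> list[PredictionRecord]:
    out = []
    for iv in map_variant(v, models, genome, contexts=contexts):
        if not iv.in_model_scope:
            continue
        ctxs = (contexts or {}).get(iv.transcript_id)
        if ctxs is None:
            tm = next(m for m in models if m.transcript_id == iv.transcript_id)
            ctxs = acceptor_windows(tm, genome)
        ctx = next(c for c in ctxs if c.covers(v.chrom, v.pos))
        fv = _feat.featurize(ctx, iv, config)
        p = _model.predict_proba(clf, fv)
        out.append(
            PredictionRecord(
                chrom=v.chrom, pos=v.pos, ref=v.ref_base, alt=v.alt_base,
                transcript_id=iv.transcript_id, int_position=iv.int_position,
                probability=p, call=clf.classify(p),
            )
        )
    return out


def predict_at(
    chrom: str,
    pos: int,
    genome: Genome,
    models: list[TranscriptModel],
    clf: _model.TrainedClassifier,
    config: _feat.FeatureConfig | None = None,
) -> list[PredictionRecord]:
    """Score the three possible SNVs at a coordinate on every covering
    transcript; empty list when no acceptor window covers the position."""
    if not models:
        raise ValueError("no transcripts loaded")
    config = config or _feat.FeatureConfig()
    ref = genome.fetch(chrom, pos, pos, "+")
    contexts = {m.transcript_id: acceptor_windows(m, genome) for m in models}
    out: list[PredictionRecord] = []
    for alt in "ACGT":
        if alt == ref:
            continue
        v = VariantRecord(chrom=chrom, pos=pos, ref_base=ref, alt_base=alt)
        out.extend(_predict_variant(v, models, genome, clf, config, contexts))
    if not out:
        log.info(
            "%s:%d is not inside any Int-50..Int-3 acceptor window", chrom, pos
        )
    return out


def batch_predict(
    variants_path: str | Path,
    genome: Genome,
    models: list[TranscriptModel],
    clf: _model.TrainedClassifier,
    config: _feat.FeatureConfig | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Predict every variant of a VCF/TSV; returns (report, skipped).

    ``skipped`` lists unmappable records with a reason (reference mismatch,
    off-contig, outside any window, out of model scope).
    """
    config = config or _feat.FeatureConfig()
    contexts = {m.transcript_id: acceptor_windows(m, genome) for m in models}
    rows: list[PredictionRecord] = []
    skipped: list[dict] = []
    for v in read_variants(variants_path):
        try:
            hits = _predict_variant(v, models, genome, clf, config, contexts)
        except (RefMismatchError, MissingContigError, ValueError) as exc:
            skipped.append({"variant": v.key, "reason": str(exc)})
            continue
        if not hits:
            skipped.append(
                {"variant": v.key, "reason": "no Int-50..Int-3 window covers it"}
            )
        rows.extend(hits)
    df = pd.DataFrame([asdict(r) for r in rows], columns=OUTPUT_COLUMNS)
    return df, skipped


# ---------------------------------------------------------------------------
# CLI


@click.group()
def main():
    """Splicing-effect prediction for intronic SNVs near 3' splice sites."""
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")


@main.command()
@click.option("--out", "out_dir", type=click.Path(), required=True)
@click.option("--seed", type=int, required=True)
@click.option("--genes", type=int, default=40, show_default=True)
@click.option("--pathogenic", "n_pathogenic", type=int, default=400, show_default=True)
@click.option("--common", "n_common", type=int, default=400, show_default=True)
def simulate(out_dir, seed, genes, n_pathogenic, n_common):
    """Generate a synthetic genome, annotation and labelled variants."""
    from .synthetic_fixtures import SimulationConfig, simulate_all

    cfg = SimulationConfig(
        seed=seed, n_genes=genes, n_pathogenic=n_pathogenic, n_common=n_common
    )
    paths = simulate_all(cfg, out_dir)
    for name, p in paths.items():
        click.echo(f"{name}\t{p}")


@main.command()
@click.option("--genome", "genome_path", type=click.Path(exists=True), required=True)
@click.option("--gtf", type=click.Path(exists=True), required=True)
@click.option("--variants", type=click.Path(exists=True), required=True)
@click.option("--out-model", type=click.Path(), required=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--tune-budget", type=int, default=0, show_default=True,
              help="randomized-search trials; 0 trains with defaults")
@click.option("--maf-hi", type=float, default=0.50, show_default=True)
def train(genome_path, gtf, variants, out_model, seed, tune_budget, maf_hi):
    """Build a balanced dataset from labelled variants and train a model."""
    genome = Genome(genome_path)
    models = read_annotation(gtf)
    records = read_variants(variants)
    records = maf_filter(records, hi=maf_hi)
    pathogenic = [r for r in records if r.label == "pathogenic"]
    common = [r for r in records if r.label == "common"]
    balanced = balance_sample(pathogenic, common, seed=seed)
    ds = build_dataset(balanced, models, genome)
    cfg = (
        _model.tune_hyperparameters(ds, budget=tune_budget, seed=seed)
        if tune_budget > 0
        else _model.ModelConfig()
    )
    clf = _model.fit(ds, cfg, seed=seed)
    clf.save(out_model)
    click.echo(f"trained on {len(ds)} rows -> {out_model}")


def _load_stack(genome_path, gtf, model_dir):
    return (
        Genome(genome_path),
        read_annotation(gtf),
        _model.TrainedClassifier.load(model_dir),
    )


def _emit(df: pd.DataFrame, skipped: list[dict], out, fmt: str):
    if not df.empty:
        df = df.assign(probability=df["probability"].round(6))
    if fmt == "json":
        payload = {
            "schema": OUTPUT_SCHEMA_VERSION,
            "predictions": df.to_dict(orient="records"),
            "skipped": skipped,
        }
        text = json.dumps(payload, indent=1)
    else:
        text = df.to_csv(sep="\t", index=False)
        if skipped:
            text += "".join(
                f"# skipped\t{s['variant']}\t{s['reason']}\n" for s in skipped
            )
    if out == "-":
        click.echo(text, nl=False)
    else:
        Path(out).write_text(text)


@main.command()
@click.option("--genome", "genome_path", type=click.Path(exists=True), required=True)
@click.option("--gtf", type=click.Path(exists=True), required=True)
@click.option("--model", "model_dir", type=click.Path(exists=True), required=True)
@click.option("--chrom", required=True)
@click.option("--pos", type=int, required=True)
@click.option("--out", default="-", show_default=True)
@click.option("--format", "fmt", type=click.Choice(["tsv", "json"]), default="tsv")
def predict(genome_path, gtf, model_dir, chrom, pos, out, fmt):
    """Score the three possible SNVs at one genomic coordinate."""
    genome, models, clf = _load_stack(genome_path, gtf, model_dir)
    try:
        recs = predict_at(chrom, pos, genome, models, clf)
    except (MissingContigError, ValueError) as exc:
        raise click.UsageError(str(exc)) from exc
    df = pd.DataFrame([asdict(r) for r in recs], columns=OUTPUT_COLUMNS)
    if df.empty:
        click.echo(
            f"# {chrom}:{pos} is not inside any Int-50..Int-3 acceptor window",
            err=True,
        )
    _emit(df, [], out, fmt)


@main.command("batch-predict")
@click.option("--genome", "genome_path", type=click.Path(exists=True), required=True)
@click.option("--gtf", type=click.Path(exists=True), required=True)
@click.option("--model", "model_dir", type=click.Path(exists=True), required=True)
@click.option("--vcf", "variants_path", type=click.Path(exists=True), required=True)
@click.option("--out", default="-", show_default=True)
@click.option("--format", "fmt", type=click.Choice(["tsv", "json"]), default="tsv")
def batch_predict_cmd(genome_path, gtf, model_dir, variants_path, out, fmt):
    """Score every variant of a VCF or TSV file."""
    genome, models, clf = _load_stack(genome_path, gtf, model_dir)
    df, skipped = batch_predict(variants_path, genome, models, clf)
    _emit(df, skipped, out, fmt)


if __name__ == "__main__":
    sys.exit(main())
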