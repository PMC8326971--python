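"""Self-contained synthetic genome + annotation + labelled variants.

Every internal exon's upstream intron is built with the canonical acceptor
architecture: a GT donor at the intron start, one planted branch-point
heptamer (the bundled matrix's consensus) with its branch A in Int-35..Int-20,
a pyrimidine-rich tract over Int-25..Int-3, a pyrimidine at Int-3 and the
terminal AG. All other AG dinucleotides inside Int-50..Int-3 are scrubbed so
that cryptic-acceptor creation is fully controlled by the planted variants.

Pathogenic variants draw from four effect classes (new upstream AG, purine
substitution in the PPT, branch-A destruction, Int-3 pyrimidine→purine);
common variants are deep substitutions or pyrimidine↔pyrimidine swaps that
avoid every planted element, with MAFs uniform on [0.01, 0.50). MAFs exist
only to exercise frequency filtering and carry no biology.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from . import features as _feat
from .genomic_io import (
    AcceptorContext,
    Genome,
    TranscriptModel,
    VariantRecord,
    WINDOW_LEN,
    acceptor_windows,
    read_annotation,
    revcomp,
    write_variants_tsv,
)

BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    ``effect_mix`` gives the fractions of the four pathogenic effect classes
    (must sum to 1); ``common_deep_fraction`` splits commons between
    deep-position substitutions and PPT pyrimidine swaps. The seed is
    mandatory: identical configs reproduce byte-identical outputs.
    """

    seed: int
    n_genes: int = 40
    exons_per_gene: int = 5
    exon_length: tuple[int, int] = (90, 180)
    intron_length: tuple[int, int] = (80, 220)
    minus_strand_fraction: float = 0.5
    n_pathogenic: int = 400
    n_common: int = 400
    effect_mix: dict[str, float] = field(
        default_factory=lambda: {
            "ag_gain": 0.35,
            "ppt_disruption": 0.25,
            "bps_disruption": 0.20,
            "int3_substitution": 0.20,
        }
    )
    common_deep_fraction: float = 0.5
    maf_range: tuple[float, float] = (0.01, 0.50)
    pad: int = 100

    def __post_init__(self):
        if abs(sum(self.effect_mix.values()) - 1.0) > 1e-9:
            raise ValueError("effect_mix fractions must sum to 1")
        if self.intron_length[0] < 60:
            raise ValueError("introns must be at least 60 nt")
        if self.exons_per_gene < 3:
            raise ValueError("need >=3 exons per gene for internal exons")


def _rand_seq(rng: np.random.Generator, n: int, p=(0.27, 0.23, 0.23, 0.27)) -> str:
    return "".join(rng.choice(list(BASES), size=n, p=p))


def _scrub_ag(window: list[str], protected: set[int]) -> None:
    """Remove AG dinucleotides fully inside Int-50..Int-3 (G -> C)."""
    for i in range(0, WINDOW_LEN - 3):
        if window[i] == "A" and window[i + 1] == "G" and (i + 1) not in protected:
            window[i + 1] = "C"


def _build_acceptor_region(
    rng: np.random.Generator, bps_consensus: str
) -> tuple[str, int]:
    """The last 50 intronic bases (sense) and the planted branch-A Int-k."""
    w = list(_rand_seq(rng, WINDOW_LEN, p=(0.20, 0.20, 0.15, 0.45)))
    # polypyrimidine tract Int-25..Int-3
    for i in range(WINDOW_LEN - 25, WINDOW_LEN - 2):
        w[i] = rng.choice(list(BASES), p=(0.08, 0.40, 0.07, 0.45))
    # branch-point heptamer centred on the branch A at Int-k
    k = int(rng.integers(20, 36))
    center = WINDOW_LEN - k
    hept_span = range(center - 3, center + 4)
    for j, i in enumerate(hept_span):
        w[i] = bps_consensus[j]
    # Int-3 pyrimidine, terminal AG
    w[WINDOW_LEN - 3] = "C" if rng.random() < 0.75 else "T"
    w[WINDOW_LEN - 2] = "A"
    w[WINDOW_LEN - 1] = "G"
    _scrub_ag(w, set(hept_span))
    # keep the tract convincingly pyrimidine-rich despite the planted purines
    tract = range(WINDOW_LEN - 25, WINDOW_LEN - 2)
    while sum(w[i] in "CT" for i in tract) < 17:
        purines = [i for i in tract if w[i] in "AG" and i not in hept_span]
        if not purines:
            break
        w[int(rng.choice(purines))] = rng.choice(["C", "T"])
    return "".join(w), k


@dataclass
class _Gene:
    gene_id: str
    chrom: str
    strand: str
    sense_seq: str
    start0: int  # 0-based contig offset of the gene block
    exons_sense: list[tuple[int, int]]  # 0-based inclusive, sense coords
    branch_k: dict[int, int]  # intron index (1-based) -> planted branch Int-k

    def genomic_exons(self) -> list[tuple[int, int]]:
        L = len(self.sense_seq)
        out = []
        for js, je in self.exons_sense:
            if self.strand == "+":
                out.append((self.start0 + js + 1, self.start0 + je + 1))
            else:
                out.append((self.start0 + L - je, self.start0 + L - js))
        return sorted(out)


def _build_gene(cfg: SimulationConfig, rng: np.random.Generator, idx: int) -> _Gene:
    bps_consensus = _feat.default_bps_matrix().consensus()
    strand = "-" if rng.random() < cfg.minus_strand_fraction else "+"
    parts: list[str] = []
    exons: list[tuple[int, int]] = []
    branch_k: dict[int, int] = {}
    pos = 0
    for e in range(cfg.exons_per_gene):
        elen = int(rng.integers(*cfg.exon_length, endpoint=True))
        exon = list(_rand_seq(rng, elen))
        # G-biased Ex+1 (acceptor consensus) for every non-first exon
        if e > 0:
            exon[0] = rng.choice(list(BASES), p=(0.25, 0.15, 0.50, 0.10))
        parts.append("".join(exon))
        exons.append((pos, pos + elen - 1))
        pos += elen
        if e < cfg.exons_per_gene - 1:
            ilen = int(rng.integers(*cfg.intron_length, endpoint=True))
            acceptor, k = _build_acceptor_region(rng, bps_consensus)
            body = _rand_seq(rng, ilen - 2 - WINDOW_LEN)
            parts.append("GT" + body + acceptor)
            branch_k[e + 1] = k
            pos += ilen
    sense = "".join(parts)
    return _Gene(
        gene_id=f"G{idx + 1}",
        chrom=f"chrS{idx + 1}",
        strand=strand,
        sense_seq=sense,
        start0=cfg.pad,
        exons_sense=exons,
        branch_k=branch_k,
    )


def simulate_genome(cfg: SimulationConfig, out_dir: str | Path) -> tuple[Path, Path]:
    """Write genome.fa and annotation.gtf for the configured cohort.

    One protein-coding single-transcript gene per contig; deterministic given
    ``cfg.seed`` (byte-identical re-runs).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    genes = [_build_gene(cfg, rng, i) for i in range(cfg.n_genes)]

    fasta = out / "genome.fa"
    with open(fasta, "w") as fh:
        for g in genes:
            block = g.sense_seq if g.strand == "+" else revcomp(g.sense_seq)
            pad_l = _rand_seq(rng, cfg.pad)
            pad_r = _rand_seq(rng, cfg.pad)
            fh.write(f">{g.chrom}\n")
            fh.write(textwrap.fill(pad_l + block + pad_r, 60) + "\n")
    for stale in (fasta.with_suffix(".fa.fai"), Path(str(fasta) + ".fai")):
        stale.unlink(missing_ok=True)

    gtf = out / "annotation.gtf"
    with open(gtf, "w") as fh:
        for g in genes:
            tid = f"{g.gene_id}T1"
            gex = g.genomic_exons()
            gs, ge = gex[0][0], gex[-1][1]
            attrs = (
                f'gene_id "{g.gene_id}"; transcript_id "{tid}"; '
                f'transcript_biotype "protein_coding";'
            )
            fh.write(
                f"{g.chrom}\tsynth\ttranscript\t{gs}\t{ge}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in gex:
                fh.write(
                    f"{g.chrom}\tsynth\texon\t{s}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )
                fh.write(
                    f"{g.chrom}\tsynth\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t{attrs}\n"
                )
    return fasta, gtf


def _class_counts(cfg: SimulationConfig) -> dict[str, int]:
    counts = {
        name: int(round(frac * cfg.n_pathogenic))
        for name, frac in cfg.effect_mix.items()
    }
    names = list(counts)
    i = 0
    while sum(counts.values()) != cfg.n_pathogenic:
        counts[names[i % len(names)]] += 1 if sum(counts.values()) < cfg.n_pathogenic else -1
        i += 1
    return counts


def _to_genomic(ctx: AcceptorContext, k: int, sense_ref: str, sense_alt: str):
    pos = ctx.genomic_pos_of(k)
    if ctx.strand == "-":
        return pos, revcomp(sense_ref), revcomp(sense_alt)
    return pos, sense_ref, sense_alt


def _creates_or_destroys_ag(window: str, idx: int, alt: str) -> bool:
    mutated = window[:idx] + alt + window[idx + 1 :]
    return _feat._ag_positions(window) != _feat._ag_positions(mutated)


def plant_variants(
    cfg: SimulationConfig,
    genome: Genome,
    models: list[TranscriptModel],
) -> list[VariantRecord]:
    """Labelled SNVs inside Int-50..Int-3 windows of the simulated cohort.

    Raises when the requested counts exceed the positions the cohort offers.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    contexts: list[AcceptorContext] = []
    for tm in models:
        contexts.extend(acceptor_windows(tm, genome))
    if not contexts:
        raise ValueError("no acceptor windows in the simulated annotation")

    used: set[tuple[str, int]] = set()
    records: list[VariantRecord] = []
    bps_span: dict[int, set[int]] = {}
    for ci, ctx in enumerate(contexts):
        bp = _feat.predict_bps(ctx.window_seq)
        center = WINDOW_LEN - (bp.position or 30)
        bps_span[ci] = set(range(center - 3, center + 4))

    def take(ctx: AcceptorContext, k: int, alt_sense: str, label: str, maf=None):
        ref_sense = ctx.base_at(k)
        pos, gref, galt = _to_genomic(ctx, k, ref_sense, alt_sense)
        if (ctx.chrom, pos) in used:
            return False
        used.add((ctx.chrom, pos))
        records.append(
            VariantRecord(
                chrom=ctx.chrom, pos=pos, ref_base=gref, alt_base=galt,
                maf=maf, label=label,
            )
        )
        return True

    def draw_maf() -> float:
        lo, hi = cfg.maf_range
        return float(lo + rng.random() * (hi - lo) * 0.999)

    counts = _class_counts(cfg)
    order = rng.permutation(len(contexts))

    def windows_cycle():
        while True:
            for i in order:
                yield i, contexts[i]

    cyc = windows_cycle()
    budget = {name: n for name, n in counts.items()}
    stall = 0
    max_stall = 50 * max(1, len(contexts))  # whole-cohort sweeps with no luck
    while any(v > 0 for v in budget.values()) and stall < max_stall:
        ci, ctx = next(cyc)
        w = ctx.window_seq
        pending = [n for n, v in budget.items() if v > 0]
        cls = pending[int(rng.integers(len(pending)))]
        ok = False
        if cls == "ag_gain":
            cands = []
            for i in range(0, WINDOW_LEN - 3):
                if w[i] == "A" and w[i + 1] != "G" and (i + 1) not in bps_span[ci]:
                    cands.append(i + 1)  # mutate the following base to G
            if cands:
                idx = int(rng.choice(cands))
                ok = take(ctx, WINDOW_LEN - idx, "G", "pathogenic")
        elif cls == "ppt_disruption":
            cands = [
                i
                for i in range(WINDOW_LEN - 25, WINDOW_LEN - 3)
                if w[i] in "CT" and i not in bps_span[ci]
            ]
            rng.shuffle(cands)
            for idx in cands:
                alts = [a for a in "AG" if not _creates_or_destroys_ag(w, idx, a)]
                if alts:
                    ok = take(ctx, WINDOW_LEN - idx, str(rng.choice(alts)), "pathogenic")
                    if ok:
                        break
        elif cls == "bps_disruption":
            bp = _feat.predict_bps(w)
            if bp.position is not None and ctx.base_at(bp.position) == "A":
                alt = str(rng.choice(["C", "T"]))
                ok = take(ctx, bp.position, alt, "pathogenic")
        elif cls == "int3_substitution":
            if w[WINDOW_LEN - 3] in "CT":
                alt = "G" if rng.random() < 0.6 else "A"
                idx = WINDOW_LEN - 3
                if not (alt == "G" and w[idx - 1] == "A"):
                    ok = take(ctx, 3, alt, "pathogenic")
        if ok:
            budget[cls] -= 1
            stall = 0
        else:
            stall += 1
    if any(v > 0 for v in budget.values()):
        raise ValueError(
            f"could not place all pathogenic variants; remaining {budget} — "
            "increase n_genes or relax effect_mix"
        )

    n_deep = int(round(cfg.n_common * cfg.common_deep_fraction))
    placed_common = 0
    stall = 0
    while placed_common < cfg.n_common and stall < max_stall:
        ci, ctx = next(cyc)
        w = ctx.window_seq
        deep = placed_common < n_deep
        if deep:
            cands = [
                i for i in range(0, WINDOW_LEN - 25) if i not in bps_span[ci]
            ]
            if not cands:
                continue
            idx = int(rng.choice(cands))
            alts = [
                a
                for a in BASES
                if a != w[idx] and not _creates_or_destroys_ag(w, idx, a)
            ]
            if not alts:
                continue
            alt = str(rng.choice(alts))
        else:
            cands = [
                i
                for i in range(WINDOW_LEN - 25, WINDOW_LEN - 3)
                if w[i] in "CT" and i not in bps_span[ci]
            ]
            if not cands:
                continue
            idx = int(rng.choice(cands))
            alt = "T" if w[idx] == "C" else "C"
        if take(ctx, WINDOW_LEN - idx, alt, "common", maf=draw_maf()):
            placed_common += 1
            stall = 0
        else:
            stall += 1
    if placed_common < cfg.n_common:
        raise ValueError(
            f"could only place {placed_common}/{cfg.n_common} common variants"
        )
    return records


def write_vcf(
    records: list[VariantRecord], genome: Genome, path: str | Path
) -> None:
    """Write records as VCF v4.2 with MAF and SPLICE_LABEL INFO fields."""
    header = pysam.VariantHeader()
    for chrom in genome.contigs:
        header.contigs.add(chrom, length=genome.contig_length(chrom))
    header.info.add("MAF", 1, "Float", "Minor allelic frequency")
    header.info.add("SPLICE_LABEL", 1, "String", "pathogenic or common")
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.alt_base)):
            rec = vf.new_record(
                contig=r.chrom, start=r.pos - 1, stop=r.pos,
                alleles=(r.ref_base, r.alt_base),
            )
            if r.maf is not None:
                rec.info["MAF"] = r.maf
            rec.info["SPLICE_LABEL"] = r.label
            vf.write(rec)


def simulate_all(cfg: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Genome + annotation + planted variants (VCF and TSV) in one call."""
    out = Path(out_dir)
    fasta, gtf = simulate_genome(cfg, out)
    genome = Genome(fasta)
    models = read_annotation(gtf)
    records = plant_variants(cfg, genome, models)
    vcf = out / "variants.vcf"
    tsv = out / "variants.tsv"
    write_vcf(records, genome, vcf)
    write_variants_tsv(
        sorted(records, key=lambda r: (r.chrom, r.pos, r.alt_base)), tsv
    )
    return {"fasta": fasta, "gtf": gtf, "vcf": vcf, "tsv": tsv}
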