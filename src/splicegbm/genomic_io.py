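"""Genome, annotation and variant I/O, and mapping of SNVs to acceptor windows.

Coordinate conventions: external files keep their native conventions (GTF is
1-based closed, VCF is 1-based); all public genomic coordinates here are
1-based. Intronic positions are numbered Int-k, counting upstream from the
intron's 3' terminus: Int-1 is the last intronic base (the G of the canonical
AG), Int-3 the third-from-last. The acceptor window runs Int-50..Int-1 and is
always reported in transcript-sense orientation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pysam
import pandas as pd
from pyfaidx import Fasta

log = logging.getLogger(__name__)

WINDOW_LEN = 50
#: Int-k range the classifier covers; Int-1/Int-2 map but are flagged out of scope
MODEL_KMIN, MODEL_KMAX = 3, 50

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID = set("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class MissingContigError(KeyError):
    pass


class RefMismatchError(ValueError):
    pass


class Genome:
    """Indexed FASTA accessor with strand-aware slicing.

    ``fetch`` takes 1-based closed coordinates and reverse-complements the
    slice when ``strand == '-'``. Characters outside ACGTN are mapped to N
    with a warning.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._fa = Fasta(str(self.path), as_raw=True, sequence_always_upper=True)

    @property
    def contigs(self) -> list[str]:
        return list(self._fa.keys())

    def contig_length(self, chrom: str) -> int:
        if chrom not in self._fa:
            raise MissingContigError(f"contig not in genome: {chrom!r}")
        return len(self._fa[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Return the sequence of [start, end] (1-based closed) on ``strand``."""
        if chrom not in self._fa:
            raise MissingContigError(f"contig not in genome: {chrom!r}")
        if start < 1 or end > len(self._fa[chrom]) or start > end:
            raise ValueError(
                f"bad interval {chrom}:{start}-{end} (contig length "
                f"{len(self._fa[chrom])})"
            )
        seq = str(self._fa[chrom][start - 1 : end]).upper()
        if not set(seq) <= _VALID:
            warnings.warn(
                f"non-ACGTN characters in {chrom}:{start}-{end}; mapped to N",
                stacklevel=2,
            )
            seq = "".join(c if c in _VALID else "N" for c in seq)
        return revcomp(seq) if strand == "-" else seq


@dataclass(frozen=True)
class TranscriptModel:
    """Strand-aware exon/intron structure of one transcript.

    ``exons`` are (start, end) pairs, 1-based closed, ordered 5'→3' in
    transcript orientation (genomically descending for '-' strand).
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    coding_flag: bool = True

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons {s1,e1} and {s2,e2}"
                )
        expect = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expect:
            raise ValueError(
                f"{self.transcript_id}: exons not ordered 5'->3' in "
                "transcript orientation"
            )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """Introns 5'→3' in transcript orientation, genomic 1-based closed."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1 + 1, s2 - 1))
            else:
                out.append((e2 + 1, s1 - 1))
        return out


@dataclass(frozen=True)
class AcceptorContext:
    """One internal exon's 3' splice-site context.

    ``window_seq`` is the 50-nt intronic sequence ending at Int-1, in
    transcript-sense orientation: ``window_seq[0]`` is Int-50 and
    ``window_seq[49]`` is Int-1, so Int-k sits at index ``50 - k``.
    ``int1_genomic_pos`` is the genomic coordinate of Int-1.
    """

    transcript_id: str
    chrom: str
    strand: str
    intron_index: int  # 1-based, transcript orientation
    window_seq: str
    exon_first_nt: str
    exon_first3: str  # first 3 exonic nt, for the 23-mer acceptor scorer
    exon_length: int
    int1_genomic_pos: int
    donor_seq: str  # Ex-3..Int+6 9-mer at the downstream exon's 5'ss
    canonical_ag: bool = field(default=True)

    def __post_init__(self):
        if len(self.window_seq) != WINDOW_LEN:
            raise ValueError(
                f"window_seq must be {WINDOW_LEN} nt, got {len(self.window_seq)}"
            )

    def base_at(self, k: int) -> str:
        """Sense base at Int-k."""
        if not 1 <= k <= WINDOW_LEN:
            raise ValueError(f"Int-k out of window: {k}")
        return self.window_seq[WINDOW_LEN - k]

    def genomic_pos_of(self, k: int) -> int:
        """Genomic coordinate of Int-k."""
        if self.strand == "+":
            return self.int1_genomic_pos - (k - 1)
        return self.int1_genomic_pos + (k - 1)

    def covers(self, chrom: str, pos: int) -> bool:
        if chrom != self.chrom:
            return False
        lo = min(self.genomic_pos_of(1), self.genomic_pos_of(WINDOW_LEN))
        hi = max(self.genomic_pos_of(1), self.genomic_pos_of(WINDOW_LEN))
        return lo <= pos <= hi

    def int_position_of(self, pos: int) -> int:
        """Int-k of a genomic coordinate inside the window."""
        if self.strand == "+":
            k = self.int1_genomic_pos - pos + 1
        else:
            k = pos - self.int1_genomic_pos + 1
        if not 1 <= k <= WINDOW_LEN:
            raise ValueError(f"position {pos} outside acceptor window")
        return k


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    maf: float | None = None
    label: str = "unlabeled"  # pathogenic | common | unlabeled

    def __post_init__(self):
        for b, name in ((self.ref_base, "ref"), (self.alt_base, "alt")):
            if b not in "ACGT" or len(b) != 1:
                raise ValueError(
                    f"{name} allele must be a single A/C/G/T base, got {b!r} "
                    f"at {self.chrom}:{self.pos} (indels are not supported)"
                )
        if self.ref_base == self.alt_base:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.maf is not None and not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"MAF outside [0,1]: {self.maf}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref_base}:{self.alt_base}"


@dataclass(frozen=True)
class IntronicVariant:
    """A VariantRecord mapped to one transcript's acceptor window."""

    variant: VariantRecord
    transcript_id: str
    int_position: int  # k of Int-k
    sense_ref: str
    sense_alt: str

    def __post_init__(self):
        if not 1 <= self.int_position <= WINDOW_LEN:
            raise ValueError(f"Int-k out of range: {self.int_position}")

    @property
    def in_model_scope(self) -> bool:
        """True for Int-50..Int-3; the canonical AG (Int-1/Int-2) is excluded."""
        return MODEL_KMIN <= self.int_position <= MODEL_KMAX

    @property
    def key(self) -> str:
        return f"{self.variant.key}:{self.transcript_id}"


def read_genome(path: str | Path) -> Genome:
    return Genome(path)


def _transcript_id_of(feature) -> str | None:
    for k in ("transcript_id", "Parent"):
        if k in feature.attributes:
            v = feature.attributes[k][0]
            return v.split(":")[-1] if k == "Parent" else v
    return None


def read_annotation(path: str | Path) -> list[TranscriptModel]:
    """Parse a GTF/GFF3 file into TranscriptModels (gz accepted).

    A transcript is flagged coding when it carries CDS features or a
    protein_coding biotype attribute. Transcripts with zero exon features are
    skipped with a warning.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list] = {}
    coding: dict[str, bool] = {}
    meta: dict[str, tuple[str, str]] = {}
    for f in db.all_features():
        tid = _transcript_id_of(f)
        if tid is None:
            continue
        biotype = None
        for k in ("transcript_biotype", "gene_biotype", "biotype"):
            if k in f.attributes:
                biotype = f.attributes[k][0]
        if f.featuretype.lower() == "exon":
            exons.setdefault(tid, []).append((f.start, f.end))
            meta[tid] = (f.seqid, f.strand)
        if f.featuretype.upper() == "CDS" or biotype == "protein_coding":
            coding[tid] = True
    models = []
    for tid, (chrom, strand) in meta.items():
        ex = sorted(exons.get(tid, []))
        if not ex:
            warnings.warn(f"transcript {tid} has no exons; skipped", stacklevel=2)
            continue
        if strand == "-":
            ex = ex[::-1]
        models.append(
            TranscriptModel(
                transcript_id=tid,
                chrom=chrom,
                strand=strand,
                exons=tuple(ex),
                coding_flag=coding.get(tid, False),
            )
        )
    return models


def acceptor_windows(tm: TranscriptModel, genome: Genome) -> list[AcceptorContext]:
    """Acceptor windows of all internal exons of ``tm``.

    One context per internal exon (transcript-orientation index 2..n-1); the
    upstream intron must be at least 50 nt, otherwise the window is skipped
    and logged.
    """
    out: list[AcceptorContext] = []
    if tm.n_exons < 3:
        return out
    introns = tm.introns()
    for i in range(1, tm.n_exons - 1):  # internal exons, 0-based index i
        istart, iend = introns[i - 1]
        ilen = iend - istart + 1
        if ilen < WINDOW_LEN:
            log.info(
                "%s intron %d is %d nt (<%d); acceptor window skipped",
                tm.transcript_id, i, ilen, WINDOW_LEN,
            )
            continue
        ex_s, ex_e = tm.exons[i]
        exon_len = ex_e - ex_s + 1
        nx_s, nx_e = tm.exons[i + 1]
        if tm.strand == "+":
            int1 = iend
            window = genome.fetch(tm.chrom, iend - WINDOW_LEN + 1, iend, "+")
            exon3 = genome.fetch(tm.chrom, ex_s, ex_s + 2, "+")
            # donor of this exon: last 3 exonic + first 6 of the next intron
            donor = genome.fetch(tm.chrom, ex_e - 2, ex_e + 6, "+")
        else:
            int1 = istart
            window = genome.fetch(tm.chrom, istart, istart + WINDOW_LEN - 1, "-")
            exon3 = genome.fetch(tm.chrom, ex_e - 2, ex_e, "-")
            donor = genome.fetch(tm.chrom, ex_s - 6, ex_s + 2, "-")
        out.append(
            AcceptorContext(
                transcript_id=tm.transcript_id,
                chrom=tm.chrom,
                strand=tm.strand,
                intron_index=i,
                window_seq=window,
                exon_first_nt=exon3[0],
                exon_first3=exon3,
                exon_length=exon_len,
                int1_genomic_pos=int1,
                donor_seq=donor,
                canonical_ag=window.endswith("AG"),
            )
        )
    return out


def map_variant(
    v: VariantRecord,
    models: Sequence[TranscriptModel],
    genome: Genome,
    contexts: dict[str, list[AcceptorContext]] | None = None,
) -> list[IntronicVariant]:
    """Map a variant to every transcript whose acceptor window covers it.

    Returns one IntronicVariant per covering (transcript, window); the empty
    list when no window covers the position. ``contexts`` may carry
    precomputed windows keyed by transcript id to avoid re-slicing.
    """
    genomic_ref = genome.fetch(v.chrom, v.pos, v.pos, "+")
    if genomic_ref != v.ref_base:
        raise RefMismatchError(
            f"reference mismatch at {v.chrom}:{v.pos}: variant says "
            f"{v.ref_base}, genome says {genomic_ref}"
        )
    hits: list[IntronicVariant] = []
    for tm in models:
        if tm.chrom != v.chrom:
            continue
        ctxs = (
            contexts.get(tm.transcript_id)
            if contexts is not None
            else acceptor_windows(tm, genome)
        ) or []
        for ctx in ctxs:
            if not ctx.covers(v.chrom, v.pos):
                continue
            k = ctx.int_position_of(v.pos)
            if tm.strand == "-":
                sense_ref, sense_alt = revcomp(v.ref_base), revcomp(v.alt_base)
            else:
                sense_ref, sense_alt = v.ref_base, v.alt_base
            assert ctx.base_at(k) == sense_ref, (
                f"window/genome inconsistency at {v.chrom}:{v.pos} Int-{k}"
            )
            hits.append(
                IntronicVariant(
                    variant=v,
                    transcript_id=tm.transcript_id,
                    int_position=k,
                    sense_ref=sense_ref,
                    sense_alt=sense_alt,
                )
            )
    return hits


def read_variants(path: str | Path) -> list[VariantRecord]:
    """Read variants from VCF (via pysam) or 5/6-column TSV (gz accepted).

    TSV columns: chrom, pos, ref, alt, maf[, label]. VCF records may carry
    ``MAF`` and ``SPLICE_LABEL`` INFO fields. Non-SNV records are rejected.
    """
    path = Path(path)
    if path.suffix in {".vcf"} or str(path).endswith((".vcf.gz", ".bcf")):
        out = []
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                for alt in rec.alts or ():
                    maf = rec.info.get("MAF")
                    if isinstance(maf, tuple):
                        maf = maf[0]
                    label = rec.info.get("SPLICE_LABEL", "unlabeled")
                    out.append(
                        VariantRecord(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref_base=rec.ref,
                            alt_base=alt,
                            maf=float(maf) if maf is not None else None,
                            label=str(label),
                        )
                    )
        return out
    df = pd.read_csv(path, sep="\t", dtype={0: str}, comment="#")
    cols = list(df.columns)
    rename = dict(zip(cols, ["chrom", "pos", "ref", "alt", "maf", "label"]))
    df = df.rename(columns=rename)
    out = []
    for row in df.itertuples(index=False):
        maf = getattr(row, "maf", None)
        out.append(
            VariantRecord(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref_base=str(row.ref),
                alt_base=str(row.alt),
                maf=None if maf is None or pd.isna(maf) else float(maf),
                label=str(getattr(row, "label", "unlabeled")),
            )
        )
    return out


def write_variants_tsv(records: Iterable[VariantRecord], path: str | Path) -> None:
    rows = [
        {
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref_base,
            "alt": r.alt_base,
            "maf": "" if r.maf is None else f"{r.maf:.6f}",
            "label": r.label,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
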