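"""Genome slicing, annotation parsing, acceptor windows, variant mapping."""

import numpy as np
import pytest

from splicegbm.genomic_io import (
    Genome,
    IntronicVariant,
    MissingContigError,
    RefMismatchError,
    TranscriptModel,
    VariantRecord,
    WINDOW_LEN,
    acceptor_windows,
    map_variant,
    read_annotation,
    revcomp,
)


def _hand_revcomp(seq):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))


class TestGenomeFetch:
    def test_identity_slice(self, tiny_fasta):
        g = Genome(tiny_fasta)
        assert g.fetch("t1", 1, 4, "+") == "ACGT"

    def test_palindromic_minus_slice(self, tiny_fasta):
        # ACGT is its own reverse complement
        g = Genome(tiny_fasta)
        assert g.fetch("t1", 1, 4, "-") == "ACGT"

    def test_minus_slice_matches_hand_oracle(self, tiny_fasta):
        g = Genome(tiny_fasta)
        assert g.fetch("t1", 2, 4, "-") == _hand_revcomp("CGT") == "ACG"

    def test_missing_contig_named_in_error(self, tiny_fasta):
        g = Genome(tiny_fasta)
        with pytest.raises(MissingContigError, match="chrZ"):
            g.fetch("chrZ", 1, 2)

    def test_non_acgt_mapped_to_n(self, tmp_path):
        p = tmp_path / "odd.fa"
        p.write_text(">c\nACRTAC\n")
        g = Genome(p)
        with pytest.warns(UserWarning, match="mapped to N"):
            assert g.fetch("c", 1, 4) == "ACNT"


GTF_3EXON = """\
c1\tx\ttranscript\t1\t300\t.\t{strand}\t.\tgene_id "g"; transcript_id "t"; transcript_biotype "protein_coding";
c1\tx\texon\t1\t60\t.\t{strand}\t.\tgene_id "g"; transcript_id "t"; transcript_biotype "protein_coding";
c1\tx\texon\t141\t200\t.\t{strand}\t.\tgene_id "g"; transcript_id "t"; transcript_biotype "protein_coding";
c1\tx\texon\t261\t300\t.\t{strand}\t.\tgene_id "g"; transcript_id "t"; transcript_biotype "protein_coding";
"""


class TestReadAnnotation:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_exon_order_follows_transcript_orientation(self, tmp_path, strand):
        p = tmp_path / "a.gtf"
        p.write_text(GTF_3EXON.format(strand=strand))
        (tm,) = read_annotation(p)
        assert tm.n_exons == 3 and tm.coding_flag
        if strand == "+":
            assert tm.exons[0] == (1, 60)
        else:
            # exon index 1 is the genomically rightmost exon
            assert tm.exons[0] == (261, 300)

    def test_fixture_annotation_counts(self, sim_small):
        models = sim_small["models"]
        assert len(models) == sim_small["cfg"].n_genes
        assert all(m.coding_flag for m in models)

    def test_unordered_exons_rejected(self):
        with pytest.raises(ValueError, match="not ordered"):
            TranscriptModel("t", "c", "+", ((141, 200), (1, 60)))


class TestAcceptorWindows:
    def test_one_context_per_internal_exon(self, sim_small):
        n_internal = sim_small["cfg"].exons_per_gene - 2
        for tm in sim_small["models"]:
            ctxs = acceptor_windows(tm, sim_small["genome"])
            assert len(ctxs) == n_internal
            for ctx in ctxs:
                assert len(ctx.window_seq) == WINDOW_LEN
                assert ctx.canonical_ag and ctx.window_seq.endswith("AG")

    def test_minus_strand_window_is_revcomp_of_genomic(self, sim_small):
        genome = sim_small["genome"]
        tm = next(m for m in sim_small["models"] if m.strand == "-")
        for ctx in acceptor_windows(tm, genome):
            genomic = genome.fetch(
                ctx.chrom, ctx.int1_genomic_pos, ctx.int1_genomic_pos + 49, "+"
            )
            assert ctx.window_seq == _hand_revcomp(genomic)

    def test_short_intron_yields_no_window(self, tmp_path):
        p = tmp_path / "short.fa"
        p.write_text(">c\n" + "ACGT" * 40 + "\n")
        g = Genome(p)
        tm = TranscriptModel("t", "c", "+", ((1, 30), (61, 90), (121, 150)))
        # introns are 30 nt (< 50): both windows skipped
        assert acceptor_windows(tm, g) == []


class TestMapVariant:
    def test_int3_by_definition(self, sim_small):
        genome, models = sim_small["genome"], sim_small["models"]
        ctx = acceptor_windows(models[0], genome)[0]
        pos = ctx.genomic_pos_of(3)
        ref = genome.fetch(ctx.chrom, pos, pos, "+")
        alt = "A" if ref != "A" else "C"
        hits = map_variant(
            VariantRecord(ctx.chrom, pos, ref, alt), models, genome
        )
        assert [h.int_position for h in hits] == [3]

    def test_position_upstream_of_window_unmapped(self, sim_small):
        genome, models = sim_small["genome"], sim_small["models"]
        ctx = acceptor_windows(models[0], genome)[0]
        pos = (
            ctx.genomic_pos_of(WINDOW_LEN) - 1
            if ctx.strand == "+"
            else ctx.genomic_pos_of(WINDOW_LEN) + 1
        )  # 51 nt upstream of the exon
        ref = genome.fetch(ctx.chrom, pos, pos, "+")
        alt = "A" if ref != "A" else "C"
        hits = map_variant(VariantRecord(ctx.chrom, pos, ref, alt), models, genome)
        assert hits == []

    def test_overlapping_transcripts_give_one_row_each(self, sim_small, overlapping_pair):
        genome = sim_small["genome"]
        ctx = acceptor_windows(overlapping_pair[0], genome)[0]
        pos = ctx.genomic_pos_of(10)
        ref = genome.fetch(ctx.chrom, pos, pos, "+")
        alt = "A" if ref != "A" else "C"
        hits = map_variant(
            VariantRecord(ctx.chrom, pos, ref, alt), overlapping_pair, genome
        )
        assert len(hits) == 2
        assert {h.transcript_id for h in hits} == {
            t.transcript_id for t in overlapping_pair
        }

    def test_ref_mismatch_names_position(self, sim_small):
        genome, models = sim_small["genome"], sim_small["models"]
        ctx = acceptor_windows(models[0], genome)[0]
        pos = ctx.genomic_pos_of(10)
        ref = genome.fetch(ctx.chrom, pos, pos, "+")
        wrong = "A" if ref != "A" else "C"
        alt = "G" if wrong != "G" else "T"
        with pytest.raises(RefMismatchError, match=str(pos)):
            map_variant(VariantRecord(ctx.chrom, pos, wrong, alt), models, genome)

    def test_indel_rejected(self):
        with pytest.raises(ValueError, match="single"):
            VariantRecord("c", 5, "AT", "A")


class TestInvariants:
    def test_int_k_round_trip_over_fixture(self, sim_small):
        """Constructing a variant at the coordinate of Int-k recovers k."""
        genome, models = sim_small["genome"], sim_small["models"]
        for tm in models[:4]:
            for ctx in acceptor_windows(tm, genome):
                for k in range(3, WINDOW_LEN + 1, 7):
                    pos = ctx.genomic_pos_of(k)
                    ref = genome.fetch(ctx.chrom, pos, pos, "+")
                    alt = "A" if ref != "A" else "C"
                    hits = map_variant(
                        VariantRecord(ctx.chrom, pos, ref, alt), [tm], genome
                    )
                    assert [h.int_position for h in hits] == [k]

    def test_window_base_equals_sense_ref(self, sim_small):
        genome, models = sim_small["genome"], sim_small["models"]
        ctx_by_tid = {
            tm.transcript_id: acceptor_windows(tm, genome) for tm in models
        }
        for rec in sim_small["records"]:
            for iv in map_variant(rec, models, genome, contexts=ctx_by_tid):
                ctx = next(
                    c
                    for c in ctx_by_tid[iv.transcript_id]
                    if c.covers(rec.chrom, rec.pos)
                )
                assert ctx.window_seq[WINDOW_LEN - iv.int_position] == iv.sense_ref

    def test_strand_symmetry_of_whole_fixture(self, sim_small, tmp_path):
        """Reverse-complementing the genome and flipping every annotation
        leaves window sequences and Int-k positions unchanged."""
        genome, models = sim_small["genome"], sim_small["models"]
        lengths = {c: genome.contig_length(c) for c in genome.contigs}
        flipped_fa = tmp_path / "flipped.fa"
        with open(flipped_fa, "w") as fh:
            for c in genome.contigs:
                fh.write(f">{c}\n{revcomp(genome.fetch(c, 1, lengths[c]))}\n")
        flipped_genome = Genome(flipped_fa)
        for tm in models:
            L = lengths[tm.chrom]
            new_exons = tuple(
                (L - e + 1, L - s + 1) for (s, e) in tm.exons
            )
            flipped = TranscriptModel(
                tm.transcript_id,
                tm.chrom,
                "-" if tm.strand == "+" else "+",
                new_exons,
                tm.coding_flag,
            )
            orig = acceptor_windows(tm, genome)
            mirr = acceptor_windows(flipped, flipped_genome)
            assert [c.window_seq for c in orig] == [c.window_seq for c in mirr]
            assert [c.exon_first3 for c in orig] == [c.exon_first3 for c in mirr]
            assert [c.donor_seq for c in orig] == [c.donor_seq for c in mirr]
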