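"""Feature computations: AG gain/loss, site-strength scores, BPS, PPT, RBP."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splicegbm import features as F
from splicegbm.genomic_io import (
    AcceptorContext,
    IntronicVariant,
    VariantRecord,
    WINDOW_LEN,
    acceptor_windows,
)

RNG = np.random.default_rng(2024)


def make_ctx(window, exon3="GAT", donor="CAGGTAAGT", strand="+", tid="t"):
    return AcceptorContext(
        transcript_id=tid, chrom="c", strand=strand, intron_index=1,
        window_seq=window, exon_first_nt=exon3[0], exon_first3=exon3,
        exon_length=120, int1_genomic_pos=1000, donor_seq=donor,
    )


def make_iv(window, k, alt, tid="t"):
    ref = window[WINDOW_LEN - k]
    v = VariantRecord("c", 1000 - (k - 1), ref, alt)
    return IntronicVariant(v, tid, k, ref, alt)


def _random_window(rng):
    w = list(rng.choice(list("ACGT"), size=WINDOW_LEN))
    w[-2:] = ["A", "G"]
    return "".join(w)


def _ag_set_oracle(seq):
    """Brute-force AG start positions fully within Int-50..Int-3."""
    return {i for i in range(0, 47) if seq[i : i + 2] == "AG"}


class TestAgGain:
    def test_creating_ag_after_an_a(self):
        w = "T" * 20 + "AC" + "T" * 26 + "AG"
        ctx = make_ctx(w)
        k = WINDOW_LEN - 21  # the C following the A
        gain, loss = F.detect_ag_gain(ctx, make_iv(w, k, "G"))
        assert (gain, loss) == (1, 0)

    def test_substitution_in_poly_t_run_is_silent(self):
        w = "T" * 48 + "AG"
        ctx = make_ctx(w)
        gain, loss = F.detect_ag_gain(ctx, make_iv(w, 10, "C"))
        assert (gain, loss) == (0, 0)

    def test_matches_string_scan_oracle_on_random_windows(self):
        for _ in range(200):
            w = _random_window(RNG)
            ctx = make_ctx(w)
            k = int(RNG.integers(3, WINDOW_LEN + 1))
            ref = w[WINDOW_LEN - k]
            for alt in "ACGT":
                if alt == ref:
                    continue
                iv = make_iv(w, k, alt)
                mut = F.mutated_window(ctx, iv)
                expect = (
                    int(bool(_ag_set_oracle(mut) - _ag_set_oracle(w))),
                    int(bool(_ag_set_oracle(w) - _ag_set_oracle(mut))),
                )
                assert F.detect_ag_gain(ctx, iv) == expect


class TestShapiroSenapathy:
    def test_consensus_scores_100_anticonsensus_0(self):
        fm = F.default_acceptor_matrix()
        assert F.shapiro_senapathy_score(fm.consensus(), fm) == pytest.approx(100)
        assert F.shapiro_senapathy_score(fm.anticonsensus(), fm) == pytest.approx(0)

    def test_hand_arithmetic_on_toy_matrix(self):
        # rows (.4,.3,.2,.1) and (.1,.2,.3,.4): t_max=.8, t_min=.2
        fm = F.FrequencyMatrix([[0.4, 0.3, 0.2, 0.1], [0.1, 0.2, 0.3, 0.4]])
        assert F.shapiro_senapathy_score("AT", fm) == pytest.approx(100)
        assert F.shapiro_senapathy_score("TA", fm) == pytest.approx(0)
        # "AC": t=.6 -> 100*(.6-.2)/(.8-.2) = 66.67
        assert F.shapiro_senapathy_score("AC", fm) == pytest.approx(200 / 3)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            F.shapiro_senapathy_score("ACGT", F.default_acceptor_matrix())

    @settings(max_examples=60, derandomize=True)
    @given(st.data())
    def test_monotone_in_base_frequency(self, data):
        """Replacing any base by a higher-frequency base never lowers the score."""
        fm = F.default_acceptor_matrix()
        seq = list(
            data.draw(st.text(alphabet="ACGT", min_size=15, max_size=15))
        )
        i = data.draw(st.integers(0, 14))
        before = F.shapiro_senapathy_score("".join(seq), fm)
        better = max("ACGT", key=lambda b: fm.freq(i, b))
        seq[i] = better
        after = F.shapiro_senapathy_score("".join(seq), fm)
        assert after >= before - 1e-12


class TestWMM:
    def test_signal_equal_background_scores_zero(self):
        fm = F.FrequencyMatrix(np.full((23, 4), 0.25))
        model = F.WeightMatrixModel(fm, fm)
        for _ in range(5):
            seq = "".join(RNG.choice(list("ACGT"), size=23))
            assert model.score(seq) == pytest.approx(0)

    def test_single_sequence_closed_form(self):
        """One training 23-mer, pseudocount c, uniform background:
        score = 23 * log2(((1+c)/(1+4c)) / 0.25)."""
        seq = "".join(RNG.choice(list("ACGT"), size=23))
        c = 0.5
        model = F.train_wmm([seq], pseudocount=c)
        expect = 23 * math.log2(((1 + c) / (1 + 4 * c)) / 0.25)
        assert model.score(seq) == pytest.approx(expect, rel=1e-12)

    def test_score_is_additive_over_positions(self):
        model = F.default_acceptor_wmm()
        seq = "".join(RNG.choice(list("ACGT"), size=23))
        assert model.score(seq) == pytest.approx(sum(model.position_scores(seq)))

    def test_background_trained_model_centres_near_zero(self):
        rng = np.random.default_rng(7)
        pool = ["".join(rng.choice(list("ACGT"), size=23)) for _ in range(500)]
        model = F.train_wmm(pool[:400], pseudocount=0.5)
        mean = np.mean([model.score(s) for s in pool[400:]])
        assert abs(mean) < 0.5

    def test_round_trip_serialization_is_bit_identical(self, tmp_path):
        model = F.train_wmm(
            ["".join(RNG.choice(list("ACGT"), size=23)) for _ in range(20)]
        )
        p = tmp_path / "wmm.json"
        model.to_json(p)
        reloaded = F.WeightMatrixModel.from_json(p)
        for _ in range(10):
            s = "".join(RNG.choice(list("ACGT"), size=23))
            assert model.score(s) == reloaded.score(s)

    def test_unknown_format_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"format": "mystery"}')
        with pytest.raises(ValueError, match="splicegbm-wmm-v1"):
            F.WeightMatrixModel.from_json(p)

    def test_empty_positives_rejected(self):
        with pytest.raises(ValueError, match="no positive"):
            F.train_wmm([])


class TestBranchPoint:
    def test_planted_consensus_recovered(self):
        fm = F.default_bps_matrix()
        hept = fm.consensus()
        anti = fm.anticonsensus()
        w = list((anti * 8)[:WINDOW_LEN])
        k = 25
        c = WINDOW_LEN - k
        w[c - 3 : c + 4] = list(hept)
        w[-2:] = ["A", "G"]
        bp = F.predict_bps("".join(w))
        assert bp.position == 25 and bp.heptamer == hept

    def test_tie_breaks_toward_3prime_ss(self):
        fm = F.default_bps_matrix()
        hept = fm.consensus()
        anti = fm.anticonsensus()
        w = list((anti * 8)[:WINDOW_LEN])
        for k in (30, 20):
            c = WINDOW_LEN - k
            w[c - 3 : c + 4] = list(hept)
        w[-2:] = ["A", "G"]
        assert F.predict_bps("".join(w)).position == 20

    def test_planted_motif_outscores_unfavoured_sequence(self):
        fm = F.default_bps_matrix()
        anti = fm.anticonsensus()
        w_plant = list((anti * 8)[:WINDOW_LEN])
        c = WINDOW_LEN - 28
        w_plant[c - 3 : c + 4] = list(fm.consensus())
        planted = F.predict_bps("".join(w_plant))
        barren = F.predict_bps((anti * 8)[:WINDOW_LEN])
        assert planted.score > barren.score

    def test_region_too_short_flags_none(self):
        bp = F.predict_bps("ACGT" * 2, region=(44, 15))
        assert bp.position is None and bp.score is None


class TestPPT:
    def test_all_t_window_counts_full_span(self):
        assert F.count_ppt_pyrimidines("T" * WINDOW_LEN) == 23

    def test_all_a_window_counts_zero(self):
        assert F.count_ppt_pyrimidines("A" * WINDOW_LEN) == 0

    def test_single_base_delta(self):
        w = "T" * 48 + "AG"
        w = w[:40] + "C" + w[41:]  # C at Int-10
        ctx = make_ctx(w)
        iv = make_iv(w, 10, "A")
        assert (
            F.count_ppt_pyrimidines(ctx) - F.count_ppt_pyrimidines(ctx, iv) == 1
        )


class TestRbpMotifs:
    def test_completed_ttt_run_counts_as_gain(self):
        w = "C" * 20 + "TTAT" + "C" * 24 + "AG"
        ctx = make_ctx(w)
        k = WINDOW_LEN - 22  # the A inside TTAT
        gain, loss = F.rbp_motif_delta(ctx, make_iv(w, k, "T"), {"TTTT": "x"})
        assert gain >= 1 and loss == 0

    def test_variant_outside_any_occurrence(self):
        w = "C" * 48 + "AG"
        ctx = make_ctx(w)
        gain, loss = F.rbp_motif_delta(ctx, make_iv(w, 40, "A"), {"TTTT": "x"})
        assert (gain, loss) == (0, 0)

    def test_empty_table_warns(self):
        w = "C" * 48 + "AG"
        ctx = make_ctx(w)
        with pytest.warns(UserWarning, match="empty"):
            assert F.rbp_motif_delta(ctx, make_iv(w, 40, "A"), {}) == (0, 0)

    def test_matches_brute_force_scanner(self):
        def brute(seq, motifs, idx):
            hits = set()
            for m in motifs:
                for s in range(len(seq) - len(m) + 1):
                    if seq[s : s + len(m)] == m and s <= idx < s + len(m):
                        hits.add((m, s))
            return hits

        motifs = {"TTTT": "x", "CTCT": "y", "GGAGG": "z", "ACAC": "w"}
        for _ in range(100):
            w = _random_window(RNG)
            ctx = make_ctx(w)
            k = int(RNG.integers(3, WINDOW_LEN + 1))
            ref = w[WINDOW_LEN - k]
            alt = next(b for b in "ACGT" if b != ref)
            iv = make_iv(w, k, alt)
            mut = F.mutated_window(ctx, iv)
            idx = WINDOW_LEN - k
            ref_occ = brute(w, motifs, idx)
            alt_occ = brute(mut, motifs, idx)
            assert F.rbp_motif_delta(ctx, iv, motifs) == (
                len(alt_occ - ref_occ),
                len(ref_occ - alt_occ),
            )


class TestFeaturize:
    def test_schema_is_stable_across_variants(self, sim_small):
        genome, models = sim_small["genome"], sim_small["models"]
        ctx = acceptor_windows(models[0], genome)[0]
        names = None
        for k in (3, 10, 30, 50):
            ref = ctx.base_at(k)
            alt = next(b for b in "ACGT" if b != ref)
            iv = make_iv(ctx.window_seq, k, alt, tid=ctx.transcript_id)
            fv = F.featurize(ctx, iv)
            assert list(fv) == F.feature_names()
            names = names or list(fv)
        assert len(names) == len(set(names))

    def test_alt_g_at_int3_sets_one_hot(self):
        w = "T" * 25 + "TTAACCT" + "T" * 15 + "CAG"
        ctx = make_ctx(w)
        iv = make_iv(w, 3, "G")
        fv = F.featurize(ctx, iv)
        assert fv["nt_int3_alt_G"] == 1.0 and fv["nt_int3_ref_C"] == 1.0
        assert sum(fv[f"nt_int3_alt_{b}"] for b in "ACGT") == 1.0

    def test_canonical_fixture_acceptor_with_neutral_deep_variant(self, sim_small):
        genome, models = sim_small["genome"], sim_small["models"]
        ctx = acceptor_windows(models[0], genome)[0]
        k = 45
        ref = ctx.base_at(k)
        alt = next(
            b for b in "ACGT"
            if b != ref and F.detect_ag_gain(
                ctx, make_iv(ctx.window_seq, k, b, ctx.transcript_id)
            ) == (0, 0)
        )
        fv = F.featurize(ctx, make_iv(ctx.window_seq, k, alt, ctx.transcript_id))
        assert fv["ag_gain"] == 0.0
        assert fv["ppt_count_ref"] >= 16
        assert fv["acceptor_ss_ref"] > 60

    def test_determinism(self, sim_small):
        genome, models = sim_small["genome"], sim_small["models"]
        ctx = acceptor_windows(models[0], genome)[0]
        iv = make_iv(ctx.window_seq, 20,
                     next(b for b in "ACGT" if b != ctx.base_at(20)),
                     ctx.transcript_id)
        assert F.featurize(ctx, iv) == F.featurize(ctx, iv)

    def test_strand_symmetric_features(self, sim_small):
        """Features of a '-' strand gene equal those of its '+' strand
        sense-equivalent construction."""
        from splicegbm.genomic_io import Genome, TranscriptModel, revcomp

        genome = sim_small["genome"]
        tm = next(m for m in sim_small["models"] if m.strand == "-")
        ctx = acceptor_windows(tm, genome)[0]
        # mirror the contig so the gene lands on '+'
        L = genome.contig_length(tm.chrom)
        flipped = TranscriptModel(
            tm.transcript_id, tm.chrom,
            "+", tuple((L - e + 1, L - s + 1) for (s, e) in tm.exons),
            tm.coding_flag,
        )
        import tempfile, os
        with tempfile.TemporaryDirectory() as d:
            fa = os.path.join(d, "m.fa")
            with open(fa, "w") as fh:
                fh.write(f">{tm.chrom}\n{revcomp(genome.fetch(tm.chrom, 1, L))}\n")
            g2 = Genome(fa)
            ctx2 = acceptor_windows(flipped, g2)[0]
            assert ctx2.window_seq == ctx.window_seq
            k = 17
            ref = ctx.base_at(k)
            alt = next(b for b in "ACGT" if b != ref)
            iv1 = make_iv(ctx.window_seq, k, alt, tid=tm.transcript_id)
            iv2 = make_iv(ctx2.window_seq, k, alt, tid=tm.transcript_id)
            assert F.featurize(ctx, iv1) == F.featurize(ctx2, iv2)
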