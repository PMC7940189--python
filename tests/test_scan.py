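"""PWM scanning: MEME parsing, log-odds scoring, exact null, BH, counting."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import motifcircuit as mc
from motifcircuit.scan import (
    HIT_COLUMNS,
    MotifModel,
    NullScoreDistribution,
    count_hits,
    encode_sequence,
    log_odds_matrix,
    reverse_complement,
    symmetrize_background,
)
from motifcircuit.synthetic import random_motif

UNIFORM = np.full(4, 0.25)


def _write_meme(tmp_path, body):
    path = tmp_path / "m.meme"
    path.write_text(
        "MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n"
        "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n" + body
    )
    return path


class TestParseMeme:
    def test_single_width3_motif(self, tmp_path):
        path = _write_meme(
            tmp_path,
            "MOTIF M1\nletter-probability matrix: alength= 4 w= 3 nsites= 20 E= 0\n"
            "1.0 0.0 0.0 0.0\n0.0 1.0 0.0 0.0\n0.0 0.0 1.0 0.0\n",
        )
        motifs = mc.parse_meme(path)
        assert len(motifs) == 1
        assert motifs[0].motif_id == "M1" and motifs[0].width == 3
        np.testing.assert_allclose(motifs[0].ppm[0], [1, 0, 0, 0])

    def test_two_motifs_order_preserved(self, tmp_path):
        body = (
            "MOTIF A1\nletter-probability matrix: alength= 4 w= 1 nsites= 20 E= 0\n"
            "0.25 0.25 0.25 0.25\n\n"
            "MOTIF B2\nletter-probability matrix: alength= 4 w= 2 nsites= 20 E= 0\n"
            "0.5 0.5 0.0 0.0\n0.0 0.0 0.5 0.5\n"
        )
        motifs = mc.parse_meme(_write_meme(tmp_path, body))
        assert [m.motif_id for m in motifs] == ["A1", "B2"]

    def test_write_parse_round_trip(self, tmp_path, rng):
        original = [random_motif(f"R{i}", int(rng.integers(4, 10)), rng)
                    for i in range(5)]
        path = tmp_path / "db.meme"
        mc.write_meme(original, path)
        parsed = mc.parse_meme(path)
        assert [m.motif_id for m in parsed] == [m.motif_id for m in original]
        for a, b in zip(parsed, original):
            np.testing.assert_allclose(a.ppm, b.ppm, atol=1e-5)

    def test_malformed_row_sum_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MotifModel("bad", np.array([[0.5, 0.1, 0.1, 0.1]]))


class TestLogOdds:
    def test_row_equal_background_scores_zero(self):
        motif = MotifModel("flat", np.tile(UNIFORM, (4, 1)))
        sm = log_odds_matrix(motif, UNIFORM)
        assert np.all(sm == 0)

    def test_certain_base_hand_arithmetic(self):
        # ppm[i,A]=1, uniform bg, eps=0.01: round(100*log2(0.9925/0.25)) = 199
        motif = MotifModel("pA", np.array([[1.0, 0, 0, 0]]))
        sm = log_odds_matrix(motif, UNIFORM, pseudo_fraction=0.01)
        assert sm[0, 0] == 199
        assert sm[0, 0] == round(100 * math.log2(0.9925 / 0.25))

    def test_score_decreases_with_background(self, rng):
        motif = random_motif("r", 6, rng)
        bg1 = np.array([0.25, 0.25, 0.25, 0.25])
        bg2 = np.array([0.4, 0.2, 0.2, 0.2])  # doubled A (then renormalized)
        s1 = log_odds_matrix(motif, bg1)
        s2 = log_odds_matrix(motif, bg2)
        assert np.all(s2[:, 0] < s1[:, 0])

    def test_zero_background_rejected(self):
        motif = MotifModel("x", np.array([[1.0, 0, 0, 0]]))
        with pytest.raises(ValueError):
            log_odds_matrix(motif, np.array([0.5, 0.5, 0.0, 0.0]))


def _enumerate_null(sm, bg):
    """Exhaustive oracle: frequency table of scores over all 4^w windows."""
    w = sm.shape[0]
    pmf = {}
    for word in itertools.product(range(4), repeat=w):
        score = sum(sm[i, b] for i, b in enumerate(word))
        prob = 1.0
        for b in word:
            prob *= bg[b]
        pmf[score] = pmf.get(score, 0.0) + prob
    return pmf


class TestNullDistribution:
    def test_width1_support_and_masses(self):
        motif = MotifModel("w1", np.array([[0.7, 0.1, 0.1, 0.1]]))
        sm = log_odds_matrix(motif, UNIFORM)
        null = NullScoreDistribution(sm, UNIFORM)
        support = np.nonzero(null.pmf)[0] + null.min_score
        assert support.size <= 4
        for s in support:
            mass = null.pmf[s - null.min_score]
            expected = sum(0.25 for b in range(4) if sm[0, b] == s)
            assert mass == pytest.approx(expected, abs=1e-12)

    def test_total_mass_is_one(self, rng):
        motif = random_motif("m", 9, rng)
        null = NullScoreDistribution(log_odds_matrix(motif, UNIFORM), UNIFORM)
        assert null.pmf.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("width", [2, 4, 6])
    def test_matches_exhaustive_enumeration(self, width, rng):
        motif = random_motif(f"m{width}", width, rng)
        bg = symmetrize_background([0.3, 0.2, 0.2, 0.3])
        sm = log_odds_matrix(motif, bg)
        null = NullScoreDistribution(sm, bg)
        oracle = _enumerate_null(sm, bg)
        for score, mass in oracle.items():
            assert null.pmf[score - null.min_score] == pytest.approx(
                mass, abs=1e-12
            )

    def test_pvalue_outside_support(self):
        motif = MotifModel("w1", np.array([[1.0, 0, 0, 0]]))
        null = NullScoreDistribution(log_odds_matrix(motif, UNIFORM), UNIFORM)
        assert null.pvalue(null.min_score - 10)[0] == 1.0
        assert null.pvalue(null.max_score + 10)[0] == 0.0


def _brute_force_hits(sequence, motif, bg, p_threshold):
    """Independent scanner: python loops, enumerated p-values."""
    sm = log_odds_matrix(motif, bg)
    w = motif.width
    pmf = _enumerate_null(sm, bg)
    def pval(s):
        return sum(m for sc, m in pmf.items() if sc >= s)
    hits = set()
    for strand in "+-":
        seq = sequence if strand == "+" else reverse_complement(sequence)
        for i in range(len(seq) - w + 1):
            window = seq[i : i + w]
            if "N" in window:
                continue
            score = sum(sm[j, "ACGT".index(b)] for j, b in enumerate(window))
            if pval(score) <= p_threshold:
                start = i if strand == "+" else len(sequence) - w - i
                hits.add((start, strand, score))
    return hits


class TestScan:
    def test_unique_exact_match_poly_a(self):
        motif = MotifModel("pA4", np.tile([1.0, 0, 0, 0], (4, 1)))
        hits = mc.scan_sequence("CCCCAAAACCCC", motif, p_threshold=0.01)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].strand) == (4, "+")

    def test_palindromic_motif_hits_both_strands(self):
        ppm = np.array([[0.9, 0.03, 0.03, 0.04],
                        [0.04, 0.03, 0.03, 0.9]])  # 'AT' = its own revcomp
        motif = MotifModel("pal", ppm)
        hits = mc.scan_sequence("GGGATGGG", motif, p_threshold=0.2)
        plus = {(h.start, h.score) for h in hits if h.strand == "+"}
        minus = {(h.start, h.score) for h in hits if h.strand == "-"}
        assert plus == minus != set()

    def test_windows_with_n_skipped(self):
        motif = MotifModel("pA4", np.tile([1.0, 0, 0, 0], (4, 1)))
        hits = mc.scan_sequence("CCAANACCCC", motif, p_threshold=1.0)
        assert all("N" not in "CCAANACCCC"[h.start : h.start + 4] for h in hits)

    def test_short_sequence_warns_and_empty(self):
        motif = MotifModel("pA4", np.tile([1.0, 0, 0, 0], (4, 1)))
        with pytest.warns(UserWarning, match="shorter than motif"):
            assert mc.scan_sequence("AC", motif) == []

    def test_matches_brute_force_scanner(self, rng):
        bg = symmetrize_background(UNIFORM)
        for _ in range(10):
            motif = random_motif("m", 5, rng, concentration=0.3)
            seq = "".join(rng.choice(list("ACGT"), size=80))
            df = mc.scan_sequences({"s": seq}, [motif], p_threshold=0.01)
            got = {(int(r.start), r.strand, int(r.score))
                   for r in df.itertuples(index=False)}
            assert got == _brute_force_hits(seq, motif, bg, 0.01)

    def test_strand_invariance(self, rng):
        """Scanning the reverse complement mirrors hits with equal scores."""
        motif = random_motif("m", 6, rng, concentration=0.3)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        fwd = mc.scan_sequences({"s": seq}, [motif], p_threshold=0.05)
        rev = mc.scan_sequences({"s": reverse_complement(seq)}, [motif],
                                p_threshold=0.05)
        flip = {"+": "-", "-": "+"}
        mirrored = {
            (len(seq) - 6 - int(r.start), flip[r.strand], int(r.score))
            for r in rev.itertuples(index=False)
        }
        assert {(int(r.start), r.strand, int(r.score))
                for r in fwd.itertuples(index=False)} == mirrored

    def test_background_calibration(self, rng):
        """On background DNA, P(p <= alpha) <= alpha within sampling noise."""
        motif = random_motif("m", 8, rng)
        seqs = {
            f"s{i}": "".join(rng.choice(list("ACGT"), size=2000))
            for i in range(10)
        }
        df = mc.scan_sequences(seqs, [motif], p_threshold=1.0)
        n_windows = 10 * (2000 - 8 + 1) * 2
        for alpha in (1e-2, 1e-3):
            frac = (df["p"] <= alpha).sum() / n_windows
            sd = math.sqrt(alpha * (1 - alpha) / n_windows)
            assert frac <= alpha + 3 * sd


class TestQValues:
    def test_single_hit_identity(self):
        hits = pd.DataFrame({"sequence": ["s"], "motif": ["m"], "start": [0],
                             "strand": ["+"], "score": [1], "p": [0.01]})
        assert mc.assign_qvalues(hits)["q"].iloc[0] == pytest.approx(0.01)

    def test_hand_computed_bh(self):
        hits = pd.DataFrame({"sequence": list("abc"), "motif": ["m"] * 3,
                             "start": [0] * 3, "strand": ["+"] * 3,
                             "score": [1] * 3, "p": [0.01, 0.02, 0.03]})
        np.testing.assert_allclose(mc.assign_qvalues(hits)["q"], [0.03] * 3)

    def test_all_p_one(self):
        hits = pd.DataFrame({"sequence": list("ab"), "motif": ["m"] * 2,
                             "start": [0] * 2, "strand": ["+"] * 2,
                             "score": [1] * 2, "p": [1.0, 1.0]})
        assert (mc.assign_qvalues(hits)["q"] == 1.0).all()

    def test_empty_group(self):
        out = mc.assign_qvalues(pd.DataFrame(columns=HIT_COLUMNS))
        assert len(out) == 0 and "q" in out.columns


class TestCountHits:
    def _hits(self, rows):
        return pd.DataFrame(
            rows, columns=["sequence", "motif", "start", "strand", "score",
                           "p", "q"]
        )

    def test_counts_pooled_over_ocrs(self):
        hits = self._hits([
            ("g1|ocr|c:0-10(+)", "M", 1, "+", 5, 1e-5, 0.01),
            ("g1|ocr|c:20-30(+)", "M", 2, "-", 5, 1e-5, 0.01),
        ])
        matrix = count_hits(
            hits,
            {"g1|ocr|c:0-10(+)": "g1", "g1|ocr|c:20-30(+)": "g1"},
            {"g1": "positive"},
            ["M"],
        )
        assert matrix.counts[0, 0] == 2

    def test_q_filter_modes(self):
        hits = self._hits([
            ("s1", "M", 1, "+", 5, 1e-5, 0.01),
            ("s1", "M", 9, "+", 5, 1e-2, 0.2),
        ])
        le = count_hits(hits, {"s1": "g"}, {"g": "positive"}, ["M"])
        gt = count_hits(hits, {"s1": "g"}, {"g": "positive"}, ["M"],
                        mode="keep_gt")
        assert le.counts[0, 0] == 1 and gt.counts[0, 0] == 1
        both = count_hits(hits, {"s1": "g"}, {"g": "positive"}, ["M"],
                          q_threshold=0.5)
        assert both.counts[0, 0] == 2

    def test_random_hits_match_groupby_oracle(self, rng):
        genes = [f"g{i}" for i in range(6)]
        motifs = [f"m{j}" for j in range(4)]
        rows = [
            (rng.choice(genes), rng.choice(motifs), 0, "+", 1, 1e-5,
             float(rng.uniform(0, 0.1)))
            for _ in range(200)
        ]
        hits = self._hits(rows)
        matrix = count_hits(hits, {g: g for g in genes},
                            {g: "positive" for g in genes}, motifs)
        kept = hits[hits["q"] <= 0.05]
        oracle = kept.groupby(["sequence", "motif"]).size()
        for (g, m), n in oracle.items():
            assert matrix.counts[genes.index(g), motifs.index(m)] == n
        assert matrix.counts.sum() == len(kept)

    def test_all_filtered_gives_zero_matrix(self):
        hits = self._hits([("s1", "M", 1, "+", 5, 1e-2, 0.9)])
        matrix = count_hits(hits, {"s1": "g"}, {"g": "positive"}, ["M"])
        assert matrix.counts.sum() == 0


class TestHitCountMatrix:
    def test_tsv_round_trip(self, tmp_path, rng):
        counts = rng.integers(0, 4, size=(5, 3))
        genes = [f"g{i}" for i in range(5)]
        matrix = mc.HitCountMatrix(
            genes=genes, motifs=["a", "b", "c"], counts=counts,
            labels={g: ("positive" if i < 3 else "negative1")
                    for i, g in enumerate(genes)},
        )
        path = tmp_path / "counts.tsv"
        matrix.write_tsv(path)
        again = mc.HitCountMatrix.read_tsv(path)
        np.testing.assert_array_equal(again.counts, matrix.counts)
        assert again.labels == matrix.labels
        np.testing.assert_array_equal(again.label_array(), [1, 1, 1, 0, 0])

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            mc.HitCountMatrix(["g"], ["m"], np.array([[-1]]), {"g": "positive"})
        with pytest.raises(ValueError):
            mc.HitCountMatrix(["g", "g"], ["m"], np.zeros((2, 1)),
                              {"g": "positive"})
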