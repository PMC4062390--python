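"""Bit-weight matrix construction and promoter scanning."""

import math

import numpy as np
import pytest

from regulonscan.motifs import MotifModel, SiteInstance
from regulonscan.pwm import (
    ScoringMatrix,
    best_hit,
    build_scoring_matrix,
    read_meme,
    scan_threshold,
    score_distribution,
    score_window,
    write_meme,
)
from regulonscan.sequences import revcomp
from regulonscan.simulate import PlantingSpec, make_background, pfm_from_consensus, plant_elements

from conftest import brute_scan, brute_score, random_seq, toy_promoter


def motif_from_counts(counts: np.ndarray) -> MotifModel:
    counts = np.asarray(counts, dtype=float)
    n = int(counts[:, 0].sum())
    sites = [SiteInstance(f"p{i}", 0, "+", "A" * counts.shape[1]) for i in range(max(n, 2))]
    f = (counts + 0.25) / (counts.sum(axis=0) + 1.0)
    return MotifModel(counts.shape[1], sites, counts, f, gamma=0.5)


def pure_matrix(consensus: str) -> ScoringMatrix:
    """Zero-pseudocount matrix that is 1.0 on the consensus base."""
    w = len(consensus)
    counts = np.zeros((4, w))
    counts["ACGT".index("A"), :] = 0
    for l, b in enumerate(consensus):
        counts["ACGT".index(b), l] = 10
    counts[counts == 0] = 1e-12  # all-positive so pseudocount 0 is legal
    m = motif_from_counts(counts)
    return build_scoring_matrix(m, pseudocount=0.0, name="pure")


class TestBuild:
    def test_pure_column_scores_two_bits(self):
        m = pure_matrix("ACGTAC")
        # consensus base weight ~2 bits, max score ~2*width
        assert m.weights.max(axis=0) == pytest.approx(np.full(6, 2.0), abs=1e-6)
        assert m.max_score == pytest.approx(12.0, abs=1e-5)

    def test_uniform_column_is_zero(self):
        counts = np.full((4, 4), 5.0)
        m = build_scoring_matrix(motif_from_counts(counts), pseudocount=0.25)
        assert np.allclose(m.weights, 0.0)
        assert np.allclose(m.info_content, 0.0)

    def test_hand_computed_weights(self):
        # 20 sites, pseudocount 0.25/base, one column (A:18, C:1, G:1, T:0)
        counts = np.zeros((4, 4))
        counts[:, 0] = [18, 1, 1, 0]
        counts[0, 1:] = 20
        m = build_scoring_matrix(motif_from_counts(counts), pseudocount=0.25)
        expect = [2 + math.log2((c + 0.25) / 21.0) for c in (18, 1, 1, 0)]
        assert m.weights[:, 0] == pytest.approx(expect)

    def test_zero_pseudocount_with_zero_counts_rejected(self):
        counts = np.zeros((4, 4))
        counts[0] = 10
        with pytest.raises(ValueError, match="pseudocount"):
            build_scoring_matrix(motif_from_counts(counts), pseudocount=0.0)

    def test_window_too_narrow_rejected(self):
        counts = np.full((4, 8), 5.0)
        with pytest.raises(ValueError, match="width"):
            build_scoring_matrix(motif_from_counts(counts), window=(0, 3))

    def test_weights_bounded_by_two_bits(self, rng):
        counts = rng.integers(0, 50, size=(4, 8)).astype(float)
        m = build_scoring_matrix(motif_from_counts(counts), pseudocount=0.25)
        assert (m.weights <= 2.0 + 1e-12).all()
        assert m.max_score <= 2 * m.width + 1e-9
        assert ((0 <= m.info_content + 1e-9) & (m.info_content <= 2 + 1e-9)).all()


class TestScoreWindow:
    def test_perfect_consensus_scores_two_per_position(self):
        m = pure_matrix("GGCTAAAT")
        assert score_window(m, "GGCTAAAT", "+") == pytest.approx(16.0, abs=1e-5)

    def test_strand_duality(self, rng):
        counts = rng.integers(1, 30, size=(4, 7)).astype(float)
        m = build_scoring_matrix(motif_from_counts(counts))
        for _ in range(50):
            s = random_seq(rng, 7)
            assert score_window(m, s, "-") == pytest.approx(score_window(m, revcomp(s), "+"))

    def test_matches_hand_sum(self, rng):
        counts = rng.integers(1, 30, size=(4, 6)).astype(float)
        m = build_scoring_matrix(motif_from_counts(counts))
        for _ in range(20):
            s = random_seq(rng, 6)
            assert score_window(m, s, "+") == pytest.approx(brute_score(m.weights, s))

    def test_n_window_unscorable(self):
        m = pure_matrix("ACGTAC")
        assert score_window(m, "ACGNAC", "+") is None

    def test_length_mismatch_rejected(self):
        m = pure_matrix("ACGTAC")
        with pytest.raises(ValueError):
            score_window(m, "ACGT", "+")


class TestScan:
    def _random_matrix(self, rng, width=None):
        width = width or int(rng.integers(6, 11))
        counts = rng.integers(0, 40, size=(4, width)).astype(float)
        return build_scoring_matrix(motif_from_counts(counts), pseudocount=0.25)

    def test_best_hit_finds_planted_consensus(self, rng):
        m = pure_matrix("GGCTAAAT")
        bg = random_seq(rng, 300)
        seq = bg[:137] + "GGCTAAAT" + bg[145:]
        hit = best_hit(m, toy_promoter(seq))
        assert (hit.offset, hit.score) == (137, pytest.approx(16.0, abs=1e-5))

    def test_all_n_promoter_has_no_hit(self):
        m = pure_matrix("ACGTAC")
        assert best_hit(m, toy_promoter("N" * 50)) is None

    def test_tie_breaks_to_smallest_offset(self):
        m = pure_matrix("ACGTAC")
        seq = "ACGTAC" + "T" * 30 + "ACGTAC" + "TT"
        hit = best_hit(m, toy_promoter(seq))
        assert (hit.offset, hit.strand) == (0, "+")

    def test_low_threshold_counts_all_windows(self, rng):
        m = self._random_matrix(rng, 6)
        prom = toy_promoter(random_seq(rng, 80))
        hits = scan_threshold(m, prom, -1e9)
        assert len(hits) == 2 * (80 - 6 + 1)

    def test_threshold_above_max_is_empty(self, rng):
        m = self._random_matrix(rng, 6)
        prom = toy_promoter(random_seq(rng, 80))
        assert scan_threshold(m, prom, m.max_score + 0.1) == []

    def test_scan_matches_brute_force(self, rng):
        for _ in range(10):
            m = self._random_matrix(rng)
            prom = toy_promoter(random_seq(rng, 500))
            got = [(h.offset, h.strand, h.score) for h in scan_threshold(m, prom, 6.2)]
            want = brute_scan(m.weights, prom.seq, 6.2)
            assert [(o, s) for o, s, _ in got] == [(o, s) for o, s, _ in want]
            assert np.allclose([s for *_, s in got], [s for *_, s in want])

    def test_best_hit_equals_scan_maximum(self, rng):
        for _ in range(10):
            m = self._random_matrix(rng)
            prom = toy_promoter(random_seq(rng, 200))
            hit = best_hit(m, prom)
            scores = [h.score for h in scan_threshold(m, prom, -1e9)]
            assert hit.score == pytest.approx(max(scores))

    def test_threshold_monotonicity(self, rng):
        m = self._random_matrix(rng)
        prom = toy_promoter(random_seq(rng, 400))
        counts = [len(scan_threshold(m, prom, t)) for t in np.linspace(-5, m.max_score, 12)]
        assert counts == sorted(counts, reverse=True)

    def test_revcomp_duality_of_hit_list(self, rng):
        m = self._random_matrix(rng, 8)
        seq = random_seq(rng, 150)
        fwd = scan_threshold(m, toy_promoter(seq), 4.0)
        rev = scan_threshold(m, toy_promoter(revcomp(seq)), 4.0)
        L, w = len(seq), 8
        mirrored = sorted(
            (L - h.offset - w, "-" if h.strand == "+" else "+", round(h.score, 6))
            for h in fwd
        )
        got = sorted((h.offset, h.strand, round(h.score, 6)) for h in rev)
        assert got == mirrored

    def test_atg_position_is_offset_minus_length(self, rng):
        m = self._random_matrix(rng, 6)
        prom = toy_promoter(random_seq(rng, 100))
        for h in scan_threshold(m, prom, -1e9)[:20]:
            assert h.atg_position == h.offset - 100


class TestScoreDistribution:
    def test_rows_match_best_hits(self, rng):
        m = pure_matrix("GGCTAAAT")
        proms = [toy_promoter(random_seq(rng, 60), f"g{i}") for i in range(3)]
        table = score_distribution(m, proms)
        assert len(table) == 3
        for _, row in table.iterrows():
            prom = next(p for p in proms if p.gene_id == row.promoter_id)
            assert row.best_score == pytest.approx(best_hit(m, prom).score)

    def test_unscorable_promoters_filtered(self, rng):
        m = pure_matrix("ACGTAC")
        proms = [toy_promoter(random_seq(rng, 60), "ok"), toy_promoter("N" * 60, "allN")]
        table = score_distribution(m, proms)
        assert list(table.promoter_id) == ["ok"]

    def test_planted_foreground_dominates_background(self):
        from scipy.stats import mannwhitneyu

        pfm = pfm_from_consensus("GGCTAAAT", 0.95)
        matrix = ScoringMatrix("truth", 2 + np.log2(pfm), pfm)
        bg = make_background(40, 400, seed=5)
        fg0 = make_background(40, 400, seed=6)
        fg, _ = plant_elements(fg0, PlantingSpec(pfm, "single_zoops", planting_fraction=1.0, seed=7))
        s_fg = score_distribution(matrix, fg)["best_score"]
        s_bg = score_distribution(matrix, bg)["best_score"]
        stat = mannwhitneyu(s_fg, s_bg, alternative="greater")
        assert stat.pvalue < 1e-6


class TestMemeFormat:
    def test_round_trip(self, tmp_path, rng):
        counts = rng.integers(1, 30, size=(4, 8)).astype(float)
        m = build_scoring_matrix(motif_from_counts(counts), name="M1")
        path = tmp_path / "m.meme"
        write_meme([m], path)
        (back,) = read_meme(path)
        assert back.name == "M1"
        assert np.allclose(back.freqs, m.freqs, atol=1e-5)
        assert np.allclose(back.weights, m.weights, atol=1e-3)
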