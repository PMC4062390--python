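"""ZOOPS EM discovery, consensus matching and motif merging."""

import numpy as np
import pytest

from regulonscan.motifs import (
    MotifModel,
    SiteInstance,
    discover_motifs,
    match_consensus,
    merge_motifs,
    read_sites_tsv,
    seed_pfms,
    write_sites_tsv,
    zoops_em,
)
from regulonscan.sequences import IUPAC, revcomp
from regulonscan.simulate import PlantingSpec, make_background, pfm_from_consensus, plant_elements

from conftest import toy_promoter


def run_em_best(promoters, width, k=5, **kw):
    best = None
    for pfm in seed_pfms(promoters, width, k=k):
        m = zoops_em(promoters, width, pfm, **kw)
        if best is None or m.llr > best.llr:
            best = m
    return best


def planted_set(consensus, n=100, length=200, sharpness=0.9, seed=11, fraction=1.0):
    pfm = pfm_from_consensus(consensus, sharpness)
    proms = make_background(n, length, seed=seed)
    return plant_elements(
        proms, PlantingSpec(pfm, "single_zoops", planting_fraction=fraction, seed=seed + 1)
    )


class TestZoopsEm:
    def test_recovers_planted_consensus_and_positions(self):
        planted, truth = planted_set("GGCTAATA", n=100, length=200)
        motif = run_em_best(planted, 8)
        assert motif.consensus == "GGCTAATA"
        tpos = {t.promoter_id: t.offsets[0] for t in truth}
        exact = sum(1 for s in motif.sites if tpos.get(s.promoter_id) == s.offset)
        assert exact / len(truth) >= 0.7

    def test_gamma_small_on_pure_noise(self):
        gammas = []
        for seed in range(5):
            proms = make_background(80, 300, seed=500 + seed)
            motif = run_em_best(proms, 8, k=3)
            gammas.append(motif.gamma)
        assert np.mean(gammas) < 0.5

    def test_single_window_degenerate_case(self):
        prom = toy_promoter("GGCTAATA")
        pfm = pfm_from_consensus("GGCTAATA", 0.7)
        motif = zoops_em([prom], 8, pfm)
        assert len(motif.sites) == 1
        assert (motif.sites[0].offset, motif.sites[0].strand) == (0, "+")
        # gamma approaches its prior-limited upper bound n/(n + b - 1)
        assert motif.gamma > 0.8

    def test_width_longer_than_promoter_rejected(self):
        with pytest.raises(ValueError, match="width"):
            zoops_em([toy_promoter("ACGT")], 6, np.full((4, 6), 0.25))

    def test_degenerate_init_rejected(self):
        pfm = np.full((4, 6), 0.25)
        pfm[:, 2] = [1.0, 0.0, 0.0, 0.0]
        with pytest.raises(ValueError, match="init"):
            zoops_em([toy_promoter("ACGTACGTACGT")], 6, pfm)

    def test_strand_symmetry(self):
        """Reverse-complementing every promoter leaves the motif invariant.

        The ZOOPS model scores both strands and seeds are revcomp-canonical,
        so the recovered motif is the same up to orientation, and each
        hard-assigned site maps to the mirrored window on the flipped set.
        """
        planted, _ = planted_set("GGCTAATA", n=60, length=150, seed=21)
        fwd = run_em_best(planted, 8, k=3)
        flipped = [toy_promoter(revcomp(p.seq), p.gene_id) for p in planted]
        rev = run_em_best(flipped, 8, k=3)
        assert rev.consensus in (fwd.consensus, revcomp(fwd.consensus))
        L, w = 150, 8
        fwd_sites = {(s.promoter_id, s.offset) for s in fwd.sites}
        rev_sites = {(s.promoter_id, L - s.offset - w) for s in rev.sites}
        overlap = len(fwd_sites & rev_sites) / max(1, len(fwd_sites))
        assert overlap >= 0.9

    def test_gamma_tracks_planting_fraction(self):
        """Recovery and gamma are non-decreasing in the planting rate."""
        gammas = []
        for fraction in (0.2, 0.5, 0.9):
            planted, _ = planted_set(
                "GGCTAATA", n=80, length=150, seed=31, fraction=fraction
            )
            gammas.append(run_em_best(planted, 8, k=3).gamma)
        assert gammas == sorted(gammas)


class TestDiscoverMotifs:
    def test_two_disjoint_motifs_recovered(self):
        pfm1 = pfm_from_consensus("GGCTAATA", 0.95)
        pfm2 = pfm_from_consensus("TCCGACGG", 0.95)
        a = make_background(40, 150, seed=41, id_prefix="a")
        b = make_background(40, 150, seed=42, id_prefix="b")
        a, _ = plant_elements(a, PlantingSpec(pfm1, "single_zoops", planting_fraction=1.0, seed=43))
        b, _ = plant_elements(b, PlantingSpec(pfm2, "single_zoops", planting_fraction=1.0, seed=44))
        found = discover_motifs(a + b, width_range=(8, 8), n_motifs=3, seeds_per_width=5)
        consensi = {m.consensus for m in found} | {revcomp(m.consensus) for m in found}
        assert "GGCTAATA" in consensi
        assert "TCCGACGG" in consensi

    def test_n_motifs_one_returns_one(self):
        planted, _ = planted_set("GGCTAATA", n=30, length=120, seed=51)
        found = discover_motifs(planted, width_range=(8, 8), n_motifs=1, seeds_per_width=3)
        assert len(found) == 1

    def test_all_n_input_yields_nothing(self):
        proms = [toy_promoter("N" * 100, f"g{i}") for i in range(5)]
        assert discover_motifs(proms, width_range=(6, 6), n_motifs=2) == []

    def test_masking_soundness(self):
        """No later motif's site overlaps an earlier motif's masked window."""
        planted, _ = planted_set("GGCTAATA", n=40, length=150, seed=61)
        found = discover_motifs(planted, width_range=(8, 8), n_motifs=3, seeds_per_width=3)
        claimed: dict[str, list[tuple[int, int]]] = {}
        for motif in found:
            for s in motif.sites:
                span = (s.offset, s.offset + motif.width)
                for lo, hi in claimed.get(s.promoter_id, []):
                    assert not (span[0] < hi and lo < span[1])
            for s in motif.sites:
                claimed.setdefault(s.promoter_id, []).append((s.offset, s.offset + motif.width))

    def test_recovery_nondecreasing_in_planting_fraction(self):
        """Detection power grows with the planting rate at fixed sharpness:
        at 10% planting the motif is not found at all, at higher rates an
        increasing share of planted sites is recovered exactly."""
        rates = []
        for fraction in (0.1, 0.4, 0.9):
            planted, truth = planted_set(
                "GGCTAATA", n=80, length=300, sharpness=0.85, seed=71, fraction=fraction
            )
            motif = run_em_best(planted, 8, k=3)
            tpos = {t.promoter_id: t.offsets[0] for t in truth}
            exact = sum(1 for s in motif.sites if tpos.get(s.promoter_id) == s.offset)
            rates.append(exact / max(1, len(truth)))
        assert rates[0] <= rates[1] + 0.05 and rates[1] <= rates[2] + 0.05


class TestMatchConsensus:
    def _motif(self, consensus):
        pfm = pfm_from_consensus(consensus, 0.9)
        counts = pfm * 100
        sites = [SiteInstance("p1", 0, "+", consensus), SiteInstance("p2", 0, "+", consensus)]
        return MotifModel(len(consensus), sites, counts, pfm, gamma=0.5)

    def test_exact_iupac_match(self):
        sim, offset, strand = match_consensus(self._motif("GGCTAA"), "GGCWWW")
        assert (sim, offset, strand) == (1.0, 0, "+")

    def test_revcomp_match(self):
        sim, offset, strand = match_consensus(self._motif("TTAGCC"), "GGCWWW")
        assert (sim, strand) == (1.0, "-")

    def test_matches_brute_force_enumeration(self, rng):
        pattern = "GGCWWW"
        for _ in range(20):
            consensus = "".join(rng.choice(list("ACGT"), size=8))
            motif = self._motif(consensus)
            best = -1.0
            for cons in (consensus, revcomp(consensus)):
                for off in range(len(cons) - len(pattern) + 1):
                    sim = sum(
                        cons[off + i] in IUPAC[c] for i, c in enumerate(pattern)
                    ) / len(pattern)
                    best = max(best, sim)
            assert match_consensus(motif, pattern)[0] == pytest.approx(best)

    def test_pattern_longer_than_motif_rejected(self):
        with pytest.raises(ValueError):
            match_consensus(self._motif("GGCTAA"), "GGCWWWGG")


class TestMergeMotifs:
    def _em_motif(self, seed=81):
        planted, _ = planted_set("GGCTAATA", n=40, length=120, seed=seed)
        return run_em_best(planted, 8, k=3)

    def test_self_merge_doubles_sites_keeps_freqs(self):
        m = self._em_motif()
        merged = merge_motifs(m, m)
        assert merged.width == m.width
        assert len(merged.sites) == 2 * len(m.sites)
        # frequency shift only from pseudocount shrink at doubled counts
        assert np.allclose(merged.freqs, m.freqs, atol=0.02)

    def test_shared_core_survives_merge(self):
        """Two variants sharing a GGC core keep it after IC-maximal merging."""
        a, _ = planted_set("GGCTAATA", n=40, length=120, seed=91)
        b, _ = planted_set("GGCTATTC", n=40, length=120, seed=95)
        m1 = run_em_best(a, 8, k=3)
        m2 = run_em_best(b, 8, k=3)
        merged = merge_motifs(m1, m2)
        assert merged.consensus[:5] == "GGCTA"

    def test_insufficient_overlap_rejected(self):
        m = self._em_motif()
        with pytest.raises(ValueError, match="overlap"):
            merge_motifs(m, m, min_overlap=9)

    def test_merged_sites_regenerate_from_promoters(self):
        """Trimmed/re-oriented site coordinates still match their subsequences."""
        planted, _ = planted_set("GGCTAATA", n=40, length=120, seed=101)
        by_id = {p.gene_id: p.seq for p in planted}
        m = run_em_best(planted, 8, k=3)
        merged = merge_motifs(m, m)
        for s in merged.sites:
            window = by_id[s.promoter_id][s.offset : s.offset + merged.width]
            assert s.subseq == (window if s.strand == "+" else revcomp(window))


class TestSiteListIO:
    def test_round_trip(self, tmp_path):
        planted, _ = planted_set("GGCTAATA", n=30, length=120, seed=111)
        motif = run_em_best(planted, 8, k=3)
        path = tmp_path / "sites.tsv"
        write_sites_tsv(motif, path)
        back = read_sites_tsv(path)
        assert [(s.promoter_id, s.offset, s.strand, s.subseq) for s in back.sites] == [
            (s.promoter_id, s.offset, s.strand, s.subseq) for s in motif.sites
        ]
        assert np.array_equal(back.counts, motif.counts)
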