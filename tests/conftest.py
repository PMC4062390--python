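"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from regulonscan.genome_io import PromoterRecord
from regulonscan.sequences import revcomp


def toy_promoter(seq: str, gene_id: str = "g1") -> PromoterRecord:
    return PromoterRecord(gene_id, seq, False, (f"{gene_id}_contig", 1, len(seq), "+"))


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


# --- independent brute-force scorer (double loop, no numpy vectorization) --

def brute_score(weights: np.ndarray, window: str) -> float | None:
    """Position-by-position hand sum; None if the window contains N."""
    total = 0.0
    for l, base in enumerate(window):
        if base == "N":
            return None
        total += weights["ACGT".index(base), l]
    return total


def brute_scan(weights: np.ndarray, seq: str, threshold: float) -> list[tuple[int, str, float]]:
    """All (offset, strand, score) with score >= threshold, offset-sorted."""
    w = weights.shape[1]
    out = []
    for offset in range(len(seq) - w + 1):
        window = seq[offset : offset + w]
        for strand in "+-":
            s = brute_score(weights, window if strand == "+" else revcomp(window))
            if s is not None and s >= threshold:
                out.append((offset, strand, s))
    return out


def brute_best(weights: np.ndarray, seq: str) -> tuple[int, str, float] | None:
    """Max-scoring window; ties to smallest offset then + strand."""
    best = None
    w = weights.shape[1]
    for offset in range(len(seq) - w + 1):
        window = seq[offset : offset + w]
        for strand in "+-":
            s = brute_score(weights, window if strand == "+" else revcomp(window))
            if s is not None and (best is None or s > best[2]):
                best = (offset, strand, s)
    return best


def brute_pairs(hits, allowed, gap_min, gap_max, threshold):
    """Exhaustive O(n^2) ordered-pair enumeration (the architecture oracle)."""
    from regulonscan.architecture import classify_pair

    kept = [h for h in hits if h.score >= threshold]
    out = []
    for up in kept:
        for down in kept:
            if down.offset <= up.offset:
                continue
            gap = down.offset - (up.offset + up.width)
            if gap_min <= gap <= gap_max:
                orient = classify_pair(up.strand, down.strand)
                if orient in allowed:
                    out.append((up.offset, up.strand, down.offset, down.strand, orient, gap))
    return sorted(out)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
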