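"""Information-content position weight matrices and promoter scanning.

A scoring matrix assigns each base ``b`` at column ``l`` the weight

    w(b, l) = 2 + log2 f(b, l)        (bits)

where ``f`` is the pseudocounted base frequency from the aligned sites.  A
window's score is the sum over columns, so a perfect consensus on a pure
(zero-pseudocount) matrix scores exactly ``2 * width`` bits and a uniform
column contributes 0.  Per-column information content is
``R(l) = 2 + sum_b f(b,l) * log2 f(b,l)``.

Weights are information relative to a uniform background; an optional
log-odds mode divides out a supplied background composition instead.
Windows containing N are unscorable and skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .sequences import N_CODE, encode, revcomp

logger = logging.getLogger(__name__)

UNSCORABLE = None  # sentinel returned by score_window for N-containing windows


@dataclass
class SiteHit:
    """One scored motif occurrence on a promoter.

    ``offset`` is the 0-based start of the motif-forward window within the
    promoter; ``atg_position`` the ATG-relative start (offset - promoter
    length, always negative).  ``strand`` '-' means the motif matches the
    reverse complement of the window.
    """

    promoter_id: str
    offset: int
    strand: str
    score: float
    width: int
    atg_position: int


@dataclass
class ScoringMatrix:
    """Per-position, per-base bit weights; scores windows on either strand."""

    name: str
    weights: np.ndarray  # 4 x width, bits
    freqs: np.ndarray    # 4 x width, the pseudocounted frequencies behind weights

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.weights.shape != self.freqs.shape or self.weights.shape[0] != 4:
            raise ValueError("weights/freqs must be 4 x width and congruent")

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=0).sum())

    @property
    def info_content(self) -> np.ndarray:
        """Per-column R(l) = 2 + sum_b f log2 f, in bits."""
        f = self.freqs
        return 2.0 + (f * np.log2(f)).sum(axis=0)

    @property
    def total_info(self) -> float:
        return float(self.info_content.sum())

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.freqs.argmax(axis=0))

    def revcomp_weights(self) -> np.ndarray:
        """Weight matrix scoring the - strand on forward-encoded sequence."""
        return self.weights[::-1, ::-1]


def build_scoring_matrix(
    motif,
    window: tuple[int, int] | None = None,
    pseudocount: float = 0.25,
    name: str | None = None,
    background: Sequence[float] | None = None,
) -> ScoringMatrix:
    """Build a bit-weight matrix from a motif's count matrix.

    ``window`` is a half-open column range within the motif (default: full
    width); the resulting width must be >= 4.  ``pseudocount`` is added per
    base per column; it must be positive whenever any windowed count is zero.
    With ``background`` given, weights become log-odds log2(f/bg) instead of
    the default information weights 2 + log2 f.
    """
    counts = np.asarray(motif.counts, dtype=float)
    if counts.sum() == 0:
        raise ValueError("motif has an empty site set")
    if window is not None:
        lo, hi = window
        if not (0 <= lo < hi <= counts.shape[1]):
            raise ValueError(f"window {window} outside motif width {counts.shape[1]}")
        counts = counts[:, lo:hi]
    if counts.shape[1] < 4:
        raise ValueError("scoring matrix width must be >= 4")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount == 0 and (counts == 0).any():
        raise ValueError("zero pseudocount requires strictly positive counts")
    f = (counts + pseudocount) / (counts.sum(axis=0) + 4 * pseudocount)
    with np.errstate(divide="ignore"):
        if background is None:
            w = 2.0 + np.log2(f)
        else:
            bg = np.asarray(background, dtype=float).reshape(4, 1)
            w = np.log2(f) - np.log2(bg)
    return ScoringMatrix(name or getattr(motif, "source_label", "pwm"), w, f)


def score_window(matrix: ScoringMatrix, seq_window: str, strand: str = "+") -> float | None:
    """Score one window; strand '-' scores its reverse complement.

    Returns ``None`` (unscorable) if the window contains N.
    """
    if len(seq_window) != matrix.width:
        raise ValueError(
            f"window length {len(seq_window)} != matrix width {matrix.width}"
        )
    if strand == "-":
        seq_window = revcomp(seq_window)
    codes = encode(seq_window)
    if (codes == N_CODE).any():
        return UNSCORABLE
    return float(matrix.weights[codes, np.arange(matrix.width)].sum())


def _window_scores(matrix: ScoringMatrix, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-offset scores on both strands; NaN where unscorable."""
    w = matrix.width
    n_off = len(codes) - w + 1
    if n_off <= 0:
        return np.empty(0), np.empty(0)
    fwd = np.zeros(n_off)
    rev = np.zeros(n_off)
    bad = np.zeros(n_off, dtype=bool)
    wt, wt_rc = matrix.weights, matrix.revcomp_weights()
    safe = np.where(codes == N_CODE, 0, codes)
    for l in range(w):
        col = safe[l : l + n_off]
        fwd += wt[col, l]
        rev += wt_rc[col, l]
        bad |= codes[l : l + n_off] == N_CODE
    fwd[bad] = np.nan
    rev[bad] = np.nan
    return fwd, rev


def _promoter_codes(promoter) -> np.ndarray:
    cached = getattr(promoter, "_codes", None)
    if cached is None:
        cached = encode(promoter.seq)
        try:
            promoter._codes = cached
        except AttributeError:
            pass
    return cached


def best_hit(matrix: ScoringMatrix, promoter) -> SiteHit | None:
    """Best-scoring window over all offsets and both strands.

    Ties break toward the smallest offset, then the + strand.  Returns
    ``None`` if the promoter is shorter than the matrix or every window is
    unscorable.
    """
    L = len(promoter.seq)
    if L < matrix.width:
        logger.warning(
            "promoter %s shorter than matrix width %d", promoter.gene_id, matrix.width
        )
        return None
    fwd, rev = _window_scores(matrix, _promoter_codes(promoter))
    both = np.concatenate([fwd, rev])
    if np.isnan(both).all():
        return None
    # offset-major, + before - at equal offset, so interleave for the tie rule
    stacked = np.empty((len(fwd), 2))
    stacked[:, 0] = fwd
    stacked[:, 1] = rev
    flat = np.nan_to_num(stacked, nan=-np.inf).ravel()
    k = int(flat.argmax())
    offset, s = divmod(k, 2)
    strand = "+" if s == 0 else "-"
    return SiteHit(
        promoter.gene_id, offset, strand, float(stacked[offset, s]),
        matrix.width, offset - L,
    )


def scan_threshold(matrix: ScoringMatrix, promoter, threshold: float) -> list[SiteHit]:
    """All windows scoring >= threshold on either strand, sorted by offset.

    Overlapping hits are all reported; any architecture filtering happens
    downstream.  At equal offset the + strand hit precedes the - one.
    """
    L = len(promoter.seq)
    if L < matrix.width:
        return []
    fwd, rev = _window_scores(matrix, _promoter_codes(promoter))
    hits: list[SiteHit] = []
    with np.errstate(invalid="ignore"):
        fmask = fwd >= threshold
        rmask = rev >= threshold
    for offset in np.nonzero(fmask | rmask)[0]:
        off = int(offset)
        if fmask[off]:
            hits.append(SiteHit(promoter.gene_id, off, "+", float(fwd[off]), matrix.width, off - L))
        if rmask[off]:
            hits.append(SiteHit(promoter.gene_id, off, "-", float(rev[off]), matrix.width, off - L))
    return hits


def score_distribution(matrix: ScoringMatrix, promoter_set: Iterable) -> "pd.DataFrame":
    """Best-hit score per promoter (one row per scorable promoter)."""
    import pandas as pd

    rows = []
    for prom in promoter_set:
        hit = best_hit(matrix, prom)
        if hit is not None:
            rows.append((prom.gene_id, hit.score))
    return pd.DataFrame(rows, columns=["promoter_id", "best_score"])


# --- matrix serialization -------------------------------------------------

def write_meme(matrices: Sequence[ScoringMatrix], path, background: Sequence[float] = (0.25,) * 4) -> None:
    """Write minimal MEME-format motif file (letter-probability matrices)."""
    lines = [
        "MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", "",
        "Background letter frequencies",
        "A {:.5f} C {:.5f} G {:.5f} T {:.5f}".format(*background), "",
    ]
    for m in matrices:
        lines.append(f"MOTIF {m.name}")
        lines.append(f"letter-probability matrix: alength= 4 w= {m.width} nsites= 20 E= 0")
        for l in range(m.width):
            lines.append(" ".join(f"{m.freqs[b, l]:.6f}" for b in range(4)))
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_meme(path) -> list[ScoringMatrix]:
    """Read matrices back from minimal MEME format (frequencies -> weights)."""
    matrices: list[ScoringMatrix] = []
    name: str | None = None
    rows: list[list[float]] = []

    def _flush() -> None:
        if name is not None and rows:
            f = np.array(rows).T  # width x 4 -> 4 x width
            f = np.clip(f, 1e-9, None)
            f /= f.sum(axis=0)
            matrices.append(ScoringMatrix(name, 2.0 + np.log2(f), f))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                _flush()
                name = line.split()[1]
                rows = []
            elif name is not None and line and line[0] in "0123456789.":
                vals = [float(x) for x in line.split()]
                if len(vals) == 4:
                    rows.append(vals)
    _flush()
    return matrices


def write_weights_tsv(matrix: ScoringMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tA\tC\tG\tT\tinfo_bits\n")
        info = matrix.info_content
        for l in range(matrix.width):
            cells = "\t".join(f"{matrix.weights[b, l]:.4f}" for b in range(4))
            fh.write(f"{l + 1}\t{cells}\t{info[l]:.4f}\n")
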