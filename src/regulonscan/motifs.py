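"""De novo discovery of short ungapped motifs under a ZOOPS model.

ZOOPS ("zero or one occurrence per sequence") assumes every promoter
contains at most one instance of the motif, on either strand.  The latent
variable for a sequence of length ``L`` and motif width ``w`` ranges over
{absent} plus the ``2 * (L - w + 1)`` (position, strand) placements, with a
uniform position prior given presence.  EM alternates:

* E-step: posterior responsibility of each placement against an order-0
  background estimated once from the input set;
* M-step: responsibility-weighted base counts (+0.25 pseudocount per base
  per column) re-estimate the frequency matrix, and the mean presence
  posterior re-estimates gamma, the prior probability that a sequence
  carries a site.

The observed-data log-likelihood (relative to the all-background null) is
non-decreasing across iterations; this is asserted on every run.  Multiple
motifs come from iterative masking: the hard-assigned sites of each motif
are replaced by N before the next round.  Runs are deterministic: EM starts
are enumerated from the most over-represented w-mers, not sampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .sequences import IUPAC, N_CODE, encode, revcomp

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 0.25  # per base per column, responsibility-weighted counts


@dataclass
class SiteInstance:
    """One aligned motif occurrence, oriented motif-forward."""

    promoter_id: str
    offset: int   # 0-based start within the promoter, forward coordinates
    strand: str
    subseq: str   # motif-forward (revcomp of the window when strand is '-')


@dataclass
class MotifModel:
    """An aligned site set with its count/frequency matrices.

    ``gamma`` is the fitted prior probability that a promoter contains a
    site; ``llr`` the final ZOOPS log-likelihood ratio over the
    all-background null (natural log), used for ranking.
    """

    width: int
    sites: list[SiteInstance]
    counts: np.ndarray            # 4 x width, from the hard-assigned sites
    freqs: np.ndarray             # 4 x width, pseudocounted, columns sum to 1
    gamma: float
    source_label: str = "motif"
    llr: float = 0.0

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.freqs.argmax(axis=0))

    @property
    def info_content(self) -> np.ndarray:
        f = self.freqs
        return 2.0 + (f * np.log2(f)).sum(axis=0)


def _counts_from_sites(sites: list[SiteInstance], width: int) -> np.ndarray:
    counts = np.zeros((4, width))
    for s in sites:
        codes = encode(s.subseq)
        for l, c in enumerate(codes):
            if c != N_CODE:
                counts[c, l] += 1
    return counts


def _freqs_from_counts(counts: np.ndarray, pseudocount: float = PSEUDOCOUNT) -> np.ndarray:
    return (counts + pseudocount) / (counts.sum(axis=0) + 4 * pseudocount)


def background_composition(promoters) -> np.ndarray:
    """Order-0 base composition of a promoter set (N excluded)."""
    counts = np.zeros(4)
    for p in promoters:
        codes = encode(p.seq)
        counts += np.bincount(codes[codes != N_CODE], minlength=4)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def _placement_log_odds(codes: np.ndarray, log_ratio: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-offset log(motif/background) for both strands; -inf where N."""
    n_off = len(codes) - w + 1
    if n_off <= 0:
        return np.empty(0), np.empty(0)
    fwd = np.zeros(n_off)
    rev = np.zeros(n_off)
    bad = np.zeros(n_off, dtype=bool)
    lr_rc = log_ratio[::-1, ::-1]
    safe = np.where(codes == N_CODE, 0, codes)
    for l in range(w):
        col = safe[l : l + n_off]
        fwd += log_ratio[col, l]
        rev += lr_rc[col, l]
        bad |= codes[l : l + n_off] == N_CODE
    fwd[bad] = -np.inf
    rev[bad] = -np.inf
    return fwd, rev


def zoops_em(
    promoters,
    width: int,
    init_pfm: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int | None = None,
    background: np.ndarray | None = None,
    presence_threshold: float = 0.5,
    gamma0: float = 0.5,
    presence_prior_weight: float = 0.1,
    source_label: str = "motif",
) -> MotifModel:
    """Fit one ZOOPS motif by EM from a given initial frequency matrix.

    ``seed`` is accepted for interface symmetry; the algorithm itself is
    deterministic given the initialization.  Raises if the motif is wider
    than the shortest promoter or the init matrix has non-positive entries.

    ``presence_prior_weight`` sets a weak Beta(1, 1 + weight*n) prior on
    gamma.  Without it the all-background fixed point is unstable: a motif
    that collapses to the background composition gives every sequence a
    likelihood ratio near 1, the presence posterior then equals the prior
    gamma, and gamma ratchets toward 1 on pure noise.  The prior biases
    gamma down by at most ~weight but lets it fall to ~0 when no motif
    structure exists; with real sites the data term dominates entirely.
    """
    init_pfm = np.asarray(init_pfm, dtype=float)
    if init_pfm.shape != (4, width):
        raise ValueError(f"init_pfm must be 4 x {width}")
    if (init_pfm <= 0).any():
        raise ValueError("init_pfm entries must all be positive (degenerate init)")
    shortest = min(len(p.seq) for p in promoters)
    if width > shortest:
        raise ValueError(f"width {width} exceeds shortest promoter ({shortest} bp)")
    if background is None:
        background = background_composition(promoters)
    log_bg = np.log(np.clip(background, 1e-9, None)).reshape(4, 1)

    encoded = [encode(p.seq) for p in promoters]
    freqs = init_pfm / init_pfm.sum(axis=0)
    gamma = float(gamma0)
    prev_obj = -np.inf
    ll = -np.inf

    for _ in range(max_iter):
        log_ratio = np.log(freqs) - log_bg
        weighted = np.zeros((4, width))
        presence = np.zeros(len(encoded))
        ll = 0.0
        for i, codes in enumerate(encoded):
            fwd, rev = _placement_log_odds(codes, log_ratio, width)
            n_off = len(fwd)
            if n_off == 0:
                continue
            odds = np.concatenate([fwd, rev])
            finite = np.isfinite(odds)
            if gamma > 0 and finite.any():
                m = odds[finite].max()
                s = np.exp(odds[finite] - m).sum()
                # log[(1-gamma) + gamma/(2m) * sum exp(odds)]
                log_mix = np.logaddexp(
                    np.log1p(-gamma) if gamma < 1 else -np.inf,
                    np.log(gamma / (2 * n_off)) + m + np.log(s),
                )
            else:
                log_mix = np.log1p(-gamma) if gamma < 1 else -np.inf
            ll += log_mix
            # responsibilities
            r = np.zeros(2 * n_off)
            if gamma > 0 and finite.any():
                r[finite] = np.exp(np.log(gamma / (2 * n_off)) + odds[finite] - log_mix)
            presence[i] = r.sum()
            # accumulate weighted counts over placements
            r_fwd, r_rev = r[:n_off], r[n_off:]
            safe = np.where(codes == N_CODE, 0, codes)
            valid = codes != N_CODE
            for l in range(width):
                col = safe[l : l + n_off]
                v = valid[l : l + n_off]
                np.add.at(weighted[:, l], col[v], r_fwd[v])
                # '-' placement at offset o covers base o+w-1-l at motif col l, complemented
                col_r = 3 - safe[width - 1 - l : width - 1 - l + n_off]
                v_r = valid[width - 1 - l : width - 1 - l + n_off]
                np.add.at(weighted[:, l], col_r[v_r], r_rev[v_r])
        # the pseudocounted M-step and the Beta prior on gamma make this MAP
        # EM, so the monotone quantity is the penalized objective, not the
        # bare LL
        prior_b = 1.0 + presence_prior_weight * len(encoded)
        obj = ll + PSEUDOCOUNT * float(np.log(freqs).sum())
        if prior_b > 1.0:
            obj += (prior_b - 1.0) * float(np.log1p(-gamma))
        if obj < prev_obj - 1e-9:
            raise AssertionError(
                f"ZOOPS EM objective decreased: {prev_obj:.6f} -> {obj:.6f}"
            )
        if np.isfinite(prev_obj) and obj - prev_obj < tol:
            break
        prev_obj = obj
        freqs = _freqs_from_counts(weighted)
        gamma = float(presence.sum() / (len(encoded) + prior_b - 1.0))

    # hard assignment: sequences with presence posterior > threshold
    log_ratio = np.log(freqs) - log_bg
    sites: list[SiteInstance] = []
    for prom, codes in zip(promoters, encoded):
        fwd, rev = _placement_log_odds(codes, log_ratio, width)
        n_off = len(fwd)
        if n_off == 0:
            continue
        odds = np.concatenate([fwd, rev])
        finite = np.isfinite(odds)
        if not finite.any() or gamma <= 0:
            continue
        m = odds[finite].max()
        s = np.exp(odds[finite] - m).sum()
        log_site_mass = np.log(gamma / (2 * n_off)) + m + np.log(s)
        log_absent = np.log1p(-gamma) if gamma < 1 else -np.inf
        log_mix = np.logaddexp(log_absent, log_site_mass)
        if np.exp(log_site_mass - log_mix) <= presence_threshold:
            continue
        k = int(np.nanargmax(np.where(finite, odds, -np.inf)))
        if k < n_off:
            offset, strand = k, "+"
            sub = prom.seq[offset : offset + width]
        else:
            offset, strand = k - n_off, "-"
            sub = revcomp(prom.seq[offset : offset + width])
        sites.append(SiteInstance(prom.gene_id, offset, strand, sub))

    counts = _counts_from_sites(sites, width)
    return MotifModel(
        width=width,
        sites=sites,
        counts=counts,
        freqs=_freqs_from_counts(counts) if sites else freqs,
        gamma=gamma,
        source_label=source_label,
        llr=float(ll),
    )


def seed_pfms(promoters, width: int, k: int = 20, background: np.ndarray | None = None) -> list[np.ndarray]:
    """Initial PFMs from the k most over-represented w-mers.

    Over-representation is observed count (both strands, revcomp-canonical)
    versus the order-0 background expectation.  Each seed w-mer is softened
    to 0.7 on its own base and 0.1 elsewhere.
    """
    if background is None:
        background = background_composition(promoters)
    counts: dict[str, int] = {}
    total_windows = 0
    for p in promoters:
        seq = p.seq
        for i in range(len(seq) - width + 1):
            wmer = seq[i : i + width]
            if "N" in wmer:
                continue
            total_windows += 1
            canonical = min(wmer, revcomp(wmer))
            counts[canonical] = counts.get(canonical, 0) + 1
    if not counts:
        return []
    log_bg = np.log(np.clip(background, 1e-9, None))

    def expectation(wmer: str) -> float:
        codes = encode(wmer)
        p_f = float(np.exp(log_bg[codes].sum()))
        p_r = float(np.exp(log_bg[encode(revcomp(wmer))].sum()))
        return total_windows * (p_f + p_r)

    ranked = sorted(
        counts, key=lambda w: (-counts[w] / expectation(w), w)
    )[:k]
    pfms = []
    for wmer in ranked:
        pfm = np.full((4, width), 0.1)
        pfm[encode(wmer), np.arange(width)] = 0.7
        pfms.append(pfm)
    return pfms


@dataclass
class _Masked:
    """Lightweight promoter view used during iterative masking."""

    gene_id: str
    seq: str


def discover_motifs(
    promoters,
    width_range: tuple[int, int] = (6, 10),
    n_motifs: int = 10,
    seeds_per_width: int = 5,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
    min_llr: float = 0.0,
) -> list[MotifModel]:
    """Discover up to ``n_motifs`` motifs per width by EM with masking.

    For each width, seed PFMs are enumerated from over-represented w-mers;
    the best EM run by final likelihood ratio is kept, its hard-assigned
    sites masked with N, and the search repeated until ``n_motifs`` are
    found or no run beats the null.  All widths' motifs are pooled and
    sorted by likelihood ratio, descending.
    """
    if n_motifs < 1:
        raise ValueError("n_motifs must be >= 1")
    results: list[MotifModel] = []
    run_counter = seed
    for width in range(width_range[0], width_range[1] + 1):
        working = [_Masked(p.gene_id, p.seq) for p in promoters]
        if min(len(p.seq) for p in working) < width:
            continue
        background = background_composition(working)
        for round_idx in range(n_motifs):
            pfms = seed_pfms(working, width, k=seeds_per_width, background=background)
            if not pfms:
                break
            best: MotifModel | None = None
            for pfm in pfms:
                run_counter += 1
                try:
                    motif = zoops_em(
                        working, width, pfm, max_iter=max_iter, tol=tol,
                        seed=run_counter, background=background,
                        source_label=f"w{width}-m{round_idx + 1}",
                    )
                except (ValueError, AssertionError) as exc:
                    logger.warning("EM run skipped: %s", exc)
                    continue
                if best is None or motif.llr > best.llr:
                    best = motif
            if best is None or best.llr <= min_llr or len(best.sites) < 2:
                break
            results.append(best)
            # mask the found sites so later motifs cannot reuse them
            by_prom: dict[str, list[SiteInstance]] = {}
            for s in best.sites:
                by_prom.setdefault(s.promoter_id, []).append(s)
            for i, p in enumerate(working):
                if p.gene_id in by_prom:
                    chars = list(p.seq)
                    for s in by_prom[p.gene_id]:
                        chars[s.offset : s.offset + width] = "N" * width
                    working[i] = _Masked(p.gene_id, "".join(chars))
    results.sort(key=lambda m: -m.llr)
    return results


def match_consensus(motif: MotifModel, iupac: str) -> tuple[float, int, str]:
    """Best ungapped alignment of an IUPAC pattern to the motif consensus.

    Similarity is the fraction of pattern positions whose IUPAC set contains
    the motif's majority base, maximized over all offsets and both motif
    orientations.  Ties break toward the smaller offset, then the + strand.
    """
    from .sequences import validate_iupac

    validate_iupac(iupac)
    if len(iupac) > motif.width:
        raise ValueError("pattern longer than motif width")
    best = (-1.0, 0, "+")
    for strand, consensus in (("+", motif.consensus), ("-", revcomp(motif.consensus))):
        for offset in range(motif.width - len(iupac) + 1):
            matched = sum(
                1 for l, code in enumerate(iupac)
                if consensus[offset + l] in IUPAC[code]
            )
            sim = matched / len(iupac)
            key = (sim, -offset, strand == "+")
            best_key = (best[0], -best[1], best[2] == "+")
            if key > best_key:
                best = (sim, offset, strand)
    return best


def merge_motifs(m1: MotifModel, m2: MotifModel, min_overlap: int = 6) -> MotifModel:
    """Merge two motifs' site sets at the information-maximizing alignment.

    m2's consensus is slid along m1's in both orientations; for each
    alignment with overlap >= ``min_overlap`` the pooled, trimmed site set
    is scored by total information content, and the best pooling wins.
    """
    best: tuple[float, np.ndarray, list[SiteInstance]] | None = None
    for strand in ("+", "-"):
        sites2 = m2.sites if strand == "+" else [
            SiteInstance(s.promoter_id, s.offset,
                         "-" if s.strand == "+" else "+", revcomp(s.subseq))
            for s in m2.sites
        ]
        for shift in range(-(m2.width - min_overlap), m1.width - min_overlap + 1):
            lo = max(0, shift)                      # overlap window in m1 coords
            hi = min(m1.width, shift + m2.width)
            if hi - lo < min_overlap:
                continue
            pooled = [_trim_site(s, lo, hi - lo) for s in m1.sites]
            pooled += [_trim_site(s, lo - shift, hi - lo) for s in sites2]
            counts = _counts_from_sites(pooled, hi - lo)
            freqs = _freqs_from_counts(counts)
            total_ic = float((2.0 + (freqs * np.log2(freqs)).sum(axis=0)).sum())
            if best is None or total_ic > best[0]:
                best = (total_ic, counts, pooled)
    if best is None:
        raise ValueError(f"no alignment with overlap >= {min_overlap}")
    _, counts, pooled = best
    width = counts.shape[1]
    return MotifModel(
        width=width,
        sites=pooled,
        counts=counts,
        freqs=_freqs_from_counts(counts),
        gamma=max(m1.gamma, m2.gamma),
        source_label=f"{m1.source_label}+{m2.source_label}",
        llr=m1.llr + m2.llr,
    )


def _trim_site(s: SiteInstance, start: int, width: int) -> SiteInstance:
    """Trim a site to columns [start, start+width) of its motif frame.

    In promoter coordinates a left-trim of ``a`` bases moves a + site's
    offset by +a but a - site's offset by the right-trim amount, because the
    motif-forward subsequence of a - site reads the promoter window
    backwards.
    """
    a = start
    b = len(s.subseq) - (start + width)  # right trim
    offset = s.offset + (a if s.strand == "+" else b)
    return SiteInstance(s.promoter_id, offset, s.strand, s.subseq[start : start + width])


# --- site-list serialization ---------------------------------------------

def write_sites_tsv(motif: MotifModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("promoter_id\toffset\tstrand\tsubseq\n")
        for s in motif.sites:
            fh.write(f"{s.promoter_id}\t{s.offset}\t{s.strand}\t{s.subseq}\n")


def read_sites_tsv(path, source_label: str = "motif") -> MotifModel:
    sites: list[SiteInstance] = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            pid, off, strand, sub = line.rstrip("\n").split("\t")
            sites.append(SiteInstance(pid, int(off), strand, sub))
    if not sites:
        raise ValueError(f"no sites in {path}")
    width = len(sites[0].subseq)
    counts = _counts_from_sites(sites, width)
    return MotifModel(width, sites, counts, _freqs_from_counts(counts),
                      gamma=0.5, source_label=source_label)
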