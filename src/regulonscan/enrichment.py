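"""Fold and enrichment of dual binding sites in a gene set vs the genome.

The statistic follows the sites-per-promoter logic: at each score
threshold, ``fold`` is the number of qualifying dual sites divided by the
number of promoters in the set, and ``enrichment`` is the foreground fold
over the background fold.  The counting unit is dual sites (pairs), not the
single hits that compose them.

The plain ratio carries no interval, so a promoter-level bootstrap
(resampling promoters with replacement) supplies a percentile CI.  No
multiple-testing correction is applied anywhere; output headers say so.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .architecture import ArchitectureSpec, DualSite, best_pair, find_dual_sites
from .pwm import ScoringMatrix, scan_threshold

NO_CORRECTION_NOTE = "enrichment = fg_fold / bg_fold; no multiple-testing correction applied"


@dataclass
class EnrichmentRow:
    threshold: float
    fg_pairs: int
    fg_promoters: int
    bg_pairs: int
    bg_promoters: int
    enrichment_ci: tuple[float, float] | None = None

    @property
    def fg_fold(self) -> float:
        return self.fg_pairs / self.fg_promoters

    @property
    def bg_fold(self) -> float:
        return self.bg_pairs / self.bg_promoters

    @property
    def enrichment(self) -> float | None:
        """fg fold over bg fold; missing (None) when the background is empty."""
        if self.bg_fold == 0:
            return None
        return self.fg_fold / self.bg_fold


@dataclass
class RegulonCall:
    gene_id: str
    n_dual_sites: int
    best_pair: DualSite
    pairs: list[DualSite]


def _pair_counts(matrix: ScoringMatrix, promoters, spec: ArchitectureSpec,
                 thresholds: list[float]) -> np.ndarray:
    """Per-promoter dual-site counts at each threshold (len(thr) x n)."""
    base = min(thresholds)
    counts = np.zeros((len(thresholds), len(promoters)), dtype=int)
    for j, prom in enumerate(promoters):
        hits = scan_threshold(matrix, prom, base)
        for i, t in enumerate(thresholds):
            kept = [h for h in hits if h.score >= t]
            counts[i, j] = len(find_dual_sites(kept, spec.with_threshold(t)))
    return counts


def bootstrap_enrichment_ci(fg_counts: np.ndarray, bg_counts: np.ndarray,
                            n_boot: int = 200, seed: int = 0,
                            alpha: float = 0.05) -> tuple[float, float]:
    """Percentile CI for the ratio of mean pair counts, promoter-resampled."""
    rng = np.random.default_rng(seed)
    nf, nb = len(fg_counts), len(bg_counts)
    ratios = np.full(n_boot, np.nan)
    for b in range(n_boot):
        fg = fg_counts[rng.integers(0, nf, nf)].mean()
        bg = bg_counts[rng.integers(0, nb, nb)].mean()
        if bg > 0:
            ratios[b] = fg / bg
    valid = ratios[np.isfinite(ratios)]
    if len(valid) == 0:
        return (np.nan, np.nan)
    lo, hi = np.quantile(valid, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def threshold_sweep(matrix: ScoringMatrix, fg_promoters, bg_promoters,
                    spec_template: ArchitectureSpec, thresholds: list[float],
                    n_boot: int = 200, seed: int = 0) -> list[EnrichmentRow]:
    """Dual-site fold and enrichment across an ascending threshold grid."""
    if not fg_promoters or not bg_promoters:
        raise ValueError("foreground and background sets must be non-empty")
    thresholds = sorted(thresholds)
    fg = _pair_counts(matrix, fg_promoters, spec_template, thresholds)
    bg = _pair_counts(matrix, bg_promoters, spec_template, thresholds)
    rows = []
    for i, t in enumerate(thresholds):
        ci = bootstrap_enrichment_ci(fg[i], bg[i], n_boot=n_boot, seed=seed + i)
        rows.append(EnrichmentRow(t, int(fg[i].sum()), fg.shape[1],
                                  int(bg[i].sum()), bg.shape[1], ci))
    return rows


def genome_regulon(matrix: ScoringMatrix, all_promoters, spec: ArchitectureSpec) -> list[RegulonCall]:
    """Promoters carrying at least one qualifying dual site, best first."""
    calls = []
    for prom in all_promoters:
        hits = scan_threshold(matrix, prom, spec.threshold)
        duals = find_dual_sites(hits, spec)
        if duals:
            calls.append(RegulonCall(prom.gene_id, len(duals), best_pair(duals), duals))
    calls.sort(key=lambda c: -c.best_pair.pair_score)
    return calls


def flag_gene_lists(gene_lists: dict[str, list[str]], regulon: list[RegulonCall],
                    promoter_universe: set[str] | None = None) -> pd.DataFrame:
    """Fraction of each gene list carrying a regulon call.

    Lists are de-duplicated; genes outside the promoter universe (when one
    is given) are tallied separately as unmapped and excluded from the
    percentage denominator.
    """
    members = {c.gene_id for c in regulon}
    rows = []
    for name, genes in gene_lists.items():
        uniq = sorted(set(genes))
        if promoter_universe is not None:
            unmapped = [g for g in uniq if g not in promoter_universe]
            mapped = [g for g in uniq if g in promoter_universe]
        else:
            unmapped, mapped = [], uniq
        flagged = sum(1 for g in mapped if g in members)
        pct = 100.0 * flagged / len(mapped) if mapped else np.nan
        rows.append((name, len(uniq), len(mapped), flagged, len(unmapped), pct))
    return pd.DataFrame(
        rows, columns=["list", "n_genes", "n_mapped", "n_flagged", "n_unmapped", "pct_flagged"]
    )


def category_composition(regulon_a: list[str], regulon_b: list[str],
                         category_map: dict[str, str],
                         labels: tuple[str, str] = ("A", "B")) -> pd.DataFrame:
    """Per-category counts and percentage composition of two regulons.

    Genes missing from the map are binned as ``unknown``.  The last column
    is the log2 ratio of percentages (A over B); categories absent from one
    regulon yield +/-inf there.
    """
    la, lb = labels

    def tally(genes: list[str]) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in set(genes):
            cat = category_map.get(g, "unknown")
            out[cat] = out.get(cat, 0) + 1
        return out

    ta, tb = tally(regulon_a), tally(regulon_b)
    cats = sorted(set(ta) | set(tb))
    na, nb = max(1, sum(ta.values())), max(1, sum(tb.values()))
    rows = []
    with np.errstate(divide="ignore"):
        for cat in cats:
            pa = 100.0 * ta.get(cat, 0) / na
            pb = 100.0 * tb.get(cat, 0) / nb
            rows.append((cat, ta.get(cat, 0), pa, tb.get(cat, 0), pb,
                         float(np.log2(pa / pb)) if pb > 0 and pa > 0
                         else (np.inf if pa > 0 else (-np.inf if pb > 0 else 0.0))))
    return pd.DataFrame(
        rows,
        columns=["category", f"count_{la}", f"pct_{la}", f"count_{lb}", f"pct_{lb}", "log2_ratio"],
    )


def sweep_to_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.threshold, r.fg_pairs, r.fg_promoters, r.fg_fold, r.bg_pairs,
             r.bg_promoters, r.bg_fold, r.enrichment,
             r.enrichment_ci[0] if r.enrichment_ci else np.nan,
             r.enrichment_ci[1] if r.enrichment_ci else np.nan)
            for r in rows
        ],
        columns=["threshold", "fg_pairs", "fg_promoters", "fg_fold", "bg_pairs",
                 "bg_promoters", "bg_fold", "enrichment", "ci_lo", "ci_hi"],
    )
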