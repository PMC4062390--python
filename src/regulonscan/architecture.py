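"""Dual binding-site architectures: orientation classes and gap windows.

Two same-motif occurrences on one promoter form a repeat whose class is set
by their strands, reading 5'->3' on the promoter:

* ``(+,+)`` or ``(-,-)`` — direct repeat;
* ``(+,-)`` — inverted repeat (head-to-head);
* ``(-,+)`` — everted repeat (tail-to-tail).

Motif polarity makes these labels convention-dependent; the convention
above is written into every output header.  The gap is measured
edge-to-edge — intervening bases between the end of the upstream window and
the start of the downstream window — and overlapping windows (negative gap)
never pair.

Two presets mirror common zinc-finger regulator architectures: an
activator-style search over inverted+everted repeats spaced 8-30 bp, and a
repressor-style search over inverted+direct repeats spaced 5-30 bp.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pwm import ScoringMatrix, SiteHit, best_hit, scan_threshold

ORIENTATION_CONVENTION = (
    "orientation convention: (+,+)/(-,-)=direct, (+,-)=inverted, (-,+)=everted; "
    "gap=edge-to-edge intervening bp"
)


@dataclass
class ArchitectureSpec:
    """Which orientations qualify and how far apart the two sites may sit."""

    allowed_orientations: frozenset[str]
    gap_min: int
    gap_max: int
    threshold: float  # bits, applies to both sites

    def __post_init__(self) -> None:
        self.allowed_orientations = frozenset(self.allowed_orientations)
        bad = self.allowed_orientations - {"inverted", "everted", "direct"}
        if bad or not self.allowed_orientations:
            raise ValueError(f"invalid orientation set {set(self.allowed_orientations)}")
        if self.gap_min < 0 or self.gap_min > self.gap_max:
            raise ValueError("need 0 <= gap_min <= gap_max")

    def with_threshold(self, threshold: float) -> "ArchitectureSpec":
        return ArchitectureSpec(self.allowed_orientations, self.gap_min, self.gap_max, threshold)


def xyr1_preset(threshold: float = 6.2) -> ArchitectureSpec:
    """Activator-style preset: inverted + everted repeats, 8-30 bp apart."""
    return ArchitectureSpec(frozenset({"inverted", "everted"}), 8, 30, threshold)


def cre1_preset(threshold: float = 8.0) -> ArchitectureSpec:
    """Repressor-style preset: inverted + direct repeats, 5-30 bp apart."""
    return ArchitectureSpec(frozenset({"inverted", "direct"}), 5, 30, threshold)


@dataclass
class DualSite:
    upstream_hit: SiteHit
    downstream_hit: SiteHit
    orientation: str
    gap: int

    @property
    def pair_score(self) -> float:
        return min(self.upstream_hit.score, self.downstream_hit.score)

    @property
    def atg_span(self) -> tuple[int, int]:
        """ATG-relative positions of the first and last base of the element."""
        up, down = self.upstream_hit, self.downstream_hit
        return up.atg_position, down.atg_position + down.width - 1


def classify_pair(upstream_strand: str, downstream_strand: str) -> str:
    if upstream_strand == downstream_strand:
        return "direct"
    return "inverted" if upstream_strand == "+" else "everted"


def find_dual_sites(hits: list[SiteHit], spec: ArchitectureSpec) -> list[DualSite]:
    """All qualifying ordered pairs among one promoter's hits.

    A hit may participate in several pairs; output is sorted by upstream
    offset, then gap.  Hits below the spec threshold are dropped first
    (defensive re-filter).
    """
    kept = sorted(
        (h for h in hits if h.score >= spec.threshold),
        key=lambda h: (h.offset, h.strand != "+"),
    )
    pairs: list[DualSite] = []
    for i, up in enumerate(kept):
        for down in kept[i + 1 :]:
            gap = down.offset - (up.offset + up.width)
            if gap > spec.gap_max:
                break  # kept is offset-sorted; later downstreams only widen the gap
            if gap < spec.gap_min:
                continue
            orientation = classify_pair(up.strand, down.strand)
            if orientation in spec.allowed_orientations:
                pairs.append(DualSite(up, down, orientation, gap))
    pairs.sort(key=lambda d: (d.upstream_hit.offset, d.gap))
    return pairs


def promoter_architecture_report(promoter, matrix: ScoringMatrix, spec: ArchitectureSpec) -> dict:
    """Best single hit plus all qualifying dual sites for one promoter."""
    hits = scan_threshold(matrix, promoter, spec.threshold)
    duals = find_dual_sites(hits, spec)
    return {
        "promoter_id": promoter.gene_id,
        "best_single": best_hit(matrix, promoter),
        "hits": hits,
        "duals": duals,
    }


def best_pair(duals: list[DualSite]) -> DualSite | None:
    """One-line-per-promoter reducer: max pair score, then smallest gap."""
    if not duals:
        return None
    return max(duals, key=lambda d: (d.pair_score, -d.gap))


def write_pairs_tsv(duals_by_promoter: dict[str, list[DualSite]], path) -> None:
    cols = (
        "promoter_id\tup_offset\tup_strand\tup_score\tdown_offset\tdown_strand\t"
        "down_score\torientation\tgap\tpair_score\tatg_start\tatg_end"
    )
    with open(path, "w") as fh:
        fh.write(f"# {ORIENTATION_CONVENTION}\n{cols}\n")
        for pid in duals_by_promoter:
            for d in duals_by_promoter[pid]:
                u, dn = d.upstream_hit, d.downstream_hit
                span = d.atg_span
                fh.write(
                    f"{pid}\t{u.offset}\t{u.strand}\t{u.score:.4f}\t{dn.offset}\t"
                    f"{dn.strand}\t{dn.score:.4f}\t{d.orientation}\t{d.gap}\t"
                    f"{d.pair_score:.4f}\t{span[0]}\t{span[1]}\n"
                )
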