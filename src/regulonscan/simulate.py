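"""Synthetic promoter sets with planted binding sites and exact truth tables.

The generator emulates the study conditions every upstream stage is tested
against: promoter sets of configurable size and length drawn from an
order-0 composition or an order-1 Markov chain, and ground-truth motif
instances planted either zero-or-once per sequence (the ZOOPS assumption)
or as oriented dual sites with a uniform gap from a stated window.
Planting replaces background bases — promoter length never changes — so
ATG-relative coordinates stay exact, and every planted element is written
to a truth record that can be compared position-for-position with scanner
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .genome_io import PromoterRecord, write_fasta, SequenceRecord
from .sequences import decode, revcomp

ORIENTATIONS = ("inverted", "everted", "direct")


def pfm_from_consensus(consensus: str, sharpness: float = 0.9) -> np.ndarray:
    """4 x w frequency matrix with ``sharpness`` on the consensus base."""
    if not 0.25 <= sharpness <= 1.0:
        raise ValueError("sharpness must be in [0.25, 1]")
    w = len(consensus)
    pfm = np.full((4, w), (1.0 - sharpness) / 3.0)
    for l, base in enumerate(consensus):
        pfm["ACGT".index(base), l] = sharpness
    return pfm


def expected_site_score(pfm: np.ndarray) -> float:
    """Mean information score of a site sampled from its own PFM:
    sum_l sum_b f(b,l) * (2 + log2 f(b,l)) bits."""
    pfm = np.asarray(pfm, dtype=float)
    return float((pfm * (2.0 + np.log2(pfm))).sum())


@dataclass
class PlantingSpec:
    """What to plant, where, and how often."""

    truth_pfm: np.ndarray
    mode: str = "single_zoops"          # none | single_zoops | dual
    orientation: str = "inverted"       # dual mode only
    gap_range: tuple[int, int] = (8, 30)
    planting_fraction: float = 1.0
    seed: int = 0
    fixed_atg_start: int | None = None  # plant at this ATG-relative start instead of uniform

    def __post_init__(self) -> None:
        self.truth_pfm = np.asarray(self.truth_pfm, dtype=float)
        if not np.allclose(self.truth_pfm.sum(axis=0), 1.0):
            raise ValueError("truth_pfm columns must sum to 1")
        if self.mode not in ("none", "single_zoops", "dual"):
            raise ValueError(f"unknown planting mode {self.mode!r}")
        if self.mode == "dual" and self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.gap_range[0] < 0 or self.gap_range[0] > self.gap_range[1]:
            raise ValueError("invalid gap_range")
        if not 0.0 <= self.planting_fraction <= 1.0:
            raise ValueError("planting_fraction must be in [0,1]")

    @property
    def width(self) -> int:
        return self.truth_pfm.shape[1]


@dataclass
class TruthRecord:
    """Exact coordinates of the elements planted in one promoter."""

    promoter_id: str
    offsets: list[int]       # 0-based starts, upstream first
    strands: list[str]
    subseqs: list[str]       # motif-forward subsequences, parallel to offsets
    orientation: str | None  # dual mode only
    gap: int | None


def make_background(n: int, length: int,
                    base_composition=(0.25, 0.25, 0.25, 0.25),
                    markov1_params: np.ndarray | None = None,
                    seed: int = 0,
                    id_prefix: str = "prom") -> list[PromoterRecord]:
    """i.i.d. or order-1 Markov background promoters, reproducible by seed.

    ``markov1_params`` is a 4x4 row-stochastic transition matrix (rows =
    current base); when given it overrides ``base_composition`` for all but
    the first base, whose distribution is the chain's stationary vector.
    """
    if n < 1 or length < 1:
        raise ValueError("need n >= 1 and length >= 1")
    rng = np.random.default_rng(seed)
    records = []
    if markov1_params is not None:
        trans = np.asarray(markov1_params, dtype=float)
        if trans.shape != (4, 4) or not np.allclose(trans.sum(axis=1), 1.0):
            raise ValueError("markov1_params must be 4x4 row-stochastic")
        # stationary distribution for the first base
        vals, vecs = np.linalg.eig(trans.T)
        pi = np.real(vecs[:, np.argmax(np.real(vals))])
        pi = np.abs(pi) / np.abs(pi).sum()
        cum = trans.cumsum(axis=1)
        for i in range(n):
            seq = np.empty(length, dtype=np.int8)
            seq[0] = rng.choice(4, p=pi)
            u = rng.random(length)
            for j in range(1, length):
                seq[j] = np.searchsorted(cum[seq[j - 1]], u[j])
            records.append(_promoter(f"{id_prefix}{i + 1}", decode(seq)))
    else:
        comp = np.asarray(base_composition, dtype=float)
        if comp.shape != (4,) or not np.isclose(comp.sum(), 1.0) or (comp < 0).any():
            raise ValueError("base_composition must be 4 non-negative values summing to 1")
        for i in range(n):
            seq = rng.choice(4, size=length, p=comp)
            records.append(_promoter(f"{id_prefix}{i + 1}", decode(seq.astype(np.int8))))
    return records


def _promoter(gene_id: str, seq: str) -> PromoterRecord:
    # synthetic promoters get a notional anchor on a contig of their own
    return PromoterRecord(gene_id, seq, False, (f"{gene_id}_contig", 1, len(seq), "+"))


def _sample_site(pfm: np.ndarray, rng: np.random.Generator) -> str:
    cols = [rng.choice(4, p=pfm[:, l]) for l in range(pfm.shape[1])]
    return "".join("ACGT"[c] for c in cols)


def plant_elements(promoters: list[PromoterRecord], spec: PlantingSpec,
                   avoid: dict[str, list[tuple[int, int]]] | None = None,
                   max_tries: int = 100) -> tuple[list[PromoterRecord], list[TruthRecord]]:
    """Plant elements per spec; returns modified promoters plus exact truth.

    ``avoid`` maps promoter ids to half-open intervals the new element must
    not overlap (e.g. previously planted single-mode sites); collisions are
    resolved by resampling the position up to ``max_tries`` times.
    """
    rng = np.random.default_rng(spec.seed)
    w = spec.width
    avoid = avoid or {}
    if spec.mode == "none":
        return list(promoters), []

    out: list[PromoterRecord] = []
    truth: list[TruthRecord] = []
    for prom in promoters:
        L = len(prom.seq)
        if spec.mode == "single_zoops":
            span_needed = w
        else:
            span_needed = 2 * w + spec.gap_range[1]
        if span_needed > L:
            raise ValueError(
                f"promoter {prom.gene_id} ({L} bp) too short for planting span {span_needed}"
            )
        if rng.random() >= spec.planting_fraction:
            out.append(prom)
            continue
        forbidden = avoid.get(prom.gene_id, [])
        if spec.mode == "single_zoops":
            site = _sample_site(spec.truth_pfm, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            placed = site if strand == "+" else revcomp(site)
            offset = _place(rng, L, w, forbidden, spec.fixed_atg_start, max_tries)
            seq = prom.seq[:offset] + placed + prom.seq[offset + w:]
            out.append(replace(prom, seq=seq))
            truth.append(TruthRecord(prom.gene_id, [offset], [strand], [site], None, None))
        else:
            gap = int(rng.integers(spec.gap_range[0], spec.gap_range[1] + 1))
            span = 2 * w + gap
            offset = _place(rng, L, span, forbidden, spec.fixed_atg_start, max_tries)
            s_up, s_down = _orient(spec.orientation, rng)
            site_up = _sample_site(spec.truth_pfm, rng)
            site_down = _sample_site(spec.truth_pfm, rng)
            up_placed = site_up if s_up == "+" else revcomp(site_up)
            down_placed = site_down if s_down == "+" else revcomp(site_down)
            down_off = offset + w + gap
            chars = list(prom.seq)
            chars[offset : offset + w] = up_placed
            chars[down_off : down_off + w] = down_placed
            out.append(replace(prom, seq="".join(chars)))
            truth.append(TruthRecord(prom.gene_id, [offset, down_off], [s_up, s_down],
                                     [site_up, site_down], spec.orientation, gap))
    return out, truth


def _orient(orientation: str, rng: np.random.Generator) -> tuple[str, str]:
    if orientation == "inverted":
        return "+", "-"
    if orientation == "everted":
        return "-", "+"
    return ("+", "+") if rng.random() < 0.5 else ("-", "-")


def _place(rng: np.random.Generator, L: int, span: int,
           forbidden: list[tuple[int, int]], fixed_atg_start: int | None,
           max_tries: int) -> int:
    if fixed_atg_start is not None:
        offset = L + fixed_atg_start
        if offset < 0 or offset + span > L:
            raise ValueError(f"fixed ATG start {fixed_atg_start} does not fit span {span}")
        return offset
    for _ in range(max_tries):
        offset = int(rng.integers(0, L - span + 1))
        if not any(offset < e and s < offset + span for s, e in forbidden):
            return offset
    raise RuntimeError(f"could not place element of span {span} in {max_tries} tries")


# --- paper-like study preset ----------------------------------------------

#: Activator-like (zinc binuclear cluster) 8-nt motif: GGC core, AT-rich tail.
XYR1_LIKE_CONSENSUS = "GGCTAAAT"
#: Repressor-like 10-nt motif with a GGAG core (SYGGRG-compatible 5' half).
CRE1_LIKE_CONSENSUS = "GCGGAGGCGT"
STRONG_SHARPNESS = 0.95


@dataclass
class StudyConfig:
    """Sizes, contrast and seeds of a synthetic foreground/background study."""

    n_fg: int = 50
    n_bg: int = 2000
    length: int = 1500
    consensus: str = XYR1_LIKE_CONSENSUS
    sharpness: float = STRONG_SHARPNESS
    orientation: str = "everted"
    gap_range: tuple[int, int] = (8, 30)
    fg_rate: float = 0.6
    bg_rate: float = 0.1
    base_composition: tuple = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0
    fixed_atg_start: int | None = None  # pin foreground elements to one ATG-relative start


@dataclass
class StudyBundle:
    config: StudyConfig
    foreground: list[PromoterRecord]
    background: list[PromoterRecord]
    fg_truth: list[TruthRecord]
    bg_truth: list[TruthRecord]
    truth_pfm: np.ndarray
    gene_lists: dict[str, list[str]]
    category_map: dict[str, str]


def make_study(config: StudyConfig) -> StudyBundle:
    """Generate a full foreground/background study with truth tables.

    Foreground promoters receive dual elements at ``fg_rate`` per promoter,
    background at ``bg_rate``; a small gene-list / category map is derived
    from the truth so downstream flagging and composition stages have
    inputs.  Everything is a pure function of the config (seeds below 2^31).
    """
    if config.fg_rate < 0 or config.bg_rate < 0:
        raise ValueError("planting rates must be non-negative (field: fg_rate/bg_rate)")
    pfm = pfm_from_consensus(config.consensus, config.sharpness)
    base = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)
    fg0 = make_background(config.n_fg, config.length, config.base_composition,
                          seed=int(base[0]), id_prefix="fg")
    bg0 = make_background(config.n_bg, config.length, config.base_composition,
                          seed=int(base[1]), id_prefix="bg")
    spec_fg = PlantingSpec(pfm, "dual", config.orientation, config.gap_range,
                           config.fg_rate, seed=int(base[2]),
                           fixed_atg_start=config.fixed_atg_start)
    spec_bg = PlantingSpec(pfm, "dual", config.orientation, config.gap_range,
                           config.bg_rate, seed=int(base[3]))
    fg, fg_truth = plant_elements(fg0, spec_fg)
    bg, bg_truth = plant_elements(bg0, spec_bg)
    planted_bg = {t.promoter_id for t in bg_truth}
    gene_lists = {
        "planted_fg": [t.promoter_id for t in fg_truth],
        "planted_bg": sorted(planted_bg),
    }
    category_map = {p.gene_id: ("planted" if p.gene_id in planted_bg else "background")
                    for p in bg}
    return StudyBundle(config, fg, bg, fg_truth, bg_truth, pfm, gene_lists, category_map)


def write_study(bundle: StudyBundle, outdir: str | Path) -> None:
    """Write FASTA promoters, BED6 truth, TSV lists and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, proms in (("foreground", bundle.foreground), ("background", bundle.background)):
        write_fasta([SequenceRecord(p.gene_id, p.seq) for p in proms],
                    outdir / f"{name}.fasta")
    w = bundle.truth_pfm.shape[1]
    for name, truth in (("foreground", bundle.fg_truth), ("background", bundle.bg_truth)):
        with open(outdir / f"{name}_truth.bed", "w") as fh:
            for t in truth:
                for off, strand in zip(t.offsets, t.strands):
                    fh.write(f"{t.promoter_id}\t{off}\t{off + w}\ttruth\t0\t{strand}\n")
    with open(outdir / "gene_lists.tsv", "w") as fh:
        for name, genes in bundle.gene_lists.items():
            for g in genes:
                fh.write(f"{name}\t{g}\n")
    with open(outdir / "category_map.tsv", "w") as fh:
        for g, cat in sorted(bundle.category_map.items()):
            fh.write(f"{g}\t{cat}\n")
    c = bundle.config
    manifest = {
        "n_fg": c.n_fg, "n_bg": c.n_bg, "length": c.length,
        "consensus": c.consensus, "sharpness": c.sharpness,
        "orientation": c.orientation, "gap_min": c.gap_range[0],
        "gap_max": c.gap_range[1], "fg_rate": c.fg_rate, "bg_rate": c.bg_rate,
        "seed": c.seed,
    }
    with open(outdir / "manifest.txt", "w") as fh:
        for k, v in manifest.items():
            fh.write(f"{k}\t{v}\n")


def read_manifest(path: str | Path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            k, v = line.rstrip("\n").split("\t")
            out[k] = v
    return out
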