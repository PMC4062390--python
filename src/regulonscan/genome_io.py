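"""Genome and annotation I/O plus strand-aware promoter extraction.

The coordinate conventions used throughout the package are fixed here:

* internal coordinates are 0-based half-open;
* user-facing site positions are ATG-relative negative offsets, where -1 is
  the base immediately upstream of the start codon (the last base of a
  promoter sequence);
* a promoter of a ``+`` gene with coding start ``s`` (1-based, first base of
  the ATG) covers forward-strand bases ``[s-length, s-1]``; for a ``-`` gene
  it is the reverse complement of forward bases ``[s+1, s+length]``.

Windows running off a contig edge are clipped and flagged ``truncated``
rather than discarded, so genome-background promoter sets are not biased
toward long-contig genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .sequences import IUPAC, revcomp

logger = logging.getLogger(__name__)

_AMBIGUITY = set(IUPAC) - set("ACGTN")


@dataclass
class SequenceRecord:
    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    strand: str
    coding_start: int  # 1-based, first base of the start codon, forward coords

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.coding_start < 1:
            raise ValueError(f"gene {self.gene_id}: coding_start must be >= 1")


@dataclass
class PromoterRecord:
    """One gene's upstream region in an ATG-anchored frame.

    ``genome_anchor`` is (contig, start, end, strand) with 1-based inclusive
    forward-strand coordinates of the extracted window.  Position -1 in the
    ATG-relative frame is always the last base of ``seq``.
    """

    gene_id: str
    seq: str
    truncated: bool
    genome_anchor: tuple[str, int, int, str]

    @property
    def length(self) -> int:
        return len(self.seq)

    def atg_position(self, offset: int) -> int:
        """ATG-relative position of the promoter base at 0-based ``offset``."""
        return offset - self.length


def _normalize_seq(seq: str, rec_id: str) -> str:
    seq = seq.upper()
    ambiguous = set(seq) & _AMBIGUITY
    if ambiguous:
        logger.warning(
            "record %s: ambiguity codes %s converted to N", rec_id, sorted(ambiguous)
        )
        seq = "".join("N" if c in _AMBIGUITY else c for c in seq)
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"record {rec_id!r}: non-nucleotide characters {sorted(bad)}")
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA into normalized records.

    Sequences are uppercased; IUPAC ambiguity codes other than N become N
    with a logged warning.  Duplicate ids, empty files and non-nucleotide
    characters raise ``ValueError``.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(rec.id, _normalize_seq(str(rec.seq), rec.id), rec.description)
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_annotation(path: str | Path, dialect: str = "tsv") -> list[GeneModel]:
    """Read gene models from GFF3 or a minimal 4-column TSV.

    TSV columns: gene_id, contig, strand, coding_start (1-based).  For GFF3
    the coding start is the CDS edge nearest the 5' end of the gene: the
    smallest CDS start on ``+`` genes, the largest CDS end on ``-`` genes.
    Genes without CDS features are skipped with a warning.
    """
    if dialect == "tsv":
        return _read_annotation_tsv(path)
    if dialect == "gff3":
        return _read_annotation_gff3(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _read_annotation_tsv(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("gene_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            gene_id, contig, strand, start = parts
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            genes.append(GeneModel(gene_id, contig, strand, int(start)))
    return genes


def _read_annotation_gff3(path: str | Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        cds = list(db.children(gene, featuretype="CDS"))
        if not cds:
            logger.warning("gene %s has no CDS feature; skipped", gene.id)
            continue
        if gene.strand == "+":
            coding_start = min(c.start for c in cds)
        else:
            coding_start = max(c.end for c in cds)
        genes.append(GeneModel(gene.id, gene.seqid, gene.strand, coding_start))
    return genes


def extract_promoters(
    genome: Sequence[SequenceRecord] | dict[str, str],
    genes: Iterable[GeneModel],
    length: int = 1500,
) -> tuple[list[PromoterRecord], dict[str, str]]:
    """Extract fixed-length upstream regions for each gene.

    Returns ``(promoters, errors)`` where ``errors`` maps gene ids to a
    message (missing contig); one bad gene never aborts the batch.  Windows
    clipped at contig edges come back shorter with ``truncated=True``;
    zero-length windows are dropped with a warning.  Output order follows
    input gene order.
    """
    if length < 1:
        raise ValueError("promoter length must be >= 1")
    if not isinstance(genome, dict):
        genome = {r.id: r.seq for r in genome}
    promoters: list[PromoterRecord] = []
    errors: dict[str, str] = {}
    for gene in genes:
        contig = genome.get(gene.contig)
        if contig is None:
            errors[gene.gene_id] = f"contig {gene.contig!r} not in genome"
            continue
        clen = len(contig)
        if gene.strand == "+":
            start = max(1, gene.coding_start - length)  # 1-based inclusive
            end = gene.coding_start - 1
            seq = contig[start - 1 : end]
        else:
            start = gene.coding_start + 1
            end = min(clen, gene.coding_start + length)
            seq = revcomp(contig[start - 1 : end])
        if not seq:
            logger.warning("gene %s: zero-length promoter window; dropped", gene.gene_id)
            continue
        truncated = len(seq) < length
        promoters.append(
            PromoterRecord(gene.gene_id, seq, truncated, (gene.contig, start, end, gene.strand))
        )
    return promoters, errors


def promoters_from_fasta(path: str | Path) -> list[PromoterRecord]:
    """Load promoter sequences written without genome context.

    Each record gets a notional forward anchor on its own contig, so
    promoter-frame reporting and ATG-relative coordinates work as usual.
    """
    return [
        PromoterRecord(r.id, r.seq, False, (f"{r.id}_contig", 1, len(r.seq), "+"))
        for r in read_fasta(path)
    ]


def hit_genome_interval(promoter: PromoterRecord, offset: int, width: int) -> tuple[str, int, int, str]:
    """Map a promoter window to (contig, bed_start, bed_end, genome_strand).

    Coordinates are BED-style 0-based half-open on the forward strand of the
    contig.  A ``+`` hit strand means motif-forward on the promoter (i.e. the
    gene's own strand); on ``-`` genes that flips on the genome.
    """
    contig, astart, aend, gstrand = promoter.genome_anchor
    if gstrand == "+":
        bed_start = astart - 1 + offset
        return contig, bed_start, bed_start + width, "+"
    # promoter offset 0 is the complement of forward base aend
    bed_end = aend - offset  # half-open end
    return contig, bed_end - width, bed_end, "-"


def write_sites_bed(hits_or_pairs, promoters: Sequence[PromoterRecord], path: str | Path, frame: str = "promoter") -> None:
    """Serialize site hits or dual-site pairs as BED6.

    ``frame='promoter'``: chrom is the gene id and coordinates are 0-based
    offsets within the promoter.  ``frame='genome'``: coordinates are mapped
    through each promoter's genome anchor.  Score column is the bit score
    x100, rounded.  Pairs emit two lines sharing a ``pairN`` name prefix.
    """
    if frame not in ("promoter", "genome"):
        raise ValueError(f"frame must be 'promoter' or 'genome', got {frame!r}")
    index = {p.gene_id: p for p in promoters}

    def _line(hit, name: str) -> str:
        prom = index.get(hit.promoter_id)
        if prom is None:
            raise KeyError(f"hit references unknown gene id {hit.promoter_id!r}")
        score = round(hit.score * 100)
        if frame == "promoter":
            chrom, start, end, strand = (
                prom.gene_id, hit.offset, hit.offset + hit.width, hit.strand,
            )
        else:
            contig, start, end, gstrand = hit_genome_interval(prom, hit.offset, hit.width)
            chrom = contig
            strand = gstrand if hit.strand == "+" else ("-" if gstrand == "+" else "+")
        return f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}"

    lines: list[str] = []
    pair_counter = 0
    for item in hits_or_pairs:
        if hasattr(item, "upstream_hit"):
            pair_counter += 1
            pid = f"pair{pair_counter}"
            lines.append(_line(item.upstream_hit, f"{pid}_up"))
            lines.append(_line(item.downstream_hit, f"{pid}_down"))
        else:
            lines.append(_line(item, "site"))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
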