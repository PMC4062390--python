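#!/usr/bin/env python
"""De novo ZOOPS motif discovery on the simulated foreground promoters.

Runs the EM search at width 8, reports each motif's consensus, site count
and likelihood ratio, and checks which discovered motifs resemble the
GGCWWW activator consensus.  Writes results/motifs_summary.tsv and the
matrices in minimal MEME format.
"""

from pathlib import Path

from regulonscan.genome_io import promoters_from_fasta
from regulonscan.motifs import discover_motifs, match_consensus
from regulonscan.pwm import build_scoring_matrix, write_meme

STUDY = Path("results/study")
OUT = Path("results")


def main() -> None:
    promoters = promoters_from_fasta(STUDY / "foreground.fasta")
    found = discover_motifs(promoters, width_range=(8, 8), n_motifs=3,
                            seeds_per_width=5, seed=1)
    print(f"{len(found)} motifs discovered in {len(promoters)} promoters")
    rows = []
    for motif in found:
        similarity, offset, strand = match_consensus(motif, "GGCWWW")
        rows.append((motif.source_label, motif.consensus, len(motif.sites),
                     round(motif.gamma, 3), round(motif.llr, 1),
                     round(similarity, 2)))
        print(f"  {motif.source_label}: {motif.consensus}  sites={len(motif.sites)} "
              f"gamma={motif.gamma:.2f}  llr={motif.llr:.1f}  "
              f"GGCWWW similarity={similarity:.2f} ({strand}{offset:+d})")
    OUT.mkdir(exist_ok=True)
    with open(OUT / "motifs_summary.tsv", "w") as fh:
        fh.write("label\tconsensus\tn_sites\tgamma\tllr\tggcwww_similarity\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
    write_meme([build_scoring_matrix(m, name=m.source_label) for m in found],
               OUT / "motifs.meme")
    print(f"wrote {OUT}/motifs_summary.tsv and {OUT}/motifs.meme")


if __name__ == "__main__":
    main()
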