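# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic studies can and cannot show.

## Promoter extraction and coordinates

Promoters are fixed-length windows immediately upstream of the first base
of the start codon: for a `+` gene with 1-based coding start *s*, forward
bases `[s − L, s − 1]`; for a `−` gene, the reverse complement of
`[s + 1, s + L]`, with *L* = 1500 by default.  Windows running off a contig
are clipped and flagged `truncated` rather than discarded — discarding
would bias genome background sets toward genes on long contigs.  Upstream
windows are extracted regardless of overlap with neighbouring gene bodies,
and repeat masking is out of scope.

Internally all coordinates are 0-based half-open; every user-facing report
is ATG-relative, with −1 the base adjacent to the start codon.  The two
frames are linked by `atg_position = offset − promoter_length`, and the
genome anchor of each promoter makes BED output exact in either frame, also
for truncated windows.

GFF3 coding starts are taken from the CDS feature nearest the gene's 5'
end (smallest CDS start on `+`, largest CDS end on `−`); no isoform
resolution is attempted.  IUPAC ambiguity codes other than N are converted
to N on ingest with a warning; N bases are retained in promoters and the
scanner decides their treatment (below).

## ZOOPS motif model

Each promoter contains zero or one motif instance, on either strand.  For
a sequence with *m* scannable windows per strand the latent variable ranges
over {absent} ∪ {(position, strand)}, with prior γ for presence and uniform
1/(2m) over placements given presence.  The background is an order-0
composition estimated once from the input set.

EM details:

* **E-step** — placement responsibilities proportional to
  γ/(2m) · exp(Σ_l log f(b,l)/bg(b)); windows containing N get zero
  responsibility.
* **M-step** — frequencies from responsibility-weighted counts plus a
  pseudocount of 0.25 per base per column (one pseudo-observation per
  column); γ from the mean presence posterior under a weak Beta prior
  (below).
* **Objective** — the pseudocounts and the γ prior make this MAP EM, so
  the asserted-monotone quantity is the penalized log-likelihood
  (checked to 1e-9 every iteration); convergence when the improvement
  drops below 1e-6, cap 100 iterations.
* **Site calling** — sequences with presence posterior > 0.5 contribute
  their maximum-responsibility placement as a hard site.

**Gamma prior.** The update γ = Σ presence / (n + b − 1) uses a
Beta(1, b) prior with b = 1 + 0.1·n.  Without it the ZOOPS likelihood has a
degenerate attractor on unstructured input: a motif that drifts to the
background composition gives every sequence a likelihood ratio near 1, the
presence posterior then equals the prior, and γ ratchets to 1.  The prior
biases γ down by at most ~10% — negligible when real sites dominate the
likelihood — and lets γ collapse toward 0 on noise, where fitted γ is
typically ~0.3 at these problem sizes.

**Seeding and determinism.** EM starts are enumerated, not sampled: the k
most over-represented w-mers (observed count over the order-0 expectation,
revcomp-canonical; k = 5 per width by default) are softened to 0.7
consensus / 0.1 off-consensus.  All stochastic behaviour elsewhere fans out
from one integer seed.  Ties anywhere break to the smaller offset, then the
`+` strand.

**Multiple motifs.** After each accepted motif its hard sites are masked
with N and the search repeats, up to 10 motifs per width in the 6–10 range;
the search stops when the best run's log-likelihood ratio over the
all-background null reaches 0 (a γ = 0 fit is exactly the null, so the
ratio is never negative).  Because both strands are modelled and seeds are
revcomp-canonical, a motif's orientation is arbitrary; consensus matching
against IUPAC patterns therefore checks both orientations, scoring the
fraction of pattern positions whose degenerate set contains the motif's
majority base over all ungapped offsets.

**Merging.** Two motifs' site sets are merged at the alignment (both
orientations, ungapped shifts, overlap ≥ 6) that maximizes the pooled
matrix's total information content; sites are trimmed to the overlap
window and re-oriented as needed.  The information-maximizing alignment is
this package's choice where several near-equivalent alignments exist.

## Information-content scoring

A scoring matrix assigns w(b, l) = 2 + log2 f(b, l) bits from the
pseudocounted site frequencies; a window scores the sum over columns and
per-column information is R(l) = 2 + Σ_b f log2 f.  Consequences used as
test anchors: weights never exceed 2 bits, a perfect consensus on a pure
zero-pseudocount matrix scores exactly 2·width, and uniform columns score 0.
The small-sample correction sometimes applied to R(l) is omitted (site
counts here are configurable, and scores stay on the 2·width-bounded scale);
weights are information relative to a uniform composition, with an optional
log-odds-versus-background mode that is off by default.

Scanning conventions: `-` strand scores the reverse complement;
N-containing windows are unscorable and skipped rather than scored with
background; thresholds are inclusive (score ≥ t) so boundary counts are
deterministic; best-hit ties break to the smaller offset then `+`.  The
scanner is vectorized per promoter but is verified window-by-window against
an independent double-loop scorer in the tests.

## Dual-site architecture

Orientation is read from the strand pair 5'→3' on the promoter:
(+,−) inverted, (−,+) everted, same-strand direct.  These labels are
convention-dependent because motif polarity is arbitrary; the convention is
written into every output header.  The gap is edge-to-edge — intervening
bases between the windows — and overlapping windows never pair.  All
qualifying ordered pairs are reported (a hit may join several pairs); a
best-pair reducer (max pair score = min of the two site scores, then
smallest gap) serves one-line-per-promoter maps.  Default windows follow
the two reference architectures: 8–30 bp for inverted+everted
(activator-style) and 5–30 bp for inverted+direct (repressor-style);
whether literature distances are edge-to-edge is not standardized, so the
bounds are configuration.

## Enrichment and regulon calling

At each threshold of an ascending sweep (default grid 6.1–6.6), fold =
qualifying dual sites / promoters, separately for the foreground set and
the background; enrichment is their ratio.  The counting unit is pairs,
not participating single hits.  A promoter-level bootstrap (resample
promoters with replacement, B = 200) gives a percentile CI so synthetic
recovery has a calibrated criterion; no multiple-testing correction is
applied anywhere and output headers say so.  The background set includes
the foreground genes by default (an exclusion flag exists).  The stringent
regulon is every promoter with ≥ 1 qualifying pair at its stringent
threshold (defaults 6.6 activator / 9.2 repressor), ranked by best pair
score; gene lists are flagged by regulon membership with unmapped genes
tallied separately, and category composition compares percentage
breakdowns of two gene sets with log2 ratios.

## Synthetic studies: what they emulate, and what not

The generator draws backgrounds from an order-0 composition (order-1
Markov available), then plants sites by **replacing** background bases —
length never changes, so ATG-relative truth coordinates are exact.  Single
sites follow the ZOOPS generative story (Bernoulli presence, uniform
position/strand, columns sampled from the truth PFM); dual elements place
two sampled sites with a chosen orientation and a uniform gap from the
window.  The default study: 50 foreground promoters of 1.5 kb at 0.6 dual
elements/promoter vs 2000 background promoters at 0.1, truth consensus
GGCTAAAT at 0.95 per-column sharpness ("strong"), everted pairs, gaps
8–30 bp.  The motif-recovery condition uses 0.9 sharpness on 300-bp
promoters, where exact-position recovery runs at the identifiability
ceiling: a 0.9-sharp site carries ~1 expected mismatch, and equally good
windows occur by chance, so ≥ 90% exact recovery requires widths ≥ 10 at
these lengths.

What passing tests do **not** show about real promoters: real backgrounds
have higher-order composition, repeats and nucleosome-shaped site placement
none of which the generator emulates; real motif instances are not
independent column draws; and real regulons are defined by function, not by
a planting coin.  The synthetic results validate the machinery —
estimator correctness, calibration and coordinate bookkeeping — not any
biological claim.

## Problem sizes

Test and acceptance runs are scaled for a laptop-class single core: motif
recovery at 200 × 300 bp, enrichment recovery at 50 + 2000 × 1.5 kb, null
calibration at 50 replicates of 40 + 160 × 600 bp, genome-regulon checks
at 300–500 promoters.  The analysis scripts use the default study sizes
above; all complete in seconds to a few minutes.

## Known limitations

* The EM is a simplified ZOOPS (order-0 background, single-component
  Dirichlet smoothing, enumerated seeding); it is not a reimplementation of
  MEME and motif sets will differ in detail.
* Likelihood-ratio ranking replaces E-values; no p-value calibration of
  bit scores is attempted.
* No gapped motifs, no OOPS/ANR models, no triplet architectures, no
  spacing weights inside the gap window.
* Category analysis reports percentages and log2 ratios only; no
  statistical test is attached.
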