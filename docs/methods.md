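# Methods

## Coordinate and sequence conventions

All coordinates are 1-based inclusive, matching GTF; BED-like inputs would
need a one-off shift at the boundary (`read_circ_junctions(shift=1)`).
Sequences are stored as upper-case DNA; `U` is converted to `T` on ingest
and `N` is allowed but never scores as a match. A BSJ row gives two
coordinates and a strand; the acceptor is always the transcriptionally
upstream site (the smaller coordinate on `+`, the larger on `-`), which
makes the input order-insensitive. Duplicate BSJ rows are collapsed with a
logged count rather than rejected, since database exports commonly contain
them.

## BSJ validation and circle construction

A junction passes when its donor is an annotated transcription-orientation
3' exon end and its acceptor a 5' exon start *in the same transcript* on
the event's strand; matching boundaries drawn from two different
transcripts fail with a reason code. When several transcripts carry both
boundaries, the circle is built from the one yielding the longest exonic
circle (ties broken lexicographically by transcript id) — the most
inclusive exon model, chosen deterministically. The junction pseudo-read is
the last min(100, L) nt of the circle followed by its first min(100, L) nt;
arms shorter than 100 nt are not wrapped around the circle a second time,
which would plant artificial tandem repeats in the read and trigger the
multi-hit screen against itself.

## The built-in aligner

Ambiguity screening and RCS scanning need local alignment. Production runs
can feed pre-computed BLAT PSL, tabular BLAST or miRanda text files through
the adapters in `circaxis.external`; the built-in engine exists so the
pipeline is a single self-contained artifact. It is a seed-and-extend
design: exact k-mer seeds (k = 11 for the default profile, k = 9 for the
sensitive one, mirroring the two BLAT tile sizes) are clustered by
diagonal, and each cluster window is resolved with a full affine-gap
Smith–Waterman pass (numba-compiled). Within a window the reported score is
therefore the true local optimum; secondary hits are recovered
Waterman–Eggert-style by masking the query span of each reported alignment
and re-aligning. Inputs small enough that the full matrix is cheap
(≤ 40 000 cells) skip the windowing entirely, so on short pairs the engine
is exactly Smith–Waterman. The test suite checks this equivalence against
biotite's `align_optimal` on a seed-guaranteed random corpus.

Scoring is match +2, mismatch −3, gap open −5, gap extend −2, with a
length-L gap costing open + (L−1)·extend. Raw scores are converted to bits
with the Karlin–Altschul transform (λ = 0.625, K = 0.41, the classical
ungapped constants for +2/−3 nucleotide scoring), which makes the
"bitscore > 100" RCS rule meaningful for the built-in path: a perfect match
needs ≥ 55 columns to clear it.

## Ambiguity screening

Per profile, the pseudo-read is searched against every chromosome and every
spliced transcript, both strands. Hits at the event's own locus — the
circle's genomic span (±10 nt) or any transcript overlapping it — are
exempt: every genuine circRNA maps to its own locus non-co-linearly, and
counting that mapping would flag everything. Two detectors run on the
remaining hits:

* **co-linear alternative**: some contiguous (non-split) hit has
  matches / pseudo-read length > 0.80. Coverage identity, not block
  identity, is used deliberately: a short high-identity block should not
  "explain" the junction.
* **multiple hits**: the best own-locus alignment fails to beat some
  alternative-locus alignment by ≥ 3 score units. This reads the "mapping
  scores < 3" rule as a best-vs-alternative score-difference criterion, the
  established form in non-co-linear transcript detection.

An event is retained only if clean under both profiles; adding a profile
can only shrink the retained set. In per-event outputs the co-linear flag
takes precedence, so the two failure classes are disjoint counts. Genome
and transcript hits are pooled when comparing scores.

## RCS scanning

Flanks are the ± N genomic nucleotides outside the circle span (default
N = 10 000, `--dist`), taken in transcription orientation and clipped at
chromosome ends with a flag. Across-pairs come from aligning the upstream
flank against the reverse complement of the downstream flank; within-pairs
from aligning a flank against its own reverse complement. A within-scan
sees each inverted repeat twice (mirror alignments) and a palindromic
region can align onto itself, so hits whose two members overlap are
discarded and the rest are canonicalized (left member first) and
deduplicated — each arc is counted once, matching how across/within pairs
are drawn. Fragmented hits sharing > 50 % of both spans are merged before
counting. Retention requires bitscore > 100 AND aligned columns > 50 AND
identity > 80 %, all strict; "alignment length" counts aligned columns
including gaps. Flanks are pure genomic windows — neighbouring genes are
not masked.

## miRNA site prediction

The built-in scanner anchors candidates at perfect Watson–Crick matches to
the miRNA seed (positions 2–8) and scores the full antiparallel duplex with
a weighted complementarity sum: Watson–Crick pair = 1, G:U wobble = 0.5,
seed positions doubled. Score = 6 × weighted sum and energy = −1.2 ×
weighted sum; a perfect 22-nt duplex then scores 174 with energy −34.8
kcal/mol, so the conventional retention thresholds (score > 155,
energy < −20, both strict) keep perfect and near-perfect duplexes and
reject seed-only matches (a seed-only 22-mer scores ≈ 90). The linear
factors are a deliberate calibration of this simplified scorer around those
published thresholds — with the more obvious factor 5 a perfect site would
score 145 and fail its own default cutoff; an external miRanda output file
is the fidelity path and flows through identical filtering.

Junction-spanning sites are found by scanning the circle extended with its
own first min(overhang, L) nt (default overhang 25 ≥ longest mature miRNA);
extended positions fold back modulo L, sites wholly inside the extension
are dropped as duplicates, and overlapping candidates keep the higher
score. CLIP support projects each site through the circle's exon spans to
genomic intervals and marks any ≥ 1 nt overlap with a supplied binding
region (same chromosome and strand); the CLIP annotation runs whenever a
region file is supplied, regardless of species.

## Network, categories, co-regulation

Evidence tables are merged per (miRNA, gene) with a union of source labels.
A circRNA–miRNA edge is "experimental" when CLIP-supported; a miRNA–mRNA
edge when any source is validated or clip; category 1 = both, 2 = exactly
one, 3 = neither. The co-regulation test uses the hypergeometric tail
P(X ≥ s) with X ~ Hypergeom(N, t, c) (scipy, exact in log space). The
universe N is the union of miRNAs scanned against circRNAs and miRNAs
appearing in the evidence tables — the set actually capable of generating
evidence on either axis; t, c, s are computed on the post-filter
interaction sets, since the hypothesis concerns reported interactions. One
test is run per distinct (circRNA, gene) pair appearing in ≥ 1 axis
(pairs with s = 0 included, P = 1), BH-adjusted once across all pairs
(statsmodels), and broadcast to axes; retention is FDR < 0.05, strict. The
export format is XGMML, which Cytoscape imports natively; a binary session
writer is out of scope.

## Enrichment

The 2×2 table is (targets ∩ list, targets \ list, list \ targets,
background remainder); the odds ratio is the sample cross-product ratio
(reported as infinity when a zero cell makes it undefined), and the P value
the one-tailed (enrichment) Fisher/hypergeometric tail. Target genes absent
from the background are dropped with a warning. The empirical P draws
|targets| genes without replacement from the background n\_draws times
(default 10 000) and applies empP = (1 + #{p_i > p\_obs}) / (n\_draws + 1)
with a strict inequality, so its lower bound is 1/(n\_draws + 1) and ties
never count as more extreme. Since the in-list count of a uniform draw is a
hypergeometric variate, the null is sampled directly from that distribution
with a seeded numpy Generator — identical in distribution to enumerating
gene draws, deterministic, and fast. Fisher and empirical families are
BH-adjusted separately. The background is user-supplied (a human run would
typically use ~20 000 protein-coding genes); nothing is hard-coded.

## Synthetic references

The generator emulates exactly the features the screens measure, nothing
more. Background sequence is uniform-random and verified single-copy (no
40-mer occurs twice anywhere), so negative controls are guaranteed rather
than probabilistic. Multi-exon genes (3 exons of 120–200 nt, introns
250–400 nt) alternate strands across two 100-kb chromosomes, spaced so that
neighbouring flank windows never overlap. miRNA sequences (21–23 nt) are
drawn under rejection so their seed reverse-complements occur in no
unplanted circle and in no other miRNA's site, making scanner negatives
exact. Planted features:

* duplications copy the pseudo-read to an intergenic locus (optionally
  degraded with a substitution every 10 nt: no 11-mer survives, 9-mers do —
  detectable only by the sensitive profile, identity 90 % > 80 %);
* multi-hit loci copy the two pseudo-read arms with an intervening gap,
  including 12 nt of flanking context so the planted locus can match any
  chance extension of the own locus and never loses the score comparison;
* RCS plants write segment/reverse-complement pairs into the flanks with
  exact identities (evenly spaced substitutions); consecutive plants are
  spaced 250 nt apart and across-pairs are laid out in reversed order on
  the two flanks, so no single (non-crossing) local alignment can chain two
  pairs into one hit;
* miRNA sites write the reverse complement of a miRNA into a circle;
  seed-only sites replace every non-seed position with the miRNA's own base
  at the paired position, which can neither Watson–Crick nor wobble pair.

What the fixture does **not** emulate: realistic base composition and
repeat families (Alu-like elements), splice-site motifs, expression levels,
sequencing error. Passing the planted-truth tests therefore demonstrates
the correctness of the decision rules and counting, not recall on real
repeat-rich genomes, where RCS counts and ambiguity rates are dominated by
repeat content.

The default test/acceptance problem size — 20 events on 2 × 100 kb
chromosomes with 3-kb flank windows and a 40-miRNA co-regulation universe —
is the package's chosen desk-scale study: large enough that every feature
class (3 duplications, 3 multi-hit loci, across/within/sub-threshold RCS
plants, perfect/seed-only/junction-spanning sites, all four evidence
combinations) is exercised with exact expected counts.

## Numerical and degenerate-input choices

* Strict inequalities everywhere a retention rule quotes a cutoff (155,
  −20, 100, 50, 0.80, 0.05); boundary values are rejected.
* BH ties share the adjusted value of their best rank after monotonization;
  adjustment is order-invariant and never below the raw P.
* Deterministic tie-breaks: transcripts by id, hits by (−score, target,
  position), outputs sorted by event/miRNA/gene. Parallel screening
  (`-p`/workers) farms out whole events and re-sorts by event id, so
  parallel runs are byte-identical to serial ones.
* Flank windows and region extractions clip at chromosome ends and carry a
  `clipped` flag instead of erroring.
* Empty inputs produce empty-but-valid outputs (header-only tables, a valid
  empty XGMML document).

## Known limitations

* The built-in site scanner is a seed-anchored linear model, not a
  thermodynamic folder; bulged duplexes and seed wobbles are out of reach
  of the candidate stage (the miRanda adapter covers them).
* The windowed aligner guarantees the local optimum only within seeded
  windows; alignments with no intact seed k-mer are invisible by design,
  exactly as in tile-based production aligners.
* Events whose donor/acceptor boundaries exist only in unannotated
  transcripts fail validation; intronic circRNAs are unsupported.
* repMatch-style repeat masking is abstracted into a hit-count cap; on
  repeat-dense genomes the external-aligner path is the realistic one.
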