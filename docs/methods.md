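# Methods

## Gene model and coordinates

GFF3 (1-based, closed intervals) is converted to 0-based half-open
coordinates at the single parsing entry point; all downstream interval
arithmetic uses that convention, which removes the usual off-by-one drift
between annotation, BED output and alignment blocks. Introns are derived
per transcript as the gaps between consecutive exons; intron ordinals
count in transcription order, so for a minus-strand transcript intron 1 is
the highest-coordinate intron. When several transcripts of a gene imply
the same genomic interval, the catalog merges them into one entry carrying
the union of transcript ids — intron-level statistics are then reported
once per distinct interval, and gene-level summaries count each intron
once.

Exons extending beyond their chromosome are rejected with a logged
warning; overlapping exons within a transcript and transcripts without
exon children are hard errors, because both indicate a corrupt annotation
rather than a tolerable record.

## Retention quantification

The retention level of intron *i* is
`IR = n_intron / n_transcript`:

- `n_intron` — reads with at least one aligned block overlapping the
  intron by ≥ `min_overlap` nt (default 1). A read whose `N` gap spans the
  intron is **not** an intron read: it is junction evidence of the spliced
  isoform and is tallied separately. The numerator therefore contains
  retention evidence only.
- `n_transcript` — distinct reads whose blocks overlap the genomic span
  (exons + introns) of any transcript carrying the intron. Counting the
  span rather than exonic intervals keeps retained-intron reads in the
  denominator, so IR ∈ [0, 1]. IR is undefined (NaN) when the denominator
  is zero, and such introns are excluded downstream.

Read strand is ignored; each mate of a pair, if present, counts
independently. Library size is the number of distinct reads assigned to
any transcript, and gene CPM is `10^6 · n_gene / library_size`. The
expression filter requires CPM ≥ threshold (inclusive) in **every**
sample; the default threshold is 10, with 1 available through
configuration — both conventions circulate for "detectable expression"
and the choice is recorded in every output header.

The two-isoform estimator `n_intron / (n_intron + n_junction)` requires a
minimum of 10 informative reads by default. It deliberately does not
length-normalize: an intron-retaining molecule exposes `m + r − 1` read
start positions that overlap the intron while a spliced molecule exposes
`r − 1` junction-spanning starts, so the read-level fraction overstates
the molecule-level retained fraction. Tests validate it against exactly
that position-enumeration expectation.

## Differential classification

Per replicate pair, `FC = (IR_test + ε)/(IR_ref + ε)` with ε = 0.001. The
pseudocount is applied to the ratio of rates, not to raw counts, because
the retention level is already a rate; ε bounds the FC when the reference
IR is 0 and cancels exactly when both IRs are equal. Bins are assigned
from the minimum FC across replicates — the strictest reading of "changed
in both replicates" — and partition the classified introns:
`<2` (min FC ≤ 2), `2-4` (2, 4], `>4` (4, 8], `>8` (> 8). "Over x-fold"
queries use `min_fc > x` directly so the nested counts (over 2-fold ⊇
over 4-fold ⊇ over 8-fold) remain available. Direction is `increase` when
every replicate FC exceeds 1, `decrease` when every FC is below 1
(magnitude then uses 1/FC), otherwise `none`. The global condition
comparison is Welch's unequal-variance t-test on the IR distributions,
reported per replicate pair and pooled; a plain t-test is the conventional
choice for box-plot-level comparisons of retention levels, and the
nonparametric alternative is available for the feature comparisons below.

Gene summaries report the fraction of classified introns affected at each
threshold (concordant increase) and the fraction of genes with ≥ 1
affected intron, always together with their denominators — introns and
genes that passed the expression filter — because headline percentages
are meaningless without them.

Suppressor recovery: the deficient set contains introns with a concordant
> 8-fold retention increase in the mutant versus wild type. An intron is
recovered when every suppressor sample shows IR within 2-fold of the mean
wild-type IR. The suppressor replicate layout is not constrained to match
the main design (suppressor strains are often sequenced once), hence the
per-sample rule and the mean-wild-type baseline.

## Branch points and sequence features

The branch-point scanner matches an IUPAC consensus (default `CTRAC`,
one literal `A` anchor — the branch adenosine) against the intron's
coding-strand sequence. Candidates are restricted to branch-A distances of
5–60 nt from the 3' end (0-based offsets); the score is the fraction of
consensus positions satisfied, the anchor must match exactly, ties go to
the candidate nearest the 3'ss (the biologically typical position), and
calls below `min_score = 0.8` are rejected. Consensus, window and score
threshold are configuration: fungal branch points follow a CURAY-like
consensus but there is no single canonical scanning rule, so the defaults
are a documented, conservative convention, and the scanner is tested for
exact equivalence with brute-force scoring of every window.

Distances are measured to/from the branch adenosine with 0-based offsets:
`dist_5ss_bp` is the A's offset from the intron start,
`dist_bp_3ss = length − 1 − dist_5ss_bp`, so the two always sum to
`length − 1`. Feature comparisons (length, both BP distances,
introns-per-gene) between affected (> 4-fold, concordant increase) and
unaffected (≤ 2-fold in every replicate) introns use Welch's t by default
with Mann-Whitney as the alternative; introns between the two cutoffs
belong to neither class and are excluded rather than diluting either.

Position frequency matrices are built from equal-length windows (5'ss: 3
exonic + 8 intronic nt; 3'ss: 12 intronic + 3 exonic; BP: 7 nt centered
on the branch A). `N` bases carry no column weight. Information content is
2 − H (bits). Motif comparison reports per-column Jensen-Shannon
divergence and chi-square p-values on counts, with Bonferroni correction
across columns; "no difference" means no column rejects after correction
— deliberately conservative, since the claim being supported is a
negative one.

## The simulator

The simulator emulates a two-condition × two-replicate design over a toy
genome: random genes (default 100) with 0–4 introns, exons 120–300 bp,
introns 55–115 bp (centered near the ~83 bp genome-wide average typical
of compact fungal genomes), half on the minus strand, canonical `GT..AG`
boundaries, and exactly one embedded branch-point consensus per intron at
a recorded distance 7–50 nt from the 3'ss (accidental exact-consensus
matches are mutated away so the planted site is the unique exact match —
the intron has one branch point by construction). Per-gene expected read
counts are log-uniform over 0.5–2000 so the CPM filter boundary is
exercised in both directions.

Retention truth: wild-type θ = 0.02 for every intron; mutant θ is a
mixture — with probability 0.55 the intron keeps the wild-type level
(unaffected), otherwise θ ~ Uniform(0.08, 0.6) — emulating a mutant that
impairs splicing of a subset of introns rather than abolishing it.
Explicit per-intron θ maps, scalars or ranges can replace either spec.

Reads are emitted directly as perfect-match, single-end, MAPQ-255 SAM
alignments (sorted, with `@SQ` headers), removing any aligner from the
loop: molecule forms retain each intron independently with its θ; a form
is chosen with probability proportional to its abundance times its number
of valid read starts, and the start is uniform — making read density
uniform per molecule nucleotide, which is exactly the sampling scheme
under which the closed-form expected retention level is exact rather than
approximate. Skipped introns appear as `N` gaps whose intervals match the
annotation exactly. All randomness flows from one integer seed (per-sample
streams are derived via CRC32 tags, masked below 2³¹); reruns are
byte-identical.

What the simulator does **not** emulate: sequencing errors, mismatches and
multi-mappers; paired-end fragments; positional coverage bias; partial or
recursive splicing order effects (introns are independent); alternative
splice sites; overlapping genes. Passing tests therefore demonstrate the
correctness of the counting, estimation and classification machinery under
the stated sampling model — not robustness to alignment artifacts in real
libraries, which should be handled upstream (MAPQ filtering is available).

## Problem sizes and numerical choices

- The fold-factor binning study uses θ_wt = 0.02 with planted factors
  {1, 3, 6, 16}, 50 single-intron genes per factor, two replicates per
  condition, read length 50, exons 55–65 bp and introns 75–95 bp, at an
  expected depth of 1500 reads per gene. The depth was set by a counting-
  noise calculation: with ~70 wild-type intron reads per gene, the
  standard error of log FC (~0.13–0.16) leaves ≥ 2 standard errors to the
  nearest bin boundary for every planted factor, so ≥ 90% correct bin
  assignment per group is expected; shallower depth puts the factor-6
  group too close to the 4-fold boundary.
- Retention-recovery checks use ≥ 5000 transcript reads so the 3-SE
  binomial band around E[IR] is a few parts in a thousand.
- Type-I calibration of the feature test uses 200 repetitions of a null
  split (gamma-distributed lengths), accepting a 1–10% empirical rejection
  band at nominal 5%.
- Welch's t is used wherever a t-test is called for; degenerate PFM
  columns (no contrast) are assigned p = 1; BED/TSV round trips preserve
  coordinates exactly; undefined quantities (zero denominators, empty
  deficient sets) are NaN/None sentinels, never zeros.

## Known limitations

- IR compares intron reads to whole-transcript reads, so long transcripts
  with many introns dilute each intron's signal; the estimator is unbiased
  under the simulator's uniform sampling but depth-sensitive at low CPM.
- Fold-change binning is a thresholding procedure, not a statistical test
  per intron; no per-intron FDR is computed (count-based models such as
  beta-binomial GLMs are out of scope by design).
- The branch-point scan reports the best consensus match, which on short
  introns with weak consensus may be absent; distance features are then
  null and excluded, which can bias distance comparisons toward introns
  with strong branch points.
- Multi-transcript genes share reads across transcripts without EM-style
  assignment; the intron denominator uses the union of carrying
  transcripts.
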