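# Methods

This note records the models, conventions and numerical choices behind
each stage, what the synthetic data does and does not emulate, and the
known limitations.

## Coordinates, alphabets, formats

Genomic intervals are 0-based half-open internally; every user-facing
report (cleavage positions, locus tables) is 1-based inclusive.
Sequences are compared in DNA space (U mapped to T, uppercased); writers
preserve the alphabet of the reference they were given. All tabular
artifacts are TSV with a single commented header line (`#...`).
Adapter/quality trimming is out of scope: tag tables and FASTQ inputs
are assumed to be clean reads. Unique tags are obtained by collapsing
reads before genome matching.

## Annotation

Each 18–28 nt tag receives exactly one category by the priority rule
`rRNAetc (GenBank > Rfam) > known miRNA > repeat > exon > intron`, else
`unann`. Sequence-database classes (structural RNAs, known miRNAs) are
assigned by sequence match — equality or containment, U/T-insensitive —
regardless of genome position, mirroring a database-first annotation
flow; interval classes (repeat/exon/intron) require an exact genome hit
overlapping the interval by ≥1 nt on either strand (the strandedness of
repeat/exon matching is a convention; any-strand is the permissive
choice). Multi-hit tags take the best class over all hits. Genome
matching is exact (both strands); the summary table conserves mass:
category uniques/totals partition the clean reads.

## Known miRNA identification

Four steps. (1) Tags are aligned to the reference mature/precursor
database semi-globally; the alignment minimises total edits (mismatch
and gap each cost 1, ties toward fewer mismatches) and is accepted when
the optimal alignment has ≤2 mismatches **and** ≤3 gaps — the budgets
are separate, and checking them on the minimum-edit alignment prevents a
substitution from being re-explained as two gaps. (2) Per family, the
assigned tag with the highest summed count becomes the representative
(ties: lexicographically smaller sequence). (3) Expression is
re-quantified ungapped: every tag within 2 mismatches of a
representative contributes its counts to exactly one representative —
its best match, ties toward the higher-expressed representative, so no
tag is counted twice. (4) A precursor that cannot fold into a hairpin
would mark the record as pseudo; the hairpin test below is shared with
novel prediction. A miRNA is reported for a genotype only when
identified in both of its replicate libraries.

## Novel miRNA prediction

Candidate tags (unannotated genome-matching, intron, antisense-exon)
are clustered by genomic position (gap ≤ 100 nt). The cluster's
highest-count tag is the mature candidate; a grid of excision windows
(lengths 80–300 nt, small upstream offsets, anchored at either cluster
edge) is folded with ViennaRNA's deterministic MFE fold, and the first
window satisfying all criteria is kept:

- **hairpin**: the mature is wholly in one arm (all pairing partners on
  one side) and at most one terminal loop lies between the mature and
  its partner region (no multiloop);
- **star**: the star interval is computed from the pairing as
  `[partner(mature_end−2), partner(mature_start)+2]`, giving 2-nt 3′
  overhangs at both duplex ends; the computation fails when an anchor is
  unpaired, the mature spans the loop, the interval leaves the
  precursor (blunt end at the boundary) or the mature's overhang bases
  pair into the star. The star sequence must additionally be observed
  among the sequenced tags (novel records require a miRNA\*);
- **duplex bulges**: the largest internal loop/bulge side within the
  mature-anchored duplex must be ≤ 5 nt (the threshold is configurable;
  the underlying criterion — "no large loops or bulges" — is qualitative);
- **MFE** ≤ −18 kcal/mol;
- **expression**: summed mature count ≥ 5 (inclusive).

A hairpin is an inverted repeat and therefore matches both genome
strands; records sharing the mature at overlapping coordinates are
deduplicated, and hairpins whose mature or star is already in the known
reference are not reported as novel.

## Differential expression

RPM = count / library total × 10⁶, where the totals are the library
clean-read totals (not the sums of the quantified subset — this keeps a
single abundant miRNA from shifting every other gene's ratio). Exact
zeros are then imputed to 0.01. For gene A,
`M_A = log₂(MT_avg / WT_avg)` and `D_A = |WT_avg − MT_avg|`, with
imputation applied per library before averaging. The noise model is the
set of per-gene (Mₙ, Dₙ) points from every within-group unordered
library pair (2 groups × 1 pair × G genes = 2G points for the 2+2
design), and

    prob = #{ |Mₙ| < |M_A| and Dₙ < D_A } / #points.

Strict inequality on both axes is the conservative tie-handling choice
(ties count against the signal). Significance is `|M_A| ≥ 1.0` (inclusive)
and `prob > 0.8` (strict). The published NOISeq package adds resampling
and kernel smoothing around the same idea; this module implements the
plain empirical-counting model and documents the divergence. Output
tables round M to two decimals, half away from zero. No
multiple-testing correction is applied.

## Degradome target calling

Degradome tags are first reannotated by `Rfam > GenBank > polyN`
(polyN: one base strictly >70% of the tag). Surviving tags are matched
to cDNA sense strands; their 5′ ends form per-transcript
position→abundance profiles. For each (miRNA, transcript), every
supported position is tested as a cleavage site by excising the window
whose ungapped placement pairs that position with miRNA position 10,
and scoring miRNA vs. reverse-complemented window with a global DP:
mismatch 1.0, G:U 0.5, gap 1.0, penalties doubled at miRNA positions
2–13 (the score threshold of 4.5 is applied after the core weighting).
Pairs with score ≤ 4.5 are targets; the per-pair best (category, score)
site is reported. The cleavage coordinate is the transcript base
pairing miRNA position 10 — for an ungapped L-nt window starting at s
(1-based) that is `s + L − 10` — i.e. the 5′-most nucleotide of the
downstream fragment.

Categories: a site with exactly one raw read is category 4 regardless
of the rest of the transcript (this precedence makes the "only raw
reads" wording deterministic); otherwise 0 = unique maximum, 1 = shared
maximum, 2 = above the median, 3 = at or below the median, with the
median taken over positions with ≥1 read so that long unsupported
transcripts cannot force category 2. The published per-target P-value
has no printed formula and is emitted as `NA`.

## Phasing

Only 21-nt genome-matching tags enter. A tag's effective position is
its 5′ start; antisense tags are shifted +2 nt onto the sense register
(duplex 3′-overhang geometry). Windows of phase × cycles = 231 nt are
anchored at every observed effective start; within a window, n =
distinct (strand, position) pairs, k = those on the anchor's 21-nt
register, and

    P = hypergeometric tail P(X ≥ k),  population 2·21·11 = 462,
        successes 2·11 = 22, draws n.

Windows need k ≥ 3 and P ≤ 10⁻⁴; overlapping significant windows merge
keeping the minimum-P window's coordinates. The statistic counts
distinct start positions, not read counts. The published algorithm has
variant population/success definitions; the one implemented here is
stated above and is verified against an explicit combinatorial
enumeration in the tests, not against the original tool. Triggers:
a degradome-supported cleavage site falling within a locus window
extended by one phase on each side links that miRNA to the locus.

## Synthetic data

Hairpin loci are built as perfect inverted repeats (arm, loop, reverse
complement) with the mature planted 3 nt from the arm end, so the
canonical star (2-nt 3′ overhangs) fits inside the precursor; knobs
exist to plant a blunt star (`overhang=0`) or an oversized duplex bulge,
which the criterion-ablation tests use. Locus abundance is log-normal
(`meanlog 4, sdlog 1.2` — many low, few high, matching the
orders-of-magnitude RPM spread real libraries show), replicates are
Poisson around the group mean, fold-change injections multiply the MT
mean, and random background tags are added at a configurable row
fraction. Degradome profiles can be forced into each category 0–4, with
unsatisfiable requests rejected. Phased loci plant tags exactly on the
register (antisense at register −2) plus uniform off-register tags.
Every generator is a pure function of (config, seed).

Not emulated: sequencing error, quality scores, adapters, isomiR
heterogeneity, multi-locus identical matures, composition bias between
libraries, and genome repeats. Passing tests therefore demonstrate the
correctness of the computations under clean planted signals, not
robustness to those real-data effects.

## Problem sizes and determinism

The shipped demo uses a 60 kb single-chromosome genome, 12 miRNA loci,
2 phased loci and 4 target transcripts; the acceptance script uses 1000
random degradome profiles, 20 × 200-gene DE simulations, 10 000 random
phasing windows, and a 9-locus end-to-end run. These sizes exercise
every code path while keeping a full run in well under a minute per
stage. All randomness flows from explicit seeds; identical configs
reproduce byte-identical outputs.

## Known limitations

- Genome matching is exact only; mismatched genome hits (and hence
  mismatch-tolerant interval annotation) are not supported.
- Novel-locus excision uses a fixed window grid rather than
  read-cluster-shape heuristics; very long precursors (>300 nt) are not
  excised.
- The DE probability is the plain empirical count; with few genes the
  noise cloud is coarse and prob takes few distinct values.
- `call_targets` scores ungapped window placements (the scorer itself
  supports gaps); bulged target sites shift the reported site by the
  gap offset.
- Phasing abundance weighting is not implemented; distinct starts only.
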