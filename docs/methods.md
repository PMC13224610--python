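# Methods

## The proximity-enrichment model

The pipeline quantifies whether point events on a genome — DSB breakends,
SNVs, or cohort mutations, all width-1 intervals at the recorded nucleotide —
co-occur with a feature track of G4 motif intervals more often than chance.
The primitive is *windowed association*: an event is associated with the
track if the symmetric extension of its interval by `w` bp intersects at
least one base of any feature, computed in 0-based half-open coordinates.
This replicates `bedtools window -u -w` exactly: the query is reported at
most once, with original coordinates, and duplicate events (two breakends at
one base) count individually.  The phrase "within w bp" is defined
operationally by this window semantics, not by a separate distance metric;
`w = 5` is the default analysis window.

Three layers of inference sit on top:

1. **Per-sample percents.**  `100 · |associated| / |events|` per sample or
   replicate, displayed against *shuffled controls*: the same events
   relocated uniformly at random over the genome (chromosome drawn with
   probability proportional to length, start uniform over valid positions,
   widths preserved, exclusion regions avoided by rejection sampling with up
   to 1000 tries per interval).  One shuffle replicate per observed set is
   the default, matching the one-control-per-sample display convention; a
   many-shuffle mode reports the full list.  Replicate `r` draws from seed
   `seed + r` so any single replicate is reproducible in isolation.
2. **Pooled contingency.**  Conditions (e.g. parental vs knockout, replicates
   combined) form the rows of a 2×2 table with columns
   (associated, not associated).  Expected counts come from the marginals;
   the statistic is the sum of squared Pearson residuals `(O−E)/√E` with
   df = 1 and **no continuity correction** — the residuals are the quantities
   shaded in mosaic plots and are defined without it.
3. **Distance decay.**  Bin `i` of a distance profile counts events
   associated at window `edges[i]` but not at `edges[i−1]` (edge 0 = direct
   intersection).  Bins are mutually exclusive by construction and sum to the
   count at the outermost edge.  The two display resolutions are 5 bp bins
   over 0–50 bp and 1 bp bins over 0–5 bp; a true at-the-motif effect puts
   the entire between-condition excess in the 0 bp bin.

Group comparisons use rank statistics: Mann–Whitney (exact null when both
sizes ≤ 8 and tie-free, tie-corrected normal approximation otherwise),
one-sample Wilcoxon (zeros dropped; exact for n ≤ 15 tie-free), and
Kruskal–Wallis with Dunn's pairwise z-tests on mean pooled ranks,
Bonferroni-adjusted over all pairs (the procedure names the test but not the
adjustment family; Bonferroni is the standard Dunn choice).  Fold changes use
a pseudocount, `(obs + 1)/(ctrl + 1)`, so empty controls cannot divide by
zero.

## PQS scanner

The canonical predicted-quadruplex grammar is four tracts of ≥ 3 guanines
separated by loops of 1–7 nt, total length ≤ 50 bp; all four numbers are
configurable.  Matching is leftmost-greedy and non-overlapping per strand;
the ambiguity code N never matches a tract or loop base, so any N breaks a
candidate motif.  Minus-strand motifs (C-run mirror images) are found by
scanning the reverse complement with the same grammar and mirroring
coordinates, which makes the collapsed (strand-merged) track exactly
symmetric under reverse complementation — a tested invariant rather than an
approximation.  The scanner is a motif-grammar stand-in, not a thermodynamic
or machine-learning scorer: the enrichment machinery accepts any externally
produced G4 BED track interchangeably, and real-genome PQS counts from
scoring tools are not a replication surface here.

## Confounder stratification

G4s concentrate in promoters and open chromatin, so an apparent G4
association can be driven by those features instead.  The stratified
re-analysis removes events within `w` (by default the same window as the main
analysis) of *any* supplied confounder track — open-chromatin peaks,
promoter/enhancer elements, histone-PTM peaks — from every condition, then
recomputes the pooled contingency on the remainder, reporting retained counts
per condition.  A planted enrichment that is independent of the confounder
track survives this exclusion; one that is merely a shadow of the confounder
does not.

## Cohort procedure

Samples carry mutation-status flags for two stratifying genes.  Samples
mutant in both are excluded outright ("double mutant") to avoid confounded
assignment; the rest partition into geneA-mutant, geneB-mutant and neither.
Mutations (SNV/MNV/indel pooled into one per-sample statistic) are loaded
from MAF-like 1-based or BED-like 0-based TSV, converted to half-open
coordinates at the boundary.  Per-sample percent-within-`w` is computed over
that sample's records only; zero-mutation samples are dropped with a warning
(no minimum mutation count is imposed).  Shuffled controls relocate each
sample's mutations with a blacklist excluded.  Because the mutant group is
typically small, the two larger groups are also subsampled without
replacement to its size (one draw per run, seed logged) and medians
recomputed; subsampling never changes a per-sample percent, only group
membership.  The three retained groups are compared with Kruskal–Wallis +
Dunn.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the pipeline must detect,
with known truth:

- **Genome.**  Background bases are drawn at the requested GC fraction with
  every G-run and C-run capped at `min_tract − 1`, so the background provably
  contains no canonical motif on either strand; motifs (default the 21 bp
  four-tract `GGGTTAGGGTTAGGGTTAGGG`, telomere-repeat-like) are planted at
  uniform non-overlapping positions with a minimum spacing, and one flanking
  base on each side is forced to A so adjacent background guanines cannot
  extend a planted tract.  Scanner recall and precision on such genomes are
  exactly 100%, which is what makes the round-trip test sharp.
- **Events.**  Each event independently falls uniformly inside the motif
  footprint with probability `p`, otherwise uniformly on the genome, so the
  expected direct-intersection percent is `100·(p + (1−p)·f)` with `f` the
  footprint fraction.  Truth flags are returned aligned to the sorted event
  order.
- **Peaks.**  A stated fraction of peaks is forced to cover a motif base;
  condition-specific event counts are Poisson draws over the four disjoint
  base strata (peak∩motif, peak-only, motif-only, background), uniform within
  each stratum.
- **Cohorts.**  Per-group sample counts, a Poisson or negative-binomial
  mutations-per-sample distribution, group-specific `p`, planted double
  mutants, and an optional random blacklist.

What it deliberately does **not** emulate: mutational signatures and
context-dependent rates, replication timing, transcription-coupled damage,
chromatin-state correlations between tracks, and non-canonical (bulged or
mismatched) motifs.  Passing tests therefore demonstrate that the machinery
measures planted mixture-model enrichment correctly and calibrates its null;
they do not certify effect sizes on real genomes, where G4 tracks, event
rates and confounders are all correlated.

## Defaults and problem sizes

| Parameter | Default | Notes |
| --- | --- | --- |
| analysis window `w` | 5 bp | symmetric extension, both directions |
| PQS grammar | G≥3, 4 tracts, loops 1–7 nt, ≤ 50 bp | configurable |
| shuffle | chromosome not preserved, 1000 tries | exclusions apply to shuffles only |
| merge gap | 0 (book-ended intervals fuse) | fuse iff `start₂ − end₁ ≤ gap` |
| promoter window | −3000/+3000 bp around TSS | downstream limit 3000 bp |
| TSS distance bins | 1, 3, 5, 10, 100 kb | edges configurable |
| shuffle replicates | 1 per observed set | many-shuffle mode available |
| desk-scale study | 1 Mb genome, 476 × 21 bp motifs (f ≈ 1%), 10,000 events/condition | runs in seconds |
| cohort study | 10/50/50 samples, ~500 mutations each | 3 planted double mutants |

The desk-scale sizes are the package's chosen study conditions for its own
simulation-based verification: large enough that binomial standard errors on
a 1% footprint are a fraction of the planted effects, small enough that the
full suite and the acceptance script run in minutes on one CPU.

## Numerical and design choices

- One internal coordinate convention (0-based half-open) everywhere;
  1-based inclusive inputs (MAF-like, GFF3) convert at the I/O boundary.
- Merge fuses intervals iff `start₂ − end₁ ≤ gap`; book-ended intervals fuse
  at gap 0.  Replicate consensus counts each replicate's coverage once per
  base (internal duplicates collapse) and returns maximal runs covered by at
  least `k` replicates.
- Shuffling draws target chromosomes length-proportionally by default;
  whether the original procedure preserved chromosome assignment is not
  documented, so the tool-default behaviour was chosen and `preserve_chrom`
  exposed.  Shuffled intervals may overlap each other, as placements are
  independent.
- Nearest-TSS ties break by lexicographic gene id; feature categories use the
  fixed priority Promoter > Exon > Intron > Downstream > Distal Intergenic,
  with no UTR split (gene spans + optional exons are the input, not full
  transcript models).
- Exact rank tests switch to tie-corrected normal approximations in the
  presence of ties; p-values are reported at full precision, never truncated
  at display thresholds.
- All generators and analyses are deterministic under a master seed; derived
  streams (seed + replicate index) keep every replicate independently
  reproducible, and seeds are logged in outputs.

## Known limitations

- The scanner collapses overlapping alternative quadruplex registers into one
  leftmost-greedy hit; it does not enumerate register ambiguity or score
  stability.
- Rejection-sampled shuffling becomes slow (and eventually errors, naming the
  interval) when exclusions cover most of a chromosome; this is intended
  behaviour rather than a silent fallback.
- The null-calibration checks rely on chi-square asymptotics, which need
  expected cell counts of a few tens; very sparse tables (tiny `f·n`) are the
  user's responsibility to avoid.
- The cohort loader trusts the supplied status table for mutant/wild-type
  assignment; it does not call gene mutations from the records themselves.
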