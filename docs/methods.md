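# Methods

`enhancerlink` implements the integrative procedure for identifying the
active enhancer network of a ligand-activated nuclear receptor in a
differentiated cell type: nascent-transcription (GRO-seq-style) transcript
and divergent-site calling, classification of transcription-factor binding
sites into transcriptionally active versus silent, ligand-induced change
calling, enhancer-to-gene annotation, CTCF/cohesin functional-domain
construction, and 3C-style interaction-frequency statistics. This note
describes the models, the tunable parameters, the synthetic-data generator
that stands in for sequencing data, and the numerical choices made where
the design was open.

## Coordinate model and formats

All internal coordinates are 0-based half-open (BED-native). GTF input
(1-based closed) is converted at the I/O boundary; the TSS of a gene is the
strand-appropriate end of the union of its records. Strand `.` is allowed
on peaks only; transcript units are always stranded. Overlapping bedGraph
records are summed (tolerant of replicate-merged tracks) with a warning.

## Transcript units and divergent sites

A coverage track is segmented per strand into maximal runs of nonzero
signal; runs separated by at most `max_gap_bp` (default 50 bp) of zero
signal are merged, and runs shorter than `min_length_bp` (default 50 bp)
or below an RPKM floor are discarded. RPKM is
`read_count / ((length/10^3) x (library/10^6))` where `read_count` is the
coverage mass inside the unit. Two floors carry the biology and are
deliberately separate parameters:

- **0.006 RPKM** — the expression floor used when measuring the
  transcribed fraction of the genome;
- **0.2 RPKM** — the floor (on the stronger partner) for divergent-site
  calling.

A divergent site pairs a minus-strand and a plus-strand unit on one
chromosome whose 5' ends are less than 300 bp apart (strict) and point
away from each other. We require the plus-strand 5' end to lie at or to
the right of the minus-strand 5' end; convergent configurations are
elongation, not initiation, and are never sites. Pairing is a greedy
matching by smallest 5'-gap with leftmost tie-break, so each unit joins at
most one site and the output is deterministic and order-independent for
sorted input. Whether both partners or only the stronger one must clear
the 0.2 RPKM floor is ambiguous in the underlying protocol; the default
tests only the maximum, with a `require_both` switch.

The site's BED interval spans the two 5' ends. For differential testing,
however, reads are counted over the site's transcribed *span* (from the
start of the minus arm to the end of the plus arm, both strands): the
inter-5'-end interval itself is empty of signal by construction, since both
transcripts point away from it.

## Cistrome integration

Binding sites are classified GRO-positive iff they overlap (>= 1 bp) a
divergent-site interval; the partition is exhaustive and exclusive and is
asserted on every run. Overlap reports use >= 1 bp by default (the most
permissive convention). Summit profiles bin both-strand coverage in a 3-kb
window (25-bp bins) around the peak summit, defaulting to the interval
midpoint when no summit is recorded. TSS distances are signed and
gene-strand-oriented (negative = upstream), closest by absolute value with
ties to the lexicographically smaller gene id.

Motif scanning is deliberately a literal consensus scan, not a PWM:
direct repeats DR0-DR5 of the nuclear-receptor half-site `AGGTCA` are
matched with a per-half mismatch budget (default 1) on both strands, `N`
never matching. This mirrors fuzznuc-style targeted scanning; de novo
discovery is out of scope.

## Differential calling

Changes between a vehicle and a ligand library are tested per region with
a two-sided exact binomial test of the ligand count against the pooled
count, null success probability `lib_ligand / (lib_vehicle + lib_ligand)`
(the conditional Poisson test for equal depth-normalized rates).
P-values are Benjamini-Hochberg adjusted; a region is `up` (`down`) when
the depth-normalized fold change strictly exceeds 2 (falls below 1/2) and
q < 0.1 — "FDR < 0.1 and a more than twofold change". A pseudocount of 1
read per condition enters the fold change only, never the test. Zero-count
regions get p = 1. Replicates are summed before counting; in a time
course, each later timepoint is tested against t0 and a region changes if
any timepoint passes, signed by the most significant one.

The pipeline passes *effective* library sizes to this test: the ligand
library is rescaled by the median per-gene count ratio (median-of-ratios,
the DESeq-style estimator under the assumption that most genes are
unchanged). Equal-depth sequencing of a strongly induced transcriptome is
compositionally shifted — unchanged regions lose count share to induced
ones — and without this correction truly unchanged weak regions drift
toward spurious "down" calls. With it, unchanged regions center on fold 1
and induced regions recover the planted fold.

## Enhancer-to-gene annotation

Regions eligible for annotation are GRO-positive signal-factor peaks whose
matched divergent site changes. Each is assigned to the closest changing
gene by |region midpoint - TSS| — genome-wide within the chromosome by
default, because very-long-range enhancers are the point of the method; an
optional cap drops-and-counts distal assignments, and an optional flag
restricts candidates to genes sharing a merged CTCF/cohesin domain.
Distance ties go to the more significantly changing gene, then to the
smaller gene id. Sign-concordant assignments (region and gene both up or
both down) are enhancers; discordant ones are silencers — the declared
operationalization of the enhancer/silencer split, flagged as such in the
output. `assigned = enhancers + silencers` is asserted on every run.

## Functional domains

CTCF/RAD21 co-peaks (>= 1 bp overlap; each CTCF peak takes its
largest-overlap RAD21 partner, ties leftmost) become boundaries when both
scores strictly exceed 15 and their ratio is strictly below 3. The same
3-fold similarity constant is reused when pairing boundaries into domains
(one consistent constant, separately exposed). Pairing scans left to
right: an unconsumed boundary pairs with the nearest unconsumed
score-similar boundary to its right; both are consumed, and any boundaries
skipped in between are retired unpaired, because pairing them afterwards
would create overlapping domains. Domain coordinates run between boundary
interval midpoints (symmetric and deterministic; the source protocol is
silent on this). Consecutive domains separated by strictly less than
100 kb merge transitively into active domains; merging is idempotent. A
regulated gene resides in the architecture when its TSS and *all* of its
assigned regions fall within a single merged domain.

## Interaction statistics

Reads anchored at one bait are mapped onto fixed 1-Mb windows (last window
truncated) and expressed as frequencies normalized to 1000 total reads.
Bins are classified with precedence target > active > inactive: target if
the bin overlaps any regulated gene or assigned region, active if it
overlaps a merged domain, inactive otherwise. Class frequency
distributions are compared with an unpaired two-tailed Welch t-test
(pooled-variance available via a flag; "unpaired two-tailed t-test" is
ambiguous and Welch is the robust default), optionally excluding the
bait's own chromosome to isolate interchromosomal signal. Restriction
fragments are not modeled; at megabase resolution prey positions are
points.

## The synthetic genome

The generator plants a complete, internally consistent study on a compact
genome (default: 4 chromosomes x 2.5 Mb). Planted features:

- **Genes** (default 200, 4-8 kb) in regularly spaced slots inside
  domains, random strand, each with a divergent promoter: the gene-body
  transcript plus an opposite-strand 300-500 bp upstream arm whose 5' end
  sits exactly `divergent_gap_bp` (default 150) from the TSS.
- **Enhancers** (default 300) placed 3-10.5 kb upstream of their target
  gene's TSS, each two outward-pointing 300-500 bp eRNA transcripts with
  5' ends `divergent_gap_bp` apart, plus a signal-factor (RXR) peak over
  the center; lineage-factor (PU.1) peaks cover ~75% of signal-factor
  sites plus standalone promoter sites, and cofactor (P300) peaks mark
  active enhancers. Placement guarantees the nearest changing TSS is the
  true target, so nearest-gene annotation is well-posed against ground
  truth.
- **Ligand response**: a fraction of genes (default 0.25, i.e. 50) is
  induced `gene_fold_change`-fold (default 4); their promoter arms and
  enhancers follow (`erna_fold_change`). Induced genes are confined to
  domains in the first megabase of each chromosome so megabase bins have
  deterministic regulatory classes.
- **Silent signal-factor sites** (default 250) in untranscribed gaps —
  the GRO-negative class.
- **Boundaries and domains**: CTCF and RAD21 co-located at domain edges
  with scores drawn so that within-site and within-domain ratios stay
  below 3; decoy co-peaks with >= 3-fold score ratios, lone CTCF peaks and
  sub-threshold co-peaks exercise every rejection rule. Inter-domain gaps
  alternate below/above the 100-kb merge threshold so merging is
  non-trivial and its expected result is known at planting time.
- **Filler transcripts** top the transcribed genome up to
  `target_transcribed_fraction` (default 0.20) and absorb the read mass
  not attributed to genes and eRNAs, so each condition's expected total
  equals `library_size` exactly.
- **Interaction reads** (default 3000, 80% trans) for one bait at an
  active enhancer: trans reads land in 1-Mb bins at rates proportional to
  1:2:3 for inactive:active:target bins. The depth is chosen so the Welch
  test at 3 bins per class (all a 10-Mb genome affords) detects the 3x
  target enrichment at p < 0.01 with per-replicate power ~0.999
  (Monte-Carlo verified); real bait libraries are far deeper.

**Noise model.** Each region's read count per condition is Poisson around
its expected mass (negative-binomial via an `overdispersion` switch),
spread uniformly within the region; `noise=False` gives exact expected
counts for noise-free recovery tests. Coverage is therefore piecewise
constant — realistic position-level raggedness, 5'-end shot noise, mapping
artifacts and batch effects are *not* modeled, so passing recovery tests
demonstrates correctness of the algorithms under the stated statistical
structure, not robustness to real-data messiness.

**Scale conventions.** Planted RPKM values live on the compact genome's
scale: 10^6 reads over 10 Mb is a mean depth of 0.1x, about 0.5x over the
transcribed 20%, so default basal values are 600 RPKM for genes (~0.6x
depth, ~3600 reads per gene) and 50 RPKM for eRNA arms (~20 reads per
arm). Carrying over mammalian-scale RPKM values (an eRNA near 1 RPKM)
would leave ~0.4 expected reads per arm at this library size and nothing
would be detectable; depth, not RPKM, is the scale-invariant quantity.
The printed thresholds (0.006 / 0.2 RPKM) are kept as thresholds — they
are far below every planted feature, as they are in real data.

**Equal-depth conditions.** Both conditions are sequenced to
`library_size`. Induction raises the ligand condition's transcription mass
~1.56-fold under the defaults, so all ligand expectations are rescaled to
the common depth: raw-count ratios of induced regions compress to
~4 x 0.64 ~ 2.6 while depth-normalized ratios recover the planted 4x —
exactly the compositional behavior of real libraries, and the reason the
pipeline normalizes by median-of-ratios.

## Problem sizes used in tests

The test suite runs most modules on a 2 x 1 Mb genome (30 genes, 45
enhancers, 6 domains, 4 x 10^5 reads) and the recovery checks on the
full default study (10 Mb, 10^6 reads per condition); the null-FDR
simulation uses 200 replicates of 120 regions, and oracle-equivalence
checks use 100-1000 random instances per operation. These sizes were
chosen so the planted effects are identifiable with comfortable margins
under the noise model above.

## Known limitations

- The change-calling engine is a two-library binomial test; it models no
  biological replicate dispersion. Replicates are summed, which is
  anticonservative when true overdispersion is present.
- Enhancer placement in the generator is upstream-only and within ~10 kb,
  so the synthetic TSS-distance distribution is narrower and more
  upstream-biased than real enhancer landscapes.
- Domain pairing is greedy and consume-once; boundary reuse across
  adjacent domains is not modeled.
- Interaction analysis treats preys as points and models no distance decay
  within chromosomes; cis statistics are limited accordingly.
- The published headline counts (51,657 divergent sites, 10,204 domains,
  81.15-kb median domain length, ...) derive from genome-scale libraries
  and are not reproducible on a desk-scale synthetic genome; the package
  recomputes their arithmetic identities and demonstrates recovery of
  planted parameters instead.
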