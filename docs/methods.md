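# Methods

## The measurement problem

Editing efficiency at a genomic target confounds two things: the guide
sequence and the chromatin it sits in. Multicopy CRISPR sites (MCsites)
fix the sequence: one 20-nt protospacer + NGG occurring at several loci
lets efficiency and repair-outcome differences across the copies be
attributed to chromatin context. The pipeline has four analysis stages
(discovery, annotation, profiling, association) plus a synthetic-data
layer that plants known truth for all of them.

## Site discovery

Both strands of the nuclear chromosomes are scanned for 23-mers matching
`N{20}NGG`; windows containing N are skipped. Distinctness is by literal
23-mer, so a sequence and its reverse complement are separate catalog
entries — Cas9 targeting is strand-specific. Occurrences are stored with
forward-strand 0-based half-open coordinates and a strand flag; slicing
the genome at a "−" occurrence and reverse-complementing reproduces the
catalog key exactly (tested invariant).

The candidate cascade applies five independent predicates; survivors do
not depend on filter order, and each dropped sequence records the first
stage it failed:

| filter | rule | default |
|---|---|---|
| copy range | lo ≤ occurrences ≤ hi, bounds inclusive | 7–25 |
| simple motif | no homopolymer run of ≥ 5 in the protospacer | run ≤ 4 |
| GC | protospacer GC fraction in [lo, hi] inclusive | 0.40–0.60 |
| organellar | 23-mer absent from organellar contigs, either strand | — |
| restriction | some enzyme motif (IUPAC, either strand) covers protospacer base 17 or 18 | 26 common motifs |

GC bounds are inclusive because "outside 40–60 %" is what gets removed;
on 20 nt these are exact fractions (8–12 G/C), so no tolerance is needed.
Copy counting uses nuclear chromosomes only; organellar sequences act
solely as a removal filter. The restriction rule covers base 17 *or* 18
(1-based protospacer coordinates) because the cut falls between them and
an indel there destroys any motif spanning either base; the search is
confined to the 23-mer by default, with optional genomic flanks. The
shipped enzyme table is a configurable stand-in for a commercial
catalogue; survivor counts on a real genome depend on the exact table
used, so no specific survivor count is claimed.

A family qualifies as chromatin-diverse when its members include at least
one open and one closed site, at least three distinct methylation-domain
labels (windows with no data in a needed context do not count), and at
least two distinct chromatin states. Chromatin-state labels are consumed
from a pre-made BED annotation and never recomputed.

## Methylation domains

Weighted methylation per context over a region is
Σ methylated counts / Σ total counts across all cytosines of that context
on both strands — read-count weighting rather than a mean of per-site
fractions, the standard convention for window-level plant methylomes and
robust to uneven coverage (the alternative is a documented unknown in the
source procedure). Windows are a 100-bp non-overlapping tiling; a context
with zero covered cytosines is undefined, and such windows classify as
"no data" rather than being guessed.

Domain classification is a pure function of (mCG, mCHG, mCHH) with an
explicit precedence, because the raw threshold rules overlap (a window
can satisfy both the RdDM and heterochromatin conditions):

1. unmethylated: all three < 0.10
2. RdDM: mCHH ≥ 0.15
3. heterochromatin: mCG > 0.40 and mCHG > 0.40
4. CG-only: mCG > 0.40 and mCHG < 0.10 and mCHH < 0.10
5. intermediate: everything else with data

RdDM precedes heterochromatin because RdDM is defined by its CHH
component; CG-only additionally requires low mCHG/mCHH, without which it
would be ambiguous against heterochromatin. The tie-break order is a
documented choice; the partition property (exactly one label everywhere
on [0,1]³) is verified against an independent vectorized rule table.

A site's domain is that of the single tiling window containing its cut
(17 bases from the protospacer 5′ end; on "−" sites, 17 bases from the
interval's 3′ end). Accessibility is open iff ≥ 1 bp of ATAC-peak overlap
(half-open intervals; abutment is not overlap). Feature signal is the
coverage-weighted mean over [center − 500, center + 500) with center the
floor midpoint of the 23-mer, partially overlapping bedGraph intervals
contributing pro rata and missing coverage counting as zero — verified
against a per-base expansion oracle and invariant to interval splitting.
Features are min–max normalized per column to [0, 1]; constant columns
map to 0 with a warning.

## Indel profiling

Reads are treated as pre-merged amplicons; base qualities are ignored.
Each read is globally aligned to the reference with affine gap scoring
(match 2, mismatch −4, gap open −10, gap extend −1). Affine rather than
unit costs is deliberate: under unit costs a k-bp deletion ties with a
(k−2)-bp deletion plus two mismatches, which fragments deletion alleles
and misbins them; the large open penalty keeps a deletion contiguous.
Equivalent gap placements are normalized to the leftmost position, so
edit scripts are deterministic and read-order-independent.

A read is *edited* iff an indel overlaps the quantification window
cut ± w (default w = 10 bp — wide enough for microhomology deletions in
the > 10 bp class, narrow enough to exclude distal artifacts; the source
procedure does not print a width). Substitution-only reads are unedited.
Classes: a lone 1-bp insertion with no deletion is "+1 bp"; anything with
deleted bases is binned by total deleted length (1–5, 6–10, > 10);
multi-base pure insertions go to an overflow class excluded from the four
printed bins so they cannot inflate "+1 bp".

Indel frequency = edited / classified reads × 100, with no allele
threshold. The mutation-profile composition (class distribution and
insertion rate = the "+1 bp" share) is computed after dropping alleles
(reads grouped by indel signature) below a 2 % share. The share is
measured against *mutant* reads by default: sites editing at a fraction
of a percent still have a defined outcome composition, whereas a
total-read basis would empty their profiles entirely; a total-read basis
remains available (`threshold_basis="total"`). Normalized frequency is
the site's indel frequency as a percentage of a single-copy euchromatic
control target sequenced in the same replicate; values above 100 % are
legitimate, and a replicate with a zero control frequency is excluded.

## Association statistics

Within a family, replicate-level normalized frequencies are grouped by
one-way ANOVA plus Tukey HSD (studentized-range) pairwise tests at
α = 0.05. Homogeneous subsets come from the classic sweep over sites
sorted by descending mean — grow a subset while no pair inside it is
significant, then start the next — which yields a partition even when
pairwise non-significance chains overlap (the exact subset construction
is not printed in the source procedure; this is the documented choice).
Subsets map to H/M/L: one subset → all M; two → H and L; three → H, M, L;
more → first H, last L, middle all M.

Correlations are Spearman rank (average ranks for ties, two-sided P via
the t approximation). Efficiency correlations default to replicate-level
observations and insertion-rate correlations to site means: the printed
efficiency P-values are only consistent with replicate-level n, while the
insertion-rate P-values match n = 15 site means; both levels are
switchable. Raw P-values are reported; a Benjamini–Hochberg column is
added for transparency only. Clustering is agglomerative with average
linkage on Euclidean distances over the 0–1-normalized feature matrix
(linkage/distance are not printed in the source; these are chosen for
determinism and scale comparability). Condition comparisons use the
two-sided Mann–Whitney U (exact for small untied samples, normal
approximation with tie correction otherwise) with fold change of means;
family-level insertion-rate spread uses Kruskal–Wallis with tie
correction.

## Synthetic data

The generators define the study conditions, not a tuning surface:

- **Genome**: i.i.d. background at configurable GC (default 0.36, an
  Arabidopsis-like value); planted 23-mers are written at registered loci
  and any chance background copy is rejection-resampled away, so planted
  copy numbers are exact by construction. Default demo: three 30-kb
  nuclear chromosomes plus a 5-kb organellar decoy, two 8-copy families.
- **Methylation**: per-cytosine calls on both strands at the planned
  window levels, methylated counts ~ Binomial(depth, level), depth 100 by
  default; context from the plant CG/CHG/CHH definition with
  reverse-complement logic on the minus strand.
- **Tracks**: bedGraph tiles (50 bp) at the planned mean plus optional
  Gaussian noise; peaks as 0-based BED.
- **Reads**: classes drawn per plan; +1 bp insertions at the cut
  (templated duplicate of the 5′ base, or a fixed base); deletions with
  bin-uniform sizes (11–20 bp for the > 10 class) placed uniformly among
  positions overlapping the cut; substitution errors applied after
  editing (default 0.2 %, capped at 5 %). Per-site read depth is not
  published for the assay being emulated, so the default of 2,000 reads
  per replicate (10,000 in the recovery checks) is a chosen, stated size.
- **Demo truth**: family A plants normalized-frequency extremes 249.64×
  apart (one high, two moderate, five low copies) against a 50 %-efficient
  control; active marks scale with planted efficiency, repressive marks
  against it, and the H3-variant features anti-monotone with the planted
  +1 bp share (family A 56–82 %, family B 8–30 %).

What the generators do **not** emulate: read-quality structure, bisulfite
conversion error, paired-end merging, microhomology-patterned deletion
hotspots (deletion placement is uniform, so deletion alleles are more
diverse than in real amplicon data — one reason truth-recovery checks
disable the composition threshold), linked features, or genome-scale
repeat structure. Passing tests therefore demonstrate correctness of the
computations on data with known truth, not biological realism.

## Numerical and operational choices

- All coordinates 0-based half-open internally; BED output 0-based;
  1-based protospacer positions only in the restriction-overlap rule, as
  conventionally stated.
- Seeded `numpy.random.default_rng` everywhere; per-(site, replicate)
  seeds derive from the run seed via CRC32, keeping every seed < 2³¹ and
  runs bit-reproducible end to end (tested).
- Fold changes are reported to 2 decimals; a zero denominator (control or
  low extreme) is an error, not an infinity.
- Identical read sequences are aligned once and share their edit script.
- Degenerate inputs: empty genomes scan to empty catalogs; constant
  feature columns normalize to 0 with a warning; all-identical samples
  give P = 1 in rank tests; undefined methylation levels must be excluded
  before domain classification (error otherwise).

## Problem sizes

Default test and demo sizes — 30-kb chromosomes, 8-copy families, 3
replicates, 2,000 reads per replicate (10,000 in recovery checks), 100
random genomes ≤ 2.5 kb for the oracle-equivalence sweep — were chosen so
the full suite and the reproduction script each run in seconds while
leaving the stochastic bounds (binomial/multinomial standard errors) far
tighter than the tested tolerances.

## Known limitations

- The scanner is exact-match only; mismatch-tolerant (off-target-style)
  occurrence counting is out of scope.
- Survivor counts on a real genome depend on the enzyme table supplied;
  the bundled table is representative, not canonical.
- The Tukey homogeneous-subset sweep can be sensitive near α when group
  separations are comparable to replicate noise; the H/M/L mapping for
  more than three subsets collapses the middle into M by design.
- HDR outcomes, substitution quantification and deletions extending
  beyond the amplicon are not modeled.
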