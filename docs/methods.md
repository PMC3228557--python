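# Methods

This note records the scientific and numerical choices behind promotif:
what the pipeline computes, the conventions it fixes where several were
defensible, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Coordinates and sequence handling

Upstream sequences are sense-strand 5'→3' strings over {A,C,G,T,N}
ending at the base immediately 5' of the TSS.  String index *i* of a
length-*M* record maps to TSS-relative position *i − M*; every position
is negative and the TSS itself (0) is excluded.  Reported intervals are
inclusive on both ends, so a 9 bp site occupies [−119, −111].  This
single conversion point — internal indices are 0-based, TSS-relative
coordinates appear only at the reporting boundary — is deliberate: it
keeps the off-by-one surface to one function.

Truncation to an extent (1 kb, 2 kb, 10 kb …) keeps the 3'-most bases so
the TSS anchor is preserved; records shorter than the extent are kept at
full length rather than discarded, which maximises data and introduces
no bias in gene-level counting.  `N` bases are retained on load; their
treatment is a scoring decision (below), not an input-cleaning one.
Gene ids must be unique within a set (the background is a non-redundant
collection), and a target set is always a subset of its background.

## The similarity score

A motif is a matrix of per-position base frequencies; consensus motifs
are converted to matrices by spreading unit mass uniformly over each
position's allowed bases, so one scoring path serves both motif kinds.
A window *w* of the motif's length scores

    score(w) = (S − S_min) / (S_max − S_min),  S = Σᵢ fᵢ(wᵢ),

the min–max-normalised additive frequency score.  Properties that drove
this choice:

- it is a similarity in [0, 1] with "1.0 = perfect match" literally true:
  for a consensus-derived matrix, score(w) = 1 iff *w* is an expansion of
  the consensus (each column must sit at its maximum, and all allowed
  bases of a column share that maximum);
- it behaves like the familiar matrix-similarity scores used with
  TRANSFAC matrices and absolute cutoffs (0.9, 1.0);
- it needs no pseudocounts or background model, because it is never
  interpreted as a likelihood ratio.

An `N` in the window contributes the column minimum (the worst case), so
N-rich sequence cannot reach any useful cutoff; a window is never
invalidated outright, keeping hit coordinates complete.  Matrices whose
columns are all uniform have S_max = S_min and are rejected as
unscorable at construction.

Floating-point exactness at cutoff 1.0 matters for the scanner-oracle
equivalence: a perfect window accumulates exactly the same float terms
as S_max (same values, same order), so score == 1.0 holds without
tolerance, and any mismatch loses at least one-third of a column's mass,
far beyond rounding error.

## Scanning

Both strands are scanned by default.  The minus strand is scored by
scanning the sense sequence with the reverse-complemented matrix
(columns reversed, base rows complemented), which is algebraically
identical to scoring the reverse complement of each window; hits are
reported as the interval of matched sense-strand bases with strand `−`.
All windows at or above the cutoff are reported — overlapping hits are
not merged, and a palindromic site matching both strands at one offset
yields two hits — because downstream summaries count genes, not sites,
and lossless output lets users apply their own collapsing.  Hit tables
are sorted by record order, then start, then strand, making outputs
byte-reproducible.

Sets whose records share one length are scanned as a single encoded
matrix (vectorised across sequences); ragged sets fall back to a
per-sequence path.  Both paths are tested against each other.

## Positional distribution

Hits are binned by their start (5'-most sense base) into fixed-width
distance windows; bin *j* covers [−(j+1)·w, −j·w − 1] with defaults
w = 1000 and extent 10 kb.  A site straddling a boundary belongs to its
start's bin — a 9 bp site almost never straddles a 1 kb boundary, and
the start is deterministic.  Hits beyond the extent are dropped with a
logged count.  Because a "frequency per kb" axis admits two
normalisations (per sequence, or per sequence per kb of bin width), the
histogram carries raw counts alongside the per-sequence-per-kb
frequency, and the TSV output contains both.

## Co-occurrence

The gap between two inclusive intervals is the number of bases strictly
between them, 0 when they overlap.  A secondary site co-occurs with an
anchor site when both are in the same gene and gap ≤ W (default 100),
boundary inclusive, on either side.  Overlap counts as co-occurrence —
required by the canonical example of a P53 half-site at [−117, −98]
overlapping an HBS at [−119, −111] in the Caspase1 promoter.  The
identical hit is never paired with itself; a second hit of the same
motif at another offset is a valid partner.

Enrichment of co-occurrence counts genes (≥ 1 co-occurrence), and the
universe is by default the anchored genes — co-occurrence is undefined
without an anchor — with n/N the anchored target/background gene counts.
A `universe="all"` option is exposed for the alternative convention.

## Enrichment statistics

The counts are a nested urn: k of n target genes versus K of N
background genes, target ⊆ background, k ≤ K.  Three quantities are
reported per motif or term:

- the cumulative hypergeometric tail P(X ≥ k) for
  X ~ Hypergeometric(N, K, n) (scipy's stable log-gamma implementation;
  verified against exhaustive subset enumeration for all N ≤ 12);
- the Pearson 2×2 chi-square (1 df, no continuity correction) with the
  textbook-valid disjoint contrast: target (k, n−k) versus background
  *excluding* the target (K−k, (N−n)−(K−k)); a zero margin makes the
  statistic undefined and the value is reported as NaN rather than
  fabricated;
- Benjamini–Hochberg adjusted hypergeometric p-values across the library
  (statsmodels step-up; ties share their rank block's value).

The significance call is the either-test rule (hypergeometric OR
chi-square below α); the BH-adjusted p is reported alongside and is the
selection rule for annotation terms.  The frequency ratio is
(k/n)/(K/N) on the nested counts.  A motif absent from the entire
background (K = 0) is flagged: its ratio is undefined (NaN), its p is 1,
and it is never called significant.

## Differential lists

Fold changes are ratios (neutral = 1); negative values are accepted
under the signed convention −r ≡ 1/r.  Selection applies BH to the p
column (optionally skipped), keeps genes with adjusted p < α, and splits
by direction; a gene with significant p but fold exactly 1 joins neither
set and is counted in the log.  The two-condition "common set" takes the
genes significantly altered in condition A whose alteration is
diminished by at least the cutoff fraction (default 10%) in condition B:
fold_B/fold_A ≤ 0.9 for up-regulated genes and, symmetrically on
magnitudes, fold_A/fold_B ≤ 0.9 for down-regulated ones.  Genes missing
from B are excluded with a logged count.  The 10% rule is a documented
interpretation: the source procedure's wording ("10% as the cut off for
the ratios of expression") is compatible with several readings, and the
relative-diminution reading is the one that makes both directions
symmetric.

## The synthetic-data generator

The generator emulates the *structure* of a promoter-motif study:
i.i.d. sequence with a single GC-content dial, one planted motif
instance per selected gene (overwritten in place, never inserted, so
lengths and TSS anchoring are untouched), controlled position models
(fixed offset; uniform; proximal-biased with a fraction f within 2 kb,
which reproduces the TSS-proximal site distribution of real promoter
scans), controlled strand fractions, co-occurring pairs with gaps
uniform on [0, W], flat annotation maps with one designed enriched term,
and differential tables with a known true-positive subset.  Collisions
between planted sites are resolved by bounded resampling so truth tables
stay exact; a fixed-position collision errors out instead.

Target-versus-background planting rates are specified as *observed
frequencies*: the target stratum is planted at its stated rate and the
non-target remainder at the residual rate that brings the whole
background to its stated frequency (clamped at zero).  This makes "50%
of the target versus a 5% background" a single consistent design —
including the boundary case where the target stratum alone accounts for
the entire background frequency — and makes equal rates an exact null.

Differential-table nulls draw p uniformly from [null_p_min, 1] with
null_p_min = 0 by default.  The positive setting exists for exactness
checks: with nulls bounded above α no step-up selection can include
them, so recovery of the true subset is a theorem rather than a
high-probability event.  With the fully uniform default, BH at α = 0.05
is *expected* to admit a few nulls per hundred discoveries — that is
what FDR control means — and the generator's truth labels make that
measurable.

What the generator does **not** emulate, and hence what passing tests do
not show about real data: dinucleotide composition and CpG islands,
nucleosome positioning or accessibility, correlated occurrence of real
TFBSs, multiple transcripts per gene, and microarray-specific error
structure.  Conclusions supported by the synthetic studies are about the
correctness and calibration of the pipeline's computations, not about
biology.

## Problem sizes and numerical choices

The validation suite uses study sizes chosen to give the statistical
checks clear resolution while staying desk-scale: 1000–2000 promoters of
1 kb for scanner/enrichment studies, 100–200-gene target sets, 100
seeded replicates for power properties, 200–500 replicates for null
calibration, and 10,000 kb of uniform sequence for chance-hit
calibration (the analytic expectation for the HBS is
2·(M−8)·12/4⁹ hits per length-M sequence).  Power checks for planted
enrichment use a long single-expansion motif so that planted frequencies
are not diluted by chance matches; chance-match behaviour is itself
calibrated separately with the degenerate 9-mer.

Determinism contract: every stochastic function takes a seed and uses an
isolated generator; equal seed and configuration give byte-identical
FASTA, truth tables and TSVs.  Sorting tie-breaks (record order, start,
strand; p-value then item id) are fixed for the same reason.

## Known limitations

- The similarity score is *a* standard definition, not *the* one any
  particular legacy tool used; published genome-scale hit counts
  obtained with unpublished scoring cannot be expected to reproduce
  exactly, and no such counts are asserted anywhere in this package.
- Gene-level counting (≥ 1 site) is the only supported occurrence
  notion; site-level urn models are out of scope.
- Annotation maps are used flat; there is no ontology DAG traversal or
  term ancestry propagation.
- No genome-coordinate extraction (chromosome FASTA + GTF) and no
  cross-species homolog mapping; inputs must already be gene-keyed
  upstream sequences.
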