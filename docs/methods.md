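# Methods

## Coordinate model

Every coordinate inside the package is 0-based half-open `[start, end)`;
GTF/GFF3 (1-based closed) are converted at the file boundary only, so
off-by-one handling lives in exactly one place. The TSS is defined per
transcript and strand-aware: `span.start` on '+', `span.end − 1` on '−'.
The linkage stage works at transcript level because the peaklet–gene
correspondence is many-to-many; gene-level questions are answered by
taking the union over a gene's transcripts. Only `transcript`/`mRNA` and
`exon` features are consumed — nothing downstream needs UTRs or CDS.
Contig lengths come from a `.fai`/`chrom.sizes` file when supplied and are
otherwise inferred as the maximum feature end per contig.

## Peaklets

A peaklet is the window `[mode − 250, mode + 250)` around the summit of a
peak whose p-value is strictly below the threshold, clipped to the contig
and flagged `truncated` when clipped. Choices worth stating:

- **Threshold default 10⁻¹⁰.** The filter is conventionally written
  "p < 10e-10", which read literally is 10⁻⁹; we take the intended value
  to be 10⁻¹⁰ and expose `--p-threshold` so either reading is one flag
  away.
- **Centering arithmetic.** A 500bp even-width window cannot be centered
  symmetrically on a single base; we use `[mode − 250, mode + 250)`, which
  honors the width exactly.
- **Summit ties.** When the summit comes from a per-base signal vector, a
  plateau is broken by the leftmost position, for determinism.
- **Overlap counting** is ≥ 1 shared base under half-open semantics — an
  abutting fragment does not count. Supplied fragment intervals are counted
  as-is (no deduplication, no fraction-of-read rule).
- Peaklet ids are `contig:mode`; two peaks with the same summit would yield
  the same window, so the duplicate is dropped.

## Proximal / distal / exonic rules

The proximity rule has two clauses and they use different anchors,
deliberately: "overlaps the TSS" is evaluated on the full peaklet interval
(half-open membership `tss ∈ [start, end)`), while "within ±1kb / ±100kb"
is measured from the peaklet **mode**, since the peaklet-to-gene distance
is defined on the mode and TSS coordinates. Both thresholds are inclusive
(≤). For every (peaklet, transcript) pair exactly one of
proximal/distal/none holds. The reported `distance` is `mode − tss`,
sign-flipped on '−'-strand genes so positive always means downstream —
convenient for promoter/enhancer interpretation, ignorable otherwise.

The exonic filter is a property of the peaklet, not of the pair: a peaklet
is exonic when its interval is within 50bp (overlap = gap 0, boundary
inclusive) of the **genome-wide** merged exon union and contains no TSS of
any transcript. Records of exonic peaklets are dropped only when removal
is requested, so the unfiltered output is always a superset.

The production path finds candidate transcripts by a sorted-TSS window
query per contig (`bisect` over a ±100kb window). This is exhaustive: a
contained TSS is always within half a peaklet width (< 250bp) of the mode,
so no proximal hit can fall outside the window. The test suite checks the
whole operation against a literal all-pairs classifier.

FASTA export writes one forward-strand sequence per distinct peaklet,
deduplicated by peaklet id across genes — motif scanners should not see
the same sequence twice merely because it links two transcripts.

## Expression transforms and clustering

TPM is the standard within-sample normalization
(`rate = count / length_kb`, scaled to sum to 10⁶; all-zero columns stay
zero). Both log transforms use pseudocount 1, which keeps zeros at zero:
`log_tpm = log₂(TPM + 1)` and `log_fc = log₂((TPM + 1)/(TPM₀ + 1))`
against the baseline time point, whose column is therefore exactly 0.
Z-scores are computed per row on the log-scale values; a zero-variance row
maps to all zeros rather than NaN. Replicate columns may be mean-collapsed
to one column per time point upstream of all of this.

Row clustering is K-means (k-means++, `n_init=10`, fixed `random_state`,
best inertia kept), with labels renumbered 1..k by descending cluster size
(ties by first row index) so a given seed always yields the same labeling.
Within each cluster, rows are ordered by the complete-linkage
(Euclidean) dendrogram leaf order, clusters concatenated in label order;
columns can be clustered the same way. We use the plain dendrogram order
without optimal-leaf reordering — only the metric and linkage are part of
the method. The heatmap renderer is presentation only and writes
byte-deterministic PNGs for fixed inputs.

## GO over-representation

Direct annotations are propagated to all ancestors (`is_a`, plus
`part_of` treated as `is_a` by default with a flag to restrict). The graph
must be acyclic; ancestor sets are memoized. Each term is then tested with
the one-sided hypergeometric upper tail P(X ≥ k) with N = |universe|,
K = term's universe genes, n = |study|, k = term's study genes — the
Fisher exact one-sided p — and rows with raw p below the reporting
threshold (default 5%) are returned sorted by p, unadjusted, matching the
reporting convention this workflow follows. The original application used
topGO's weight01 decorrelation, which is a distinct heuristic; here the
fully specified pair of `classic` and `elim` (bottom-up, masking genes of
children significant at 0.01 before testing parents) brackets its
behavior. Enrichment runs in gene space (transcript queries collapse to
genes first), and the default universe keeps only genes with ≥ 1
annotation, with a flag to retain unannotated genes.

## Species mapping and overlap

Homology is a static four-column TSV (exportable from Ensembl BioMart);
all one-to-many links are kept rather than picking a best hit, since the
downstream consumer is a transcript set, not a 1:1 table. Pasted id lists
split on whitespace/comma/semicolon, case preserved, duplicates counted
once; unmapped ids return verbatim. DE subsetting uses a strict FDR
inequality (< 5%) at a named time point or at ≥ 1 time point (`ANY`).
Venn accounting enumerates all 2ᵐ − 1 exact membership patterns for 2–4
sets; counts sum to the union size by construction of the per-element
pattern.

## Synthetic data generator

The generator emulates the *shapes* of the study's data — a multi-contig
genome, spliced transcripts, summit-bearing narrowPeak calls, fragment
intervals, a 5-time-point TPM table (0/2/4/7/12 dpi), per-time-point DE
results, a small GO DAG with a diamond, and a homology table — with
ground-truth labels known by construction. It does not emulate read-level
noise, peak-caller behavior, realistic genome composition, annotation
complexity (one transcript per gene), or biological covariance structure,
so green tests demonstrate correctness of the computations, not
performance on real data.

Label unambiguity is geometric: each gene occupies a private 210kb slot
with its TSS at the center, so the ±100kb distal window of one gene never
reaches another gene's peaks. Summits keep guard bands around the
classification boundaries — proximal |d| ≤ 600bp, distal 2.5–98kb,
background 102–104kb — so intended labels cannot flip by a base. The
planted expression profiles are three log₂-scale temporal templates
(ramp up, ramp down, transient peak; amplitude ≈ 5) with Gaussian noise
(default sd 0.5, a tenth of the amplitude, at which K-means recovery is
exact). Each file type draws from its own RNG stream spawned from the
master seed, so adding one output never perturbs another, and a fixed seed
reproduces the bundle byte for byte.

Default sizes (6 contigs × 450kb, 12 genes, 40 peaks, 300 fragments) keep
a full pipeline run under a second while still exercising multi-contig
logic, strand reflection, truncation and every label class; tests that
need other regimes (all-proximal, zero-DE, sub-threshold peaks) construct
their own spec.

## Numerical and degenerate-input conventions

- Interval invariants (`0 ≤ start < end`, non-empty contig) are enforced at
  construction; exon lists are merged and checked against the span.
- Hypergeometric tails come from `scipy.stats.hypergeom.sf(k−1, N, K, n)`;
  tests verify them against exhaustive draw enumeration for N ≤ 12.
- Empty inputs are defined, not errors, wherever a meaningful empty output
  exists: empty annotation → empty TSS table, empty record list → valid
  empty CSV/BED/FASTA, empty fragment set → zero counts. Errors are
  reserved for unusable inputs: a peak with neither summit nor signal, an
  unknown species or time point (listing the valid ones), a missing
  contig, an empty universe, k > number of rows.

## Known limitations

- Differential expression and differential accessibility are consumed as
  input tables; no Wald testing or FDR control is performed here.
- No peak calling, motif scanning, or enhancer-activity prediction — the
  FASTA/BED exports are the hand-off to those tools.
- Canonical-transcript TSS collapsing is not implemented; all transcripts
  of a gene are scored.
- topGO's weight01 p-values are not numerically reproduced (see above).
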