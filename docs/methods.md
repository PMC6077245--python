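# Methods

This note documents the models, conventions and numerical choices behind
`lactlnc`, and what the synthetic-data tests do and do not demonstrate.

## Coordinates and formats

Internally every position is 0-based half-open; every external format —
GTF exon rows, QTL/SNP tables, per-base conservation rows — is 1-based
inclusive and converted exactly once at the I/O boundary (`genome_io`).
Chromosome names are matched by exact string equality. Overlap queries use
half-open semantics throughout (`[10,20)` does not touch `[20,30)`), served
by one interval tree per chromosome. Strand `.` is accepted on input, but
unstranded transcripts are excluded from strand-dependent operations
(antisense classification, the sense-strand ORF scan) with a logged
warning; the sequencing protocol the defaults assume is strand-specific,
so synthetic data always sets strand.

## Consensus merge

Transcript identity across assemblers and samples is purely structural —
chromosome, strand and the full exon-coordinate chain — since assembler id
namespaces are not comparable. With `end_tolerance` τ > 0 the two terminal
boundaries are bucketed to a τ-sized grid before keying (internal splice
boundaries are always exact, since assemblers jitter termini but agree on
splice sites); the default is τ = 0, i.e. literal coordinate identity.

Support counting implements a disjunction at the transcript level:
retained iff supported by ≥ 2 distinct assemblers (across any samples) or
observed in ≥ 2 distinct samples (under any single assembler). Cross terms
(assembler A in sample 1, assembler B in sample 2) therefore count as two
assemblers. The surviving representative is the lexicographically smallest
(assembler, sample, transcript id) copy, annotated with the full support
list, which makes the merge deterministic under input permutation.

## Classification cascade

Class codes use a deliberately small scheme — `=`, `i`, `u`, `x`, plus a
catch-all `o` for any other overlap — with fixed precedence
`=` > `i` > `x` > `o`, and `u` only for transcripts overlapping nothing:

- `=` requires complete intron-chain identity with a reference transcript
  on the same strand. Single-exon transcripts never match (they cannot
  survive the ≥ 2-exon structure filter anyway).
- `i` requires the whole transcript span to lie inside a single reference
  intron, on either strand.
- `x` requires ≥ 1 bp of exon-over-exon overlap on the opposite strand.

The cascade then applies, in order: structure (spliced length ≥ 200 nt and
≥ 2 exons), expression (max FPKM across the six samples ≥ 0.3; a
mean-based alternative is available), ORF (longest ORF < 120 amino acids),
coding potential, and protein domains (any hit at e ≤ 1e-5 excludes; the
threshold is configurable since "significant" is a policy choice).
Transcripts failing the ORF or coding-potential step — i.e. unannotated
but coding-looking — are routed to `novel_mRNA`; domain-hit failures are
rejected outright. Every transcript receives exactly one verdict and the
first failing step is recorded, giving a complete audit trail.

The coding-potential combination rule defaults to **any** (excluded if any
configured scorer calls the transcript coding), the conservative choice
for lncRNA purity; **all** is available. External scorer outputs
(CPC/PLEK/CNCI sign convention: > 0 = coding-like) are consumed as tables;
the built-in baseline scorer is a hexamer log-likelihood-ratio model
scored over the longest-ORF region, trained from sequences drawn from the
package's fixture distributions (a GC-third-position-biased codon-usage
table for coding, an AT-rich background for noncoding). It exists so the
cascade is fully runnable without external tools, not as a reimplementation
of those tools.

The ORF scanner is sense-strand, three-frame, ATG-initiated and
stop-terminated (TAA/TAG/TGA), with amino-acid length counted Met through
the residue before the stop; ties break to the smallest start offset, then
the smallest frame. `require_stop=False` additionally admits ORFs running
off the 3' end, which matters for truncated assemblies.

Conservation scoring is the median per-base value over a transcript's
exonic bases; unscored bases are ignored and a transcript with no scored
base is reported missing rather than zero, since absence of a score is not
evidence of non-conservation.

## Differential expression

FPKM[f,s] = counts[f,s] × 10⁹ / (length[f] × library_size[s]). Gene-level
testing aggregates transcript counts by summation within gene id before
testing. Group means are compared by a Wald statistic on log means under a
negative-binomial variance model, Var(log mean) ≈ (m + αm²)/(n m²), with a
half-count added to each group mean so group-exclusive features remain
testable. Size factors default to library-size scaling, matching FPKM.

Dispersion α is estimated per feature by method of moments from the pooled
within-group variance, floored at 0. At n = 3 + 3 this estimate is very
noisy, and the choice of reference distribution trades type-I control
against power:

- `nb_two_group_test` (the per-feature primitive) uses the plain MoM
  estimate with a Student-t reference on n₁+n₂−2 df. Measured on the null
  (NB, equal means 100, dispersion 0.1, 3v3) its type-I error at α = 0.05
  is ≈ 0.045–0.055.
- `call_de` (the family-level caller) moderates each feature's dispersion
  toward the family median, empirical-Bayes style with prior weight 20
  pseudo-observations, and gives the t reference correspondingly more df
  (prior + residual). This is the standard small-n RNA-seq remedy
  (edgeR/limma lineage) and is what makes large planted effects reach
  q < 0.05 uniformly; it can be disabled with
  ``moderate_dispersion=False``.

q-values are BH step-up over the family of expressed features (silent
features are reported `not_expressed` and excluded from the family). Fold
change is log2(LP/HP), matching the bundled tables (verified numerically
against their printed column); a zero mean in either group yields status
`hp_only`/`lp_only` with no fold change, "exclusive" meaning literally
zero in one group. Direction follows the fold-change sign: positive
(higher in LP, or LP-only) is "up", negative (or HP-only) "down".

ΔΔCt fold change uses the arithmetic mean of the reference-gene Cts per
condition; hierarchical clustering of DE features uses average linkage on
1 − Pearson r over log2(FPKM+1), with constant rows pinned at distance 1.

## Targets and integration

Cis distance is the span-to-span gap (0 on overlap), strand-agnostic for
membership; the sign encodes upstream (negative) vs downstream of the
lncRNA's 5' end. The 10 kb edge set is by construction a subset of the
100 kb set. Trans correlation uses log2(FPKM+1) to stabilize variance
(raw-scale mode available), the two-sided p from the t transform with
n−2 df, and no multiplicity correction — the stated criterion is p < 0.05,
and with n = 6 these p-values are fragile; α is configurable. Precursor
detection is exact full-length substring matching of U→T-normalized
hairpins on the sense strand (reverse-complement search behind a flag).

A candidate pair requires: lncRNA DE ∧ gene DE ∧ (cis ∨ trans) ∧ gene on
the supplied function list ∧ at least one positional flag. Positional
semantics: QTL = span intersection; SNP = within a window of the span,
default 1 Mb for real chromosomes. The function list is an input — no
enrichment is computed. The network export is a SIF edge list plus a node
table (lncRNA/mRNA/pathway); pathway labels are annotation input only.

## Synthetic data: what it emulates, and what it does not

The generator builds, from one seed: a 2 × 500 kb genome; 40 non-
overlapping protein-coding genes (3–5 exons of 180–400 bp, 1.5–2.5 kb
introns, embedded ORFs ≥ 120 AA); 12 lincRNAs (≥ 2 kb from genes),
6 ilncRNAs (strictly inside introns), 6 lncNATs (antisense exon overlap),
4 novel mRNAs; 4 assemblers × 6 samples with per-run detection,
terminal-boundary jitter and single-run single-exon artifacts; a 3-vs-3 NB
count matrix (library sizes ≈ 10⁶ ± 10%) with 6 planted DE lncRNA–gene
partner pairs at |log2FC| = 3 (two of the lncRNAs group-exclusive
instead); QTL/SNP tracks covering the partner features; scorer and
domain-hit tables consistent with the planted labels; and three 70-nt
hairpins inserted verbatim into lincRNAs. All geometric truth is
re-verified by the package's own classifier in the tests, and every
generator is a pure function of (seed, parameters).

Counts have two noise modes. `nb` draws negative-binomial counts
(dispersion 0 = Poisson limit) and is used for the calibration and power
measurements. `none` emits expected counts exactly; it is the mode of the
recovery scenarios, where non-DE features are perfectly group-balanced so
recovery of the planted truth is deterministic for any seed rather than
holding only with high probability. Pipeline runs on the miniature genome
use a 5 kb SNP window (a 1 Mb window would flag every feature on a 500 kb
chromosome).

What passing these tests shows: the merge rule, classifier geometry,
filter ordering, DE arithmetic and integration logic are implemented
exactly, and the DE test is calibrated under its own noise model. What it
does not show: behavior on real assembler output (fragmentation,
mono-exonic noise, shared ids), real dispersion structure
(mean–dispersion trends, outliers), isoform ambiguity, or the biological
validity of any particular threshold — those thresholds (200 nt, FPKM 0.3,
120 AA, e ≤ 1e-5, windows) are the field's conventions, not fitted
quantities.

## Known limitations

- The class-code scheme is a 5-symbol reduction, not the full 12-code
  comparison vocabulary; `o` conflates several overlap configurations.
- The NB Wald test is a documented stand-in for count-model DE tools, not
  a bit-compatible reimplementation of any of them.
- Trans edges at n = 6 have very low resolution; treat them as screening,
  not inference.
- Single-exon lncRNAs are out of reach by design (the structure filter
  requires ≥ 2 exons).
- External coding-potential and domain tools are consumed as score/hit
  tables; the package does not re-run them.
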