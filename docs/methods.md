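# Methods

## Study design emulated by the synthetic generator

The generator (`mirseq.simulate`) emulates a two-group small RNA-seq
experiment: `n_control = 4` vs `n_frozen = 3` samples, a universe of
`n_mirna = 49` mature miRNAs, `n_de = 5` planted differentially expressed
miRNAs (`n_de_up = 2` up, 3 down) at `|log2FC| = 2`, single-end 100-nt
reads carrying the Illumina TruSeq small-RNA 3' adapter. Library sizes
default to 50,000 reads per sample (Poisson-distributed around the mean) —
a deliberate desk-scale depth; depth only scales counting precision here,
and the defaults already give per-miRNA means near 1,000 reads, ample for
the moderated model.

Counts are negative binomial with variance μ + φμ² (dispersion
φ = 0.1, a typical bulk RNA-seq value for a handful of biological
replicates), falling back to Poisson when φ < 1e-8. Relative miRNA
abundances are log-normal (σ = 1) weights normalized to proportions.

Reads are laid out as mature sequence (20–25 nt) + adapter + random
filler to 100 nt, Q36 throughout; two artifact classes are *added on top*:
contaminants (5%; a 20–30 nt slice of a negative-reference sequence plus
adapter) and low-quality reads (2%; Q20 throughout). Constant quality
strings make filter behaviour unambiguous. Because artifacts are additive
and are fully removed by the negative and quality filters, reprocessing
the synthetic FASTQ recovers the true count matrix exactly — which is the
module's contract with every downstream recovery test.

Reference construction is deliberately stronger than "distinct 20-nt
prefixes": every 20-mer window across all positive references is globally
unique, and no negative sequence shares any 20-mer with a positive. This
guarantees the prefix→miRNA assignment is unambiguous, so round-trip
recovery is exact rather than approximate.

Each generator (references, counts, reads, target map, gene sets) draws
from its own RNG stream derived from the master seed by a fixed offset;
regenerating one artifact never perturbs another, and identical seeds give
bit-identical outputs.

The target map assigns each miRNA 40 distinct targets from a 2,000-mRNA
universe (mean ≈ 1 targeting miRNA per mRNA). Gene sets number 50 with
sizes uniform on [10, 60] (typical term sizes at this universe scale);
4 planted sets draw ≥ 70% of members from the targets of planted DE
miRNAs of one direction, alternating directions.

What the generator does **not** emulate: sequencing errors beyond the two
planted artifact classes, isomiRs, real miRBase/Rfam sequence content,
adapter dimers, or inter-sample batch effects. Passing tests therefore
demonstrate the pipeline's correctness and statistical calibration under
a clean NB model, not robustness to every artifact of real libraries.

## Read processing

Pipeline order per read: adapter trim → quality filter → negative filter
→ positive alignment → tally.

- **Trimming** removes from the leftmost position where a prefix of the
  adapter aligns to the read's 3' end with overlap ≥ 3 and mismatch
  fraction ≤ 0.1 (cutadapt-like semantics); qualities are trimmed in
  lockstep; no hit leaves the read unchanged.
- **Quality filter**: keep iff mean Phred ≥ 30 *and* length ≥ 16 after
  trimming. Whole-read mean is a simple, testable reading of
  "remove reads with scores below 30"; the 16-nt floor keeps reads
  shorter than any mature miRNA out of the aligner.
- **Alignment** is exact substring matching of the read's first 20 bases
  against the reference (forward strand only — mature references are
  single-stranded), implemented as a 20-mer hash index. Multi-mapping
  resolves to the first reference in file order (deterministic); reads
  containing N in the seed never match. This reproduces a
  perfect-match-only, 20-nt-seed aligner configuration without FM-index
  machinery.
- **Count filter**: keep miRNAs with total count strictly greater than 4,
  interpreted across all samples (per-sample filtering would break matrix
  rectangularity).

`ProcessingStats` records every stage; counts are monotone non-increasing
and aligned + unaligned equals the post-negative-filter count — both
enforced by a validator.

## Differential expression

- **log-CPM**: log2((count + 0.5)/(libsize + 1) × 10⁶). Offsets keep zero
  counts finite.
- **Precision weights**: per-row OLS residual standard deviations are
  square-rooted and smoothed against mean log-CPM with a locally weighted
  linear smoother (span 0.5); the trend is linearly interpolated at each
  observation's fitted value (clamped to the trend's range at the
  extremes, and floored at 1e-6 against degenerate zero-variance trends)
  and inverted as trend⁻⁴. Fewer than 10 rows falls back to unit weights
  with a warning — a trend fitted through fewer points is noise.
  No additional between-sample normalization (e.g. TMM) is applied.
- **Per-miRNA model**: weighted least squares on (intercept, group);
  the group coefficient is the frozen-minus-control effect in log2 units.
- **Variance prior**: method of moments on log variances. With
  z = log s² and e = z − ψ(df/2) + log(df/2), the excess spread
  var(e) − ψ′(df/2) determines d₀ via ψ′(d₀/2) = excess, solved by
  monotone root finding on d₀ ∈ [0.1, 500]; non-positive excess (or a
  root beyond 500) gives d₀ = ∞ with the geometric-mean variance
  estimate. d₀ = 0 is the no-moderation limit and reproduces the
  classical pooled t-test exactly (tested against an independent oracle).
- **Moderated test**: s̃² = (d₀s₀² + df·s²)/(d₀ + df);
  t = β/(stdev_unscaled·s̃); two-sided p from t with df + d₀ degrees of
  freedom. Infinite d₀ is treated as 10⁶ df — numerically the normal
  limit.
- **Calling**: BH step-up FDR; significant iff p_adj < 0.05 (strict) and
  |FC| ≥ 1.5 (inclusive, applied on the linear scale as 2^|log2FC|).

## Gene-set analysis

- **miRNA score**: S_miRNA = −log₁₀(max(p_adj, 1e-300)) · signum(log₂FC).
  The FDR-adjusted p is used (not the raw p), and the floor keeps scores
  finite at p = 0.
- **mRNA score**: S_mRNA = −Σ S_miRNA over targeting miRNAs. The
  regression universe is *all* mRNAs in the target map; untargeted mRNAs
  enter with score 0 (the regression needs a background). Scored miRNAs
  absent from the target map contribute nothing and are logged — they
  model species whose miRNAs lack a mappable ortholog.
- **Enrichment**: membership ~ intercept + S_mRNA by IRLS (Newton) with
  tolerance 1e-8, ≤ 100 iterations; slope, standard error from the
  inverse observed information, two-sided Wald-z p. Sets with fewer than
  5 members (or 5 non-members) in the universe are skipped; fits with
  |slope| > 50, non-convergence, or a singular information matrix are
  flagged as separated/degenerate and excluded from FDR with a warning.
  The Wald test is used because the reported quantities are the
  coefficient and its standard error; BH adjustment runs within each
  collection separately (collections are reported as separate surfaces),
  significance at p_adj < 0.05. Direction labels: coefficient > 0 ⇒
  "decreased negative regulation", < 0 ⇒ "increased negative regulation".

A genuinely threshold-separable set (e.g. all members sharing one extreme
score value with no equally scored non-members) has a divergent MLE; the
separation flag is the honest answer there, and the test fixtures for
sign semantics therefore interleave members with equally scored
non-members.

## Orchestration and reporting

`RunConfig` drives the stages (`simulate | process | de | gsa | all`)
under a single master seed; every intermediate table is written to the
output directory, the effective configuration is echoed for provenance,
and the run summary (DE tallies, per-collection significant-set counts
split by coefficient sign) is recomputed from the exported tables rather
than carried through memory. Volcano exports are plot-ready TSVs (miRNA:
log2FC vs −log₁₀ p; sets: coefficient vs −log₁₀ p_adj); rendering is left
to the user's plotting tool, since the checkable content is the data.

Two runs with the same configuration are byte-identical in every computed
output; only the configuration echo differs when the output paths differ.

## Problem sizes used in tests and the acceptance script

Unit tests run on a scaled-down study (10,000 reads per sample) — chosen
because depth beyond that adds nothing to the properties under test —
while the round-trip, determinism, and acceptance checks run the full
default depth (50,000 reads × 7 samples). Replicate-seed summaries use
10–50 seeds depending on the statistic.

## Known limitations

- Whole-read mean quality is one of several defensible readings of the
  Q30 filter; per-base tail trimming would keep more reads.
- The >4-read filter is applied per dataset, not per sample.
- Single two-level factor only; no covariates, no random effects.
- The logistic model treats mRNA scores as fixed and ignores correlation
  between overlapping gene sets.
- Exact numerical replication of any external package's output is a
  non-goal; agreement is established against statistical oracles instead.
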