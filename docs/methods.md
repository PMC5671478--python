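# Methods

This note documents the statistical procedures `stableref` implements, the
choices made where the methods literature leaves the details open, and what
the synthetic-data tests do and do not establish.

## Screening statistics

For a transcripts × samples matrix of non-negative expression values
(FPKM or counts), per-transcript descriptives are:

* mean and SD over samples, with the **n−1 (sample) denominator** by
  default (`ddof` is configurable to 0 — published CV screens rarely say
  which they used, and with 12 samples the difference is ~4 % of the SD);
* CV = 100·SD/mean (%); MFC = max/min over samples, defined only when every
  sample exceeds the detection threshold (default 0, exclusive);
* constitutive = detected in all samples;
* log-scale stats on log₂(value), computed only for constitutive
  transcripts (no pseudocount is needed then; one is available for count
  matrices). The log-CV clause uses the **absolute value** of
  100·SD(log₂v)/mean(log₂v), since the log-mean can be negative for
  sub-unit expression values. Log base is configurable (2/10/e); base
  changes rescale both SD and mean of the logs only when the mean crosses
  magnitudes, so the 5 % default threshold is calibrated to base 2.

The stability filter keeps a transcript iff constitutive ∧ MFC < 2 ∧
(CV < 20 % ∨ |log-CV| < 5 %). The pass ledger records which clause admitted
each transcript (CV checked first). MFC is computed across all samples
rather than across condition means — stricter, and matching per-sample
expression tables; a per-condition-mean mode would be a two-line extension
of `transcript_stats` and was deliberately not added until someone needs it.

Recommendations additionally require mean expression inside a window
(default 50–1,000 expression units; a 100–1,000 preset exists — published
practice varies and the window trades qPCR template economy against
detectability) and, by default, isoform uniqueness: one annotated
transcript for the gene, because primers against multi-isoform genes
co-amplify isoforms with very different stabilities. Ranking is ascending
CV with lexicographic id tie-breaks, so output order is deterministic.

`top_overlap` compares two stability metrics by the fraction shared between
their n-smallest sets (ties again broken by id); `partition_by_expression`
splits at mean < 1.0 (strictly below → low).

## Cq handling

Long-format Cq files are aggregated to one value per gene × sample by the
arithmetic mean of replicate Cq — the field convention; since Cq is already
a log-scale quantity, the arithmetic mean of cycles equals the geometric
mean of quantities. Non-numeric cells (ND, Undetermined, …) are missing;
because all four stability algorithms need complete rows, genes with any
missing cell are dropped with a logged reason before analysis. Assay QC
passes a gene iff efficiency > 1.8, calibration R² > 0.99 and every
observed Cq < 40; the Cq clause is vacuous over missing cells so that a
metadata-only panel (efficiencies and R² without a Cq grid) can be QC'd.

Relative quantities are q = E^(Cqmin − Cq) with per-assay efficiency E
(default 2.0, perfect doubling), so each gene's best-expressed sample sits
at q = 1.

## The four stability methods

All SDs below use the n−1 denominator; all rankings are strict ordinal with
(value, gene id) tie-breaks.

**geNorm.** V_jk = SD over samples of log₂(q_j/q_k); M_j = mean of V_jk over
the other genes in the current set. The highest-M gene is removed
iteratively (among exactly tied M values the lexicographically last id goes
first, which makes a fully degenerate zero-variance panel rank
alphabetically); its M at removal is the reported per-gene value, and the
final pair shares the final M — this matches how the aggregated stability
tables of the popular web tools report geNorm values, which is why those
values are not mutually consistent as plain means. The V-curve builds
normalization factors as per-sample geometric means of the n best genes and
takes V(n/n+1) = SD over samples of log₂(NF_n/NF_{n+1}); the optimal
reference-gene count is the smallest n with V < 0.15. When every V (or no
V) clears the cutoff the answer defaults to 2 and the result carries an
`all-below`/`none-below` flag rather than pretending the curve was
informative.

**Comparative ΔCt.** Stability of gene j = mean over partners k of
SD over samples of (Cq_j − Cq_k). With all efficiencies equal to 2 this is
algebraically identical to the whole-panel geNorm M (the log₂-ratio of
quantities is a shifted Cq difference), a property the test suite enforces
to 1e−9 on random panels.

**BestKeeper.** Per-gene dispersion = mean absolute deviation of Cq from
its arithmetic mean, the behaviour of the classic spreadsheet tool's
"SD [±CP]" column; the n−1 SD is available behind a flag. Genes with
dispersion > 1 cycle are flagged inconsistent. The BestKeeper index
(per-sample geometric mean of Cq over the panel) and each gene's Pearson
correlation with it are reported but never used for ranking.

**NormFinder.** On x = −Cq (one cycle = one doubling): within each group,
samples are centred by their across-gene mean; v_ig is the n−1 variance of
the centred values, and the intra-group variance estimate is
σ̂²_ig = max(0, (v_ig − Σv/(k(k−1)))·k/(k−2)) — hence the k ≥ 3 requirement.
Group offsets d_ig (mean centred expression) yield the between-group
variance γ̂² = max(0, Var_G(d) − mean(σ̂²/n_g)) and the shrunken bias
b_ig = (d_ig − d̄_i)·γ̂²/(γ̂² + σ̂²_ig/n_g). Stability is
ρ_i = mean over groups of (|b_ig| + √(σ̂²_ig/n_g)); without grouping,
ρ_i = √σ̂²_i from the single-group decomposition. The implementation is
verified against an independent loop-level evaluation of these same
formulas; both the variance floors and the k/(k−2) correction are part of
the contract.

All four methods are invariant to per-gene constant Cq offsets (assay
chemistry) and to sample permutation — both property-tested.

**Consensus.** The geometric mean of the four ordinal ranks, final ranks
ascending on the geomean. Internally produced ranks are strict permutations
of 1..k; externally supplied rank tables (e.g. transcribed from a published
report, where ties may share a printed rank) are accepted as-is, because
published consensus values are generally reproducible only from the printed
ranks.

## Normalization and DE calling

Normalization factors are the per-sample geometric mean of the chosen
reference genes' expression (exact identity for a single reference), defined
only when every reference is positive everywhere — a zero reference value is
an error naming gene and sample, not a silent imputation. Fold change
between two groups is the ratio of arithmetic group means of normalized
values (geometric-mean mode available); calls are strict: up iff FC > 2,
down iff FC < 0.5. A zero control mean gives an undefined FC and an `ns`
call with a logged warning — ratios on trace expression are noise.
Because the factor divides every gene in a sample, calls are invariant to
global and per-sample rescaling of the matrix; this is the property that
makes internal-control normalization a between-sample normalizer, and it is
asserted to 1e−9 relative tolerance in the tests.

Concordance between two call sets classifies each gene as same call,
opposite calls (up vs down = discordant), or anything else (one side `ns`)
as same-direction/different-magnitude; the three counts partition the
shared gene universe.

## Synthetic data

`simulate_fpkm` emulates the target study design: 12 samples in 4 groups
(2 tissues × infected/control, 3 replicates), 200 transcripts in five
classes — 30 `stable_high` (base expression 50–1,000), 20 `stable_low`
(0.1–1), 100 `variable` (CV 0.8), 30 `condition_specific` (zeroed in ≥ 1
random group), 20 `silent`. Expression is log-normal around a per-transcript
base mean with class CV (σ solved from CV = √(e^σ² − 1)); stable classes use
CV 0.05 and are clipped so their MFC stays below 1.5. The class proportions
are a realistic caricature of a genome-wide screen (most transcripts
variable or condition-dependent, a small stable minority), not a fit to any
dataset.

`simulate_cq` draws Cq = base + group shift + N(0, σ) per gene: 15 genes,
2 groups × 6 samples, 3 stable genes (σ = 0.1 cycles, no shift) and 12
unstable genes (σ = 1.0; half additionally get a ±1.5-cycle shift in the
non-baseline group). Ground-truth stability order sorts by σ + RMS shift.
σ = 0.1 cycles is typical technical-replicate noise for SYBR assays;
1–1.5 cycles corresponds to 2–3-fold expression changes, the regime where
a candidate control is clearly unusable.

What passing recovery tests shows: under multiplicative log-normal (FPKM)
and additive Gaussian (Cq) noise with the configured magnitudes, the screen
recovers ≥ 95 % of designated stable transcripts and the consensus puts
≥ 2 of the 3 designated stable genes in its top 3 in ≥ 90 % of seeds. What
it does not show: robustness to features real data have and the generators
lack — library-size and gene-length biases, overdispersed counts, batch
effects, correlated genes, partial-efficiency drift across plates, or
missing-not-at-random dropouts.

## Problem sizes and numerical notes

The oracle and equivalence suites run on panels of up to 9 genes × 10
samples over 100–200 random draws, and the recovery suites on the default
generator sizes over 50–100 seeds — panels of the size practitioners
actually validate by RT-qPCR, and large enough that rank agreement is a
meaningful check while the whole suite stays interactive-fast. Agreement
tolerances are 1e−9 absolute on stability values (pure floating-point
noise), exact on ranks. All tie-breaks throughout the package are
(value, id) lexicographic, so every ranking, report and pipeline output is
byte-reproducible; the pipeline manifest records SHA-256 digests of all
inputs and outputs to make that checkable.

## Known limitations

* The stability algorithms require complete Cq rows; there is no imputation.
* geNorm's reported per-gene value is M-at-exclusion, not the final-set M;
  tools differ here, and rankings (which the consensus consumes) agree even
  when the values are reported differently.
* NormFinder's grouped mode needs ≥ 2 groups with ≥ 2 samples each and
  ≥ 3 genes; it operates on −Cq (efficiency-corrected input is a transform
  away but not wired in).
* The DE module is deliberately ratio-only: no dispersion estimation, no
  significance testing, no FDR — it re-evaluates fold changes under
  reference-gene normalization, nothing more.
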