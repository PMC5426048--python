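# Methods

This note records the statistical model, the default parameters and
their rationale, and the numerical choices made in `poolfit`. It is the
package's own specification of its behavior; every claim here is
exercised by the test suite.

## 1. Generative model (simulator)

A pool of `n_strains` barcoded strains grows competitively. Strain *i*
has relative fitness `gamma_i` in doublings per pool generation
(neutral = 1). Deterministic propagation:

```
p_i(G) = p_i(0) · 2^(E_i(G))  /  Σ_j p_j(0) · 2^(E_j(G))
```

where the growth exponent is `E_i(G) = gamma_i · G` in the default
regime.

**Ground truth.** A Bernoulli(`fraction_affected`) draw marks deficit
strains; their `gamma` is uniform on `[effect_low, effect_high]`
(defaults 0.7–0.9, i.e. 10–30% deficits, the range where depletion is
detectable but not instantaneous over 30 generations). Initial
proportions are drawn per biological replicate, either uniform or
log-normal (`sigma = 0.5`) to mimic uneven pooling.

**Takeover regime** (prolonged stress such as high ethanol). After a
change point `g_star` (default 6 generations) the non-survivor majority
grows at `slowdown × gamma` (default 0.2, i.e. near-arrest) while a
survivor minority (`survivor_fraction`, default 2%) keeps its full
rate, so survivors sweep the pool. This reproduces the diagnostic
signature of such screens: almost all strains identifiable early, only
a handful late.

**Sampling.** Each (biological replicate, technical replicate, time
point, barcode position) sample is a multinomial draw of `depth` reads
from the current proportions — technical replicates are independent
re-sequencings of the same culture, and the two barcode positions (B1
"up", B2 "down") are independent amplifications. Optional
Dirichlet-multinomial overdispersion (concentration `overdispersion`)
models PCR jackpotting; an optional multinomial `bottleneck` resamples
the culture at each transfer to model serial-dilution drift.

Default `depth = 1e6` reads per sample: with ~2000 strains this puts
the mean strain near 500 reads, comfortably above the detection filter,
and corresponds to sequencing each strain on the order of 10⁴-fold over
a 10-point series. Default schedule `(0, 3, 6, 10, 13, 16, 20, 23, 26,
30)` generations: ten roughly evenly spaced samplings over ~30
generations of competitive growth, enough points for a robust slope
while a 20–30% deficit strain still retains countable reads at the end.

**Reads.** Each read is `5-nt multiplex tag + 5' primer + 20-nt barcode
+ 3' primer` (B1 and B2 use different primer pairs; both read types are
61 nt). Synthetic strain barcodes are drawn with pairwise Hamming
distance ≥ 3, so one substitution can never convert one barcode into a
1-neighbor of another; multiplex tags have pairwise distance ≥ 2.
Substitution errors are i.i.d. per base at `seq_error_rate`. Qualities
are uninformative constants. **Not modeled:** indels, chimeric reads,
quality-dependent errors, primer errors interacting with tag
boundaries, strand effects, and cross-sample index hopping.

All randomness flows from a single integer seed through
`numpy.random.SeedSequence([seed, stage])` with a fixed stage id per
stage (truth, propagation, sampling, FASTQ, tags), so every artifact is
byte-reproducible and stages are independently stable.

## 2. Barcode counting

Per read: (1) exact match of the first 5 nt against the tag manifest —
no mismatch tolerance, since tags are only guaranteed distance ≥ 2
apart; (2) exact match of the expected 5' primer immediately after the
tag, which also identifies the barcode position; (3) the next 20 nt are
matched against the reference with at most one mismatch, via a
precomputed dictionary of all 3×20 single-substitution neighbors. A
sequence reachable from two reference barcodes at distance 1 is counted
as *ambiguous* and discarded rather than assigned; with the simulator's
distance-≥3 barcodes this cannot occur, but real references may contain
close pairs. The tally satisfies the accounting identity
`assigned + unassigned_tag + unmatched_primer/barcode + ambiguous =
total`, which is asserted after every run.

## 3. Fitness inference

**Normalization.** Counts → tags-per-million (TPM) within each (sample,
barcode position, technical replicate), removing depth differences.

**Abundance.** `a = mean over technical replicates of log2(TPM + 1)`.
Averaging in log space (rather than averaging TPM) treats technical
replicates as repeated measurements of the log-scale quantity actually
being regressed; the +1 keeps zeros finite.

**Detection filter.** A (strain, barcode position) series enters the
regression only if its summed count at the first retained time point is
strictly greater than `min_reads = 30`. The filter is applied per
barcode position independently: a strain with one failed barcode can
still be scored from the other, and requiring both would discard
information for no robustness gain. The same `> 30` rule defines
"identified" strains when counting identifiability per time point.

**Slope.** For each (strain, barcode position, biological replicate),
a Huber M-estimated linear regression of `a` on generations:
tuning constant `c = 1.345` (95% Gaussian efficiency), scale
re-estimated each iteration as `median(|residual|) / 0.6745` (MAD
normal-consistency), iterated reweighted least squares to a coefficient
change below 1e-8 or 50 iterations. If the scale collapses to 0
(perfect fit) the series is left at its current coefficients. The
implementation is vectorized across all series sharing a design matrix;
it matches `statsmodels` RLM(HuberT) to ~1e-3 and exact OLS on
noiseless data to machine precision (tested). The strain slope is the
mean of the B1 and B2 slopes; robust estimation per position plus
averaging across positions is the cheapest defense against a single
corrupted barcode series.

**Condition truncation.** For conditions where late time points are
uninformative (takeover regimes: the majority is below detection), the
fit can be restricted to the first *K* time points via
`truncate={"CONDITION": K}` (CLI `--truncate-condition NAME:K`). The
package applies no truncation unless asked.

**Standardization and hits.** Within each (pool/background, condition,
biological replicate), slopes are standardized to Z-scores
(`ddof = 1`). A strain is a *reduced-growth hit* if `Z < −1.5`
(strict) in **every** biological replicate. Under an exchangeable null
with two replicates the expected hit rate is `Φ(−1.5)² ≈ 0.0045`;
the null calibration test checks the pipeline reproduces it.

**Survivors.** In takeover conditions a strain is a *survivor* if its
abundance `log2(TPM + 1) > 2` (strict; ≈ 3 TPM) at the **last two**
time points in all replicates, with abundance taken as the mean over
B1 and B2. Requiring two consecutive late time points suppresses
one-off jackpot counts.

**Set comparisons.** `hybrid_specific_set` supports both natural
readings of "hits in the hybrid but not in the parents": `mode="calls"`
(not called a hit in either parent) and `mode="evaluable"`
(additionally requiring the strain to have been evaluable in the
parents, so absence of evidence is not treated as evidence of
absence). `summarize_hits` reports both allele-level counts (each
hemizygote) and gene-level counts (unique gene, collapsing the two
parental alleles of a gene), since the two tallies differ whenever both
hemizygotes of a gene score.

## 4. Enrichment statistics

**Hypergeometric tail.** `P(X ≥ k)` computed by log-space summation of
`gammaln` terms with a log-sum-exp reduction — accurate for p-values
far below double-precision underflow of naive products; verified
against exact rational arithmetic.

**Gene ranking.** Two-sample t-test of hybrid vs parental expression
per gene. Default is the pooled-variance Student test (`method=
"pooled"`), the conventional choice for small equal-size replicate
groups; Welch is available. Parental replicates are by default treated
as one combined group (`parent_mode="combined"`); `parent_mode="mean"`
first averages the two parents' matching replicates. Zero-variance
genes with unequal means receive p = 0 and a `degenerate` flag so the
ranking remains total.

**XL-mHG.** For a ranked binary list, the statistic is the minimal
hypergeometric tail over prefixes of depth `r ≤ L` containing at least
`X` successes (defaults X = 5, L = 400: ignore apparent enrichments
driven by fewer than five genes, and only consider the top of the
ranking). The exact p-value is computed by a dynamic program over the
(rank, successes) lattice that counts the probability mass of
arrangements whose path first enters a cell with tail ≤ the observed
statistic; the mass is accumulated directly in log space as
`W(r,k) · C(N−r, K−k) / C(N,K)`, avoiding the catastrophic
cancellation of the complementary formulation (`1 − avoid/C(N,K)`)
when p ≪ 1e-16. Path counts `W` are floats with rescaling at 1e±280 to
prevent overflow for `N` in the thousands. Ties at the observed
statistic are counted as hits, with a relative log tolerance of 1e-10
(`_LOG_TOL`) so that equal tails computed along different code paths
compare equal. The implementation is verified against exhaustive
enumeration of all `C(N,K)` arrangements for small lists and against
classical mHG (X = 1, L = N) behavior, and its null distribution is
checked for super-uniformity and approximate uniformity
(Kolmogorov–Smirnov) at realistic sizes.

**Multiple testing.** Optional Benjamini–Hochberg adjustment over
categories in `enrich_sets`.

## 5. Pipeline and provenance

`poolfit run` executes simulate → (optional FASTQ emission and
re-counting) → normalize/collapse → fit → hits/survivors and writes
TSVs plus `manifest.json` containing the package version, the full
resolved configuration, a SHA-256 hash of the configuration, and
SHA-256 hashes of every output file — two runs with the same
configuration produce identical hashes. Unknown configuration keys are
rejected rather than ignored.
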