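# poolfit

Pooled-competition fitness screening from barcode sequencing (Bar-seq),
end to end: a generative simulator with ground truth, a FASTQ barcode
counter, robust growth-rate inference with replicate-aware hit calling,
and exact enrichment statistics (hypergeometric and XL-mHG).

## The problem

A pool of thousands of barcoded yeast strains — for example hemizygous
deletion strains in a hybrid or parental background — is grown
competitively and sampled at a series of time points measured in pool
generations. At each time point, strain abundances are read out by
amplifying and sequencing two independent 20-nt barcodes per strain (an
"up" barcode, B1, and a "down" barcode, B2), with samples multiplexed by
5-nt tags. A strain whose relative fitness is below the pool average
declines in frequency; the log2 of its relative abundance falls linearly
with generations, with slope equal to its fitness deficit in doublings
per pool generation.

`poolfit` turns raw reads (or count tables) into per-strain growth-rate
slopes, replicate-consistent "reduced growth" hit calls, "survivor"
calls for takeover regimes such as prolonged ethanol stress (where a few
resistant strains overtake the pool), and gene-set enrichment p-values
for downstream interpretation.

## Model and notation

* `gamma_i` — relative fitness of strain *i*, in doublings per pool
  generation; neutral strains have `gamma = 1`.
* Pool composition: `p_i(G) ∝ p_i(0) · 2^(gamma_i · G)` after `G`
  generations.
* Sequencing: reads per strain per sample are multinomial at a fixed
  depth (optionally Dirichlet-multinomial overdispersed), per barcode
  position and technical replicate.
* Abundance: counts are normalized to tags-per-million (TPM) within each
  (sample, barcode position, technical replicate); the working abundance
  is `a = mean over technical replicates of log2(TPM + 1)`.
* Slope: a Huber robust regression of `a` on generations, fitted
  independently for B1 and B2 and averaged. For a rare strain in a large
  pool the expected slope is `gamma_i − 1`.
* Hit: per (condition, background, biological replicate), slopes are
  standardized to Z-scores; a strain is a hit when `Z < −1.5` in **all**
  biological replicates.
* Survivor: a strain with `log2(TPM + 1) > 2` at the last two time
  points in all replicates of a takeover condition.

## Worked example

Simulate a 500-strain pool (10% of strains given fitness deficits with
`gamma` uniform in [0.7, 0.9]), two biological × two technical
replicates, 200,000 reads per sample, ten time points over 30
generations; then fit and call hits:

```python
from poolfit import (SimConfig, FitnessSpec, simulate_counts,
                     fit_growth_rates, call_hits)

cfg = SimConfig(n_strains=500, depth=200_000,
                fitness_spec=FitnessSpec(0.10, 0.7, 0.9), seed=42)
truth, counts = simulate_counts(cfg)
growth = fit_growth_rates(counts, min_reads=30)
hits = call_hits(growth, z_threshold=-1.5)
```

`growth` holds one row per strain and biological replicate:

```
   strain_id   pool condition bio_rep  slope_B1  slope_B2    slope  n_points        z
strain_00000 hybrid       YPD       A  0.003465  0.004389 0.003927        10 0.314286
strain_00000 hybrid       YPD       B  0.005833  0.004412 0.005122        10 0.346331
strain_00001 hybrid       YPD       A  0.004573  0.003942 0.004257        10 0.319380
```

With this seed the simulator injects 55 deficit strains; the pipeline
calls 50 hits, all 50 of which are true deficit strains (no false
positives; the 5 misses are the mildest deficits). Fitted slopes track
the true `gamma − 1` with Pearson r = 0.9989 and RMSE = 0.0056
doublings/generation.

The same analysis from the command line:

```bash
cat > sim.yaml <<'EOF'
n_strains: 500
depth: 200000
fitness_spec: {fraction_affected: 0.10, effect_low: 0.7, effect_high: 0.9}
EOF
poolfit simulate --config sim.yaml --seed 42 --out-dir demo
poolfit fit  --counts demo/counts.tsv --out demo/growth_rates.tsv
poolfit hits --growth demo/growth_rates.tsv --out demo/hits.tsv
# -> "50 hits among 500 strain/condition pairs"
```

`poolfit run --config pipeline.yaml` executes the whole chain
(optionally via FASTQ emission and re-counting) and writes every table
plus a `manifest.json` with SHA-256 hashes of inputs and outputs.
`poolfit count` demultiplexes real FASTQ files against a tag manifest
and barcode reference (exact 5-nt tag, exact primer, ≤1-mismatch
barcode). `poolfit convert` turns an Excel workbook of count sheets into
the long-format count table. `poolfit enrich` and `poolfit xlmhg`
provide hypergeometric set enrichment and the exact XL-mHG ranked-list
test (defaults X=5, L=400).

For the statistical details and parameter rationale see
[docs/methods.md](docs/methods.md).

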