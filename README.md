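# grnpipe

Stepwise gene-regulatory-network inference from targeted qPCR expression
panels. The pipeline mirrors a candidate-gene workflow used in fin-growth
studies of non-model fish:

1. **Quantification** — raw Cq plates → relative quantities by the ddCq
   method (reference-gene normalisation, per-fin calibrator samples,
   RQ = E^−ΔΔCq with E = 2).
2. **Differential consistency** — per-gene mixed linear model gate plus
   two-tailed paired t-tests contrasting elongated (L) vs short (S) fin
   regions per fin and stage; a gene is *consistent* when at least two
   stages are significant in the same direction in at least two fins.
3. **Stepwise selection** — seed genes pull strongly co-expressed
   neighbors (supportability-filtered) from a local co-expression
   database; consistent hits form modules; modules are extended with genes
   co-expressed with *all* members.
4. **Motif / TF prediction** — enumerative motif discovery on promoter
   sets (binomial over-representation against an order-0 background),
   the at-least-half-of-genes presence filter, PWM-library matching by
   mean per-column Pearson correlation, and log-odds binding-site
   scanning (including sites of shortlisted TFs in the promoters of
   higher-S genes, i.e. candidate repression targets).
5. **Network assembly** — pooled and per-fin Pearson correlation networks
   on log RQ (edges at two-tailed P < 0.01), descriptive TF role
   classification, SIF/GraphML/TSV export.

Because no real dataset ships with the pipeline, a first-class
`synthetic` module generates every input from a planted TF→target
network (expression, Cq plates, promoters with planted binding sites, a
PWM library, and a simulated co-expression compendium), so each stage is
testable by recovery of the planted ground truth.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (quantification
identities, statistical brute-force oracles, type-I control, screen
power, stepwise/motif/network recovery benchmarks), one test per
criterion.

## CLI

```sh
grnpipe run-all --seed 1 --outdir out/          # full synthetic pipeline
grnpipe simulate --seed 1 --outdir out/         # inputs only
grnpipe quantify --outdir out/                  # plate.tsv -> rq.tsv
grnpipe difftest --outdir out/                  # significance + consistency
grnpipe select   --outdir out/                  # stepwise selection
grnpipe motifs   --outdir out/                  # discovery + TF nomination
grnpipe network  --outdir out/                  # correlation network
```

All thresholds live in one YAML config (`--config`); flags override file
values, every stage writes `#`-prefixed headers with the tool version,
seed and config digest, and reruns with identical inputs are
byte-identical. Example config:

```yaml
n_targets: 12
effect_size: 2.0
alpha: 0.05
alpha_pooled: 0.01
threshold_fraction: 0.5
```

## Layout

| module | contents |
| --- | --- |
| `grnpipe.synthetic` | planted networks, expression/Cq simulation, promoters, PWM library, co-expression compendium |
| `grnpipe.qpcr` | plate validation, reference Cq, ddCq relative quantities, efficiency QC |
| `grnpipe.consistency` | paired L/S t-tests, consistency rule, mixed-model gate, Bonferroni |
| `grnpipe.stepwise` | co-expression DB, candidate selection, module assembly/extension, the stepwise driver |
| `grnpipe.motifs` | PWM model, TRANSFAC/MEME readers, promoter extraction, discovery, matching, scanning, TF nomination |
| `grnpipe.network` | pairwise correlations, edge construction, TF roles, SIF/GraphML/TSV export |
| `grnpipe.benchmarks` | planted-recovery benchmarks used by the acceptance suite and script |
| `grnpipe.cli` | click-based orchestration (`grnpipe` entry point) |
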