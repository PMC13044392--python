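# reactionome

Gene-expression reaction norms across a population × temperature
factorial: negative-binomial mixed-model differential expression, a
GxE taxonomy with genetic assimilation/compensation calls, signed
weighted co-expression networks with bimodality-aware module
statistics, and GO overrepresentation — plus a full generative
simulator so every step can be validated against known truth.

## The scientific problem

When two populations from different thermal environments are reared at a
benign and a stressful temperature, each gene traces a *reaction norm*:
its expression as a function of temperature, per population. The
interesting biology sits in how the norms differ:

- **plasticity** — the gene responds to temperature;
- **divergence** — the populations differ regardless of temperature;
- **GxE** — the populations *respond differently*, including full
  reversals;
- **genetic assimilation** — the plastic response of the cool-origin
  population has become constitutive in the warm-origin population
  (populations differ at the benign temperature only);
- **genetic compensation** — the warm-origin population suppresses the
  plastic response and holds the uninduced level (populations differ at
  the stressful temperature only).

`reactionome` fits an NB2 GLMM per gene (fixed effects: temperature,
population, sex, temperature × population in sum-to-zero ±½ coding; a
family random intercept; size-factor offsets), classifies genes into the
7-cell significance Venn with direction subtypes, screens
temperature-and-interaction genes with four simple-effect contrasts for
assimilation/compensation, and complements the gene-level view with
signed co-expression modules whose eigengenes are tested by
family-bootstrap quantile regression — including a bimodality index that
flags modules with a switch-like, two-state response.

See [docs/methods.md](docs/methods.md) for the model, all defaults, and
known limitations.

## Worked example

Simulate a small panel (2 genes per generative category, 96 samples),
fit the GLMM for an assimilation-pattern gene, and screen it:

```python
import pandas as pd
from reactionome import (DesignSpec, default_truth_panel, generate_design,
                         generate_counts, fit_gene, posthoc_contrasts,
                         label_plasticity, wald_tests)

design = generate_design(DesignSpec(), seed=1)
truths = default_truth_panel(n_genes_per_category=2, seed=1)
ds = generate_counts(design, truths, seed=1)
print(ds.counts.shape)

sf = pd.Series(ds.size_factors_true, index=ds.counts.columns)
fit = fit_gene(ds.counts.loc["assimilation_0000"], design, sf,
               gene_id="assimilation_0000")
print({k: round(v, 4) for k, v in wald_tests(fit).items()})

ph = posthoc_contrasts(fit)
print(ph.table.round(3))
print(label_plasticity(ph, pd.Series({"sig_T": True, "sig_TP": True})))
```

Output:

```text
(26, 96)
{'temperature': 0.0, 'population': 0.0017, 'sex': 0.068, 'interaction': 0.0}
                estimate     se      p  significant
contrast
FI_34_vs_25       -1.416  0.128  0.000         True
SP_34_vs_25        0.164  0.130  0.209        False
SP_vs_FI_at_25    -1.242  0.169  0.000         True
SP_vs_FI_at_34     0.337  0.173  0.051        False
assimilation
```

Finland responds to heat, Spain sits constitutively at the induced
level, and the populations differ at 25 °C only — the assimilation
signature.

## Command-line pipeline

```bash
# full run on simulated data (writes TSVs + manifest.json to out/)
reactionome all --out-dir out --seed 1

# or stage by stage; prerequisites are re-run so intermediates exist
reactionome de --out-dir out --seed 1

# on real data / with options, use a YAML config
reactionome all --config run.yaml
```

A config file accepts any `RunConfig` field, e.g.

```yaml
counts_path: counts.tsv        # genes x samples TSV (omit to simulate)
metadata_path: metadata.tsv    # sample_id, population, family, temperature, sex
annotation_path: anno.gaf      # optional; enables the enrich stage
out_dir: out
q_cutoff: 0.05
lfc_cutoff: 1.0
seed: 1
```

Unknown keys are rejected. Outputs include `size_factors.tsv`,
`de_results.tsv`, `reactionome_calls.tsv`, `module_assignment.tsv`,
`module_statistics.tsv`, `enrichment_*.tsv` and a `manifest.json` with
configuration, per-stage summaries and output checksums.

## Tests and benchmarks

```bash
python -m pytest -q tests/
```

The unit tests check each component against independent oracles
(brute-force median-of-ratios, textbook BH step-up, a triple-loop
topological overlap, scipy's Fisher exact test, statsmodels'
`NegativeBinomial`). `tests/test_acceptance.py` runs the headline
benchmarks (classifier recovery on a 1300-gene truth panel, FDR
calibration on 2000 null genes, planted-module recovery, bimodality
power/calibration, quantile-regression accuracy); these take a few
minutes. One known-red assertion is kept honest rather than relaxed: the
null calibration of the bimodality index (see
[docs/methods.md](docs/methods.md), "Null calibration of the bimodality
index").

The same quantities can be recomputed from a fresh seed into JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
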