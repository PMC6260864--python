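# reversig

Negative-binomial differential expression and multi-contrast **reversal
classification** for factorial RNA-seq designs, with a planted-truth count
simulator that lets every stage of the pipeline be validated by parameter
recovery.

The package targets a question that comes up in aging neuroimmunology:
microglia acquire a "primed", pro-inflammatory transcriptional state with
age, and forced turnover (CSF1R-antagonist depletion followed by
repopulation) has been proposed as a way to reset it. Deciding whether
turnover *reverses* the aging signature requires more than a single
differential-expression test — it is a decision procedure over three
contrasts in a 2×2 age × treatment design, plus a parallel taxonomy for the
response to an immune challenge (peripheral LPS) in a 2×2×2 design. This
package implements that inference chain as a tested, reusable library.

## The model and the decision rules

Counts are modelled as NB2 negative binomial,
`K_gj ~ NB(mean = s_j q_gj, var = μ + α_g μ²)`, with median-of-ratios size
factors `s_j`, gene-wise dispersions `α_g` (method-of-moments within design
cells, shrunk 50/50 in log space toward a log-linear mean–dispersion trend),
and a per-contrast log-link GLM fitted by Fisher-scoring IRLS. Each contrast
yields a Wald statistic `β̂/SE(β̂)` against a standard normal, and
Benjamini–Hochberg adjustment over the tested genes.

The **age signature** is the set of genes with `P_adj < 0.05` and
`|fold change| > 1.5` (aged-control vs adult-control), after a
`baseMean > 10` expression prefilter. Each signature gene is then classified
by two further contrasts — repopulation-vs-control within aged animals
("repop" contrast) and aged-repopulation vs adult-control ("adult"
contrast), both gated on nominal `P`:

| repop contrast | direction vs age effect | adult contrast | category |
|---|---|---|---|
| P ≥ 0.05 | — | — | unaffected |
| P < 0.05 | same sign | — | exacerbated |
| P < 0.05 | opposite | P ≥ 0.05 | reversed |
| P < 0.05 | opposite | P < 0.05 | partially reversed |

The LPS taxonomy classifies each gene of the challenge arm as
*exacerbated by age* (up after LPS in adults and further increased in aged
animals), *unique to aged* (up in aged but not adult animals), *adult-only*,
or nonresponsive, and flags aged responses *prevented* in repopulated
animals.

The ΔΔCT module implements the comparative-CT closed form for qPCR data:
`ΔCT = CT_target − CT_reference`, `ΔΔCT = ΔCT − mean(control ΔCT)`,
`fold change = 2^−ΔΔCT`.

## Worked example

```python
from reversig import (SimulationConfig, generate_factorial_counts,
                      run_reversal_pipeline, evaluate_recovery)

counts, design, truth = generate_factorial_counts(SimulationConfig(
    n_genes=3000, n_per_group=6, dispersion=0.05,
    category_counts={"null": 2800,
                     "up_reversed": 50, "up_partial": 40,
                     "up_exacerbated": 10, "up_unaffected": 60,
                     "down_reversed": 10, "down_partial": 10,
                     "down_exacerbated": 5, "down_unaffected": 15},
    seed=11))
result = run_reversal_pipeline(counts, design)
report = evaluate_recovery(truth, result.classification, result.signature)
```

Running this (`python examples/03_reversal_classification.py`) prints:

```
age signature: 210 genes (165 increased, 45 decreased)
...
             recall_reversed   0.950
   recall_partially_reversed   0.980
          recall_exacerbated   1.000
           recall_unaffected   0.933
               signature_fdr   0.048
```

190 genes were planted with an age effect of 1.5–2.5 log2 units; 210 pass
the signature gates (the 20 extra calls are planted-null genes swept in at
an empirical FDR of 4.8%), and 93–100% of each planted category is assigned
to its true reversal label. The other scripts under `examples/` walk
through the individual stages: simulation, one-contrast testing, the LPS
taxonomy, ΔΔCT quantification and null calibration.

A thin CLI wraps the same pipeline for shell use
(`reversig simulate|de|classify-reversal|classify-lps|ddct|evaluate`, each
taking a YAML config and writing CSV artifacts plus a provenance record).

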