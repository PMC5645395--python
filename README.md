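# mirreg

Condition-specific miRNA/TF regulator detection and k-miRNA module
discovery from binding evidence, expression, CNV and methylation data.

miRNA regulation is dynamic: which genes a miRNA represses depends on the
cellular condition — the abundance of the miRNA, of its competing targets,
and of the other regulators acting on the same genes. `mirreg` identifies,
for each condition (a cancer type × stage stratum of tumor samples versus
that cancer's normal controls), the miRNAs and transcription factors that
regulate each gene, and then finds sets of k miRNAs that co-regulate the
same pathways recurrently across conditions. It is aimed at computational
biologists integrating chimeric-read interactomes (CLASH-style), ChIP-seq
TF binding sites and multi-omic tumor profiles.

## Method

**Site confidence.** Each binding site's chimeric count C_ijk is tested
against Binomial(C_all, P_ijk) with P_ijk = (C_ijk/Sum_i)·(C_ijk/Sum_j),
where Sum_i, Sum_j are the miRNA's and mRNA's total read counts; sites
surviving Bonferroni at α = 0.05 are kept.

**Regulatory scores.** miRNA–mRNA: RS_ij = mean_k |MFE_k|·P_ijk over the
pair's sites. TF–gene: per-site exp(−(1/2 + 4d/10⁵)) of the TSS distance
d, aggregated by noisy-OR 1 − Π(1 − RS_tjk). Each regulator's scores are
normalized to sum to 1 across its targets (a competition share).

**Regulator selection.** Per gene and condition, the model is
Y = β₁X₁ + β₂X₂ + ε, with Y the gene's log2 expression changes, X₁ the
CNV/methylation background and X₂ the regulator expression changes scaled
by their normalized scores. The background is projected out with the
Frisch–Waugh–Lovell transform M = I − X₁(X₁ᵀX₁)⁻¹X₁ᵀ, the samples are
resampled into 25 subsets of 64% (two rounds of 5-fold complements), and a
meta-lasso objective

  max_{g,ζ} Σ_m l_m − w Σ_p |g_p| − λ Σ_{m,p} |ζ_mp|,  β_mp = g_p·ζ_mp

is maximized by block coordinate descent; regulators with g_p ≠ 0 in the
final model are selected. Consistency voting lifts per-stage selections to
cancer-specific and pan-cancer sets.

**Modules.** miRNAs are linked to pathways through their selected targets;
every k-subset (k = 1..5) sharing a pathway is screened by hypergeometric
pathway enrichment, a binomial pathway-involvement test
(w_MD ~ Binomial(|W|, P_WD)) and a binomial recurrence test
(d_M ~ Binomial(|D|, P_k)); recurrence p-values are pooled into
Benjamini–Hochberg q-values and modules with q < 0.05 recurring in ≥ 2
conditions are reported.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Everything runs on synthetic data with planted ground truth — no
downloads. From Python:

```python
from mirreg.simulate import generate_bundle
from mirreg.pipeline import run_pipeline, edge_recovery
from mirreg.io import RunConfig

bundle = generate_bundle(seed=1)           # 200 genes, 30 miRNAs, 6 conditions
result = run_pipeline(bundle, RunConfig(seed=1))
print(len(result.interactions), len(result.selections))
print(edge_recovery(result.selections, bundle.truth.edges))
```

prints (numbers from this exact run):

```
533 690
{'precision': 0.994, 'recall': 0.847, 'f1': 0.915, 'n_selected': 690, 'n_true': 810}
```

533 high-confidence miRNA–mRNA interactions survive the site filter, and
690 regulator–gene–condition edges are selected, recovering the planted
regulatory network with F1 = 0.915. The selection table looks like:

```
gene_id cancer_type stage regulator_id  kind  g_effect  sign  n_subsets_nonzero
  G0001        CAN1     I         TF04    TF    -0.339    -1                 25
  G0001        CAN1     I      miR-019 miRNA    -0.428    -1                 25
  G0001        CAN1     I      miR-030 miRNA    -0.259    -1                 25
```

(negative signs: repression; `n_subsets_nonzero`: in how many of the 25
resampled subsets the regulator had a nonzero effect). The module screen
recovers the planted 4-miRNA module among 9,286 candidates:

```
                      mirna_set  k  d_m  p_recurrence  q_value
miR-005,miR-021,miR-029,miR-030  4    3       0.00024    0.021
```

i.e. the module recurs in 3 of 6 conditions (d_M = 3) with q = 0.021.

The same pipeline is available from the shell:

```sh
mirreg --seed 1 --outdir inputs simulate
mirreg --seed 1 --outdir results run-all inputs
```

with stage-wise subcommands `score-sites`, `score-regulators`,
`build-conditions`, `select-regulators`, `find-modules`, `stability`.

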