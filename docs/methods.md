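# Methods

`mirreg` infers condition-specific gene regulators (miRNAs and
transcription factors) and recurrent k-miRNA regulatory modules from four
layers of evidence: chimeric-read binding data, TF binding sites,
feature-by-sample expression tables with CNV and methylation background,
and a pathway collection. This note records the model, its assumptions,
the tunable parameters, and the design choices that were genuinely open.

## Binding-site confidence

For a site k between miRNA i and mRNA j, the chimeric count C_ijk is
tested against Binomial(C_all, P_ijk) with

    P_ijk = (C_ijk / Sum_i) · (C_ijk / Sum_j),

where Sum_i and Sum_j are the molecule's total reads (chimeric + single)
and C_all the global chimeric total. The p-value is the inclusive upper
tail, evaluated through the binomial survival function (never naive pmf
summation, which loses accuracy and time at library scale). Note the
null reuses the observed C_ijk: the test asks whether a site's count is
large relative to the product of its marginal usage rates. This makes
significance depend on single reads dominating the totals — a site is
credible when Sum_i·Sum_j >> C_ijk·C_all. Sites with a zero read total on
either molecule are rejected as malformed input rather than silently
assigned p = 1. The Bonferroni family is the full evidence table (alpha
0.05 by default); surviving sites are collapsed to unique (miRNA, mRNA)
interactions, ties in site ids broken lexicographically.

## Regulatory scores

miRNA–mRNA: RS_ij = mean over the pair's surviving sites of
|MFE_k| · P_ijk — affinity times detection strength. MFE values are
consumed as provided (the generator draws them uniform on
[−31.2, −2.9] kcal/mol); no folding is computed internally.

TF–gene: per site, RS_tjk = exp(−(1/2 + 4·d_tjk/10⁵)) with d the TSS
distance in bp; per pair, a noisy-OR 1 − Π(1 − RS_tjk), computed via
log1p so many sites cannot underflow.

Both kinds are normalized per regulator by the **sum** of its raw scores
across targets, giving a competition share in [0, 1] that sums to 1. The
miRNA normalization is deliberately the same division-by-sum used for
TFs: a regulator spread over many strong targets contributes less per
target, which is the competition behaviour the score is meant to encode.
Normalization is condition-independent (one denominator over the full
evidence table). When somatic mutations invalidate individual sites in a
condition, the affected pair's raw score is recomputed from its clean
sites, but the global denominator is kept so scores remain comparable
across conditions.

## Conditions and designs

A condition is a (cancer type, stage) stratum; its controls are the
cancer's normal samples (shared normals across subtypes are listed per
cancer in the sample sheet). Expression changes are
log2((x + c)/(x̄_control + c)) with pseudocount c = 0.5 (guards zero
controls; configurable). Differential expression requires
|mean log2 change| ≥ log2(2) and a two-sided rank-sum test with BH-adjusted
p < 0.05 across the condition's features; both thresholds configurable.

Per DE gene, the design holds Y (the gene's changes over the condition's
n tumor samples), X1 (CNV change via the same log2 rule; methylation as
arithmetic beta difference; an intercept is appended at fit time only),
and X2 = P ∘ R: the regulator change matrix P scaled column-wise by the
normalized score vector R. Column-wise scaling (X2[s,p] = P[s,p]·R[p]) is
the only reading consistent with a per-regulator coefficient; an actual
inner product would collapse X2 to one column. Candidate regulators are
the TFs with a binding site for the gene plus the miRNAs with a retained,
scored interaction whose miRNA is DE somewhere in that cancer.
Interactions must also pass the applicability checkup: median tumor
expression of both partners above the expression floor (default: strictly
positive) and at least one unmutated binding site in the condition.

## Meta-lasso selection

Background is removed first by the Frisch–Waugh–Lovell projection
M = I − A(AᵀA)⁻¹Aᵀ with A = [X1, 1], applied through a least-squares
solve (minimum-norm under rank deficiency). By the FWL theorem the lasso
on (MY, MX2) recovers exactly the X2 block of the joint regression.

The condition's samples are resampled by two rounds of 5-fold
complements: each round splits the current set into 5 folds and recurses
into each fold's 80% complement, yielding 25 overlapping subsets of 64%
of the samples. Residualization is applied within each subset (each
subset is its own dataset with its own background rows). One penalized
likelihood is then maximized jointly:

    max_{g, ζ}  Σ_m l_m − w·Σ_p |g_p| − λ·Σ_{m,p} |ζ_mp|,

with per-subset coefficients decomposed multiplicatively,
β_mp = g_p·ζ_mp. The multiplicative form is what ties selection to g:
g_p = 0 silences regulator p in every subset. l_m is the Gaussian
log-likelihood −½‖y_m − β_m0 − X_m β_m‖², with columns standardized to
unit variance within each subset (coefficients back-transformed after;
zero-variance columns are frozen at zero).

Optimization is alternating block coordinate descent with closed-form
soft-thresholding: a pooled update of each g_p given ζ, then per-subset
updates of ζ_mp given g, each an exact single-coordinate minimization.
ζ is initialized at 1 (so the first g-update is a pooled lasso; starting
both blocks at zero would freeze the origin). The g·ζ scale ambiguity is
resolved after each g-update by the penalty-minimizing rescale
s* = sqrt(λ·Σ_m|ζ_mp| / (w·|g_p|)), which leaves every β_mp unchanged,
balances the two penalty terms exactly, and — unlike normalizing ζ to a
fixed RMS — can never decrease the objective, so the objective is
provably non-decreasing across iterations (verified to 1e-10 in tests).
Convergence: max |Δβ_mp| < 1e-6 or 1000 iterations; non-convergence
returns the best iterate with a warning.

Penalties are tuned on a small grid expressed as fractions of
data-derived maxima (the smallest w that zeroes g at ζ = 1, and the
largest per-subset score for λ), scored by aggregate BIC
Σ_m n_m·log(RSS_m/n_m) + log(Σ n_m)·df with df the count of nonzero
β_mp; ties break toward larger penalties. BIC is used instead of
cross-validation because the 25 subsets already overlap heavily — CV
folds would leak. Selection is |g_p| > 1e-8; signs are reported from
g_p·median_m(ζ_mp).

Cancer-level and pan-cancer regulator sets are obtained by consistency
voting (selected in ≥ ceil(½·#stages) stages; present in
≥ ceil(½·#cancers) cancer-level sets), not by a second meta-lasso:
per-condition sample sets are disjoint and their designs differ, so a
joint likelihood across conditions has no shared rows to couple.

## Module detection

miRNAs are linked to the pathways containing their selected targets;
candidates are all k-subsets (k = 1..5) of miRNAs sharing a pathway,
with a per-pathway cap of 30 linked miRNAs guarding combinatorial
blow-up. Per candidate and condition, each pathway is tested by the
upper-tail hypergeometric over the condition's miRNA-regulated genes
(population N_D, successes round(p_w·N_D) clamped to be consistent with
the observed overlap, draws = the candidate's targets); pathways with
p < 0.05 count toward w_MD. The involvement test compares w_MD with
Binomial(|W|, P_WD), where P_WD is the condition's rate of enriched
(group, pathway) pairs among |W|·C(K,k) possibilities — K being the
number of miRNAs with a selected target anywhere. The recurrence test
compares d_M — the number of conditions where the candidate has ≥ 1
enriched pathway — with Binomial(|D|, P_k), P_k the mean per-condition
rate of size-k candidate groups over C(K,k). Recurrence p-values of
candidates that pass involvement (p < 0.05) in at least one condition are
pooled across all k into BH q-values; modules are reported when q < 0.05
and d_M ≥ 2. Degenerate corners (zero overlap, zero enriched pathways)
return p = 1 exactly.

## Stability

The stability curve re-runs the complete selection procedure on random
sample subsets of increasing size and averages, over paired repetitions,
the Jaccard similarity between regulator sets at neighbouring sizes.
Two empty selections count as similarity 1 (logged). The default lower
bound is max(5, number of candidates); repetitions default to 100 but the
pipeline's built-in spot-check uses far fewer, and coarser resampling
(e.g. one round of folds) can be forwarded for small n.

## Synthetic data

The generator emulates the pipeline's generative assumptions, not any
real cohort's marginals. Defaults: 200 genes, 30 miRNAs, 10 TFs, 6
conditions (2 cancers × stages I–III), 40 regulated genes per condition
with 3 regulators each (2 miRNAs + 1 TF), 60 tumor samples per condition
and 30 normals per cancer, residual noise σ = 0.5 log2 units, and one
planted 4-miRNA module supported in 3 conditions whose 12 target genes
co-occupy 2 pathways among 40 (sizes 8–15).

Read counts are negative-binomial with dispersion 0.5 (chimeric-read
libraries are overdispersed): true pairs get 1–3 sites at mean 30,
decoys one site at mean 0.6, and single reads dominate the totals
(means 20000 per miRNA, 5000 per mRNA), which is precisely what makes
true sites significant under the self-referential null — at these
settings ≥ 90% of true pairs and < 20% of decoys survive the Bonferroni
filter. Expression: normals are log-normal; tumor changes follow the
linear model with miRNA effects drawn negative in [−1.5, −0.5]
(repression), TF effects of either sign, CNV ~ N(0, 0.3) dosage with
coefficient +1 and methylation difference ~ N(0, 0.2) with coefficient
−1. True-regulator miRNAs are upregulated (shift ≈ 1.5 log2 units) and
TF effect signs oppose the TF's own shift, so planted contributions
reinforce rather than cancel and regulated genes stay detectably DE —
without this the ground truth would label edges the data cannot
express. A further 30% of unused miRNAs are made DE with no effect,
providing true-negative candidates.

What passing on this generator does **not** show: robustness to
library-size artefacts, batch effects, heavy-tailed expression noise,
correlated regulators, pathway overlap structure, or miRNA effects that
are weaker than the noise floor. The generator is a self-consistency
instrument, not a benchmark of real-data performance.

## Problem sizes and numerical choices

Default end-to-end runs use the generator defaults above (≈ 270
gene-condition designs, 25 subsets each), chosen so a complete run with
tests stays desk-scale. Tolerances: tail probabilities match exhaustive
enumeration to ≤ 1e-10 (populations ≤ 60); FWL agreement with joint OLS
to ≤ 1e-8; single-dataset meta-lasso matches an established lasso solver
to ≤ 1e-6. Ties and orderings are deterministic everywhere (lexicographic
regulator and candidate ordering, TFs before miRNAs); every random draw
derives from the run seed through named seed sequences, and rewriting
outputs under the same config + seed is byte-identical.

## Known limitations

- The site-level null reuses the observed count (by construction); it is
  a detection-confidence heuristic, not a calibrated test.
- Elastic-net/group variants, effect confidence intervals, and a second
  meta-lasso across conditions are out of scope.
- The per-gene candidate cap is off by default; extremely dense evidence
  tables may need it.
- Methylation enters as a beta-value difference, not an M-value.
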