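"""End-to-end pipeline: evidence -> scores -> designs -> selections -> modules.

Stage order:

1. site confidence — tally reads, binomial test per binding site,
   Bonferroni filter, collapse to interactions;
2. regulatory scoring — miRNA scores from the surviving sites, TF scores
   from TSS distances; per-regulator normalization over the full evidence
   table (condition-independent denominators);
3. per condition — differential expression of genes and miRNAs, the
   applicability checkup (expression floor + somatic-mutation exclusion),
   design assembly and meta-lasso regulator selection per DE gene;
4. consistency voting to cancer-level and pan-cancer regulator sets;
5. k-miRNA module screen over all conditions;
6. a small stability spot-check on a few genes.

Every random choice derives from the run seed through named seed
sequences, so identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mirreg import clash, conditions as cond, metalasso, modules as mod
from mirreg import scoring, stability as stab
from mirreg.io import RunConfig, write_table
from mirreg.simulate import SyntheticBundle

logger = logging.getLogger("mirreg")


@dataclass
class PipelineResult:
    site_tests: pd.DataFrame
    interactions: pd.DataFrame
    scores: pd.DataFrame
    de_genes: dict
    de_mirnas: dict
    selections: pd.DataFrame
    cancer_level: pd.DataFrame
    pan_cancer: pd.DataFrame
    module_report: mod.ModuleReport
    stability: pd.DataFrame = field(default_factory=pd.DataFrame)


def _condition_scores(passed: pd.DataFrame, mutated: set[str],
                      global_scores: pd.DataFrame) -> pd.DataFrame:
    """miRNA interaction scores valid in one condition.

    Mutated sites are removed before each pair's raw score is recomputed;
    the per-miRNA normalization denominator stays the global one, so
    scores remain comparable across conditions.
    """
    clean = passed[~passed["site_id"].isin(mutated)]
    if not mutated:
        return global_scores
    df = clean.copy()
    df["term"] = df["mfe"].abs() * df["p_null"]
    raw = (df.groupby(["mirna_id", "mrna_id"], sort=True)["term"]
           .mean().rename("raw_rs").reset_index())
    g_mi = global_scores[global_scores["kind"] == "miRNA"]
    denom = (g_mi.groupby("regulator_id")["raw_rs"].sum())
    raw["norm_rs"] = raw["raw_rs"] / raw["mirna_id"].map(denom)
    raw = raw.dropna(subset=["norm_rs"])
    raw = raw.rename(columns={"mirna_id": "regulator_id", "mrna_id": "gene_id"})
    raw.insert(1, "kind", "miRNA")
    return pd.concat([global_scores[global_scores["kind"] == "TF"],
                      raw[["regulator_id", "kind", "gene_id", "raw_rs",
                           "norm_rs"]]], ignore_index=True)


def run_pipeline(bundle: SyntheticBundle, config: RunConfig | None = None,
                 outdir: str | Path | None = None,
                 stability_genes: int = 2,
                 stability_repetitions: int = 5) -> PipelineResult:
    """Run every stage on an in-memory input bundle.

    ``bundle`` carries all inputs (typically from
    :func:`mirreg.simulate.generate_bundle` or read from disk via the
    CLI).  When ``outdir`` is given, all result tables are written as TSV
    with provenance headers.
    """
    config = config or RunConfig()

    # -- stage 1: site confidence ------------------------------------------
    sites = bundle.sites.drop(columns=["is_true"], errors="ignore")
    tally = clash.tally_reads(sites, bundle.mirna_singles, bundle.mrna_singles)
    tested = clash.test_sites(sites, tally)
    passed = clash.filter_sites(tested, config.site_alpha)
    interactions = clash.collapse_interactions(passed)
    logger.info("stage site-confidence: %d sites -> %d interactions",
                len(sites), len(interactions))

    # -- stage 2: regulatory scores ----------------------------------------
    global_scores = scoring.score_interactions(passed, bundle.tf_sites)

    # -- stage 3: per-condition DE + designs + selection -------------------
    from mirreg.io import conditions_from_sheet, condition_samples
    sheet = bundle.sample_sheet
    conds = conditions_from_sheet(sheet)
    gene_universe = [g for g in bundle.cnv.index]  # genes only (no TFs)
    de_genes, de_mirnas = {}, {}
    for cancer, stage in conds:
        tum, nor = condition_samples(sheet, cancer, stage)
        de_genes[(cancer, stage)] = cond.detect_de(
            bundle.gene_expr, tum, nor, config.de_fold_change,
            config.de_alpha, config.pseudocount)
        de_mirnas[(cancer, stage)] = cond.detect_de(
            bundle.mirna_expr, tum, nor, config.de_fold_change,
            config.de_alpha, config.pseudocount)
    de_mirna_by_cancer: dict[str, set] = {}
    for (cancer, stage), de in de_mirnas.items():
        de_mirna_by_cancer.setdefault(cancer, set()).update(
            de.index[de["de"]])

    sel_frames = []
    for ci, (cancer, stage) in enumerate(conds):
        tum, nor = condition_samples(sheet, cancer, stage)
        mutated = set(
            bundle.mutations.loc[
                (bundle.mutations["cancer_type"] == cancer)
                & (bundle.mutations["stage"] == stage), "site_id"])
        retained = cond.applicability_filter(
            interactions, bundle.gene_expr, bundle.mirna_expr, tum,
            passed, mutated, config.expression_floor)
        cscores = _condition_scores(passed, mutated, global_scores)
        retained_pairs = set(zip(retained["mirna_id"], retained["mrna_id"]))
        pair_ok = np.fromiter(
            ((r, g) in retained_pairs
             for r, g in zip(cscores["regulator_id"], cscores["gene_id"])),
            dtype=bool, count=len(cscores))
        cscores = cscores[(cscores["kind"] == "TF").to_numpy() | pair_ok]

        de_g = de_genes[(cancer, stage)]
        de_mi_cancer = de_mirna_by_cancer.get(cancer, set())
        eligible = [g for g in gene_universe if g in de_g.index
                    and bool(de_g.loc[g, "de"])]
        gene_delta = cond.delta_table(bundle.gene_expr, tum, nor,
                                      config.pseudocount)
        mirna_delta = cond.delta_table(bundle.mirna_expr, tum, nor,
                                       config.pseudocount)
        cnv_delta = cond.delta_table(bundle.cnv, tum, nor, config.pseudocount)
        meth_ctrl = bundle.methylation[nor].mean(axis=1)
        meth_delta = bundle.methylation[tum].sub(meth_ctrl, axis=0)

        cand_mi = cscores[(cscores["kind"] == "miRNA")
                          & cscores["regulator_id"].isin(de_mi_cancer)]
        cand_tf = cscores[cscores["kind"] == "TF"]
        cands = pd.concat([cand_tf, cand_mi], ignore_index=True)

        n_sel = 0
        for gi, gene in enumerate(eligible):
            gc = cands[cands["gene_id"] == gene]
            if len(gc) == 0:
                logger.debug("gene %s: no candidates in %s %s",
                             gene, cancer, stage)
                continue
            if config.candidate_cap is not None and len(gc) > config.candidate_cap:
                gc = gc.sort_values("norm_rs", ascending=False) \
                    .head(config.candidate_cap)
            design = cond.build_design(
                gene, (cancer, stage), gc, gene_delta, mirna_delta,
                cnv_delta.loc[gene], meth_delta.loc[gene], tum)
            gseed = np.random.SeedSequence(entropy=config.seed,
                                           spawn_key=(101, ci, gi))
            sel = metalasso.select_condition_regulators(
                design, config, seed=np.random.default_rng(gseed))
            if len(sel):
                sel_frames.append(sel)
                n_sel += 1
        logger.info("stage selection %s %s: %d DE genes, %d with selections",
                    cancer, stage, len(eligible), n_sel)

    selections = (pd.concat(sel_frames, ignore_index=True) if sel_frames
                  else pd.DataFrame(columns=["gene_id", "cancer_type",
                                             "stage", "regulator_id", "kind",
                                             "g_effect", "sign",
                                             "n_subsets_nonzero", "w",
                                             "lambda"]))
    selections = selections.sort_values(
        ["cancer_type", "stage", "gene_id", "kind", "regulator_id"]
    ).reset_index(drop=True)

    # -- stage 4: consistency ----------------------------------------------
    cancer_level, pan_cancer = metalasso.hierarchical_consistency(
        selections, config.consistency_fraction)

    # -- stage 5: modules ---------------------------------------------------
    report = mod.find_modules(
        selections, bundle.pathways, gene_universe,
        k_min=config.k_min, k_max=config.k_max,
        enrichment_alpha=config.enrichment_alpha,
        involvement_alpha=config.involvement_alpha,
        q_threshold=config.module_q,
        per_pathway_cap=config.pathway_mirna_cap)

    # -- stage 6: stability spot-check --------------------------------------
    stab_frames = []
    if stability_genes > 0 and len(selections):
        first_cond = conds[0]
        tum, nor = condition_samples(sheet, *first_cond)
        cond_sel = selections[(selections["cancer_type"] == first_cond[0])
                              & (selections["stage"] == first_cond[1])]
        genes = sorted(cond_sel["gene_id"].unique())[:stability_genes]
        gene_delta = cond.delta_table(bundle.gene_expr, tum, nor,
                                      config.pseudocount)
        mirna_delta = cond.delta_table(bundle.mirna_expr, tum, nor,
                                       config.pseudocount)
        cnv_delta = cond.delta_table(bundle.cnv, tum, nor, config.pseudocount)
        meth_ctrl = bundle.methylation[nor].mean(axis=1)
        meth_delta = bundle.methylation[tum].sub(meth_ctrl, axis=0)
        de_mi_cancer = de_mirna_by_cancer.get(first_cond[0], set())
        cand_mi = global_scores[(global_scores["kind"] == "miRNA")
                                & global_scores["regulator_id"].isin(de_mi_cancer)]
        cands = pd.concat([global_scores[global_scores["kind"] == "TF"],
                           cand_mi], ignore_index=True)
        n = len(tum)
        lo = max(config.folds ** config.rounds, n // 2)
        sizes = sorted({lo, (lo + n) // 2, n})
        for gi, gene in enumerate(genes):
            gc = cands[cands["gene_id"] == gene]
            if len(gc) == 0:
                continue
            design = cond.build_design(gene, first_cond, gc, gene_delta,
                                       mirna_delta, cnv_delta.loc[gene],
                                       meth_delta.loc[gene], tum)
            sseed = np.random.SeedSequence(entropy=config.seed,
                                           spawn_key=(202, gi))
            curve = stab.stability_curve(
                design, sizes, repetitions=stability_repetitions,
                seed=int(sseed.generate_state(1)[0] % (2**31)),
                folds=config.folds, rounds=config.rounds,
                w_grid=config.w_grid, lambda_grid=config.lambda_grid)
            stab_frames.append(curve)
    stability = (pd.concat(stab_frames, ignore_index=True) if stab_frames
                 else pd.DataFrame(columns=["gene_id", "n", "mean_J", "sd_J",
                                            "repetitions", "seed"]))

    result = PipelineResult(
        site_tests=tested, interactions=interactions, scores=global_scores,
        de_genes=de_genes, de_mirnas=de_mirnas, selections=selections,
        cancer_level=cancer_level, pan_cancer=pan_cancer,
        module_report=report, stability=stability)

    if outdir is not None:
        outdir = Path(outdir)
        write_table(tested, outdir / "site_tests.tsv", config=config)
        write_table(interactions, outdir / "interactions.tsv", config=config)
        write_table(global_scores, outdir / "interaction_scores.tsv",
                    config=config)
        write_table(selections, outdir / "selections.tsv", config=config)
        write_table(cancer_level, outdir / "cancer_level.tsv", config=config)
        write_table(pan_cancer, outdir / "pan_cancer.tsv", config=config)
        write_table(report.candidates, outdir / "module_candidates.tsv",
                    config=config)
        write_table(report.modules, outdir / "modules.tsv", config=config)
        write_table(report.target_genes, outdir / "module_targets.tsv",
                    config=config)
        write_table(stability, outdir / "stability.tsv", config=config)
    return result


def edge_recovery(selections: pd.DataFrame, truth_edges: pd.DataFrame,
                  kind: str | None = None) -> dict[str, float]:
    """Precision/recall/F1 of selected (condition, gene, regulator) edges."""
    def key(df):
        return set(zip(df["cancer_type"], df["stage"], df["gene_id"],
                       df["regulator_id"]))

    sel, tru = selections, truth_edges
    if kind is not None:
        sel = sel[sel["kind"] == kind]
        tru = tru[tru["kind"] == kind]
    s, t = key(sel), key(tru)
    tp = len(s & t)
    precision = tp / len(s) if s else 0.0
    recall = tp / len(t) if t else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {"precision": precision, "recall": recall, "f1": f1,
            "n_selected": len(s), "n_true": len(t)}
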