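"""Per-condition design construction.

A condition is one (cancer type, stage) stratum.  For each gene in each
condition the method regresses the gene's per-patient log2 expression
change (vs. the cancer's normal-control mean) on

* X1 — background: per-sample CNV change and methylation change, plus an
  intercept appended at fit time, and
* X2 — regulator effects: the regulator expression-change matrix P scaled
  column-wise by the normalized regulatory score R of each candidate
  regulator for the gene.

This module computes expression changes, flags differentially expressed
(DE) features per condition, applies the interaction-applicability checkup
(expression floor + somatic-mutation exclusion of binding sites), and
assembles the Y/X1/P/R/X2 design for every eligible gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("mirreg")


def log2_change(value: np.ndarray | float, control_mean: np.ndarray | float,
                pseudocount: float = 0.5) -> np.ndarray | float:
    """log2((value + c) / (control_mean + c)); c > 0 guards zero controls."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    value = np.asarray(value, dtype=float)
    control_mean = np.asarray(control_mean, dtype=float)
    if (value < 0).any() or (control_mean < 0).any():
        raise ValueError("expression values must be >= 0")
    out = np.log2((value + pseudocount) / (control_mean + pseudocount))
    return float(out) if out.ndim == 0 else out


def delta_table(expr: pd.DataFrame, tumor_ids: list[str],
                normal_ids: list[str], pseudocount: float = 0.5
                ) -> pd.DataFrame:
    """Per-feature log2 changes of tumor samples vs the normal-group mean."""
    control_mean = expr[normal_ids].mean(axis=1).to_numpy()
    vals = expr[tumor_ids].to_numpy(dtype=float)
    delta = np.log2((vals + pseudocount) / (control_mean[:, None] + pseudocount))
    return pd.DataFrame(delta, index=expr.index, columns=tumor_ids)


def detect_de(expr: pd.DataFrame, tumor_ids: list[str], normal_ids: list[str],
              fc_threshold: float = 2.0, alpha: float = 0.05,
              pseudocount: float = 0.5) -> pd.DataFrame:
    """Differential expression per feature for one condition.

    A feature is DE when |mean log2 change| >= log2(fc_threshold) AND its
    two-sided rank-sum (Mann-Whitney) p-value, BH-adjusted across all
    features of the condition, is below ``alpha``.  Groups with fewer than
    2 samples cannot be tested; the whole call degenerates to no DE calls
    with a warning.
    """
    if len(tumor_ids) < 2 or len(normal_ids) < 2:
        logger.warning("detect_de: <2 samples in a group; no DE calls")
        return pd.DataFrame({"mean_delta": np.nan, "p_value": np.nan,
                             "adjusted_p": np.nan, "de": False},
                            index=expr.index)
    tum = expr[tumor_ids].to_numpy(dtype=float)
    nor = expr[normal_ids].to_numpy(dtype=float)
    control_mean = nor.mean(axis=1)
    mean_delta = np.log2((tum + pseudocount)
                         / (control_mean[:, None] + pseudocount)).mean(axis=1)
    # mannwhitneyu handles ties via the normal approximation
    res = stats.mannwhitneyu(tum, nor, axis=1, alternative="two-sided",
                             method="asymptotic")
    pvals = np.asarray(res.pvalue, dtype=float)
    # all-tied rows can yield nan under the tie-corrected approximation
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    adj = multipletests(pvals, method="fdr_bh")[1]
    de = (np.abs(mean_delta) >= np.log2(fc_threshold)) & (adj < alpha)
    return pd.DataFrame({"mean_delta": mean_delta, "p_value": pvals,
                         "adjusted_p": adj, "de": de}, index=expr.index)


def applicability_filter(interactions: pd.DataFrame,
                         gene_expr: pd.DataFrame,
                         mirna_expr: pd.DataFrame,
                         tumor_ids: list[str],
                         site_table: pd.DataFrame,
                         mutated_site_ids: set[str],
                         expression_floor: float = 0.0) -> pd.DataFrame:
    """Retain miRNA-gene interactions usable in one condition.

    An interaction survives iff (a) the median tumor expression of both
    the miRNA and the gene exceeds ``expression_floor``, and (b) at least
    one of its binding sites is free of somatic mutations in this
    condition.  Mutated sites are excluded from the pair's regulatory
    score before the pair-level decision, so a pair with one clean site
    stays, scored from its clean sites only.

    Returns the retained interactions with a ``clean_site_ids`` column
    listing the sites that still support each pair.
    """
    if len(interactions) == 0:
        return interactions.assign(clean_site_ids=pd.Series(dtype=object))
    med_gene = gene_expr[tumor_ids].median(axis=1)
    med_mirna = mirna_expr[tumor_ids].median(axis=1)

    sites = site_table[~site_table["site_id"].isin(mutated_site_ids)]
    clean = (sites.groupby(["mirna_id", "mrna_id"])["site_id"]
             .apply(lambda s: tuple(sorted(s))).rename("clean_site_ids"))

    out = interactions.merge(clean, left_on=["mirna_id", "mrna_id"],
                             right_index=True, how="left")
    has_clean = out["clean_site_ids"].notna()
    expr_ok = (out["mirna_id"].map(med_mirna).fillna(0.0) > expression_floor) \
        & (out["mrna_id"].map(med_gene).fillna(0.0) > expression_floor)
    kept = out[has_clean & expr_ok].reset_index(drop=True)
    logger.info("applicability filter: kept %d / %d interactions",
                len(kept), len(interactions))
    return kept


@dataclass
class GeneConditionDesign:
    """The regression design for one gene in one condition.

    ``y`` (n,) gene expression changes; ``x1`` (n, 2) CNV and methylation
    changes (intercept appended at fit time); ``p`` (n, r) regulator
    expression changes; ``r`` (r,) normalized regulatory scores; ``x2``
    (n, r) = P * R column-wise.  Column order of p/r/x2 follows
    ``regulator_ids`` (TFs first, then miRNAs, lexicographic within kind).
    """

    gene_id: str
    condition: tuple[str, str]
    y: np.ndarray
    x1: np.ndarray
    p: np.ndarray
    r: np.ndarray
    x2: np.ndarray
    regulator_ids: list[str]
    regulator_kinds: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        n = self.y.shape[0]
        if n < 1:
            raise ValueError("design needs >= 1 sample")
        if self.p.shape != (n, self.r.shape[0]) or self.x2.shape != self.p.shape:
            raise ValueError("P/R/X2 dimensions disagree")
        for arr in (self.y, self.x1, self.p, self.r, self.x2):
            if not np.isfinite(arr).all():
                raise ValueError("design contains non-finite values")


def build_design(gene_id: str, condition: tuple[str, str],
                 candidates: pd.DataFrame,
                 gene_delta: pd.DataFrame, mirna_delta: pd.DataFrame,
                 cnv_delta: pd.Series, meth_delta: pd.Series,
                 tumor_ids: list[str]) -> GeneConditionDesign:
    """Assemble Y/X1/P/R/X2 for one gene.

    ``candidates`` holds this gene's retained regulators (columns
    ``regulator_id``, ``kind``, ``norm_rs``); TF expression changes are
    looked up in ``gene_delta`` (TFs are genes), miRNA changes in
    ``mirna_delta``.  ``cnv_delta`` / ``meth_delta`` are this gene's
    per-sample background changes.
    """
    if len(candidates) == 0:
        raise ValueError(f"gene {gene_id!r} has no candidate regulators")
    kind_rank = {"TF": 0, "miRNA": 1}
    cand = candidates.assign(_k=candidates["kind"].map(kind_rank)).sort_values(
        ["_k", "regulator_id"])
    reg_ids = cand["regulator_id"].tolist()
    kinds = cand["kind"].tolist()
    cols = []
    for rid, kind in zip(reg_ids, kinds):
        src = mirna_delta if kind == "miRNA" else gene_delta
        if rid not in src.index:
            raise KeyError(f"candidate {rid!r} missing from expression changes")
        cols.append(src.loc[rid, tumor_ids].to_numpy(dtype=float))
    p_mat = np.column_stack(cols)
    r_vec = cand["norm_rs"].to_numpy(dtype=float)
    x2 = p_mat * r_vec[None, :]
    y = gene_delta.loc[gene_id, tumor_ids].to_numpy(dtype=float)
    x1 = np.column_stack([cnv_delta.loc[tumor_ids].to_numpy(dtype=float),
                          meth_delta.loc[tumor_ids].to_numpy(dtype=float)])
    return GeneConditionDesign(gene_id=gene_id, condition=condition, y=y,
                               x1=x1, p=p_mat, r=r_vec, x2=x2,
                               regulator_ids=reg_ids, regulator_kinds=kinds,
                               sample_ids=list(tumor_ids))
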