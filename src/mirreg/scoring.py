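"""Regulatory scores for miRNA-mRNA and TF-gene pairs.

A miRNA-mRNA pair's raw score averages |MFE| x binding probability over its
high-confidence sites, so both affinity and detection strength contribute.
A TF-gene pair's raw score combines per-site scores exp(-(1/2 + 4d/1e5)),
a decaying function of the site's distance d (bp) to the transcription
start site, through a noisy-OR: RS_tj = 1 - prod_k (1 - RS_tjk).

Raw scores are then normalized within each regulator across its targets so
they sum to one — a competition share: a regulator spread over many strong
targets contributes less per target.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd


def mirna_raw_rs(mfes: Sequence[float], p_nulls: Sequence[float]) -> float:
    """Raw miRNA-mRNA score: mean over sites of |MFE_k| * P_ijk."""
    mfes = np.asarray(mfes, dtype=float)
    p_nulls = np.asarray(p_nulls, dtype=float)
    if mfes.size == 0 or mfes.size != p_nulls.size:
        raise ValueError("need >= 1 site with matching MFE and probability")
    if (mfes > 0).any():
        raise ValueError("MFE must be <= 0 kcal/mol")
    return float(np.mean(np.abs(mfes) * p_nulls))


def normalize_rs(raw: pd.Series) -> pd.Series:
    """Normalize one regulator's raw scores across its targets to sum to 1."""
    total = float(raw.sum())
    if len(raw) == 0:
        raise ValueError("regulator has no targets")
    if total <= 0.0:
        raise ValueError("regulator has all-zero raw scores (no usable evidence)")
    return raw / total


def tf_site_rs(tss_distance: float) -> float:
    """Per-site TF score exp(-(1/2 + 4 d / 1e5)) for TSS distance d in bp."""
    if tss_distance < 0:
        raise ValueError(f"tss_distance must be >= 0, got {tss_distance}")
    return math.exp(-(0.5 + 4.0 * tss_distance / 1e5))


def tf_gene_rs(site_scores: Sequence[float]) -> float:
    """Noisy-OR aggregation 1 - prod(1 - s_k) over a pair's site scores.

    Computed in log space (log1p) so many sites cannot underflow the
    product; score-0 sites are no-ops, scores must stay below 1.
    """
    s = np.asarray(site_scores, dtype=float)
    if s.size == 0:
        raise ValueError("need >= 1 site score")
    if (s < 0).any() or (s >= 1).any():
        raise ValueError("site scores must lie in [0, 1)")
    return float(-np.expm1(np.sum(np.log1p(-s))))


def score_mirna_interactions(passed_sites: pd.DataFrame) -> pd.DataFrame:
    """Score all miRNA-mRNA pairs from filtered site tests.

    ``passed_sites`` must carry ``mfe`` and ``p_null`` per site.  Returns
    one row per (mirna, gene) pair with ``raw_rs`` and ``norm_rs``; pairs
    of a miRNA whose raw scores are all zero are dropped (no usable
    evidence for that regulator).
    """
    if len(passed_sites) == 0:
        return pd.DataFrame(columns=["regulator_id", "kind", "gene_id",
                                     "raw_rs", "norm_rs"])
    df = passed_sites.copy()
    df["term"] = df["mfe"].abs() * df["p_null"]
    raw = (df.groupby(["mirna_id", "mrna_id"], sort=True)["term"]
           .mean().rename("raw_rs").reset_index())
    totals = raw.groupby("mirna_id")["raw_rs"].transform("sum")
    raw = raw[totals > 0].copy()
    raw["norm_rs"] = raw["raw_rs"] / raw.groupby("mirna_id")["raw_rs"].transform("sum")
    raw = raw.rename(columns={"mirna_id": "regulator_id", "mrna_id": "gene_id"})
    raw.insert(1, "kind", "miRNA")
    return raw[["regulator_id", "kind", "gene_id", "raw_rs", "norm_rs"]]


def score_tf_interactions(tf_sites: pd.DataFrame) -> pd.DataFrame:
    """Score all TF-gene pairs from a TSS-distance site table."""
    if len(tf_sites) == 0:
        return pd.DataFrame(columns=["regulator_id", "kind", "gene_id",
                                     "raw_rs", "norm_rs"])
    df = tf_sites.copy()
    if (df["tss_distance"] < 0).any():
        raise ValueError("negative tss_distance in TF site table")
    df["site_rs"] = np.exp(-(0.5 + 4.0 * df["tss_distance"].astype(float) / 1e5))
    agg = (df.groupby(["tf_id", "gene_id"], sort=True)["site_rs"]
           .apply(lambda s: -np.expm1(np.sum(np.log1p(-s.to_numpy()))))
           .rename("raw_rs").reset_index())
    agg["norm_rs"] = agg["raw_rs"] / agg.groupby("tf_id")["raw_rs"].transform("sum")
    agg = agg.rename(columns={"tf_id": "regulator_id"})
    agg.insert(1, "kind", "TF")
    return agg[["regulator_id", "kind", "gene_id", "raw_rs", "norm_rs"]]


def score_interactions(passed_sites: pd.DataFrame,
                       tf_sites: pd.DataFrame) -> pd.DataFrame:
    """Concatenated TF + miRNA interaction scores (TFs first)."""
    return pd.concat([score_tf_interactions(tf_sites),
                      score_mirna_interactions(passed_sites)],
                     ignore_index=True)


def build_rs_row(gene_id: str, scores: pd.DataFrame,
                 regulator_ids: Sequence[str] | None = None
                 ) -> tuple[list[str], np.ndarray]:
    """Assemble the ordered normalized-score row for one gene.

    Regulator order is canonical — TFs first, then miRNAs, lexicographic
    within kind — matching the column order of the condition's regulator
    expression matrix.  Returns ``(ordered regulator ids, score row)``.
    If ``regulator_ids`` is given, every one of them must have a score for
    this gene (a candidate without evidence is a contract violation).
    """
    gene_scores = scores[scores["gene_id"] == gene_id]
    if regulator_ids is None:
        sel = gene_scores
    else:
        have = set(gene_scores["regulator_id"])
        missing = [r for r in regulator_ids if r not in have]
        if missing:
            raise KeyError(
                f"regulator(s) {missing} have no score for gene {gene_id!r}")
        sel = gene_scores[gene_scores["regulator_id"].isin(set(regulator_ids))]
    if len(sel) == 0:
        raise ValueError(f"gene {gene_id!r} has no scored candidate regulators")
    kind_rank = {"TF": 0, "miRNA": 1}
    sel = sel.assign(_k=sel["kind"].map(kind_rank)).sort_values(
        ["_k", "regulator_id"])
    return sel["regulator_id"].tolist(), sel["norm_rs"].to_numpy(dtype=float)
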