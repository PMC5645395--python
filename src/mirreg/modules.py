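"""k-miRNA regulatory module discovery.

Starting from per-condition regulator selections, miRNAs are linked to the
pathways their selected targets belong to, and every k-subset of miRNAs
sharing a pathway (k = 1..5 by default) becomes a candidate module.  Each
candidate is then screened in three stages:

1. per (candidate, condition, pathway): hypergeometric over-representation
   of the candidate's target genes in the pathway, within the population
   of miRNA-regulated genes of that condition;
2. per (candidate, condition): a binomial test of how many pathways the
   candidate is enriched for (w_MD), against the condition's background
   rate of enriched (group, pathway) pairs;
3. per candidate: a binomial test of recurrence — the number of conditions
   in which the candidate is pathway-associated (d_M) against the overall
   per-condition rate of size-k candidate groups.

Recurrence p-values of candidates passing the involvement screen are
pooled across all k and converted to Benjamini-Hochberg q-values; modules
with q below threshold that recur in at least two conditions are reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("mirreg")


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------


def pathway_enrichment(r_w: int, population: int, pathway_fraction: float,
                       n_draws: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= r_w).

    Population: the condition's miRNA-regulated genes; successes:
    ``round(pathway_fraction * population)``; draws: the candidate's
    target-gene count.
    """
    if not 0.0 < pathway_fraction <= 1.0:
        raise ValueError(f"pathway_fraction must be in (0,1], got {pathway_fraction}")
    if not 0 <= r_w <= n_draws <= population:
        raise ValueError(
            f"need 0 <= r_w <= n <= N, got r_w={r_w}, n={n_draws}, N={population}")
    successes = round(pathway_fraction * population)
    if successes < r_w:
        raise ValueError(
            f"pathway holds {successes} population genes but overlap is {r_w}")
    if r_w == 0:
        return 1.0
    return float(stats.hypergeom.sf(r_w - 1, population, successes, n_draws))


def _binom_upper_tail(x: int, n: int, p: float) -> float:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must be in [0,1], got {p}")
    if not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    if x == 0:
        return 1.0
    return float(stats.binom.sf(x - 1, n, p))


def involvement_test(w_md: int, n_pathways: int, p_wd: float) -> float:
    """P(X >= w_MD), X ~ Binomial(|W|, P_WD): is the candidate enriched for
    more pathways than the condition's background rate predicts?"""
    return _binom_upper_tail(w_md, n_pathways, p_wd)


def recurrence_test(d_m: int, n_conditions: int, p_k: float) -> float:
    """P(X >= d_M), X ~ Binomial(|D|, P_k): does the candidate recur across
    more conditions than size-k groups do on average?"""
    return _binom_upper_tail(d_m, n_conditions, p_k)


def fdr_control(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# candidate construction
# ---------------------------------------------------------------------------


def link_mirnas_to_pathways(mirna_targets: Mapping[str, set[str]],
                            pathways: Mapping[str, frozenset[str]]
                            ) -> dict[str, set[str]]:
    """miRNA -> pathways containing >= 1 of its selected targets."""
    out: dict[str, set[str]] = {}
    for mirna, targets in mirna_targets.items():
        out[mirna] = {w for w, genes in pathways.items() if targets & genes}
    return out


def enumerate_candidates(mirna_pathways: Mapping[str, set[str]], k: int,
                         per_pathway_cap: int = 30) -> list[tuple[str, ...]]:
    """All k-subsets of miRNAs sharing at least one pathway.

    Candidates are the union over pathways w of the k-subsets of the
    miRNAs linked to w, deduplicated, in sorted order.  Pathways linking
    more than ``per_pathway_cap`` miRNAs are truncated (lexicographically)
    with a warning to bound the combinatorics.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    by_pathway: dict[str, list[str]] = {}
    for mirna, ws in mirna_pathways.items():
        for w in ws:
            by_pathway.setdefault(w, []).append(mirna)
    cands: set[tuple[str, ...]] = set()
    for w, members in by_pathway.items():
        members = sorted(members)
        if len(members) > per_pathway_cap:
            logger.warning("pathway %s links %d miRNAs; capping at %d",
                           w, len(members), per_pathway_cap)
            members = members[:per_pathway_cap]
        cands.update(combinations(members, k))
    return sorted(cands)


# ---------------------------------------------------------------------------
# full screen
# ---------------------------------------------------------------------------


@dataclass
class ModuleReport:
    """Scored module candidates plus the reported (significant) subset."""

    candidates: pd.DataFrame
    modules: pd.DataFrame
    target_genes: pd.DataFrame = field(default_factory=pd.DataFrame)


def _condition_key(cancer: str, stage: str) -> str:
    return f"{cancer}|{stage}"


def find_modules(selections: pd.DataFrame,
                 pathways: Mapping[str, frozenset[str]],
                 gene_universe: Iterable[str],
                 k_min: int = 1, k_max: int = 5,
                 enrichment_alpha: float = 0.05,
                 involvement_alpha: float = 0.05,
                 q_threshold: float = 0.05,
                 per_pathway_cap: int = 30) -> ModuleReport:
    """Run the full module screen over all conditions.

    ``selections`` is the per-condition regulator table (columns gene_id,
    cancer_type, stage, regulator_id, kind); only miRNA rows are used.
    ``gene_universe`` is the full gene background for pathway fractions
    p_w.  K (the subset-count denominator) is the number of miRNAs with at
    least one selected target in any condition.
    """
    universe = set(gene_universe)
    if not universe:
        raise ValueError("empty gene universe")
    n_pathways = len(pathways)
    path_fracs = {w: len(genes & universe) / len(universe)
                  for w, genes in pathways.items()}

    mir_sel = selections[selections["kind"] == "miRNA"]
    conditions = sorted({_condition_key(c, s) for c, s in
                         zip(mir_sel["cancer_type"], mir_sel["stage"])})
    n_conditions = len(conditions)
    big_k = mir_sel["regulator_id"].nunique()

    # per-condition miRNA -> targets and candidate sets
    per_cond_targets: dict[str, dict[str, set[str]]] = {}
    for cond in conditions:
        cancer, stage = cond.split("|")
        sub = mir_sel[(mir_sel["cancer_type"] == cancer)
                      & (mir_sel["stage"] == stage)]
        per_cond_targets[cond] = {m: set(g["gene_id"])
                                  for m, g in sub.groupby("regulator_id")}

    rows = []          # one row per (candidate, k) with per-condition stats
    # counts for Eq.15 numerator: (condition, k) -> enriched (group, pathway) pairs
    enriched_pairs: dict[tuple[str, int], int] = {}
    # counts for Eq.17 numerator: (condition, k) -> number of candidates
    cand_counts: dict[tuple[str, int], int] = {}
    per_candidate: dict[tuple[str, ...], dict] = {}
    target_rows = []

    for cond in conditions:
        targets = per_cond_targets[cond]
        regulated = set().union(*targets.values()) if targets else set()
        n_d = len(regulated)
        if n_d == 0:
            continue
        linked = link_mirnas_to_pathways(targets, pathways)
        for k in range(k_min, k_max + 1):
            cands = enumerate_candidates(linked, k, per_pathway_cap)
            cand_counts[(cond, k)] = len(cands)
            n_enriched_pairs = 0
            for cand in cands:
                t = set().union(*(targets[m] for m in cand))
                n_draws = len(t)
                enriched = {}
                for w, genes in pathways.items():
                    r_w = len(t & genes)
                    if r_w == 0:
                        continue
                    frac = path_fracs[w]
                    if frac <= 0.0:
                        continue
                    successes = min(max(round(frac * n_d), r_w), n_d)
                    p = float(stats.hypergeom.sf(r_w - 1, n_d, successes,
                                                 min(n_draws, n_d)))
                    if p < enrichment_alpha:
                        enriched[w] = (r_w, p)
                n_enriched_pairs += len(enriched)
                if enriched:
                    entry = per_candidate.setdefault(
                        cand, {"k": k, "conditions": {}})
                    entry["conditions"][cond] = {
                        "w_md": len(enriched),
                        "pathways": sorted(enriched),
                        "n_targets": n_draws,
                    }
                    for w in enriched:
                        target_rows.append({
                            "mirna_set": ",".join(cand),
                            "condition": cond,
                            "pathway": w,
                            "target_genes": ",".join(
                                sorted(t & pathways[w])),
                        })
            enriched_pairs[(cond, k)] = n_enriched_pairs

    # Eq. 15 / Eq. 17 background rates per k
    p_wd: dict[tuple[str, int], float] = {}
    p_k: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        denom_groups = math.comb(big_k, k) if big_k >= k else 0
        if denom_groups == 0:
            continue
        for cond in conditions:
            num = enriched_pairs.get((cond, k), 0)
            p_wd[(cond, k)] = min(1.0, num / (n_pathways * denom_groups)) \
                if n_pathways else 0.0
        total = sum(cand_counts.get((cond, k), 0) for cond in conditions)
        p_k[k] = min(1.0, total / (n_conditions * denom_groups)) \
            if n_conditions else 0.0

    # involvement + recurrence per candidate
    for cand, entry in per_candidate.items():
        k = entry["k"]
        inv_ps = {}
        for cond, stats_d in entry["conditions"].items():
            inv_ps[cond] = involvement_test(stats_d["w_md"], n_pathways,
                                            p_wd[(cond, k)])
        entry["involvement_p"] = inv_ps
        entry["d_m"] = len(entry["conditions"])
        entry["passes_involvement"] = any(
            p < involvement_alpha for p in inv_ps.values())
        entry["recurrence_p"] = recurrence_test(entry["d_m"], n_conditions,
                                                p_k[k])

    for cand, entry in sorted(per_candidate.items()):
        rows.append({
            "mirna_set": ",".join(cand),
            "k": entry["k"],
            "conditions": ";".join(sorted(entry["conditions"])),
            "pathways": ";".join(sorted({w for c in entry["conditions"].values()
                                         for w in c["pathways"]})),
            "w_md": ";".join(f"{c}:{entry['conditions'][c]['w_md']}"
                             for c in sorted(entry["conditions"])),
            "d_m": entry["d_m"],
            "min_p_involvement": min(entry["involvement_p"].values()),
            "passes_involvement": entry["passes_involvement"],
            "p_recurrence": entry["recurrence_p"],
        })
    candidates = pd.DataFrame(rows, columns=[
        "mirna_set", "k", "conditions", "pathways", "w_md", "d_m",
        "min_p_involvement", "passes_involvement", "p_recurrence"])

    # BH over the recurrence p-values of involvement-passing candidates,
    # pooled across all k
    candidates["q_value"] = np.nan
    mask = candidates["passes_involvement"].to_numpy(dtype=bool) \
        if len(candidates) else np.array([], dtype=bool)
    if mask.any():
        candidates.loc[mask, "q_value"] = fdr_control(
            candidates.loc[mask, "p_recurrence"])
    reported = candidates[(candidates["q_value"] < q_threshold)
                          & (candidates["d_m"] >= 2)].reset_index(drop=True)
    logger.info("module screen: %d candidates, %d reported",
                len(candidates), len(reported))
    tg = pd.DataFrame(target_rows, columns=["mirna_set", "condition",
                                            "pathway", "target_genes"])
    if len(reported):
        tg = tg[tg["mirna_set"].isin(set(reported["mirna_set"]))]
    else:
        tg = tg.iloc[0:0]
    return ModuleReport(candidates=candidates, modules=reported,
                        target_genes=tg.reset_index(drop=True))
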