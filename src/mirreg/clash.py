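"""Detection-confidence tests for chimeric-read binding sites.

Chimeric-read experiments (CLASH-style) yield, for each putative
miRNA-mRNA binding site k, a chimeric read count C_ijk plus single-read
counts for the unbound miRNA and mRNA.  Under the null, C_ijk is binomial
over the global chimeric total C_all with per-site probability

    P_ijk = (C_ijk / Sum_i) * (C_ijk / Sum_j)

where Sum_i and Sum_j are the total reads (chimeric + single) seen for the
miRNA and the mRNA.  A site is kept when its upper-tail binomial p-value
survives Bonferroni correction over all tested sites.

Note the null probability deliberately reuses the observed C_ijk — the
test asks whether the chimeric count is high relative to the product of
the pair's marginal usage rates, not against an independent null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("mirreg")


@dataclass(frozen=True)
class ReadTally:
    """Per-miRNA and per-mRNA total read counts plus the chimeric total.

    ``mirna_totals[i]`` = Sum_i = chimeric reads of all sites of miRNA i
    plus its single (unbound) reads; ``mrna_totals[j]`` analogous;
    ``chimeric_total`` = C_all over every site in the evidence table.
    """

    mirna_totals: pd.Series
    mrna_totals: pd.Series
    chimeric_total: int


def tally_reads(sites: pd.DataFrame,
                mirna_singles: pd.Series,
                mrna_singles: pd.Series) -> ReadTally:
    """Aggregate chimeric and single reads into per-molecule totals.

    Parameters
    ----------
    sites:
        Binding-site evidence with columns ``mirna_id``, ``mrna_id``,
        ``chimeric_count``.
    mirna_singles, mrna_singles:
        Single-read counts indexed by molecule id.  Every id referenced by
        ``sites`` must be present (zero counts allowed).
    """
    unknown_mi = set(sites["mirna_id"]) - set(mirna_singles.index)
    if unknown_mi:
        raise KeyError(f"miRNA id(s) missing from single-read table: "
                       f"{sorted(unknown_mi)[:5]}")
    unknown_mr = set(sites["mrna_id"]) - set(mrna_singles.index)
    if unknown_mr:
        raise KeyError(f"mRNA id(s) missing from single-read table: "
                       f"{sorted(unknown_mr)[:5]}")
    chim_by_mi = sites.groupby("mirna_id")["chimeric_count"].sum()
    chim_by_mr = sites.groupby("mrna_id")["chimeric_count"].sum()
    mirna_totals = mirna_singles.add(chim_by_mi, fill_value=0).astype(int)
    mrna_totals = mrna_singles.add(chim_by_mr, fill_value=0).astype(int)
    return ReadTally(mirna_totals=mirna_totals, mrna_totals=mrna_totals,
                     chimeric_total=int(sites["chimeric_count"].sum()))


def site_null_probability(c_ijk: int, sum_i: int, sum_j: int) -> float:
    """Null binding probability (C_ijk/Sum_i)·(C_ijk/Sum_j) for one site."""
    if sum_i <= 0 or sum_j <= 0:
        raise ValueError(
            f"zero read total (Sum_i={sum_i}, Sum_j={sum_j}); "
            "every tested site needs reads on both molecules")
    if c_ijk < 0 or c_ijk > min(sum_i, sum_j):
        raise ValueError(f"chimeric count {c_ijk} exceeds a marginal total")
    return (c_ijk / sum_i) * (c_ijk / sum_j)


def site_pvalue(c_ijk: int, c_all: int, p_ijk: float) -> float:
    """Upper-tail binomial p-value P(X >= C_ijk), X ~ Binom(C_all, P_ijk).

    Uses the survival function, which is numerically stable for the large
    C_all of deep libraries; ``sf(k-1)`` gives the inclusive tail.
    """
    if not 0 <= c_ijk <= c_all:
        raise ValueError(f"need 0 <= C_ijk <= C_all, got {c_ijk} > {c_all}")
    if not 0.0 <= p_ijk <= 1.0:
        raise ValueError(f"P_ijk must be in [0,1], got {p_ijk}")
    if c_ijk == 0:
        return 1.0
    return float(stats.binom.sf(c_ijk - 1, c_all, p_ijk))


def test_sites(sites: pd.DataFrame, tally: ReadTally) -> pd.DataFrame:
    """Score every binding site: null probability, p-value, Bonferroni.

    Returns a copy of ``sites`` with columns ``p_null``, ``p_value``,
    ``adjusted_p`` (Bonferroni over all tested sites, capped at 1) and
    ``passed`` left unset — thresholding happens in :func:`filter_sites`.
    """
    out = sites.copy()
    sum_i = tally.mirna_totals.loc[out["mirna_id"]].to_numpy(dtype=float)
    sum_j = tally.mrna_totals.loc[out["mrna_id"]].to_numpy(dtype=float)
    c = out["chimeric_count"].to_numpy(dtype=float)
    if (sum_i <= 0).any() or (sum_j <= 0).any():
        bad = out.loc[(sum_i <= 0) | (sum_j <= 0),
                      ["mirna_id", "mrna_id", "site_id"]].iloc[0].tolist()
        raise ValueError(f"site {bad} has a zero read total")
    p_null = (c / sum_i) * (c / sum_j)
    c_all = tally.chimeric_total
    p_value = np.where(c == 0, 1.0,
                       stats.binom.sf(np.maximum(c, 1) - 1, c_all, p_null))
    out["p_null"] = p_null
    out["p_value"] = p_value
    out["adjusted_p"] = np.minimum(1.0, p_value * len(out))
    return out


def filter_sites(tested: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Keep sites whose Bonferroni-adjusted p-value is below ``alpha``.

    The Bonferroni family is the full evidence table (all sites tested
    jointly).  Output order is canonical (mirna_id, mrna_id, site_id)
    regardless of input order.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if len(tested) == 0:
        raise ValueError("no tested sites to filter")
    out = tested.copy()
    out["passed"] = out["p_value"] * len(out) < alpha
    kept = int(out["passed"].sum())
    logger.info("site filter: kept %d / %d (%.1f%%)",
                kept, len(out), 100.0 * kept / len(out))
    return (out[out["passed"]]
            .sort_values(["mirna_id", "mrna_id", "site_id"])
            .reset_index(drop=True))


def collapse_interactions(passed_sites: pd.DataFrame) -> pd.DataFrame:
    """Collapse high-confidence sites to unique (miRNA, mRNA) interactions.

    Reports per-pair site count and the best (smallest) adjusted p;
    deterministic ordering by (mirna_id, mrna_id).
    """
    grp = passed_sites.groupby(["mirna_id", "mrna_id"], sort=True)
    out = grp.agg(n_sites=("site_id", "size"),
                  min_adjusted_p=("adjusted_p", "min")).reset_index()
    return out
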