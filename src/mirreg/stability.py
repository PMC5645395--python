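"""Selection-stability assessment versus sample size.

For a gene, the regulator-selection procedure is re-run on random sample
subsets of increasing size; stability is the Jaccard similarity between
the regulator sets selected at neighbouring sizes, averaged over paired
repetitions.  A method whose selections stop churning as samples accrue
produces a curve that climbs toward 1.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from mirreg.metalasso import select_condition_regulators

logger = logging.getLogger("mirreg")


def jaccard(a: set, b: set) -> float:
    """|A n B| / |A u B|; two empty sets count as identical (1.0)."""
    a, b = set(a), set(b)
    if not a and not b:
        logger.debug("jaccard of two empty sets: 1.0 by convention")
        return 1.0
    return len(a & b) / len(a | b)


def _subset_design(design, idx: np.ndarray):
    return replace(
        design,
        y=design.y[idx],
        x1=design.x1[idx],
        p=design.p[idx],
        x2=design.x2[idx],
        sample_ids=[design.sample_ids[i] for i in idx],
    )


def stability_curve(design, sizes, repetitions: int = 100, seed: int = 0,
                    **selection_kwargs) -> pd.DataFrame:
    """Mean Jaccard similarity of selections at neighbouring sample sizes.

    For each size n in ``sizes`` (ascending) and repetition r, a random
    n-sample subset of the condition is drawn and the full selection
    procedure re-run; J is computed between repetition r at size n and the
    same repetition at the previous size, then averaged over repetitions.
    Returns a frame (gene_id, n, mean_J, sd_J, repetitions, seed) with one
    row per size after the first; fewer than two sizes yields an empty
    curve with a warning.

    Extra keyword arguments (folds, rounds, grids...) are forwarded to the
    selection procedure, allowing coarser resampling at small n.
    """
    sizes = sorted(set(int(s) for s in sizes))
    n_total = design.y.shape[0]
    if sizes and sizes[-1] > n_total:
        raise ValueError(f"size {sizes[-1]} exceeds the {n_total} samples")
    if len(sizes) < 2:
        logger.warning("stability_curve: need >= 2 sizes for transitions")
        return pd.DataFrame(columns=["gene_id", "n", "mean_J", "sd_J",
                                     "repetitions", "seed"])
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    rng = np.random.default_rng(seed)
    # selections[s][r] = frozenset of regulator ids
    selections: list[list[frozenset]] = []
    for n in sizes:
        per_rep = []
        for _ in range(repetitions):
            idx = rng.choice(n_total, size=n, replace=False)
            sub = _subset_design(design, np.sort(idx))
            sel = select_condition_regulators(
                sub, seed=rng.integers(2**31), **selection_kwargs)
            per_rep.append(frozenset(sel["regulator_id"]))
        selections.append(per_rep)
    rows = []
    for i in range(1, len(sizes)):
        js = [jaccard(selections[i][r], selections[i - 1][r])
              for r in range(repetitions)]
        rows.append({"gene_id": design.gene_id, "n": sizes[i],
                     "mean_J": float(np.mean(js)),
                     "sd_J": float(np.std(js, ddof=1)) if repetitions > 1 else 0.0,
                     "repetitions": repetitions, "seed": seed})
    return pd.DataFrame(rows)
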