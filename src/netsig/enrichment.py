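"""Over-representation analysis and the fold-change/p-value DE filter.

ORA tests each gene set with the upper hypergeometric tail against a
fixed background universe and adjusts per collection with
Benjamini-Hochberg; the differential-expression filter reproduces the
classic "minimum fold change at nominal p" rule (Welch t-test, no
multiplicity adjustment by design, with an optional BH column for
context).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "ora", "de_filter"]


@dataclass
class GeneSetCollection:
    """Named gene sets over a background universe.

    Sets are restricted to the universe on construction; set names must
    be unique.
    """

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        self.universe = set(self.universe)
        restricted = {}
        for name, members in self.sets.items():
            members = set(members)
            outside = members - self.universe
            if outside:
                logger.warning(
                    "set %r: %d genes outside the universe dropped",
                    name, len(outside),
                )
            restricted[name] = members & self.universe
        self.sets = restricted

    def __len__(self) -> int:
        return len(self.sets)


def ora(
    query_genes,
    collection: GeneSetCollection,
    fdr_threshold: float = 0.001,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query gene list.

    For each set: k = |query ∩ set|, K = |set|, n = |query|,
    N = |universe|, p = P(X >= k) for X ~ Hypergeom(N, K, n); q is the
    BH-adjusted p across the collection.  Query genes outside the
    universe are dropped with a warning.  Rows are sorted by p
    ascending, ties by set name; ``significant`` flags q <= threshold.
    """
    query = set(query_genes)
    if not collection.universe:
        raise ValueError("empty universe")
    dropped = query - collection.universe
    if dropped:
        logger.warning("%d query genes outside the universe dropped", len(dropped))
        query &= collection.universe
    if not query:
        raise ValueError("empty query after restriction to the universe")
    if not collection.sets:
        raise ValueError("empty gene-set collection")

    N = len(collection.universe)
    n = len(query)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        K = len(members)
        k = len(query & members)
        # upper tail P(X >= k); sf(k-1) is exact for integer support
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append((name, k, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["name", "k", "K", "n", "N", "p"])
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    df["significant"] = df["q"] <= fdr_threshold
    return df.sort_values(["p", "name"]).reset_index(drop=True)


def de_filter(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.02,
    log2_input: bool = True,
) -> pd.DataFrame:
    """Fold-change + nominal-p differential-expression filter.

    Fold change is the ratio of linear-scale group means, reported
    direction-aware as max(ratio, 1/ratio) with sign (negative = lower
    in group A); p comes from a two-sided Welch t-test on the input
    scale.  A gene passes iff fold_change >= ``fc_threshold`` and
    p < ``p_threshold``; no multiple-testing correction is applied to
    the pass rule, but a BH-adjusted column is included for context.

    ``group_a``/``group_b`` are gene x sample frames with a shared
    index; ``log2_input`` linearizes via 2**x before the means.
    """
    if group_a.shape[1] < 2 or group_b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    if not group_a.index.equals(group_b.index):
        raise ValueError("group frames must share the same gene index")

    a = group_a.to_numpy(dtype=float)
    b = group_b.to_numpy(dtype=float)
    lin_a = np.power(2.0, a) if log2_input else a
    lin_b = np.power(2.0, b) if log2_input else b
    mean_a = lin_a.mean(axis=1)
    mean_b = lin_b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mean_a / mean_b
    with np.errstate(invalid="ignore"):
        t_res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(t_res.pvalue, dtype=float)
    p[~np.isfinite(p)] = 1.0  # zero-variance identical groups

    fc = np.where(ratio >= 1.0, ratio, 1.0 / ratio)
    direction = np.where(ratio >= 1.0, 1.0, -1.0)
    passes = (fc >= fc_threshold) & (p < p_threshold)
    out = pd.DataFrame(
        {
            "fold_change": fc * direction,
            "abs_fold_change": fc,
            "p": p,
            "q_bh": multipletests(p, method="fdr_bh")[1],
            "passes": passes,
        },
        index=group_a.index,
    )
    return out
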