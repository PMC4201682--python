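"""Canalization-vs-Baldwin classification of GxE genes and direction cross-tabs.

A gene's plasticity within an origin is delta = mean(28 C) - mean(18 C) of
its log2 expression. Among genes with a significant temperature-by-origin
interaction, the Southern (heat-tolerant, derived) genotypes showing a
*greater* absolute plasticity than the Northern (heat-sensitive,
ancestral-like) ones is the Baldwin pattern (evolved enhancement of
plasticity); a *smaller* absolute plasticity is canalization (evolved
reduction). Exact equality of magnitudes is kept as an explicit tie class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .anova import DEFAULT_ALPHA, GenomewideTables

GXE_CLASSES = ("baldwin", "canalized", "tie", "not_significant")
DIRECTIONS = ("ns", "up", "down")


def classify_gxe(tables: GenomewideTables, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Classify genes with q_Txgeo < alpha by comparing |delta_S| vs |delta_N|.

    Returns a table with columns gene_id, delta_N, delta_S, q_T_x_geo,
    gxe_class (baldwin / canalized / tie / not_significant).
    """
    full = tables.genes
    rn = tables.region_N.set_index("gene_id")
    rs = tables.region_S.set_index("gene_id")
    missing = set(full["gene_id"]) - set(rn.index) | set(full["gene_id"]) - set(rs.index)
    if missing:
        raise KeyError(f"genes missing from region tables, e.g. {sorted(missing)[:5]}")

    delta_n = rn.loc[full["gene_id"], "delta"].to_numpy()
    delta_s = rs.loc[full["gene_id"], "delta"].to_numpy()
    q = full["q_T_x_geo"].to_numpy()
    sig = q < alpha  # NaN q (constant genes) compares False
    cls = np.select(
        [
            sig & (np.abs(delta_s) > np.abs(delta_n)),
            sig & (np.abs(delta_s) < np.abs(delta_n)),
            sig,
        ],
        ["baldwin", "canalized", "tie"],
        default="not_significant",
    )
    return pd.DataFrame(
        {
            "gene_id": full["gene_id"],
            "delta_N": delta_n,
            "delta_S": delta_s,
            "q_T_x_geo": q,
            "gxe_class": cls,
        }
    )


def direction_crosstab(tables: GenomewideTables) -> pd.DataFrame:
    """3x3 cross-tabulation of region direction calls (N rows x S columns).

    Rows/columns are ordered ns/up/down with margins; cell (up, up) counts
    genes up-regulated at 28 C in both origins.
    """
    rn = tables.region_N.set_index("gene_id")["direction"]
    rs = tables.region_S.set_index("gene_id")["direction"]
    if not rn.index.equals(rs.index):
        if set(rn.index) != set(rs.index):
            raise KeyError("region tables cover different gene sets")
        rs = rs.reindex(rn.index)
    tab = pd.crosstab(
        pd.Categorical(rn, categories=DIRECTIONS),
        pd.Categorical(rs, categories=DIRECTIONS),
        dropna=False,
    )
    tab.index = pd.Index(DIRECTIONS, name="N")
    tab.columns = pd.Index(DIRECTIONS, name="S")
    tab["total"] = tab.sum(axis=1)
    tab.loc["total"] = tab.sum(axis=0)
    return tab


def plasticity_summary(calls: pd.DataFrame) -> dict:
    """Counts of baldwin/canalized/tie plus a binomial test against 1:1.

    The binomial test (baldwin successes out of baldwin+canalized, p=0.5) is
    descriptive: it asks whether enhancement and reduction of plasticity are
    equally frequent among significant-GxE genes.
    """
    counts = calls["gxe_class"].value_counts()
    n_b = int(counts.get("baldwin", 0))
    n_c = int(counts.get("canalized", 0))
    n_t = int(counts.get("tie", 0))
    n_informative = n_b + n_c
    if n_informative:
        p_binom = float(stats.binomtest(n_b, n_informative, 0.5).pvalue)
        ratio = n_b / n_informative
    else:
        p_binom, ratio = np.nan, np.nan
    return {
        "baldwin": n_b,
        "canalized": n_c,
        "tie": n_t,
        "baldwin_fraction": ratio,
        "binomial_p_vs_1to1": p_binom,
    }
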