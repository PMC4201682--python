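"""Pathway over-representation of differentially expressed genes.

Each pathway is tested with Fisher's exact test on the 2x2 table of
(DE, non-DE) x (in pathway, not in pathway), with the non-differentially
expressed genes of the universe as the reference margin, followed by BH
correction across pathways. The universe defaults to every gene in the
expression matrix (no background-intensity filtering), with an option to
restrict to annotated genes. KOG-id lists split by direction are exported
in the one-id-per-line format pathway-mapping servers such as iPATH accept.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .anova import DEFAULT_ALPHA, GenomewideTables, bh_fdr

logger = logging.getLogger(__name__)


def fisher_pathway(
    de_genes: set[str],
    annotation: pd.DataFrame,
    universe: set[str],
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Per-pathway Fisher exact tests of DE over-representation.

    Parameters
    ----------
    de_genes : set
        Differentially expressed gene ids; must be a subset of ``universe``.
    annotation : DataFrame
        Columns gene_id, pathway_id (kog_id optional); memberships outside
        the universe are ignored, duplicates deduplicated per (gene, pathway).
    universe : set
        The reference gene set (all genes analyzed).

    Returns
    -------
    DataFrame with columns pathway_id, a (DE in pathway), b (non-DE in
    pathway), c (DE outside), d (non-DE outside), odds_ratio (inf when
    b*c = 0 with a*d > 0), p, q.
    """
    if not de_genes <= universe:
        raise ValueError("de_genes must be a subset of the universe")
    if not universe:
        raise ValueError("empty universe")
    ann = annotation[annotation["gene_id"].isin(universe)]
    ann = ann.drop_duplicates(["gene_id", "pathway_id"])
    n_universe = len(universe)
    n_de = len(de_genes)

    rows = []
    for pid, members in ann.groupby("pathway_id")["gene_id"]:
        mset = set(members)
        if not mset:
            logger.info("pathway %s has no members in the universe; skipped", pid)
            continue
        a = len(mset & de_genes)
        b = len(mset) - a
        c = n_de - a
        d = n_universe - n_de - b
        res = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = np.divide(a * d, b * c) if b * c else (np.inf if a * d else np.nan)
        rows.append((pid, a, b, c, d, odds, res.pvalue))
    out = pd.DataFrame(
        rows, columns=["pathway_id", "a", "b", "c", "d", "odds_ratio", "p"]
    )
    out["q"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    return out


def _kog_map(annotation: pd.DataFrame) -> pd.Series:
    ann = annotation[annotation.get("kog_id", "").astype(str) != ""]
    return ann.drop_duplicates("gene_id").set_index("gene_id")["kog_id"]


def export_ipath_lists(
    tables: GenomewideTables,
    annotation: pd.DataFrame,
    out_dir,
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, int]:
    """Write KOG-id lists (one per line) for up/down genes in all/N/S sets.

    The 'all' set uses the genome-wide temperature test (q_T < alpha) with the
    sign of the mean of the two region deltas; N and S use the region calls.
    Genes without a KOG id are skipped and counted. Returns the per-file line
    counts (also logged).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    kog = _kog_map(annotation)

    rn = tables.region_N.set_index("gene_id")
    rs = tables.region_S.set_index("gene_id")
    gene_sets: dict[str, pd.Index] = {}
    for origin, rtab in (("N", rn), ("S", rs)):
        for direction in ("up", "down"):
            ids = rtab.index[rtab["direction"] == direction]
            gene_sets[f"{origin}_{direction}"] = ids
    full = tables.genes.set_index("gene_id")
    sig_all = full.index[full["q_T"] < alpha]
    mean_delta = (rn["delta"] + rs["delta"]) / 2.0
    gene_sets["all_up"] = sig_all[mean_delta.loc[sig_all] > 0]
    gene_sets["all_down"] = sig_all[mean_delta.loc[sig_all] < 0]

    counts = {}
    for name, ids in gene_sets.items():
        kogs = kog.reindex(ids).dropna()
        skipped = len(ids) - len(kogs)
        unique = sorted(set(kogs))
        path = out_dir / f"kog_{name}.txt"
        path.write_text("".join(k + "\n" for k in unique))
        counts[name] = len(unique)
        logger.info(
            "%s: %d KOG ids (%d genes without KOG skipped)", path.name, len(unique), skipped
        )
    return counts
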