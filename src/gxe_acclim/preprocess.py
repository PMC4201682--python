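"""Input loading, validation, quantile normalization and probe summarization.

Normalization follows the common microarray route: every sample column is
mapped onto the shared reference distribution of order-statistic means
(quantile normalization), after which gene values are the median of the
probes representing each gene, all on the log2 scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import (
    AlignmentError,
    ExpressionMatrix,
    MatrixError,
    ProbeMatrix,
    StudyDesign,
)

logger = logging.getLogger(__name__)


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to the mean order-statistic reference.

    After normalization every column carries the identical sorted multiset of
    values: the element of rank r becomes the mean, across columns, of each
    column's r-th order statistic. Ties within a column receive the mean of
    the tied reference quantiles, so within-column rank order is preserved
    and the transform is idempotent.

    Parameters
    ----------
    m : DataFrame
        Rows x samples, at least two columns, all values finite.
    """
    if m.shape[1] < 2:
        raise MatrixError("quantile normalization needs at least 2 columns")
    arr = m.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise MatrixError("non-finite values in matrix")
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        order = np.argsort(arr[:, j], kind="mergesort")
        sorted_vals = arr[order, j]
        # ties receive the mean of the reference quantiles they span
        _, inv, counts = np.unique(sorted_vals, return_inverse=True, return_counts=True)
        group_means = np.bincount(inv, weights=reference) / counts
        out[order, j] = group_means[inv]
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def summarize_probes(pm: ProbeMatrix) -> ExpressionMatrix:
    """Collapse probes to genes using the per-sample median over probes.

    Genes with a single probe pass through unchanged; even probe counts use
    the midpoint of the two central values. Genes with zero probes cannot
    occur (the probe map is total) but unmapped genes are simply absent.
    """
    grouped = pm.values.groupby(pm.probe_to_gene, sort=True).median()
    grouped.index.name = "gene_id"
    return ExpressionMatrix(grouped)


def load_and_validate(
    expr_path,
    design_path,
    annot_path=None,
    *,
    log2: bool = False,
    drop_incomplete_genes: bool = False,
) -> tuple[ExpressionMatrix, StudyDesign, pd.DataFrame | None]:
    """Read expression + design (+ optional annotation) TSVs and align them.

    The matrix columns are reordered to the design's canonical sample order
    (origin, clone, temperature, replicate). Sample-id mismatches, duplicate
    ids, unbalanced designs and non-numeric cells raise distinct errors.

    Parameters
    ----------
    log2 : bool
        Apply log2 to the matrix (hard error on values <= 0); use when the
        input is on the raw intensity scale.
    drop_incomplete_genes : bool
        Remove genes with any missing cell instead of failing; the balanced
        ANOVA requires complete rows.
    """
    df = pd.read_csv(expr_path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ].tolist()
    if non_numeric:
        raise MatrixError(f"non-numeric cells in columns {non_numeric}")
    if df.isna().any().any():
        if drop_incomplete_genes:
            before = len(df)
            df = df.dropna(axis=0)
            logger.warning("dropped %d genes with missing cells", before - len(df))
        else:
            raise MatrixError(
                "missing values in expression matrix "
                "(use drop_incomplete_genes to remove affected genes)"
            )
    if log2:
        if (df.to_numpy() <= 0).any():
            raise MatrixError("log2 requested but matrix contains values <= 0")
        df = np.log2(df)

    design = StudyDesign.from_tsv(design_path)
    expr = ExpressionMatrix(df).align_to(design)

    annotation = None
    if annot_path is not None:
        annotation = pd.read_csv(
            annot_path, sep="\t", dtype=str, keep_default_na=False
        )
        required = {"gene_id", "pathway_id"}
        if not required <= set(annotation.columns):
            raise MatrixError(f"annotation must have columns {sorted(required)}")
        unknown = set(annotation["gene_id"]) - set(expr.gene_ids)
        if unknown:
            logger.warning(
                "annotation names %d genes absent from the expression matrix "
                "(kept for universe decisions)", len(unknown)
            )
    return expr, design, annotation


def normalize_pipeline(
    expr: ExpressionMatrix,
    probes: ProbeMatrix | None = None,
) -> ExpressionMatrix:
    """Quantile-normalize, summarizing probe-level input to genes first.

    When a probe matrix is supplied, normalization runs at probe level and the
    median-of-probes summarization follows; otherwise the gene matrix is
    normalized directly.
    """
    if probes is not None:
        if set(probes.sample_ids) != set(expr.sample_ids):
            raise AlignmentError("probe matrix samples differ from design samples")
        normed = quantile_normalize(probes.values[expr.sample_ids])
        return summarize_probes(ProbeMatrix(normed, probes.probe_to_gene))
    return ExpressionMatrix(quantile_normalize(expr.values))
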