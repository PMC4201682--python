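"""Model/Results front-end for the genome-wide acclimation analysis.

`AcclimationAnova` is the fitted-model entry point: construct it from an
expression matrix and a study design, call :meth:`fit`, and the returned
`AcclimationAnovaResults` carries the per-gene ANOVA tables, the region-wise
differential-expression calls, and methods for the downstream layers
(direction cross-tab, canalization/Baldwin classification, pathway
enrichment, KOG-list export, a text summary). `SamplePCA` plays the same
role for the sample-geometry analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import anova, enrichment, pca, plasticity
from .containers import ExpressionMatrix, StudyDesign


class AcclimationAnova:
    """Per-gene nested mixed-model ANOVA over a balanced acclimation design.

    Parameters
    ----------
    expr : ExpressionMatrix
        Genes x samples log2 expression, already normalized.
    design : StudyDesign
        Balanced 2-origin x nested-clones x 2-temperature x replicates layout.

    Examples
    --------
    >>> expr, truth = generate_dataset(1000, seed=1)   # doctest: +SKIP
    >>> res = AcclimationAnova(expr, truth.design).fit()   # doctest: +SKIP
    >>> res.crosstab()   # doctest: +SKIP
    """

    def __init__(self, expr: ExpressionMatrix, design: StudyDesign):
        self.design = design
        self.expr = expr.align_to(design)

    @classmethod
    def from_dataframe(cls, values: pd.DataFrame, design: pd.DataFrame) -> "AcclimationAnova":
        return cls(ExpressionMatrix(values), StudyDesign(design))

    @classmethod
    def from_tsv(cls, expr_path, design_path) -> "AcclimationAnova":
        return cls(ExpressionMatrix.from_tsv(expr_path), StudyDesign.from_tsv(design_path))

    def fit(
        self,
        alpha: float = anova.DEFAULT_ALPHA,
        pooling_threshold: float = anova.DEFAULT_POOLING_THRESHOLD,
        pool_applies_to: str = "both",
        fdr_method: str = "bh",
    ) -> "AcclimationAnovaResults":
        """Fit every gene and adjust each p-value family by BH.

        ``alpha`` is the FDR cut-off used for direction and GxE calls;
        ``pooling_threshold`` is the interaction P above which (strictly) the
        T*clone(geo) MS is pooled with the residual.
        """
        if not 0 < alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < pooling_threshold < 1:
            raise ValueError("pooling_threshold must lie in (0, 1)")
        tables = anova.run_genomewide(
            self.expr, self.design, alpha, pooling_threshold, pool_applies_to, fdr_method
        )
        return AcclimationAnovaResults(model=self, tables=tables)


@dataclass(frozen=True)
class AcclimationAnovaResults:
    """Genome-wide fit results; downstream analyses hang off this object."""

    model: AcclimationAnova = field(repr=False)
    tables: anova.GenomewideTables = field(repr=False)

    @property
    def gene_table(self) -> pd.DataFrame:
        return self.tables.genes

    @property
    def region_N(self) -> pd.DataFrame:
        return self.tables.region_N

    @property
    def region_S(self) -> pd.DataFrame:
        return self.tables.region_S

    @property
    def alpha(self) -> float:
        return self.tables.alpha

    def crosstab(self) -> pd.DataFrame:
        """3x3 N-direction x S-direction cross-tabulation with margins."""
        return plasticity.direction_crosstab(self.tables)

    def classify_gxe(self, alpha: float | None = None) -> pd.DataFrame:
        """Canalization-vs-Baldwin calls for significant-GxE genes."""
        return plasticity.classify_gxe(self.tables, alpha or self.alpha)

    def plasticity_summary(self, alpha: float | None = None) -> dict:
        return plasticity.plasticity_summary(self.classify_gxe(alpha))

    def de_genes(self, family: str = "T", alpha: float | None = None) -> set[str]:
        """Gene ids significant in a genome-wide family ('T' or 'T_x_geo')."""
        a = alpha or self.alpha
        g = self.tables.genes
        return set(g.loc[g[f"q_{family}"] < a, "gene_id"])

    def pathway_enrichment(
        self,
        annotation: pd.DataFrame,
        alpha: float | None = None,
        universe: str = "all",
        alternative: str = "two-sided",
    ) -> pd.DataFrame:
        """Fisher over-representation of genome-wide DE genes per pathway.

        ``universe`` is 'all' (every gene in the matrix; the default mirrors
        an unfiltered analysis) or 'annotated' (genes with any pathway).
        """
        uni = set(self.model.expr.gene_ids)
        if universe == "annotated":
            uni &= set(annotation["gene_id"])
        elif universe != "all":
            raise ValueError("universe must be 'all' or 'annotated'")
        de = self.de_genes("T", alpha) & uni
        return enrichment.fisher_pathway(de, annotation, uni, alternative)

    def ipath_lists(self, annotation: pd.DataFrame, out_dir, alpha: float | None = None):
        return enrichment.export_ipath_lists(
            self.tables, annotation, out_dir, alpha or self.alpha
        )

    def summary(self) -> str:
        """Plain-text summary: design, pooling rate, DE counts, cross-tab, GxE."""
        g = self.tables.genes
        n = len(g)
        lines = [
            "Acclimation GxE nested ANOVA",
            "=" * 60,
            f"genes: {n}   samples: {self.model.design.n_samples}   "
            f"alpha (FDR): {self.alpha}   pooling P>: {self.tables.pooling_threshold}",
            f"pooled T*clone(geo) with error: {int(g['pooled'].sum())}/{n} genes",
            f"q_T < {self.alpha}: {int((g['q_T'] < self.alpha).sum())} genes;  "
            f"q_Txgeo < {self.alpha}: {int((g['q_T_x_geo'] < self.alpha).sum())} genes",
            "",
            "Direction cross-tab (rows N, cols S):",
            self.crosstab().to_string(),
            "",
        ]
        summ = self.plasticity_summary()
        lines.append(
            "GxE classes: baldwin={baldwin} canalized={canalized} tie={tie} "
            "(binomial p vs 1:1 = {binomial_p_vs_1to1:.3g})".format(**summ)
            if summ["baldwin"] + summ["canalized"]
            else "GxE classes: no significant T*geo genes"
        )
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        """Write anova_full.tsv and the two region tables."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.tables.genes.to_csv(out / "anova_full.tsv", sep="\t", index=False,
                                 float_format="%.10g")
        self.tables.region_N.to_csv(out / "anova_region_N.tsv", sep="\t", index=False,
                                    float_format="%.10g")
        self.tables.region_S.to_csv(out / "anova_region_S.tsv", sep="\t", index=False,
                                    float_format="%.10g")


class SamplePCA:
    """PCA of samples in gene space with acclimation-vector geometry."""

    def __init__(self, expr: ExpressionMatrix, design: StudyDesign):
        self.design = design
        self.expr = expr.align_to(design)

    def fit(
        self, k: int = 3, scale: bool = False, subspace: tuple[int, ...] = (1, 2, 3)
    ) -> "PCAGeometryResults":
        geom = pca.pca_samples(self.expr, k=k, scale=scale)
        geom = pca.centroid_vectors(geom, self.design, subspace)
        return PCAGeometryResults(model=self, geometry=geom)


@dataclass(frozen=True)
class PCAGeometryResults:
    """Fitted PCA geometry with summary/plot/save conveniences."""

    model: SamplePCA = field(repr=False)
    geometry: pca.PCAGeometry = field(repr=False)

    def mean_clone_arrow_cosine(self, full_space: bool = False) -> float:
        """Mean pairwise cosine among the four clone acclimation arrows."""
        cos = (
            self.geometry.clone_arrow_cosines_full
            if full_space else self.geometry.clone_arrow_cosines
        )
        vals = cos.to_numpy()
        tri = vals[np.triu_indices_from(vals, k=1)]
        return float(np.nanmean(tri))

    def summary(self) -> str:
        g = self.geometry
        vf = ", ".join(f"PC{i + 1}={v:.1%}" for i, v in enumerate(g.variance_fraction))
        return "\n".join(
            [
                "Sample PCA geometry",
                "=" * 60,
                f"variance explained: {vf} (sum {g.variance_fraction.sum():.1%})",
                f"mean pairwise clone-arrow cosine (PC subspace {g.subspace}): "
                f"{self.mean_clone_arrow_cosine():.3f}",
                f"temperature-vs-origin arrow cosine: {g.temp_origin_cosine:.3f} "
                f"(full space {g.temp_origin_cosine_full:.3f})",
            ]
        )

    def plot(self, path) -> None:
        pca.plot_geometry(self.geometry, self.model.design, path)

    def save(self, scores_path, geometry_path) -> None:
        g = self.geometry
        g.scores.to_csv(scores_path, sep="\t", float_format="%.10g")
        rows = []
        for clone, arrow in g.clone_arrows.iterrows():
            rows.append({"vector": f"clone_{clone}", **arrow.to_dict()})
        rows.append({"vector": "temperature_18_to_28", **g.temp_arrow.to_dict()})
        rows.append({"vector": "origin_N_to_S", **g.origin_arrow.to_dict()})
        geom_df = pd.DataFrame(rows)
        geom_df["mean_clone_cosine"] = self.mean_clone_arrow_cosine()
        geom_df["temp_origin_cosine"] = g.temp_origin_cosine
        geom_df.to_csv(geometry_path, sep="\t", index=False, float_format="%.10g")
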