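"""PCA of samples in gene space and the centroid-vector geometry of acclimation.

Samples are projected onto principal components of the gene-centered
expression matrix. Euclidean centroids of the replicate groups define, per
clone, an arrow from its 18 C centroid to its 28 C centroid (the clone's
acclimation trajectory), a summary 18->28 C arrow over all samples, and an
origin arrow from the Northern to the Southern centroid (standing
divergence). Cosines between these arrows quantify how parallel the clones'
plastic responses are, and whether the plastic (temperature) axis is
orthogonal to the divergence (origin) axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, MatrixError, StudyDesign


@dataclass(frozen=True)
class PCAGeometry:
    """Sample scores, explained variance, and (once completed) centroid vectors."""

    scores: pd.DataFrame = field(repr=False)   # samples x PCs
    variance_fraction: np.ndarray = field(repr=False)
    clone_temp_centroids: pd.DataFrame | None = field(default=None, repr=False)
    temp_centroids: pd.DataFrame | None = field(default=None, repr=False)
    origin_centroids: pd.DataFrame | None = field(default=None, repr=False)
    clone_arrows: pd.DataFrame | None = field(default=None, repr=False)
    temp_arrow: pd.Series | None = field(default=None, repr=False)
    origin_arrow: pd.Series | None = field(default=None, repr=False)
    clone_arrow_cosines: pd.DataFrame | None = field(default=None, repr=False)
    clone_arrow_cosines_full: pd.DataFrame | None = field(default=None, repr=False)
    temp_origin_cosine: float = np.nan
    temp_origin_cosine_full: float = np.nan
    subspace: tuple[int, ...] = ()

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca_samples(expr: ExpressionMatrix, k: int = 3, scale: bool = False) -> PCAGeometry:
    """Principal-component scores of samples from the gene-centered matrix.

    Each gene is centered across samples (optionally scaled to unit SD);
    sample scores come from the singular value decomposition of the centered
    matrix, and variance_fraction_i = s_i^2 / total centered sum of squares.
    """
    x = expr.to_numpy()
    n_samples = x.shape[1]
    if n_samples < 2:
        raise MatrixError("PCA needs at least 2 samples")
    if not 1 <= k < n_samples:
        raise MatrixError(f"k must lie in 1..{n_samples - 1}")
    centered = x - x.mean(axis=1, keepdims=True)
    if scale:
        sd = centered.std(axis=1, ddof=1, keepdims=True)
        centered = np.divide(centered, sd, out=np.zeros_like(centered), where=sd > 0)
    total_ss = float((centered**2).sum())
    if total_ss <= 0:
        raise MatrixError("zero-variance matrix; PCA undefined")

    # economy SVD; sample scores are V * s
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = vt.T[:, :k] * s[:k]
    # deterministic fallback orientation: largest-|score| entry positive
    for j in range(scores.shape[1]):
        i = int(np.argmax(np.abs(scores[:, j])))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    var_frac = s[:k] ** 2 / total_ss
    score_df = pd.DataFrame(
        scores, index=pd.Index(expr.sample_ids, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PCAGeometry(scores=score_df, variance_fraction=var_frac)


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return np.nan
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def _pairwise_cosines(arrows: pd.DataFrame) -> pd.DataFrame:
    ids = arrows.index
    mat = np.full((len(ids), len(ids)), np.nan)
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            mat[i, j] = _cosine(arrows.loc[a].to_numpy(), arrows.loc[b].to_numpy())
    return pd.DataFrame(mat, index=ids, columns=ids)


def centroid_vectors(
    geom: PCAGeometry,
    design: StudyDesign,
    subspace: tuple[int, ...] = (1, 2, 3),
) -> PCAGeometry:
    """Complete a PCAGeometry with centroids, arrows and cosine metrics.

    Principal components are re-oriented so the summary 18->28 C arrow has a
    non-negative component on every PC where it is nonzero (a deterministic
    sign convention across SVD implementations). Cosines are reported both
    in the requested PC subspace (default first three) and in full score
    space.
    """
    scores = geom.scores.loc[design.sample_ids].copy()
    meta = design.table.set_index("sample_id")
    subspace = tuple(i for i in subspace if i <= scores.shape[1])
    if not subspace:
        raise MatrixError("subspace selects no computed components")

    temps = meta["temperature"]
    temp_cent = scores.groupby(temps).mean()
    temp_arrow_raw = temp_cent.loc[28] - temp_cent.loc[18]
    flip = np.where(temp_arrow_raw.to_numpy() < 0, -1.0, 1.0)
    scores = scores * flip

    temp_cent = scores.groupby(temps).mean()
    origin_cent = scores.groupby(meta["origin"]).mean()
    ct = scores.groupby([meta["clone_id"], temps]).mean()
    if ct.isna().any().any():
        raise MatrixError("empty clone x temperature group")
    temp_arrow = temp_cent.loc[28] - temp_cent.loc[18]
    origin_arrow = origin_cent.loc["S"] - origin_cent.loc["N"]

    arrows = {}
    for clone in design.clones:
        arrows[clone] = ct.loc[(clone, 28)] - ct.loc[(clone, 18)]
    clone_arrows = pd.DataFrame(arrows).T
    clone_arrows.index.name = "clone_id"

    sub_cols = [f"PC{i}" for i in subspace]
    cos_sub = _pairwise_cosines(clone_arrows[sub_cols])
    cos_full = _pairwise_cosines(clone_arrows)
    to_cos = _cosine(temp_arrow[sub_cols].to_numpy(), origin_arrow[sub_cols].to_numpy())
    to_cos_full = _cosine(temp_arrow.to_numpy(), origin_arrow.to_numpy())

    return PCAGeometry(
        scores=scores,
        variance_fraction=geom.variance_fraction,
        clone_temp_centroids=ct,
        temp_centroids=temp_cent,
        origin_centroids=origin_cent,
        clone_arrows=clone_arrows,
        temp_arrow=temp_arrow,
        origin_arrow=origin_arrow,
        clone_arrow_cosines=cos_sub,
        clone_arrow_cosines_full=cos_full,
        temp_origin_cosine=to_cos,
        temp_origin_cosine_full=to_cos_full,
        subspace=subspace,
    )


def plot_geometry(geom: PCAGeometry, design: StudyDesign, path) -> None:
    """Scatter of PC1/PC2 scores with clone, temperature and origin arrows (SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    meta = design.table.set_index("sample_id")
    fig, ax = plt.subplots(figsize=(6, 5))
    colors = {18: "tab:blue", 28: "tab:red"}
    markers = {"N": "o", "S": "s"}
    for sid, row in geom.scores.iterrows():
        m = meta.loc[sid]
        ax.scatter(
            row["PC1"], row["PC2"], c=colors[m["temperature"]],
            marker=markers[m["origin"]],
            facecolors="none" if m["origin"] == "N" else None, s=40,
        )
    if geom.clone_arrows is not None:
        for clone, arrow in geom.clone_arrows.iterrows():
            start = geom.clone_temp_centroids.loc[(clone, 18)]
            ax.annotate(
                "", xy=(start["PC1"] + arrow["PC1"], start["PC2"] + arrow["PC2"]),
                xytext=(start["PC1"], start["PC2"]),
                arrowprops=dict(arrowstyle="->", lw=1, color="gray"),
            )
        t0 = geom.temp_centroids.loc[18]
        ax.annotate(
            "", xy=(t0["PC1"] + geom.temp_arrow["PC1"], t0["PC2"] + geom.temp_arrow["PC2"]),
            xytext=(t0["PC1"], t0["PC2"]),
            arrowprops=dict(arrowstyle="->", lw=2.5, color="purple"),
        )
        o0 = geom.origin_centroids.loc["N"]
        ax.annotate(
            "", xy=(o0["PC1"] + geom.origin_arrow["PC1"], o0["PC2"] + geom.origin_arrow["PC2"]),
            xytext=(o0["PC1"], o0["PC2"]),
            arrowprops=dict(arrowstyle="->", lw=2.5, color="black"),
        )
    vf = geom.variance_fraction
    ax.set_xlabel(f"PC1 ({vf[0]:.1%})")
    ax.set_ylabel(f"PC2 ({vf[1]:.1%})" if len(vf) > 1 else "PC2")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
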