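"""Per-gene balanced nested mixed-model ANOVA with conditional MS pooling.

The model for a gene's log2 expression E is

    E = T + geo + clone(geo) + T*geo + T*clone(geo) + e

with acclimation temperature T and geographic origin geo fixed, and the
nested clone intercepts clone(geo) and clone slopes T*clone(geo) random.
Under the expected-mean-square logic of this mixed model, T and T*geo are
tested against the T*clone(geo) mean square; geo against clone(geo); and
clone(geo) against the residual. Because the T*clone(geo) denominator has
only 2 degrees of freedom in the default design, a conditional pooling rule
is applied per gene: whenever the T*clone(geo) interaction does not approach
significance (P > 0.2, strict), its sum of squares is pooled with the
residual and the fixed effects are tested against the pooled mean square on
the combined degrees of freedom.

Region-wise tests repeat the same logic within each origin (2 clones x 2
temperatures x replicates), and a paired-t-equivalent test (pooling both the
clone and interaction MS with the error) is available as the less
conservative alternative. All sums of squares come from the closed-form
balanced-layout decomposition over cell and marginal means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DesignError, ExpressionMatrix, StudyDesign

TERMS = ("T", "geo", "clone", "T_x_geo", "T_x_clone", "error")
REGION_TERMS = ("T", "clone", "T_x_clone", "error")

#: total-SS threshold under which a gene is flagged constant
_CONST_TOL = 1e-12

DEFAULT_ALPHA = 0.05
DEFAULT_POOLING_THRESHOLD = 0.2


# ---------------------------------------------------------------------------
# sums-of-squares decompositions (vectorized over genes)
# ---------------------------------------------------------------------------

def _group_mean_matrix(codes: np.ndarray, n_groups: int) -> np.ndarray:
    """(n_samples, n_groups) averaging matrix: Y @ A = per-group means."""
    a = np.zeros((codes.size, n_groups))
    a[np.arange(codes.size), codes] = 1.0
    return a / a.sum(axis=0, keepdims=True)


def _codes(values, categories) -> np.ndarray:
    return pd.Categorical(values, categories=categories).codes.astype(int)


@dataclass(frozen=True)
class _FullLayout:
    """Precomputed index structure of the balanced nested design."""

    design: StudyDesign
    a_t: np.ndarray
    a_g: np.ndarray
    a_c: np.ndarray
    a_tg: np.ndarray
    a_tc: np.ndarray
    clone_parent: np.ndarray      # origin code per clone
    tg_t: np.ndarray              # T code per T x geo cell
    tg_g: np.ndarray
    tc_t: np.ndarray              # T code per T x clone cell
    tc_c: np.ndarray
    tc_codes: np.ndarray          # T x clone cell per sample
    df: dict[str, int]

    @classmethod
    def build(cls, design: StudyDesign) -> "_FullLayout":
        t = design.table
        temps = [18, 28]
        origins = ["N", "S"]
        clones = design.clones
        ct = _codes(t["temperature"], temps)
        cg = _codes(t["origin"], origins)
        cc = _codes(t["clone_id"], clones)
        n_c = len(clones)
        ctg = ct * 2 + cg
        ctc = ct * n_c + cc
        clone_parent = np.array(
            [_codes([design.clone_origin()[c]], origins)[0] for c in clones]
        )
        n = design.n_samples
        df = {
            "T": 1,
            "geo": 1,
            "clone": n_c - 2,
            "T_x_geo": 1,
            "T_x_clone": n_c - 2,
            "error": n - 2 * n_c,
            "total": n - 1,
        }
        return cls(
            design=design,
            a_t=_group_mean_matrix(ct, 2),
            a_g=_group_mean_matrix(cg, 2),
            a_c=_group_mean_matrix(cc, n_c),
            a_tg=_group_mean_matrix(ctg, 4),
            a_tc=_group_mean_matrix(ctc, 2 * n_c),
            clone_parent=clone_parent,
            tg_t=np.repeat([0, 1], 2),
            tg_g=np.tile([0, 1], 2),
            tc_t=np.repeat([0, 1], n_c),
            tc_c=np.tile(np.arange(n_c), 2),
            tc_codes=ctc,
            df=df,
        )


def decompose_matrix(y: np.ndarray, design: StudyDesign) -> pd.DataFrame:
    """Balanced nested ANOVA sums of squares for every row of ``y``.

    ``y`` is (n_genes, n_samples) aligned to the design's canonical order.
    Returns a DataFrame with columns ``SS_<term>`` for every term plus
    ``SS_total`` and the boolean ``constant`` flag; degrees of freedom are
    attached in ``.attrs['df']``.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    lay = _FullLayout.build(design)
    n = design.n_samples
    if y.shape[1] != n:
        raise DesignError(f"expected {n} observations per gene, got {y.shape[1]}")
    if not np.isfinite(y).all():
        raise DesignError("non-finite observations")

    grand = y.mean(axis=1, keepdims=True)
    m_t = y @ lay.a_t
    m_g = y @ lay.a_g
    m_c = y @ lay.a_c
    m_tg = y @ lay.a_tg
    m_tc = y @ lay.a_tc

    n_t = n // 2
    n_c = n // len(design.clones)
    n_tg = n // 4
    n_tc = n // (2 * len(design.clones))

    ss_t = n_t * ((m_t - grand) ** 2).sum(axis=1)
    ss_g = n_t * ((m_g - grand) ** 2).sum(axis=1)
    ss_c = n_c * ((m_c - m_g[:, lay.clone_parent]) ** 2).sum(axis=1)
    ss_tg = n_tg * (
        (m_tg - m_t[:, lay.tg_t] - m_g[:, lay.tg_g] + grand) ** 2
    ).sum(axis=1)
    # T x clone(geo): cell mean minus clone mean minus the T x geo cell mean
    # of the clone's origin plus the origin mean
    tg_of_tc = lay.tc_t * 2 + lay.clone_parent[lay.tc_c]
    ss_tc = n_tc * (
        (m_tc - m_c[:, lay.tc_c] - m_tg[:, tg_of_tc] + m_g[:, lay.clone_parent[lay.tc_c]]) ** 2
    ).sum(axis=1)
    ss_err = ((y - m_tc[:, lay.tc_codes]) ** 2).sum(axis=1)
    ss_total = ((y - grand) ** 2).sum(axis=1)

    out = pd.DataFrame(
        {
            "SS_T": ss_t,
            "SS_geo": ss_g,
            "SS_clone": ss_c,
            "SS_T_x_geo": ss_tg,
            "SS_T_x_clone": ss_tc,
            "SS_error": ss_err,
            "SS_total": ss_total,
            "constant": ss_total <= _CONST_TOL,
        }
    )
    const = out["constant"]
    out.loc[const, out.columns != "constant"] = 0.0  # exact zeros, not float dust
    out.attrs["df"] = lay.df
    return out


def decompose_region(y: np.ndarray, design: StudyDesign) -> pd.DataFrame:
    """Within-origin two-way ANOVA sums of squares (clone crossed with T)."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    t = design.table
    if t["origin"].nunique() != 1:
        raise DesignError("region decomposition expects a single-origin design")
    temps = [18, 28]
    clones = sorted(t["clone_id"].unique())
    ct = _codes(t["temperature"], temps)
    cc = _codes(t["clone_id"], clones)
    n_cl = len(clones)
    ctc = ct * n_cl + cc
    n = len(t)
    if y.shape[1] != n:
        raise DesignError(f"expected {n} observations, got {y.shape[1]}")

    a_t = _group_mean_matrix(ct, 2)
    a_c = _group_mean_matrix(cc, n_cl)
    a_tc = _group_mean_matrix(ctc, 2 * n_cl)
    grand = y.mean(axis=1, keepdims=True)
    m_t = y @ a_t
    m_c = y @ a_c
    m_tc = y @ a_tc

    tc_t = np.repeat([0, 1], n_cl)
    tc_c = np.tile(np.arange(n_cl), 2)
    ss_t = (n // 2) * ((m_t - grand) ** 2).sum(axis=1)
    ss_c = (n // n_cl) * ((m_c - grand) ** 2).sum(axis=1)
    ss_tc = (n // (2 * n_cl)) * (
        (m_tc - m_t[:, tc_t] - m_c[:, tc_c] + grand) ** 2
    ).sum(axis=1)
    ss_err = ((y - m_tc[:, ctc]) ** 2).sum(axis=1)
    ss_total = ((y - grand) ** 2).sum(axis=1)

    out = pd.DataFrame(
        {
            "SS_T": ss_t,
            "SS_clone": ss_c,
            "SS_T_x_clone": ss_tc,
            "SS_error": ss_err,
            "SS_total": ss_total,
            "constant": ss_total <= _CONST_TOL,
            "delta": m_t[:, 1] - m_t[:, 0],
        }
    )
    const = out["constant"]
    out.loc[const, out.columns != "constant"] = 0.0
    out.attrs["df"] = {
        "T": 1,
        "clone": n_cl - 1,
        "T_x_clone": n_cl - 1,
        "error": n - 2 * n_cl,
        "total": n - 1,
    }
    return out


# ---------------------------------------------------------------------------
# F tests with the conditional pooling rule
# ---------------------------------------------------------------------------

def _f_pvalue(ss_num, df_num, ss_den, df_den) -> np.ndarray:
    """F-test p-value from sums of squares; zero-denominator convention:
    0/0 -> p = 1 (no evidence), x/0 -> p = 0 (infinite F)."""
    ms_num = np.asarray(ss_num, dtype=float) / df_num
    ms_den = np.asarray(ss_den, dtype=float) / np.asarray(df_den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_num / ms_den
        p = stats.f.sf(f, df_num, df_den)
    p = np.where((ms_den == 0) & (ms_num > 0), 0.0, p)
    p = np.where((ms_den == 0) & (ms_num == 0), 1.0, p)
    return p


def pooled_tests(
    dec: pd.DataFrame,
    pooling_threshold: float = DEFAULT_POOLING_THRESHOLD,
    pool_applies_to: str = "both",
) -> pd.DataFrame:
    """Apply the EMS denominators and the conditional pooling rule per gene.

    Adds columns p_T, p_geo, p_clone, p_T_x_geo, p_T_x_clone, pooled,
    den_df_T, den_df_T_x_geo to a copy of the decomposition table.
    ``pool_applies_to`` is 'both' (pooled denominator used for T and T*geo)
    or 'T' (T only; T*geo always tested against the interaction MS).
    """
    if pool_applies_to not in ("both", "T"):
        raise ValueError("pool_applies_to must be 'both' or 'T'")
    df = dec.attrs["df"]
    out = dec.copy()
    out.attrs["df"] = df

    p_txc = _f_pvalue(out["SS_T_x_clone"], df["T_x_clone"], out["SS_error"], df["error"])
    pooled = p_txc > pooling_threshold  # strict: P > threshold pools
    df_pool = df["T_x_clone"] + df["error"]
    ss_pool = out["SS_T_x_clone"] + out["SS_error"]

    ss_den_t = np.where(pooled, ss_pool, out["SS_T_x_clone"])
    df_den_t = np.where(pooled, df_pool, df["T_x_clone"])
    p_t = _f_pvalue(out["SS_T"], df["T"], ss_den_t, df_den_t)

    if pool_applies_to == "both":
        ss_den_tg, df_den_tg = ss_den_t, df_den_t
    else:
        ss_den_tg = out["SS_T_x_geo"] * 0 + out["SS_T_x_clone"]
        df_den_tg = np.full(len(out), df["T_x_clone"])
    p_tg = _f_pvalue(out["SS_T_x_geo"], df["T_x_geo"], ss_den_tg, df_den_tg)

    p_geo = _f_pvalue(out["SS_geo"], df["geo"], out["SS_clone"], df["clone"])
    p_clone = _f_pvalue(out["SS_clone"], df["clone"], out["SS_error"], df["error"])

    const = out["constant"].to_numpy()
    for name, arr in (
        ("p_T", p_t), ("p_geo", p_geo), ("p_clone", p_clone),
        ("p_T_x_geo", p_tg), ("p_T_x_clone", p_txc),
    ):
        out[name] = np.where(const, 1.0, arr)
    out["pooled"] = np.where(const, True, pooled)
    out["den_df_T"] = df_den_t
    out["den_df_T_x_geo"] = df_den_tg
    return out


def region_tests(
    dec: pd.DataFrame, pooling_threshold: float = DEFAULT_POOLING_THRESHOLD
) -> pd.DataFrame:
    """Region-wise T test with pooling (F on (1, n_clones-1) or pooled df)."""
    df = dec.attrs["df"]
    out = dec.copy()
    out.attrs["df"] = df
    p_txc = _f_pvalue(out["SS_T_x_clone"], df["T_x_clone"], out["SS_error"], df["error"])
    pooled = p_txc > pooling_threshold
    ss_den = np.where(pooled, out["SS_T_x_clone"] + out["SS_error"], out["SS_T_x_clone"])
    df_den = np.where(pooled, df["T_x_clone"] + df["error"], df["T_x_clone"])
    p_t = _f_pvalue(out["SS_T"], df["T"], ss_den, df_den)
    const = out["constant"].to_numpy()
    out["p_T_x_clone"] = np.where(const, 1.0, p_txc)
    out["p_T"] = np.where(const, 1.0, p_t)
    out["pooled"] = np.where(const, True, pooled)
    out["den_df_T"] = df_den
    return out


def paired_t_equivalent(y: np.ndarray, design: StudyDesign) -> np.ndarray:
    """Fully pooled region test: F_T against (SS_clone+SS_TxC+SS_err)/df.

    Equivalent to a paired t-test comparing each clone's expression at one
    temperature against the other; less conservative than the mixed-model
    route and provided for comparison only.
    """
    dec = decompose_region(y, design)
    df = dec.attrs["df"]
    df_den = df["clone"] + df["T_x_clone"] + df["error"]
    ss_den = dec["SS_clone"] + dec["SS_T_x_clone"] + dec["SS_error"]
    p = _f_pvalue(dec["SS_T"], df["T"], ss_den, df_den)
    return np.where(dec["constant"], 1.0, p)


# ---------------------------------------------------------------------------
# single-gene dataclass wrappers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaDecomposition:
    """Per-term SS/df/MS for one gene under the full nested model."""

    ss: dict[str, float]
    df: dict[str, int]
    ss_total: float
    constant: bool

    @property
    def ms(self) -> dict[str, float]:
        return {t: (self.ss[t] / self.df[t] if self.df[t] else np.nan) for t in TERMS}


@dataclass(frozen=True)
class GeneAnovaResult:
    """Single-gene test results (q fields filled genome-wide by BH)."""

    gene_id: str
    decomposition: AnovaDecomposition
    pooled: bool
    p_T: float
    p_geo: float
    p_clone: float
    p_T_x_geo: float
    p_T_x_clone: float
    den_df_T: int
    den_df_T_x_geo: int
    q_T: float = np.nan
    q_T_x_geo: float = np.nan


def fit_gene_anova(y: np.ndarray, design: StudyDesign) -> AnovaDecomposition:
    """Decompose one gene's observations into the model's sums of squares."""
    dec = decompose_matrix(np.asarray(y, dtype=float)[None, :], design)
    row = dec.iloc[0]
    return AnovaDecomposition(
        ss={t: float(row[f"SS_{t}"]) for t in TERMS},
        df=dec.attrs["df"],
        ss_total=float(row["SS_total"]),
        constant=bool(row["constant"]),
    )


def test_with_pooling(
    dec: AnovaDecomposition,
    pooling_threshold: float = DEFAULT_POOLING_THRESHOLD,
    pool_applies_to: str = "both",
    gene_id: str = "gene",
) -> GeneAnovaResult:
    """Test one gene's fixed and random terms with the conditional pooling rule."""
    table = pd.DataFrame({f"SS_{t}": [dec.ss[t]] for t in TERMS})
    table["SS_total"] = dec.ss_total
    table["constant"] = dec.constant
    table.attrs["df"] = dec.df
    res = pooled_tests(table, pooling_threshold, pool_applies_to).iloc[0]
    return GeneAnovaResult(
        gene_id=gene_id,
        decomposition=dec,
        pooled=bool(res["pooled"]),
        p_T=float(res["p_T"]),
        p_geo=float(res["p_geo"]),
        p_clone=float(res["p_clone"]),
        p_T_x_geo=float(res["p_T_x_geo"]),
        p_T_x_clone=float(res["p_T_x_clone"]),
        den_df_T=int(res["den_df_T"]),
        den_df_T_x_geo=int(res["den_df_T_x_geo"]),
    )


def fit_region(
    y: np.ndarray,
    design: StudyDesign,
    pooling_threshold: float = DEFAULT_POOLING_THRESHOLD,
) -> pd.Series:
    """Region-wise fit for one gene; returns the SS/p/delta record."""
    dec = decompose_region(np.asarray(y, dtype=float)[None, :], design)
    return region_tests(dec, pooling_threshold).iloc[0]


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j>=i} p_(j) * m / j over the sorted p-values, mapped back to
    input order. NaN entries (constant genes) propagate as NaN and are
    excluded from m.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    valid = ~np.isnan(p)
    if ((p[valid] < 0) | (p[valid] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    pv = p[valid]
    m = pv.size
    if m:
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        qv = np.empty(m)
        qv[order] = np.minimum(ranked, 1.0)
        q[valid] = qv
    return q


def by_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Yekutieli variant (BH scaled by the harmonic number)."""
    p = np.asarray(p, dtype=float)
    m = int((~np.isnan(p)).sum())
    if m == 0:
        return bh_fdr(p)
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    return np.minimum(bh_fdr(p) * c_m, 1.0)


# ---------------------------------------------------------------------------
# genome-wide orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomewideTables:
    """Per-gene full-model and region-wise result tables."""

    genes: pd.DataFrame = field(repr=False)
    region_N: pd.DataFrame = field(repr=False)
    region_S: pd.DataFrame = field(repr=False)
    alpha: float = DEFAULT_ALPHA
    pooling_threshold: float = DEFAULT_POOLING_THRESHOLD

    def region(self, origin: str) -> pd.DataFrame:
        return {"N": self.region_N, "S": self.region_S}[origin]


def run_genomewide(
    expr: ExpressionMatrix,
    design: StudyDesign,
    alpha: float = DEFAULT_ALPHA,
    pooling_threshold: float = DEFAULT_POOLING_THRESHOLD,
    pool_applies_to: str = "both",
    fdr_method: str = "bh",
) -> GenomewideTables:
    """Fit every gene, apply BH within each p-value family, call directions.

    BH runs separately for the genome-wide T and T*geo families and for the
    region-wise T family within each origin; constant genes are excluded
    from each family's m and reported with q = NaN. Region direction calls:
    up if q_T < alpha and delta > 0, down if delta < 0, else ns.
    """
    adjust = {"bh": bh_fdr, "by": by_fdr}[fdr_method]
    expr = expr.align_to(design)
    y = expr.to_numpy()

    full = pooled_tests(decompose_matrix(y, design), pooling_threshold, pool_applies_to)
    full.insert(0, "gene_id", expr.gene_ids)
    const = full["constant"].to_numpy()
    for term in ("T", "T_x_geo"):
        p = np.where(const, np.nan, full[f"p_{term}"])
        full[f"q_{term}"] = adjust(p)

    regions = {}
    for origin in ("N", "S"):
        rdesign = design.subset_origin(origin)
        cols = rdesign.sample_ids
        rdec = decompose_region(expr.values[cols].to_numpy(), rdesign)
        rtab = region_tests(rdec, pooling_threshold)
        rtab.insert(0, "gene_id", expr.gene_ids)
        rconst = rtab["constant"].to_numpy()
        rtab["q_T"] = adjust(np.where(rconst, np.nan, rtab["p_T"]))
        sig = rtab["q_T"].to_numpy() < alpha
        delta = rtab["delta"].to_numpy()
        rtab["direction"] = np.select(
            [sig & (delta > 0), sig & (delta < 0)], ["up", "down"], default="ns"
        )
        rtab.attrs["df"] = rdec.attrs["df"]
        regions[origin] = rtab

    full.attrs["df"] = decompose_matrix(y[:1], design).attrs["df"]
    return GenomewideTables(
        genes=full,
        region_N=regions["N"],
        region_S=regions["S"],
        alpha=alpha,
        pooling_threshold=pooling_threshold,
    )
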