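"""Synthetic expression data with the study's factorial structure and known truth.

Generates gene x sample log2 expression matrices under the generating model

    E_is = mu_i + tau_i * x_T + gamma_i * x_G + taugamma_i * x_T * x_G
           + a_{i,clone} + b_{i,clone} * x_T + eps_is

with effect coding x_T in {-1 (18 C), +1 (28 C)} and x_G in {-1 (N), +1 (S)}.
``a`` and ``b`` are random clone intercepts/slopes drawn once per gene x clone
(SDs ``sigma_clone`` and ``sigma_tclone``); ``eps`` is iid residual noise.
Under this coding a gene's expression plasticity within an origin is the
closed form

    Delta_g = mean(28 C) - mean(18 C) = 2 * (tau + taugamma * x_G),

so a gene whose Southern plasticity exceeds its Northern one in magnitude
(|Delta_S| > |Delta_N|, the Baldwin pattern) is planted simply by giving
``tau`` and ``taugamma`` the same sign, and a canalized gene
(|Delta_S| < |Delta_N|) by opposite signs.

Every generated dataset carries a truth table (per-gene parameters and class)
so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ProbeMatrix, StudyDesign

GENE_CLASSES = ("null", "T_only", "geo_only", "gxe_baldwin", "gxe_canalized")

#: Study-condition defaults: effect half-ranges on the log2 scale per class and
#: the noise triple (residual, clone intercept, clone x T slope SDs). A tau of
#: 0.5 means a 1 log2-unit (2-fold) expression difference between temperatures.
DEFAULT_CLASS_PROPORTIONS = {
    "null": 0.85,
    "T_only": 0.06,
    "geo_only": 0.03,
    "gxe_baldwin": 0.03,
    "gxe_canalized": 0.03,
}
DEFAULT_EFFECT_RANGES = {
    "T_only": {"tau": (0.5, 1.0)},
    "geo_only": {"gamma": (0.5, 1.0)},
    "gxe_baldwin": {"tau": (0.25, 0.5), "tau_gamma": (0.25, 0.5)},
    "gxe_canalized": {"tau": (0.25, 0.5), "tau_gamma": (0.25, 0.5)},
}
DEFAULT_NOISE = {"sigma_e": 0.25, "sigma_clone": 0.1, "sigma_tclone": 0.1}
DEFAULT_BASELINE_RANGE = (6.0, 12.0)

TRUTH_COLUMNS = [
    "gene_id",
    "mu",
    "tau",
    "gamma",
    "tau_gamma",
    "sigma_clone",
    "sigma_tclone",
    "sigma_e",
    "true_class",
    "delta_N",
    "delta_S",
]


class SyntheticSpecError(ValueError):
    """Raised for infeasible generator parameters."""


@dataclass(frozen=True)
class SyntheticTruth:
    """Per-gene generating parameters plus the seed and design used."""

    table: pd.DataFrame = field(repr=False)
    seed: int
    design: StudyDesign = field(repr=False)
    pathway_truth: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in TRUTH_COLUMNS if c not in self.table.columns]
        if missing:
            raise SyntheticSpecError(f"truth table missing {missing}")
        if (self.table[["sigma_clone", "sigma_tclone", "sigma_e"]] < 0).any().any():
            raise SyntheticSpecError("noise SDs must be non-negative")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _draw_effects(
    rng: np.random.Generator,
    classes: np.ndarray,
    effect_ranges: dict[str, dict[str, tuple[float, float]]],
) -> pd.DataFrame:
    n = len(classes)
    tau = np.zeros(n)
    gamma = np.zeros(n)
    tau_gamma = np.zeros(n)

    def unif(lohi, size):
        lo, hi = lohi
        if not 0 <= lo <= hi:
            raise SyntheticSpecError(f"effect range must satisfy 0 <= lo <= hi, got {lohi}")
        return rng.uniform(lo, hi, size)

    sign = rng.choice([-1.0, 1.0], size=n)  # random sign per gene, shared within gene
    for cls, ranges in effect_ranges.items():
        m = classes == cls
        k = int(m.sum())
        if k == 0:
            continue
        if cls == "T_only":
            tau[m] = sign[m] * unif(ranges["tau"], k)
        elif cls == "geo_only":
            gamma[m] = sign[m] * unif(ranges["gamma"], k)
        elif cls in ("gxe_baldwin", "gxe_canalized"):
            t = unif(ranges["tau"], k)
            tg = unif(ranges["tau_gamma"], k)
            if (t <= 0).any() or (tg <= 0).any():
                raise SyntheticSpecError("GxE classes need strictly positive effect ranges")
            # same sign => |Delta_S| > |Delta_N| (Baldwin); opposite => canalized
            rel = 1.0 if cls == "gxe_baldwin" else -1.0
            tau[m] = sign[m] * t
            tau_gamma[m] = rel * sign[m] * tg
            if "gamma" in ranges:
                gamma[m] = rng.choice([-1.0, 1.0], k) * unif(ranges["gamma"], k)
        elif cls == "null":
            pass
        else:
            raise SyntheticSpecError(f"unknown gene class {cls!r}")
    return pd.DataFrame({"tau": tau, "gamma": gamma, "tau_gamma": tau_gamma})


def generate_dataset(
    n_genes: int,
    class_proportions: dict[str, float] | None = None,
    effect_ranges: dict[str, dict[str, tuple[float, float]]] | None = None,
    noise: dict[str, float] | None = None,
    design: StudyDesign | None = None,
    seed: int = 0,
    baseline_range: tuple[float, float] = DEFAULT_BASELINE_RANGE,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a log2 expression matrix with planted effect classes.

    Parameters
    ----------
    n_genes : int
        Number of genes to simulate.
    class_proportions : dict, optional
        Mixture over gene classes (must sum to 1). Defaults to a mostly-null
        genome with 15% affected genes.
    effect_ranges : dict, optional
        Per-class uniform half-effect ranges in log2 units.
    noise : dict, optional
        ``sigma_e`` (residual), ``sigma_clone`` (random clone intercept SD)
        and ``sigma_tclone`` (random clone x temperature slope SD).
    design : StudyDesign, optional
        Defaults to the 24-sample study layout.
    seed : int
        Seed for the generator; identical inputs reproduce bit-identical output.

    Returns
    -------
    (ExpressionMatrix, SyntheticTruth)
    """
    if n_genes <= 0:
        raise SyntheticSpecError("n_genes must be positive")
    props = dict(DEFAULT_CLASS_PROPORTIONS if class_proportions is None else class_proportions)
    unknown = set(props) - set(GENE_CLASSES)
    if unknown:
        raise SyntheticSpecError(f"unknown classes in mixture: {sorted(unknown)}")
    total = sum(props.values())
    if not np.isclose(total, 1.0, atol=1e-9):
        raise SyntheticSpecError(f"class proportions must sum to 1, got {total}")
    if any(v < 0 for v in props.values()):
        raise SyntheticSpecError("class proportions must be non-negative")
    effect_ranges = DEFAULT_EFFECT_RANGES if effect_ranges is None else effect_ranges
    noise = dict(DEFAULT_NOISE if noise is None else noise)
    for key in ("sigma_e", "sigma_clone", "sigma_tclone"):
        noise.setdefault(key, 0.0)
        if noise[key] < 0:
            raise SyntheticSpecError(f"{key} must be >= 0")
    design = StudyDesign.default() if design is None else design

    rng = np.random.default_rng(seed)
    class_names = list(props)
    classes = rng.choice(class_names, size=n_genes, p=[props[c] for c in class_names])
    classes = np.asarray(classes, dtype=object)

    eff = _draw_effects(rng, classes, effect_ranges)
    mu = rng.uniform(*baseline_range, size=n_genes)

    x_t = design.x_temperature()  # (n_samples,)
    x_g = design.x_origin()
    clones = design.clones
    clone_idx = pd.Categorical(
        design.table["clone_id"], categories=clones
    ).codes  # (n_samples,)

    tau = eff["tau"].to_numpy()[:, None]
    gamma = eff["gamma"].to_numpy()[:, None]
    tau_gamma = eff["tau_gamma"].to_numpy()[:, None]

    fixed = (
        mu[:, None]
        + tau * x_t[None, :]
        + gamma * x_g[None, :]
        + tau_gamma * (x_t * x_g)[None, :]
    )
    a = rng.normal(0.0, noise["sigma_clone"], size=(n_genes, len(clones)))
    b = rng.normal(0.0, noise["sigma_tclone"], size=(n_genes, len(clones)))
    random_part = a[:, clone_idx] + b[:, clone_idx] * x_t[None, :]
    eps = rng.normal(0.0, noise["sigma_e"], size=(n_genes, design.n_samples))
    values = fixed + random_part + eps

    gene_ids = [f"g{i:06d}" for i in range(n_genes)]
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                     columns=design.sample_ids)
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "mu": mu,
            "tau": eff["tau"],
            "gamma": eff["gamma"],
            "tau_gamma": eff["tau_gamma"],
            "sigma_clone": noise["sigma_clone"],
            "sigma_tclone": noise["sigma_tclone"],
            "sigma_e": noise["sigma_e"],
            "true_class": classes,
            # Delta_g = 2*(tau + tau_gamma * x_G); x_G = -1 for N, +1 for S
            "delta_N": 2.0 * (eff["tau"] - eff["tau_gamma"]),
            "delta_S": 2.0 * (eff["tau"] + eff["tau_gamma"]),
        }
    )
    return expr, SyntheticTruth(truth, seed=seed, design=design)


def generate_probe_level(
    expr: ExpressionMatrix,
    probes_per_gene: tuple[int, int] = (1, 3),
    probe_offset_sd: float = 0.25,
    probe_noise_sd: float = 0.0,
    seed: int = 0,
) -> ProbeMatrix:
    """Expand a gene matrix to probe level (1-3 probes per gene).

    Each probe value is the gene value plus a fixed per-probe offset
    (N(0, probe_offset_sd^2), constant across samples) plus optional iid
    measurement noise.
    """
    lo, hi = probes_per_gene
    if not (1 <= lo <= hi <= 3):
        raise SyntheticSpecError("probes_per_gene must lie within 1..3")
    if probe_offset_sd < 0 or probe_noise_sd < 0:
        raise SyntheticSpecError("probe SDs must be >= 0")
    rng = np.random.default_rng(seed)
    n_probes = rng.integers(lo, hi + 1, size=expr.n_genes)

    gene_vals = expr.to_numpy()
    rows, probe_ids, parents = [], [], []
    for gi, gid in enumerate(expr.gene_ids):
        for p in range(int(n_probes[gi])):
            offset = rng.normal(0.0, probe_offset_sd) if probe_offset_sd > 0 else 0.0
            row = gene_vals[gi] + offset
            if probe_noise_sd > 0:
                row = row + rng.normal(0.0, probe_noise_sd, size=row.shape)
            rows.append(row)
            probe_ids.append(f"{gid}_p{p + 1}")
            parents.append(gid)
    values = pd.DataFrame(
        np.vstack(rows), index=pd.Index(probe_ids, name="probe_id"),
        columns=expr.sample_ids
    )
    pmap = pd.Series(parents, index=values.index, name="gene_id")
    return ProbeMatrix(values, pmap)


def generate_annotation(
    truth: SyntheticTruth,
    n_pathways: int = 125,
    genes_per_pathway: tuple[int, int] = (10, 60),
    n_enriched: int = 0,
    enrichment_boost: float = 1.0,
    kog_fraction: float = 0.9,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build a gene -> KOG -> pathway annotation with optional planted enrichment.

    Enriched pathways sample genes with selection weight ``enrichment_boost``
    for genes whose true class is non-null (boost 1 makes enriched and neutral
    pathways statistically identical). Genes may serve multiple pathways. A
    ``kog_fraction`` of genes receive a KOG id; the rest stay unannotated,
    mimicking incompletely annotated genomes.

    Returns
    -------
    (annotation, pathway_truth)
        ``annotation`` has columns gene_id, kog_id, pathway_id (kog_id empty
        for unannotated genes); ``pathway_truth`` flags each pathway
        enriched/neutral.
    """
    genes = truth.table["gene_id"].to_numpy()
    n_genes = len(genes)
    lo, hi = genes_per_pathway
    if not (1 <= lo <= hi <= n_genes):
        raise SyntheticSpecError(
            f"genes_per_pathway {genes_per_pathway} infeasible for {n_genes} genes"
        )
    if not 0 <= n_enriched <= n_pathways:
        raise SyntheticSpecError("n_enriched must lie in 0..n_pathways")
    if enrichment_boost <= 0:
        raise SyntheticSpecError("enrichment_boost must be positive")

    rng = np.random.default_rng(seed)
    has_kog = rng.random(n_genes) < kog_fraction
    kog_ids = np.where(has_kog, [f"KOG{i:05d}" for i in range(n_genes)], "")

    affected = (truth.table["true_class"] != "null").to_numpy().astype(float)
    weights = 1.0 + (enrichment_boost - 1.0) * affected
    weights_enriched = weights / weights.sum()
    weights_neutral = np.full(n_genes, 1.0 / n_genes)

    enriched_flags = np.zeros(n_pathways, dtype=bool)
    enriched_flags[:n_enriched] = True

    records = []
    for pi in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        w = weights_enriched if enriched_flags[pi] else weights_neutral
        members = rng.choice(n_genes, size=size, replace=False, p=w)
        pid = f"path{pi:04d}"
        for g in members:
            records.append((genes[g], kog_ids[g], pid))
    annotation = pd.DataFrame(records, columns=["gene_id", "kog_id", "pathway_id"])
    annotation = annotation.drop_duplicates(["gene_id", "pathway_id"]).reset_index(drop=True)
    pathway_truth = pd.DataFrame(
        {
            "pathway_id": [f"path{pi:04d}" for pi in range(n_pathways)],
            "enriched": enriched_flags,
        }
    )
    return annotation, pathway_truth
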