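"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the package's own code paths: ANOVA sums of
squares come from sequential least-squares projections onto indicator
matrices, Fisher p-values from exhaustive hypergeometric enumeration, and
PCA scores from an eigendecomposition of the sample Gram matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gxe_acclim import StudyDesign


@pytest.fixture(scope="session")
def design() -> StudyDesign:
    return StudyDesign.default()


@pytest.fixture(scope="session")
def region_design(design) -> StudyDesign:
    return design.subset_origin("N")


# ---------------------------------------------------------------------------
# projection oracle for balanced ANOVA sums of squares
# ---------------------------------------------------------------------------

def _indicators(factor: pd.Series) -> np.ndarray:
    return pd.get_dummies(factor.astype(str)).to_numpy(dtype=float)


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return float(np.sum((y - x @ beta) ** 2))


def projection_ss_full(y: np.ndarray, design: StudyDesign) -> dict[str, float]:
    """Sequential (type-I) SS by projecting onto growing indicator bases."""
    t = design.table
    blocks = [
        ("T", _indicators(t["temperature"])),
        ("geo", _indicators(t["origin"])),
        ("clone", _indicators(t["clone_id"])),
        ("T_x_geo", _indicators(t["temperature"].astype(str) + ":" + t["origin"])),
        ("T_x_clone", _indicators(t["temperature"].astype(str) + ":" + t["clone_id"])),
    ]
    x = np.ones((len(t), 1))
    rss_prev = _rss(x, y)
    out = {}
    for name, block in blocks:
        x = np.hstack([x, block])
        rss_now = _rss(x, y)
        out[name] = rss_prev - rss_now
        rss_prev = rss_now
    out["error"] = rss_prev
    return out


def projection_ss_region(y: np.ndarray, region_design: StudyDesign) -> dict[str, float]:
    t = region_design.table
    blocks = [
        ("T", _indicators(t["temperature"])),
        ("clone", _indicators(t["clone_id"])),
        ("T_x_clone", _indicators(t["temperature"].astype(str) + ":" + t["clone_id"])),
    ]
    x = np.ones((len(t), 1))
    rss_prev = _rss(x, y)
    out = {}
    for name, block in blocks:
        x = np.hstack([x, block])
        rss_now = _rss(x, y)
        out[name] = rss_prev - rss_now
        rss_prev = rss_now
    out["error"] = rss_prev
    return out


# ---------------------------------------------------------------------------
# Fisher exact oracle: exhaustive hypergeometric enumeration
# ---------------------------------------------------------------------------

def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing point probabilities <= that observed."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    kmin = max(0, row1 + col1 - n)
    kmax = min(row1, col1)
    pmf = {k: stats.hypergeom.pmf(k, n, row1, col1) for k in range(kmin, kmax + 1)}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9)))


# ---------------------------------------------------------------------------
# PCA oracle: eigendecomposition of the sample Gram matrix
# ---------------------------------------------------------------------------

def gram_pca_scores(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample scores and variance fractions from the centered Gram matrix."""
    centered = x - x.mean(axis=1, keepdims=True)
    gram = centered.T @ centered
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    scores = evecs[:, order[:k]] * np.sqrt(evals[:k])
    return scores, evals[:k] / evals.sum()
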