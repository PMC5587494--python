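"""Plasma-metabolite refueling index.

Plasma triglyceride rises with feeding and fat deposition; beta-hydroxy-
butyrate rises with fasting and mass loss. After an ln(1+x) transform, the
first principal component of the pair's *covariance* matrix gives a single
refueling score per bird: the sign convention puts triglyceride on the
positive loading, so larger scores mean faster fuel deposition. Scores are
centered (mean zero), so negative scores are below-average refueling, not
negative refueling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ln1p",
    "transform_metabolites",
    "MetaboliteCorrelation",
    "metabolite_correlation",
    "RefuelingIndex",
    "refueling_index",
]


def ln1p(x):
    """ln(1+x) transform; defined for x > -1."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= -1):
        raise ValueError("ln(1+x) requires x > -1")
    out = np.log1p(x)
    return float(out) if out.ndim == 0 else out


def transform_metabolites(
    plasma: pd.DataFrame,
    transform_bleedtime: bool = True,
) -> pd.DataFrame:
    """Add ln(1+x)-transformed metabolite (and optionally bleed-time) columns.

    Expects ``triglyceride`` and ``bohb`` (mmol/L); adds ``ln_trig`` and
    ``ln_bohb``, plus ``ln_bleedtime`` when requested and present.
    """
    out = plasma.copy()
    out["ln_trig"] = ln1p(out["triglyceride"].to_numpy())
    out["ln_bohb"] = ln1p(out["bohb"].to_numpy())
    if transform_bleedtime and "bleedtime" in out.columns:
        out["ln_bleedtime"] = ln1p(out["bleedtime"].to_numpy())
    return out


@dataclass
class MetaboliteCorrelation:
    r: float
    t: float
    df: int
    p: float


def metabolite_correlation(ln_trig, ln_bohb) -> MetaboliteCorrelation:
    """Pearson correlation of the transformed metabolite pair.

    Returns r together with t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 df.
    """
    x = np.asarray(ln_trig, dtype=float)
    y = np.asarray(ln_bohb, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a metabolite column")
    r, p = stats.pearsonr(x, y)
    r = float(r)
    if abs(r) == 1.0:
        t = float("inf") if r > 0 else float("-inf")
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    return MetaboliteCorrelation(r=r, t=float(t), df=n - 2, p=float(p))


@dataclass
class RefuelingIndex:
    """First-principal-component refueling scores and their provenance."""

    scores: np.ndarray
    loadings: np.ndarray          # unit-norm (trig, bohb); trig loading > 0
    variance_explained: float     # leading eigenvalue / total variance
    eigenvalues: np.ndarray       # descending
    means: np.ndarray             # centering record (ln_trig, ln_bohb)


def refueling_index(ln_trig, ln_bohb) -> RefuelingIndex:
    """Covariance-matrix PCA of the transformed metabolite pair.

    Eigen-decomposition of the 2x2 sample covariance of the centered pair;
    scores are projections on the leading eigenvector, sign-fixed so the
    triglyceride loading is positive. Scores therefore have mean zero and
    variance equal to the leading eigenvalue.
    """
    x = np.column_stack(
        [np.asarray(ln_trig, dtype=float), np.asarray(ln_bohb, dtype=float)]
    )
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x[:, 0]) == 0 or np.ptp(x[:, 1]) == 0:
        raise ValueError("constant metabolite column; PCA is rank-deficient")
    means = x.mean(axis=0)
    centered = x - means
    cov = np.cov(centered, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    lead = eigvecs[:, 0]
    if lead[0] < 0:
        lead = -lead
    scores = centered @ lead
    total = float(eigvals.sum())
    return RefuelingIndex(
        scores=scores,
        loadings=lead,
        variance_explained=float(eigvals[0] / total),
        eigenvalues=eigvals,
        means=means,
    )
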