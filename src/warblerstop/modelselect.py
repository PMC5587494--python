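"""Small-sample AICc model selection and multimodel inference.

General linear models are fit by ordinary least squares with the Gaussian
*maximum-likelihood* log-likelihood (not REML), so likelihoods are
comparable across fixed-effect structures; the parameter count k includes
the residual variance. Candidate sets are enumerated as all subsets of the
main effects, augmented with every subset of the allowed two-way
interactions whose parent mains are present (interaction hierarchy).
Estimates are averaged across models with Akaike weights, with
Burnham-Anderson unconditional standard errors, and each variable's
relative importance w+(j) is the summed weight of the models containing it.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "REFERENCE_LEVELS",
    "ModelSpec",
    "ModelFit",
    "SelectionTable",
    "aicc",
    "akaike_weights",
    "enumerate_candidate_models",
    "build_design",
    "fit_linear_model",
    "fit_candidates",
    "model_average",
]

#: Reference (baseline) levels for dummy coding, stated in all outputs.
REFERENCE_LEVELS = {
    "sex": "F",
    "age": "SY",
    "destination": "southeast",
    "timing": "early",
}


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1); requires n > k+1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> tuple[np.ndarray, np.ndarray]:
    """Delta-AICc and Akaike weights w_i = exp(-delta/2) / sum."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one model")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return delta, w / w.sum()


@dataclass(frozen=True)
class ModelSpec:
    """A model formula: main effects, two-way interactions, fixed extras."""

    mains: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()
    extras: tuple[str, ...] = ()

    @property
    def terms(self) -> tuple[str, ...]:
        return self.extras + self.mains + tuple(
            f"{a}:{b}" for a, b in self.interactions
        )

    @property
    def name(self) -> str:
        return " + ".join(self.terms) if self.terms else "null"

    def contains(self, term: str) -> bool:
        return term in self.terms


def enumerate_candidate_models(
    main_terms,
    allowed_interactions=(),
    always_include=(),
) -> list[ModelSpec]:
    """All-subsets candidate list with interaction hierarchy.

    Every subset of ``main_terms`` (including the empty/null model) is
    combined with every subset of ``allowed_interactions`` whose two parent
    mains are both present. ``always_include`` terms are appended to every
    model except the null. Duplicates are removed.
    """
    mains = tuple(dict.fromkeys(main_terms))
    if len(mains) != len(tuple(main_terms)):
        raise ValueError("duplicate main terms")
    for a, b in allowed_interactions:
        if a not in mains or b not in mains:
            raise ValueError(f"interaction ({a},{b}) references unknown main")
    always = tuple(always_include)
    specs: list[ModelSpec] = []
    seen = set()
    for r in range(len(mains) + 1):
        for subset in itertools.combinations(mains, r):
            allowed = [
                (a, b) for a, b in allowed_interactions
                if a in subset and b in subset
            ]
            for ir in range(len(allowed) + 1):
                for inter in itertools.combinations(allowed, ir):
                    extras = always if (subset or inter) else ()
                    spec = ModelSpec(subset, inter, extras)
                    if spec.terms not in seen:
                        seen.add(spec.terms)
                        specs.append(spec)
    return specs


def _encode_term(data: pd.DataFrame, term: str) -> pd.DataFrame:
    """Columns for a single main term (dummy-coded if categorical)."""
    col = data[term]
    if pd.api.types.is_numeric_dtype(col):
        return pd.DataFrame({term: col.astype(float)})
    levels = list(pd.unique(col.astype(str)))
    ref = REFERENCE_LEVELS.get(term)
    if ref in levels:
        levels.remove(ref)
        levels = [ref] + sorted(levels)
    else:
        levels = sorted(levels)
    out = {}
    for lev in levels[1:]:
        out[f"{term}[{lev}]"] = (col.astype(str) == lev).astype(float)
    return pd.DataFrame(out, index=data.index)


def build_design(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Design matrix (with intercept) for a model spec."""
    parts = [pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)]
    encoded: dict[str, pd.DataFrame] = {}
    for term in spec.extras + spec.mains:
        encoded[term] = _encode_term(data, term)
        parts.append(encoded[term])
    for a, b in spec.interactions:
        ea = encoded.get(a, _encode_term(data, a))
        eb = encoded.get(b, _encode_term(data, b))
        inter = {}
        for ca in ea.columns:
            for cb in eb.columns:
                inter[f"{ca}:{cb}"] = ea[ca] * eb[cb]
        parts.append(pd.DataFrame(inter, index=data.index))
    return pd.concat(parts, axis=1)


@dataclass
class ModelFit:
    """One fitted general linear model with its AICc bookkeeping."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    loglik: float
    k: int              # regression coefficients + residual variance
    n: int
    aicc: float
    sigma2_ml: float

    @property
    def name(self) -> str:
        return self.spec.name

    def predict(self, design_row: pd.Series | np.ndarray) -> tuple[float, float]:
        """Point prediction and its SE for one design row."""
        x = np.asarray(design_row, dtype=float)
        mu = float(x @ self.params.to_numpy())
        se = float(np.sqrt(x @ self.cov_params.to_numpy() @ x))
        return mu, se


def fit_linear_model(
    data: pd.DataFrame, response: str, spec: ModelSpec
) -> ModelFit:
    """OLS fit of one candidate model.

    Raises on rank deficiency and when n <= k+1 (AICc undefined). A zero
    residual variance (exact fit) is reported as infinite log-likelihood.
    """
    X = build_design(data, spec)
    y = data[response].to_numpy(dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X.to_numpy()) < p:
        raise ValueError(f"rank-deficient design for model {spec.name!r}")
    k = p + 1  # + residual variance
    if n <= k + 1:
        raise ValueError(f"n={n} too small for k={k} (model {spec.name!r})")
    res = sm.OLS(y, X).fit()
    sigma2_ml = float(res.ssr / n)
    if sigma2_ml <= max(1e-30, 1e-12 * float(np.var(y))):
        warnings.warn(
            f"model {spec.name!r} fits exactly (zero residual variance); "
            "log-likelihood is unbounded",
            stacklevel=2,
        )
        llf = float("inf")
        return ModelFit(
            spec=spec,
            params=res.params,
            bse=res.bse,
            cov_params=res.cov_params(),
            loglik=llf,
            k=k,
            n=n,
            aicc=float("-inf"),
            sigma2_ml=0.0,
        )
    llf = float(res.llf)  # Gaussian ML log-likelihood
    return ModelFit(
        spec=spec,
        params=res.params,
        bse=res.bse,
        cov_params=res.cov_params(),
        loglik=llf,
        k=k,
        n=n,
        aicc=aicc(llf, k, n),
        sigma2_ml=sigma2_ml,
    )


@dataclass
class SelectionTable:
    """Ranked candidate set with weights over the *full* set."""

    fits: list[ModelFit]
    delta: np.ndarray = field(init=False)
    weights: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        order = np.argsort([f.aicc for f in self.fits], kind="stable")
        self.fits = [self.fits[i] for i in order]
        self.delta, self.weights = akaike_weights([f.aicc for f in self.fits])

    @property
    def best(self) -> ModelFit:
        return self.fits[0]

    def top_set(self, delta_max: float = 4.0) -> list[int]:
        return [i for i, d in enumerate(self.delta) if d <= delta_max]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [f.name for f in self.fits],
                "k": [f.k for f in self.fits],
                "loglik": [f.loglik for f in self.fits],
                "AICc": [f.aicc for f in self.fits],
                "dAICc": self.delta,
                "weight": self.weights,
            }
        )


def _coef_term(coef_name: str) -> str:
    """Parent term of a design coefficient, e.g.
    ``destination[boreal]:timing[late]`` -> ``destination:timing``."""
    return ":".join(part.split("[", 1)[0] for part in coef_name.split(":"))


@dataclass
class AveragedEstimate:
    coefficient: str
    estimate: float
    unconditional_se: float
    w_plus: float           # relative importance of the parent term
    n_models: int


def model_average(
    table: SelectionTable,
    term: str,
    subset: list[int] | None = None,
) -> dict[str, AveragedEstimate]:
    """Average a term's coefficients across the models that contain it.

    Weights are renormalized over the containing models (within ``subset``
    if given, e.g. a delta-AICc <= 4 top set). The unconditional SE is
    sum w_i * sqrt(SE_i^2 + (b_i - b_bar)^2). The relative importance
    w+(j) is the *unrenormalized* summed Akaike weight of all candidate
    models containing the term. Returns one entry per design coefficient
    the term generates (several for a categorical term).
    """
    idx = subset if subset is not None else range(len(table.fits))
    containing = [i for i in idx if table.fits[i].spec.contains(term)]
    if not containing:
        raise ValueError(f"term {term!r} absent from all models in the set")
    w_plus = float(
        sum(table.weights[i] for i in range(len(table.fits))
            if table.fits[i].spec.contains(term))
    )
    w = np.array([table.weights[i] for i in containing], dtype=float)
    w = w / w.sum()
    # coefficient names the term generates, taken from the first containing fit
    first = table.fits[containing[0]]
    coef_names = [c for c in first.params.index if _coef_term(c) == term]
    out = {}
    for cname in coef_names:
        betas, ses, ws = [], [], []
        for wi, i in zip(w, containing):
            fit = table.fits[i]
            if cname in fit.params.index:
                betas.append(float(fit.params[cname]))
                ses.append(float(fit.bse[cname]))
                ws.append(wi)
        ws_arr = np.asarray(ws) / np.sum(ws)
        b = np.asarray(betas)
        s = np.asarray(ses)
        bbar = float(np.sum(ws_arr * b))
        use = float(np.sum(ws_arr * np.sqrt(s**2 + (b - bbar) ** 2)))
        out[cname] = AveragedEstimate(cname, bbar, use, w_plus, len(betas))
    return out
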