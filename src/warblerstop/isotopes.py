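"""Stable-hydrogen-isotope geographic assignment.

Feather d2H values are converted to precipitation equivalents through the
non-ground-foraging passerine calibration

    d2H_feather = 0.95 * d2H_precip - 17.57

and each bird's measurement/calibration error is propagated by Monte-Carlo
simulation (normal draws on the feather scale), yielding the probability
that the bird originates from each configured breeding-destination window.
An isoscape grid can be reclassified into nested 50/75/90% probability-of-
origin categories from the pooled origin density of a sample of birds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "CAL_SLOPE",
    "CAL_INTERCEPT",
    "FeatherSample",
    "AssignmentResult",
    "IsoscapeGrid",
    "feather_to_precip",
    "precip_to_feather",
    "region_probability",
    "region_probability_analytic",
    "classify_destination",
    "assign_birds",
    "origin_density",
    "hdr_thresholds",
    "reclassify_isoscape",
]

CAL_SLOPE = 0.95
CAL_INTERCEPT = -17.57

#: Plausibility bounds for feather values (permil); values outside warn.
FEATHER_PLAUSIBLE = (-250.0, 50.0)


@dataclass
class FeatherSample:
    """One bird's feather d2H measurement (permil vs VSMOW)."""

    bird_id: str
    d2h_f: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.d2h_f):
            raise ValueError(f"non-finite feather value for {self.bird_id}")
        lo, hi = FEATHER_PLAUSIBLE
        if not lo <= self.d2h_f <= hi:
            warnings.warn(
                f"feather d2H {self.d2h_f} for {self.bird_id} outside "
                f"plausible range {FEATHER_PLAUSIBLE}",
                stacklevel=2,
            )


@dataclass
class AssignmentResult:
    """Destination assignment for one bird."""

    bird_id: str
    d2h_p_equiv: float
    region_probs: dict[str, float]
    label: str
    n_draws: int


def precip_to_feather(
    d2h_p: float | np.ndarray,
    slope: float = CAL_SLOPE,
    intercept: float = CAL_INTERCEPT,
) -> float | np.ndarray:
    """Convert precipitation-scale d2H to the feather scale."""
    d2h_p = np.asarray(d2h_p, dtype=float)
    if not np.all(np.isfinite(d2h_p)):
        raise ValueError("non-finite d2H input")
    out = slope * d2h_p + intercept
    return float(out) if out.ndim == 0 else out


def feather_to_precip(
    d2h_f: float | np.ndarray,
    slope: float = CAL_SLOPE,
    intercept: float = CAL_INTERCEPT,
) -> float | np.ndarray:
    """Invert the calibration: feather-scale d2H -> precipitation scale."""
    d2h_f = np.asarray(d2h_f, dtype=float)
    if not np.all(np.isfinite(d2h_f)):
        raise ValueError("non-finite d2H input")
    out = (d2h_f - intercept) / slope
    return float(out) if out.ndim == 0 else out


def _check_windows(regions: dict[str, tuple[float, float]]) -> None:
    items = sorted(regions.items(), key=lambda kv: kv[1][0])
    for (la, wa), (lb, wb) in zip(items, items[1:]):
        if wa[1] > wb[0]:
            raise ValueError(f"destination windows overlap: {la} {wa} vs {lb} {wb}")


def region_probability(
    d2h_f: float,
    regions: dict[str, tuple[float, float]],
    error_sd: float = 5.5,
    n_draws: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> dict[str, float]:
    """Monte-Carlo probability of origin per destination window.

    Draws ``n_draws`` values N(d2h_f, error_sd^2) on the feather scale,
    converts each to the precipitation scale, and returns the fraction of
    draws falling inside each (precipitation-scale) window. Window edges are
    inclusive; the mass in the inter-window gap is not assigned, so the
    probabilities may sum to less than one.
    """
    if error_sd <= 0:
        raise ValueError("error_sd must be positive")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    _check_windows(regions)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    draws_p = feather_to_precip(rng.normal(d2h_f, error_sd, size=n_draws))
    return {
        label: float(np.mean((draws_p >= lo) & (draws_p <= hi)))
        for label, (lo, hi) in regions.items()
    }


def region_probability_analytic(
    d2h_f: float,
    regions: dict[str, tuple[float, float]],
    error_sd: float = 5.5,
) -> dict[str, float]:
    """Closed-form normal-CDF counterpart of :func:`region_probability`."""
    if error_sd <= 0:
        raise ValueError("error_sd must be positive")
    _check_windows(regions)
    out = {}
    for label, (lo, hi) in regions.items():
        f_lo, f_hi = sorted((precip_to_feather(lo), precip_to_feather(hi)))
        out[label] = float(
            norm.cdf(f_hi, d2h_f, error_sd) - norm.cdf(f_lo, d2h_f, error_sd)
        )
    return out


def classify_destination(
    d2h_p_equiv: float,
    regions: dict[str, tuple[float, float]],
    rule: str = "window",
    region_probs: dict[str, float] | None = None,
    min_prob: float = 0.5,
) -> str:
    """Assign a destination label.

    ``rule="window"`` (default): window membership of the point estimate;
    anything outside every window (including the inter-window gap) is
    ``"unassigned"``. ``rule="max_prob"``: the destination with the highest
    Monte-Carlo origin probability, provided it exceeds ``min_prob``.
    """
    if rule == "window":
        for label, (lo, hi) in regions.items():
            if lo <= d2h_p_equiv <= hi:
                return label
        return "unassigned"
    if rule == "max_prob":
        if not region_probs:
            raise ValueError("max_prob rule needs region_probs")
        label, prob = max(region_probs.items(), key=lambda kv: kv[1])
        return label if prob >= min_prob else "unassigned"
    raise ValueError(f"unknown rule {rule!r}")


def assign_birds(
    samples: list[FeatherSample],
    regions: dict[str, tuple[float, float]],
    error_sd: float = 5.5,
    n_draws: int = 1000,
    seed: int | None = 0,
    rule: str = "window",
    min_prob: float = 0.5,
) -> list[AssignmentResult]:
    """Run the full assignment for a batch of feather samples."""
    rng = np.random.default_rng(seed)
    results = []
    for s in samples:
        probs = region_probability(s.d2h_f, regions, error_sd, n_draws, rng)
        equiv = feather_to_precip(s.d2h_f)
        label = classify_destination(
            equiv, regions, rule=rule, region_probs=probs, min_prob=min_prob
        )
        results.append(AssignmentResult(s.bird_id, equiv, probs, label, n_draws))
    return results


# --------------------------------------------------------------- isoscape


@dataclass
class IsoscapeGrid:
    """Regular lon/lat lattice of precipitation-scale d2H values."""

    lons: np.ndarray  # cell-center longitudes, ascending
    lats: np.ndarray  # cell-center latitudes, ascending
    values: np.ndarray  # shape (nlat, nlon); NaN = no data
    cellsize: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.lons = np.asarray(self.lons, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.lats.size, self.lons.size):
            raise ValueError("values shape must be (nlat, nlon)")
        for ax in (self.lons, self.lats):
            if ax.size > 1 and not np.all(np.diff(ax) > 0):
                raise ValueError("grid coordinates must be strictly increasing")
        if not self.cellsize and self.lons.size > 1:
            self.cellsize = float(self.lons[1] - self.lons[0])


def origin_density(
    samples: np.ndarray | list[float],
    error_sd: float = 5.5,
):
    """Pooled probability density of precipitation-scale origin values.

    Each feather value contributes one normal component: mean
    ``feather_to_precip(d2h_f)`` and SD ``error_sd / CAL_SLOPE`` (the
    feather-scale error mapped through the inverse calibration). Returns a
    vectorized density function on the precipitation scale.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty sample set")
    mus = np.asarray(feather_to_precip(samples), dtype=float).ravel()
    sd = error_sd / CAL_SLOPE

    def density(v):
        v = np.atleast_1d(np.asarray(v, dtype=float))
        out = norm.pdf(v[:, None], mus[None, :], sd).mean(axis=1)
        return out

    density.components = mus  # type: ignore[attr-defined]
    density.sd = sd  # type: ignore[attr-defined]
    return density


def hdr_thresholds(
    density,
    levels: tuple[float, ...] = (0.5, 0.75, 0.9),
    n_grid: int = 4096,
) -> dict[float, float]:
    """Highest-density-region density thresholds for the given mass levels.

    For each level L the returned threshold c satisfies (by fine-grid
    quadrature) integral of the density over {v : f(v) >= c} == L.
    """
    mus, sd = density.components, density.sd
    lo, hi = mus.min() - 8 * sd, mus.max() + 8 * sd
    grid = np.linspace(lo, hi, n_grid)
    f = density(grid)
    dx = grid[1] - grid[0]
    order = np.argsort(f)[::-1]
    cummass = np.cumsum(f[order]) * dx
    out = {}
    for level in levels:
        idx = int(np.searchsorted(cummass, level))
        idx = min(idx, n_grid - 1)
        out[level] = float(f[order][idx])
    return out


def reclassify_isoscape(
    grid: IsoscapeGrid,
    samples_by_destination: dict[str, np.ndarray | list[float]],
    error_sd: float = 5.5,
    levels: tuple[float, ...] = (0.5, 0.75, 0.9),
) -> dict[str, np.ndarray]:
    """Reclassify an isoscape into nested probability-of-origin categories.

    For each destination, the pooled origin density of its feather samples
    is thresholded at the highest-density levels; every grid cell is labeled
    with the smallest level whose density threshold its value exceeds
    (stored as the percentage, e.g. 50), or 0 outside the widest region.
    No-data cells stay 0. Categories are nested by construction.
    """
    if np.all(~np.isfinite(grid.values)):
        raise ValueError("all-no-data grid")
    levels = tuple(sorted(levels))
    out: dict[str, np.ndarray] = {}
    for label, samples in samples_by_destination.items():
        dens = origin_density(samples, error_sd)
        thresholds = hdr_thresholds(dens, levels)
        cat = np.zeros(grid.values.shape, dtype=int)
        finite = np.isfinite(grid.values)
        fvals = np.zeros_like(grid.values)
        fvals[finite] = dens(grid.values[finite])
        # assign from widest to tightest so tighter levels overwrite
        for level in levels[::-1]:
            cat[finite & (fvals >= thresholds[level])] = int(round(level * 100))
        out[label] = cat
    return out
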