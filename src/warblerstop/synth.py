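"""Synthetic study-data generator.

Emulates the statistical structure the downstream analysis assumes: two
breeding-destination groups with disjoint precipitation-isotope windows and
Gaussian feather-scale measurement error; group- and timing-structured
arrival dates; a negatively correlated plasma-metabolite pair with
covariate effects placed along its leading residual axis; and capture
histories from a transient/resident mixture (daily persistence phi,
year-specific detection p). A truth record retains every generating value
so recovery tests can compare estimates against it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as wio
from .birds import fat_free_mass
from .cjs import CaptureHistory
from .config import TIMING_CLASSES, SimulationConfig
from .isotopes import precip_to_feather

__all__ = [
    "StudyData",
    "gen_isotope_samples",
    "gen_birds",
    "gen_capture_histories",
    "simulate_histories",
    "gen_metabolite_samples",
    "gen_study_dataset",
]


@dataclass
class StudyData:
    """Bundle of generated tables plus the generating truth."""

    birds: pd.DataFrame
    plasma: pd.DataFrame
    histories: pd.DataFrame
    truth: dict


def _draw_destinations(config: SimulationConfig, n: int) -> np.ndarray:
    """Deterministic even split of n birds across destinations."""
    labels = [d.label for d in config.destinations]
    return np.array([labels[i % len(labels)] for i in range(n)])


def gen_isotope_samples(config: SimulationConfig, n: int) -> pd.DataFrame:
    """Feather samples with known true origin.

    True precipitation-scale d2H is uniform within the bird's destination
    window, converted to the feather scale by the calibration and blurred
    with N(0, error_sd^2) feather-scale noise.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = config.rng("isotopes")
    dests = _draw_destinations(config, n)
    lo = np.array([config.destination(d).window[0] for d in dests])
    hi = np.array([config.destination(d).window[1] for d in dests])
    true_p = rng.uniform(lo, hi) if n else np.array([])
    noise = rng.normal(0.0, config.error_sd, size=n)
    feather = precip_to_feather(true_p) + noise if n else np.array([])
    return pd.DataFrame(
        {
            "bird_id": [f"b{i:04d}" for i in range(n)],
            "d2h_feather": feather,
            "true_destination": dests,
            "true_d2h_p": true_p,
        }
    )


def gen_birds(config: SimulationConfig) -> pd.DataFrame:
    """Banding table with latent truth columns (``true_*``).

    Arrival day-of-year comes from the destination's per-timing-class
    normal; wing chord and condition are normal draws and body mass is
    reconstructed as fat-free mass plus condition, so the condition index
    round-trips exactly through the published lean-mass equation.
    """
    rng = config.rng("birds")
    n = config.n_birds_per_group * len(config.destinations)
    rows = []
    i = 0
    for dest in config.destinations:
        for j in range(config.n_birds_per_group):
            timing = TIMING_CLASSES[j % len(TIMING_CLASSES)]
            mean, sd = dest.arrival[timing]
            doy = int(round(rng.normal(mean, sd)))
            year = int(rng.choice(config.years))
            sex = "M" if rng.random() < 0.5 else "F"
            age = "ASY" if rng.random() < 0.6 else "SY"
            wing = float(
                np.clip(
                    rng.normal(config.wing_chord_mean_mm, config.wing_chord_sd_mm),
                    58.0,
                    74.0,
                )
            )
            condition = float(
                np.clip(
                    rng.normal(config.condition_mean_g, config.condition_sd_g),
                    -1.4,
                    3.5,
                )
            )
            mass = float(fat_free_mass(wing) + condition)
            true_p = float(rng.uniform(*dest.window))
            feather = float(
                precip_to_feather(true_p) + rng.normal(0.0, config.error_sd)
            )
            rows.append(
                {
                    "bird_id": f"b{i:04d}",
                    "day_of_year": doy,
                    "year": year,
                    "sex": sex,
                    "age": age,
                    "wing_chord_mm": round(wing, 1),
                    "body_mass_g": round(mass, 3),
                    "d2h_feather": round(feather, 2),
                    "true_destination": dest.label,
                    "true_timing": timing,
                    "true_condition": condition,
                    "true_d2h_p": true_p,
                }
            )
            i += 1
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(
            columns=[
                "bird_id", "day_of_year", "year", "sex", "age",
                "wing_chord_mm", "body_mass_g", "d2h_feather",
                "true_destination", "true_timing", "true_condition", "true_d2h_p",
            ]
        )
    return df


def simulate_histories(
    n: int,
    tau: float | np.ndarray,
    phi: float | np.ndarray,
    p: float | np.ndarray,
    n_occasions: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Detection matrices from the transient/resident point mixture.

    Every bird is detected at occasion 1. With probability tau the bird is
    a transient present only on occasion 1; residents persist through each
    daily interval with probability phi. Present birds are detected with
    probability p on occasions >= 2. The apparent first-interval
    persistence is therefore (1 - tau) * phi in expectation.
    """
    if n_occasions < 2:
        raise ValueError("n_occasions must be >= 2")
    tau = np.broadcast_to(np.asarray(tau, dtype=float), (n,))
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (n,))
    p = np.broadcast_to(np.asarray(p, dtype=float), (n,))
    transient = rng.random(n) < tau
    det = np.zeros((n, n_occasions), dtype=int)
    det[:, 0] = 1
    present = ~transient
    for t in range(1, n_occasions):
        present = present & (rng.random(n) < phi)
        det[present & (rng.random(n) < p), t] = 1
    return det


def gen_capture_histories(
    config: SimulationConfig, n: int, birds: pd.DataFrame | None = None
) -> list[CaptureHistory]:
    """Capture histories with group covariates.

    If ``birds`` (from :func:`gen_birds`) is given, one history per bird is
    generated using its destination, year and condition; otherwise ``n``
    standalone birds are synthesized with evenly split destinations.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = config.rng("cjs")
    if birds is None or birds.empty:
        dests = _draw_destinations(config, n)
        years = np.array([config.years[i % len(config.years)] for i in range(n)])
        timing = np.array([TIMING_CLASSES[i % 3] for i in range(n)])
        sex = np.array([("M", "F")[i % 2] for i in range(n)])
        condition = rng.normal(
            config.condition_mean_g, config.condition_sd_g, size=n
        )
        ids = [f"h{i:04d}" for i in range(n)]
    else:
        n = len(birds)
        dests = birds["true_destination"].to_numpy()
        years = birds["year"].to_numpy()
        timing = birds["true_timing"].to_numpy()
        sex = birds["sex"].to_numpy()
        condition = birds["true_condition"].to_numpy(dtype=float)
        ids = birds["bird_id"].tolist()
    if n == 0:
        return []

    tau = np.array([config.destination(d).transient_fraction for d in dests])
    logit_phi = np.array(
        [np.log(config.destination(d).persistence /
                (1 - config.destination(d).persistence)) for d in dests]
    )
    # optional condition effect on resident persistence, centered so the
    # configured phi holds at the mean condition
    logit_phi = logit_phi + config.cjs.condition_beta * (
        condition - config.condition_mean_g
    )
    phi = 1.0 / (1.0 + np.exp(-logit_phi))
    p = np.array([config.cjs.detection[int(y)] for y in years])
    det = simulate_histories(n, tau, phi, p, config.cjs.n_occasions, rng)

    first_year = min(config.years)
    out = []
    for i in range(n):
        out.append(
            CaptureHistory(
                ids[i],
                det[i],
                covariates={
                    "destination": dests[i],
                    "timing": timing[i],
                    "sex": sex[i],
                    "year": int(years[i]),
                    "first_year": float(int(years[i]) == first_year),
                    "condition": float(condition[i]),
                    "true_transient": bool(det[i, 1:].sum() == 0),
                },
            )
        )
    return out


def gen_metabolite_samples(
    config: SimulationConfig, birds: pd.DataFrame
) -> pd.DataFrame:
    """Plasma table for a set of birds.

    The transformed pair (ln(1+trig), ln(1+bohb)) is bivariate normal
    around linear predictors; covariate effects (centered ln-bleedtime,
    condition, destination x timing offsets) act along the residual
    leading eigenvector so their sizes are on the refueling-index scale.
    Back-transformed concentrations are kept positive.
    """
    if birds.empty:
        raise ValueError("birds table is empty")
    spec = config.metabolites
    rng = config.rng("plasma")
    n = len(birds)

    shape = (spec.bleedtime_mean_min / spec.bleedtime_sd_min) ** 2
    scale = spec.bleedtime_mean_min / shape
    bleedtime = np.clip(rng.gamma(shape, scale, size=n), 0.5, 20.0)
    daytime = rng.uniform(90.0, 540.0, size=n)

    ln_bleed = np.log1p(bleedtime)
    ln_bleed_c = ln_bleed - np.log1p(spec.bleedtime_mean_min)
    condition = birds["true_condition"].to_numpy(dtype=float)
    cond_c = condition - config.condition_mean_g
    offsets = np.array(
        [
            spec.group_timing_effects.get((d, t), 0.0)
            for d, t in zip(birds["true_destination"], birds["true_timing"])
        ]
    )
    index_effect = (
        spec.beta_bleedtime * ln_bleed_c + spec.beta_condition * cond_c + offsets
    )

    direction = spec.index_direction()
    mean = np.asarray(spec.ln_intercepts) + index_effect[:, None] * direction
    cov = spec.residual_cov()
    if cov.any():
        resid = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
    else:
        resid = np.zeros((n, 2))
    ln_pair = mean + resid
    conc = np.expm1(ln_pair)
    conc = np.maximum(conc, 1e-3)  # keep back-transformed concentrations positive

    return pd.DataFrame(
        {
            "bird_id": birds["bird_id"].to_numpy(),
            "triglyceride": conc[:, 0],
            "bohb": conc[:, 1],
            "bleedtime": bleedtime,
            "daytime": daytime,
            "day_of_year": birds["day_of_year"].to_numpy(),
            "year": birds["year"].to_numpy(),
        }
    )


def gen_study_dataset(
    config: SimulationConfig, outdir: str | Path | None = None
) -> StudyData:
    """Generate the full study bundle and optionally write it to disk.

    Writes ``birds.csv``, ``plasma.csv``, ``histories.inp``,
    ``histories.csv`` and ``truth.yaml`` under ``outdir``. The plasma table
    covers a seeded random subsample of ``n_plasma`` birds (all birds if
    fewer exist).
    """
    birds = gen_birds(config)
    histories = gen_capture_histories(config, len(birds), birds)
    if len(birds):
        n_plasma = min(config.n_plasma, len(birds))
        pick = np.sort(
            config.rng("plasma-subset").choice(len(birds), n_plasma, replace=False)
        )
        plasma = gen_metabolite_samples(config, birds.iloc[pick])
    else:
        plasma = pd.DataFrame(columns=wio.PLASMA_COLUMNS)

    hist_rows = []
    for h in histories:
        row = {"bird_id": h.bird_id}
        row.update(
            {f"occ{t + 1}": int(v) for t, v in enumerate(h.detections)}
        )
        row.update(
            {k: v for k, v in h.covariates.items() if k != "true_transient"}
        )
        hist_rows.append(row)
    hist_df = pd.DataFrame(hist_rows)

    truth = {
        "config": config.to_dict(),
        "per_destination": {
            d.label: {
                "transient_fraction": d.transient_fraction,
                "persistence": d.persistence,
                "window": list(d.window),
            }
            for d in config.destinations
        },
        "detection": {int(k): v for k, v in config.cjs.detection.items()},
        "index_effects": {
            "beta_bleedtime": config.metabolites.beta_bleedtime,
            "beta_condition": config.metabolites.beta_condition,
            "group_timing": {
                f"{k[0]}|{k[1]}": v
                for k, v in config.metabolites.group_timing_effects.items()
            },
        },
        "birds": {
            "bird_id": birds["bird_id"].tolist() if len(birds) else [],
            "true_destination": birds["true_destination"].tolist() if len(birds) else [],
            "true_timing": birds["true_timing"].tolist() if len(birds) else [],
        },
    }

    data = StudyData(birds=birds, plasma=plasma, histories=hist_df, truth=truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        public = birds[wio.BIRD_COLUMNS] if len(birds) else birds.reindex(
            columns=wio.BIRD_COLUMNS
        )
        wio.write_birds(public, outdir / "birds.csv")
        wio.write_plasma(plasma, outdir / "plasma.csv")
        wio.write_inp(histories, outdir / "histories.inp")
        wio.write_histories_csv(hist_df, outdir / "histories.csv")
        (outdir / "truth.yaml").write_text(yaml.safe_dump(truth, sort_keys=True))
    return data
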