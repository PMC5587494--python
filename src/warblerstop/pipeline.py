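"""End-to-end orchestration: simulate -> assign -> prep -> refuel -> stopover.

Each stage persists its outputs; a run log records inputs, seeds, versions
and warnings; and a Markdown report summarizes predicted refueling index by
destination x timing and stopover duration / transient probability by group.
A stage failure aborts the run with the failing stage named; outputs of
completed stages are retained.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as wio
from .birds import assign_timing_classes, condition_index
from .cjs import stopover_model_selection
from .config import SimulationConfig
from .io import histories_from_frame
from .isotopes import FeatherSample, assign_birds
from .refuel import RefuelingAnalysis, two_tier_refueling_analysis
from .synth import gen_study_dataset

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "validate_inputs"]

DEFAULT_REGIONS = {"southeast": (-50.0, -10.0), "boreal": (-130.0, -70.0)}

DEFAULT_PHI2_CANDIDATES = [
    (),
    ("condition",),
    ("destination",),
    ("sex",),
    ("timing",),
    ("destination", "condition"),
    ("sex", "condition"),
    ("timing", "condition"),
]


@dataclass
class PipelineConfig:
    """Pipeline inputs and stage parameters.

    Either ``simulate`` (a :class:`SimulationConfig`) or the three input
    paths must be provided. The global ``seed`` drives the simulation and
    the Monte-Carlo assignment.
    """

    outdir: Path
    seed: int = 0
    simulate: SimulationConfig | None = None
    birds_path: Path | None = None
    plasma_path: Path | None = None
    histories_path: Path | None = None
    regions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS)
    )
    error_sd: float = 5.5
    n_draws: int = 1000
    assignment_rule: str = "window"
    delta_threshold: float = 4.0
    phi2_candidates: list[tuple[str, ...]] = field(
        default_factory=lambda: list(DEFAULT_PHI2_CANDIDATES)
    )
    phi1_terms: tuple[str, ...] = ("destination",)
    p_terms: tuple[str, ...] = ("first_year",)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        sim = d.get("simulate")
        cfg = cls(
            outdir=Path(d["outdir"]),
            seed=int(d.get("seed", 0)),
            simulate=SimulationConfig.from_dict(sim) if sim else None,
            birds_path=Path(d["birds"]) if d.get("birds") else None,
            plasma_path=Path(d["plasma"]) if d.get("plasma") else None,
            histories_path=Path(d["histories"]) if d.get("histories") else None,
        )
        for key in ("error_sd", "n_draws", "assignment_rule", "delta_threshold"):
            if key in d:
                setattr(cfg, key, d[key])
        if "regions" in d:
            cfg.regions = {k: tuple(v) for k, v in d["regions"].items()}
        return cfg


@dataclass
class PipelineReport:
    outdir: Path
    birds: pd.DataFrame
    refuel: RefuelingAnalysis
    stopover_estimates: pd.DataFrame
    report_path: Path
    log: dict[str, Any]


def validate_inputs(
    birds_path: str | Path,
    plasma_path: str | Path | None = None,
    histories_path: str | Path | None = None,
) -> dict[str, list[str]]:
    """Schema and cross-file checks; returns {'errors': [...], 'warnings': [...]}."""
    errors: list[str] = []
    warns: list[str] = []
    try:
        birds = wio.read_birds(birds_path)
    except Exception as e:  # noqa: BLE001 - report, don't crash
        return {"errors": [f"birds: {e}"], "warnings": []}
    if birds["bird_id"].duplicated().any():
        dupes = birds.loc[birds["bird_id"].duplicated(), "bird_id"].tolist()
        warns.append(f"duplicate band ids in birds table: {dupes[:5]}")
    if (birds["wing_chord_mm"] <= 0).any():
        errors.append("non-positive wing chord in birds table")
    if (birds["body_mass_g"] <= 0).any():
        errors.append("non-positive body mass in birds table")
    out_of_range = ~birds["d2h_feather"].between(-250, 50)
    if out_of_range.any():
        warns.append(f"{int(out_of_range.sum())} feather d2H values outside -250..50")

    if plasma_path is not None:
        try:
            plasma = wio.read_plasma(plasma_path)
        except Exception as e:  # noqa: BLE001
            errors.append(f"plasma: {e}")
            plasma = None
        if plasma is not None:
            for col in ("triglyceride", "bohb"):
                if (plasma[col] <= 0).any():
                    errors.append(f"non-positive {col} concentration")
            if (plasma["bleedtime"] < 0).any():
                errors.append("negative bleedtime")
            orphans = set(plasma["bird_id"]) - set(birds["bird_id"])
            if orphans:
                warns.append(
                    f"{len(orphans)} plasma ids absent from birds table "
                    f"(e.g. {sorted(orphans)[:3]})"
                )
    if histories_path is not None:
        try:
            hist = wio.read_histories_csv(histories_path)
            orphans = set(hist["bird_id"]) - set(birds["bird_id"])
            if orphans:
                warns.append(f"{len(orphans)} history ids absent from birds table")
        except Exception as e:  # noqa: BLE001
            errors.append(f"histories: {e}")
    return {"errors": errors, "warnings": warns}


def _fmt(x: float, nd: int = 3) -> str:
    return f"{x:.{nd}f}"


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute all stages and write outputs under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict[str, Any] = {
        "seed": config.seed,
        "version": __version__,
        "stages": [],
        "warnings": [],
    }
    stage = "simulate"
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            # ---------------------------------------------------- simulate
            if config.simulate is not None:
                sim = config.simulate
                sim.seed = config.seed
                data = gen_study_dataset(sim, outdir / "inputs")
                birds = data.birds[wio.BIRD_COLUMNS].copy()
                plasma = data.plasma
                det, hcov = histories_from_frame(data.histories)
                log["stages"].append({"simulate": {"n_birds": len(birds)}})
            else:
                birds = wio.read_birds(config.birds_path)
                plasma = wio.read_plasma(config.plasma_path)
                hist = wio.read_histories_csv(config.histories_path)
                det, hcov = histories_from_frame(hist)
                log["stages"].append({"load": {"n_birds": len(birds)}})

            # ------------------------------------------------------ assign
            stage = "assign"
            samples = [
                FeatherSample(str(r.bird_id), float(r.d2h_feather))
                for r in birds.itertuples(index=False)
            ]
            results = assign_birds(
                samples,
                config.regions,
                error_sd=config.error_sd,
                n_draws=config.n_draws,
                seed=config.seed,
                rule=config.assignment_rule,
            )
            birds = birds.assign(
                d2h_p_equiv=[r.d2h_p_equiv for r in results],
                destination=[r.label for r in results],
                **{
                    f"p_{label}": [r.region_probs[label] for r in results]
                    for label in config.regions
                },
            )
            birds.to_csv(outdir / "birds_assigned.csv", index=False,
                         float_format="%.6g")
            n_unassigned = int((birds["destination"] == "unassigned").sum())
            log["stages"].append({"assign": {"unassigned": n_unassigned}})

            # -------------------------------------------------------- prep
            stage = "prep"
            birds["condition"] = condition_index(
                birds["body_mass_g"], birds["wing_chord_mm"]
            )
            assigned = birds[birds["destination"] != "unassigned"].copy()
            assigned = assign_timing_classes(assigned)
            birds = birds.merge(
                assigned[["bird_id", "timing"]], on="bird_id", how="left"
            )
            birds.to_csv(outdir / "birds_prepped.csv", index=False,
                         float_format="%.6g")
            log["stages"].append({"prep": {"n_grouped": len(assigned)}})

            # ------------------------------------------------------ refuel
            stage = "refuel"
            refuel = two_tier_refueling_analysis(
                plasma, birds, delta_threshold=config.delta_threshold
            )
            refuel.tier1.to_frame().to_csv(
                outdir / "refuel_tier1.csv", index=False, float_format="%.6g"
            )
            refuel.tier2.to_frame().to_csv(
                outdir / "refuel_tier2.csv", index=False, float_format="%.6g"
            )
            effects = {
                term: {
                    c: {
                        "estimate": round(est.estimate, 6),
                        "unconditional_se": round(est.unconditional_se, 6),
                        "w_plus": round(est.w_plus, 6),
                    }
                    for c, est in coefs.items()
                }
                for term, coefs in refuel.averaged.items()
            }
            (outdir / "refuel_effects.json").write_text(
                json.dumps(effects, indent=2, sort_keys=True)
            )
            refuel.group_means.to_csv(
                outdir / "refuel_group_means.csv", index=False, float_format="%.6g"
            )
            log["stages"].append(
                {
                    "refuel": {
                        "n_plasma": int(len(plasma)),
                        "n_modeled": int(len(refuel.data)),
                        "carried": list(refuel.carried_terms),
                        "n_candidates": list(refuel.n_candidates),
                    }
                }
            )

            # ---------------------------------------------------- stopover
            stage = "stopover"
            hjoin = hcov.merge(
                birds[["bird_id", "destination", "timing", "condition"]],
                on="bird_id",
                how="left",
                suffixes=("_gen", ""),
            )
            keep = hjoin["destination"].isin(config.regions).to_numpy()
            keep &= hjoin["timing"].notna().to_numpy()
            stop = stopover_model_selection(
                (det[keep], hjoin.loc[keep].reset_index(drop=True)),
                config.phi2_candidates,
                phi1_terms=config.phi1_terms,
                p_terms=config.p_terms,
                delta_threshold=config.delta_threshold,
                seed=config.seed,
            )
            stop.table.to_csv(
                outdir / "stopover_models.csv", index=False, float_format="%.6g"
            )
            stop.estimates.to_csv(
                outdir / "stopover_estimates.csv", index=False, float_format="%.6g"
            )
            log["stages"].append(
                {"stopover": {"n_histories": int(keep.sum())}}
            )

            log["warnings"] = sorted({str(w.message) for w in caught})
    except Exception as e:
        log["failed_stage"] = stage
        log["error"] = str(e)
        (outdir / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=True))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {e}") from e

    report_path = outdir / "report.md"
    report_path.write_text(_render_report(refuel, stop, log))
    (outdir / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=True))
    return PipelineReport(
        outdir=outdir,
        birds=birds,
        refuel=refuel,
        stopover_estimates=stop.estimates,
        report_path=report_path,
        log=log,
    )


def _render_report(refuel: RefuelingAnalysis, stop, log: dict) -> str:
    lines = [
        "# Stopover-strategy analysis report",
        "",
        f"Seed: {log['seed']}  |  package version: {log['version']}",
        "",
        "## Refueling index",
        "",
        f"- metabolite correlation r = {_fmt(refuel.correlation.r)} "
        f"(t = {_fmt(refuel.correlation.t, 2)}, df = {refuel.correlation.df})",
        f"- PC1 variance explained = {_fmt(100 * refuel.index.variance_explained, 1)}%",
        f"- loadings: triglyceride {_fmt(refuel.index.loadings[0], 2)}, "
        f"BOHB {_fmt(refuel.index.loadings[1], 2)}",
        f"- tier-1 terms carried forward: "
        f"{', '.join(refuel.carried_terms) or '(none)'}",
        f"- candidate models: tier 1 n = {refuel.n_candidates[0]}, "
        f"tier 2 n = {refuel.n_candidates[1]}",
        "",
        "### Predicted refueling index by destination x timing",
        "",
        "| destination | timing | n | predicted index | SE |",
        "|---|---|---|---|---|",
    ]
    for r in refuel.group_means.itertuples(index=False):
        lines.append(
            f"| {r.destination} | {r.timing} | {r.n} | "
            f"{_fmt(r.predicted_index)} | {_fmt(r.se)} |"
        )
    lines += [
        "",
        "## Stopover duration and transients",
        "",
        "| group | n | phi2 | duration (d) | SE | transient (%) | SE |",
        "|---|---|---|---|---|---|---|",
    ]
    for r in stop.estimates.itertuples(index=False):
        lines.append(
            f"| {r.group} | {r.n} | {_fmt(r.phi2)} | {_fmt(r.duration_days, 2)} | "
            f"{_fmt(r.duration_se, 2)} | {_fmt(r.transient_pct, 1)} | "
            f"{_fmt(r.transient_pct_se, 1)} |"
        )
    if stop.condition_days_per_unit is not None:
        lines += [
            "",
            f"Condition effect on stopover duration: "
            f"{_fmt(stop.condition_days_per_unit, 2)} days per unit condition.",
        ]
    lines.append("")
    return "\n".join(lines)
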