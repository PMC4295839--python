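"""End-to-end analysis configurations.

The study design compares four ways of explaining a target promoter's
activity from its regulators' reporter data, of increasing mechanistic
fidelity:

1. ``activities`` — promoter activities as protein proxies, no global
   effects (Hill/titration model only);
2. ``activities+global`` — same proxies, constitutive-promoter multiplier;
3. ``proteins+global`` — protein concentrations reconstructed at fixed
   (measured) half-lives, with the global multiplier;
4. ``proteins+global+halflives`` — as 3, but the FliA/FlgM half-lives are
   estimated from the data over a discretized grid.

On data generated by the full mechanism, the fit quality improves along
this ladder. ``run_configuration`` executes any subset and reports the
fits, sign-pattern verdicts and a Q comparison table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import signpatterns, synthetic_data
from .fitting import ConditionData, FitDataset, FitResult, _dataset_at, fit_regulation, fit_with_halflives
from .preprocess import ActivityProfile, GAMMA_R_DEFAULT
from .reconstruct import (
    HalfLifeGrid,
    PrecultureSpec,
    precompute_profiles,
)

__all__ = [
    "PipelineConfig",
    "run_configuration",
    "scan_inputs",
    "sign_map_report",
]

CONFIGURATIONS = (
    "activities",
    "activities+global",
    "proteins+global",
    "proteins+global+halflives",
)


@dataclass
class PipelineConfig:
    """Settings of a full analysis run on a synthetic scenario."""

    gamma_r: float = GAMMA_R_DEFAULT
    half_lives: tuple[float, float] = (30.0, 18.0)  # (FliA, FlgM), minutes
    half_life_grid: tuple = (7.0, 18.0, 30.0, 60.0, 120.0, 240.0)
    n_starts: int = 8
    seed: int = 0
    grid_step: float = 8.0
    noise_rel: float = 0.05
    configurations: tuple = CONFIGURATIONS
    maxiter: int | None = None


def _activity_profiles_from_truth(truth) -> tuple[dict, dict]:
    """ActivityProfile map (condition, regulator) and preculture specs."""
    activities: dict = {}
    precultures: dict = {}
    scenario = truth["__scenario__"]
    for cond in scenario.conditions:
        ct = truth[cond.name]
        for gene in ("fliA", "flgM"):
            prof = ActivityProfile(
                condition_id=cond.name,
                time=ct.time,
                f_mean=ct.activities[gene],
                epsilon=np.zeros_like(ct.time),
                n_replicates=scenario.n_replicates,
                reporter=gene,
            )
            prof.meta["mu"] = ct.mu
            activities[(cond.name, gene)] = prof
            precultures[(cond.name, gene)] = PrecultureSpec(
                r_T=ct.r0[gene], mu_T=0.0
            )
    return activities, precultures


def scan_inputs(scenario: synthetic_data.SyntheticScenario | None = None) -> dict:
    """Measured-style promoter activity inputs for the misfit scans.

    Per condition: the fliA/flgM/pRM activity curves, the growth rate, and
    the preculture steady-state initial protein concentrations (computed
    from the reporter concentration at the start with the stationary-phase
    degradation constants).
    """
    if scenario is None:
        scenario = synthetic_data.default_scenario()
    from .reconstruct import LN2, PRECULTURE_HALF_LIVES

    _, truth = synthetic_data.make_fit_dataset(scenario, noise_rel=0.0)
    out = {}
    for c in scenario.conditions:
        ct = truth[c.name]
        out[c.name] = {
            "time": ct.time,
            "fliA": ct.activities["fliA"],
            "flgM": ct.activities["flgM"],
            "f_const": ct.activities["pRM"],
            "mu": ct.mu,
            "p0_A": ct.r0["fliA"] * scenario.gamma_r
            / (LN2 / PRECULTURE_HALF_LIVES["FliA"]),
            "p0_M": ct.r0["flgM"] * scenario.gamma_r
            / (LN2 / PRECULTURE_HALF_LIVES["FlgM"]),
        }
    return out


def sign_map_report(
    scenario: synthetic_data.SyntheticScenario | None = None,
    grid_values: tuple = (7.0, 17.0, 41.0, 99.0, 240.0),
    noise_rel: float = 0.05,
    seed: int | None = None,
    gamma_r: float = GAMMA_R_DEFAULT,
) -> dict:
    """Half-life sign-pattern map plus the pooled verdict at the truth.

    Builds the analysis-level dataset at the scenario's noise level,
    restricts every condition to its expression window (first detection to
    growth arrest), reconstructs FliA/FlgM over ``grid_values`` and
    classifies the expected tar pattern (FliA:+1, FlgM:-1, global:+1) per
    condition and pooled ("Intersection") at every grid cell. Returns a
    dict with the map, the pooled noise-free verdict at the generating
    half-lives, and the green fraction of the pooled map.
    """
    from .reconstruct import (
        LN2,
        PRECULTURE_HALF_LIVES,
        analysis_window,
        HalfLifeGrid as HLGrid,
    )

    if scenario is None:
        scenario = synthetic_data.default_scenario()
    ds, truth = synthetic_data.make_fit_dataset(
        scenario, regressors="proteins", noise_rel=noise_rel, seed=seed
    )
    activities, precultures = _activity_profiles_from_truth(truth)
    for (cond, gene), spec in list(precultures.items()):
        precultures[(cond, gene)] = PrecultureSpec(
            r_T=spec.r_T,
            mu_T=0.0,
            gamma_p_preculture=LN2 / PRECULTURE_HALF_LIVES[gene],
        )
    grid = HLGrid(np.asarray(grid_values, dtype=float))
    profiles = precompute_profiles(activities, grid, precultures, gamma_r=gamma_r)
    targets = {}
    windows = {}
    for name, cd in ds.conditions.items():
        mu = np.interp(cd.time, truth[name].time, truth[name].mu)
        w = analysis_window(mu)
        windows[name] = w
        targets[name] = {
            "time": cd.time[w],
            "f": cd.f_target[w],
            "eps_f": cd.epsilon[w],
            "f_const": cd.f_const[w],
        }
    cmap = signpatterns.halflife_pattern_map(targets, profiles, grid)
    pooled_cells = {
        (k[1], k[2]): v for k, v in cmap.items() if k[0] == "Intersection"
    }
    green_fraction = sum(v == "green" for v in pooled_cells.values()) / len(
        pooled_cells
    )
    # pooled verdict on noise-free data with the generating regressors
    ds0, truth0 = synthetic_data.make_fit_dataset(
        scenario, regressors="proteins", noise_rel=0.0
    )
    conds = {}
    for name, cd in ds0.conditions.items():
        w = windows[name]
        conds[name] = {
            "f": cd.f_target[w],
            "eps_f": cd.epsilon[w],
            "X": {
                "fliA": cd.x1[w],
                "flgM": cd.x2[w],
                "global": cd.f_const[w],
            },
        }
    sdata = signpatterns.SignData(("fliA", "flgM", "global"), conds)
    return {
        "map": cmap,
        "pooled_cells": pooled_cells,
        "green_fraction": green_fraction,
        "pooled_noise_free": signpatterns.classify_expected(sdata, (1, -1, 1)),
        "grid_values": list(grid_values),
    }


def run_configuration(
    cfg: PipelineConfig,
    scenario: synthetic_data.SyntheticScenario | None = None,
) -> dict:
    """Run the selected analysis configurations on a (synthetic) scenario.

    Returns a report dict with per-configuration :class:`FitResult`, the
    sign-pattern classification of the expected tar pattern, a comparison
    table of Q values, and a provenance block (config and seeds).
    Deterministic given config and scenario seed.
    """
    if scenario is None:
        scenario = synthetic_data.default_scenario(seed=cfg.seed)
    # target and regressor trajectories
    ds_act, truth = synthetic_data.make_fit_dataset(
        scenario,
        regressors="activities",
        noise_rel=cfg.noise_rel,
        grid_step=cfg.grid_step,
        seed=scenario.seed,
    )
    # protein profiles precomputed over the half-life grid (plus the fixed pair)
    grid_vals = np.unique(
        np.concatenate([np.asarray(cfg.half_life_grid, float), cfg.half_lives])
    )
    grid = HalfLifeGrid(grid_vals)
    activities, precultures = _activity_profiles_from_truth(truth)
    profiles = precompute_profiles(activities, grid, precultures, gamma_r=cfg.gamma_r)
    targets = ds_act.conditions  # x1/x2 replaced per configuration below

    report: dict = {"fits": {}, "Q": {}, "provenance": {
        "seed": cfg.seed,
        "scenario_seed": scenario.seed,
        "n_starts": cfg.n_starts,
        "half_life_grid": [float(v) for v in grid_vals],
        "configurations": list(cfg.configurations),
    }}
    fixed_assignment = {n: cfg.half_lives for n in targets}
    for name in cfg.configurations:
        if name == "activities":
            res = fit_regulation(
                ds_act, "eq1_eq2", cfg.n_starts, cfg.seed, maxiter=cfg.maxiter
            )
        elif name == "activities+global":
            res = fit_regulation(
                ds_act, "eq2_eq3", cfg.n_starts, cfg.seed, maxiter=cfg.maxiter
            )
        elif name == "proteins+global":
            ds = _dataset_at(targets, profiles, fixed_assignment)
            res = fit_regulation(
                ds, "eq2_eq3", cfg.n_starts, cfg.seed, maxiter=cfg.maxiter
            )
            res.half_lives = {"FliA": cfg.half_lives[0], "FlgM": cfg.half_lives[1]}
        elif name == "proteins+global+halflives":
            res = fit_with_halflives(
                targets,
                profiles,
                grid,
                mode="shared",
                model="eq2_eq3",
                n_starts=cfg.n_starts,
                seed=cfg.seed,
                maxiter=cfg.maxiter,
            )
        else:
            raise ValueError(f"unknown configuration {name!r}")
        report["fits"][name] = res
        report["Q"][name] = res.Q

    # sign-pattern verdict for the expected tar pattern at the fixed half-lives
    ds3 = _dataset_at(targets, profiles, fixed_assignment)
    sconds = {
        n: {
            "f": cd.f_target,
            "eps_f": cd.epsilon,
            "X": {"fliA": cd.x1, "flgM": cd.x2, "global": cd.f_const},
        }
        for n, cd in ds3.conditions.items()
    }
    sdata = signpatterns.SignData(("fliA", "flgM", "global"), sconds)
    report["sign_pattern"] = signpatterns.classify_expected(sdata, (1, -1, 1))
    report["comparison"] = sorted(report["Q"].items(), key=lambda kv: kv[1], reverse=True)
    return report
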