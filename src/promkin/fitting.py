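"""Weighted multistart estimation of regulation parameters.

Given measured target activities f̄ˢ(t) with 2·SEM bands εˢ(t) over
conditions s, and regressor trajectories x̄ˢ = (x1, x2) — either the fliA
and flgM promoter activities used as proxies, or reconstructed FliA and
FlgM concentrations — the parameter vector c = (k0, k1, n, θ, K) minimizes
the band-weighted absolute deviation

    Q(c) = Σ_s Σ_t  |f̄ˢ(t) − f(x̄ˢ(t), c)| / (2 εˢ(t))

over a box C of physiologically plausible values tied to the data ranges.
Minimization is best-of-N local optimization from a seeded Latin-hypercube
sample of C. Optionally the FliA/FlgM half-lives are estimated jointly by
exhaustive search (shared across conditions) or greedy coordinate descent
(per condition) over a half-life grid, and parameter uncertainty is
quantified by a bootstrap-like resampling of the measured activities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from . import regmodel
from .preprocess import GAMMA_R_DEFAULT, ActivityProfile
from .reconstruct import HalfLifeGrid, PrecultureSpec, precompute_profiles
from .regmodel import RegulationParams

__all__ = [
    "ConditionData",
    "FitDataset",
    "FitResult",
    "objective_Q",
    "search_box",
    "fit_regulation",
    "fit_from_starts",
    "fit_flgM_variant",
    "fit_with_halflives",
    "bootstrap_cis",
]

MODELS = ("eq1_eq2", "eq2_eq3")
PARAM_NAMES = ("k0", "k1", "n", "theta", "K")


@dataclass
class ConditionData:
    """Trajectories of one condition on a shared evaluation grid."""

    time: np.ndarray
    f_target: np.ndarray  # target promoter activity mean, RFU/min
    epsilon: np.ndarray  # 2-SEM half-band, RFU/min
    x1: np.ndarray  # FliA regressor (activity or concentration)
    x2: np.ndarray  # FlgM regressor
    f_const: np.ndarray | None = None  # constitutive promoter activity

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("f_target", "epsilon", "x1", "x2"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} is not on the condition grid")
        if self.f_const is not None and len(self.f_const) != n:
            raise ValueError("f_const is not on the condition grid")


@dataclass
class FitDataset:
    """Multi-condition dataset for regulation-function fitting.

    ``f_const_mean`` (the temporal mean of the constitutive activity pooled
    over all conditions) is computed on construction when constitutive
    trajectories are present; it is needed by the α-rescaled model.
    """

    conditions: dict[str, ConditionData]
    f_const_mean: float | None = None

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("empty dataset")
        if self.f_const_mean is None:
            fc = [c.f_const for c in self.conditions.values() if c.f_const is not None]
            if fc:
                self.f_const_mean = float(np.mean(np.concatenate(fc)))

    def subset(self, names: Sequence[str]) -> "FitDataset":
        return FitDataset(
            conditions={k: self.conditions[k] for k in names},
            f_const_mean=self.f_const_mean,
        )

    def _stacked(self) -> dict:
        # concatenated view over all conditions, points with eps > 0 only;
        # cached because the objective is evaluated thousands of times
        cached = getattr(self, "_stacked_cache", None)
        if cached is None:
            parts = {"f": [], "w": [], "x1": [], "x2": [], "fc": []}
            has_const = all(
                c.f_const is not None for c in self.conditions.values()
            )
            for cd in self.conditions.values():
                m = cd.epsilon > 0
                parts["f"].append(cd.f_target[m])
                parts["w"].append(0.5 / cd.epsilon[m])
                parts["x1"].append(cd.x1[m])
                parts["x2"].append(cd.x2[m])
                if has_const:
                    parts["fc"].append(cd.f_const[m])
            cached = {
                "f": np.concatenate(parts["f"]),
                "w": np.concatenate(parts["w"]),
                "x1": np.concatenate(parts["x1"]),
                "x2": np.concatenate(parts["x2"]),
                "fc": np.concatenate(parts["fc"]) if has_const else None,
            }
            object.__setattr__(self, "_stacked_cache", cached)
        return cached


@dataclass
class FitResult:
    params: RegulationParams
    Q: float
    model: str
    n_starts: int
    seed: int | None
    start_Qs: np.ndarray = field(default_factory=lambda: np.array([]))
    residuals: dict = field(default_factory=dict)  # condition -> f̄ − f_model
    predictions: dict = field(default_factory=dict)  # condition -> f_model
    half_lives: dict | None = None  # regulator -> minutes (or per-condition map)
    ci: dict | None = None  # parameter -> (lo, hi)


def _predict(c: RegulationParams, cd: ConditionData, model: str) -> np.ndarray:
    pA_free = regmodel.free_fliA(cd.x1, cd.x2, c.K)
    if model == "eq1_eq2":
        return np.asarray(regmodel.hill_activity(pA_free, c))
    if model == "eq2_eq3":
        if cd.f_const is None:
            raise ValueError("model eq2_eq3 needs a constitutive trajectory")
        return np.asarray(regmodel.global_activity(cd.f_const, pA_free, c))
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def objective_Q(
    c: RegulationParams | np.ndarray,
    data: FitDataset,
    model: str = "eq2_eq3",
    loss: str = "abs",
) -> float:
    """Band-weighted misfit Q(c); points with ε = 0 are excluded.

    ``loss="abs"`` is the printed weighted absolute deviation; ``"square"``
    replaces |·| by (·)² for users preferring a mean-square criterion.
    """
    if not isinstance(c, RegulationParams):
        c = RegulationParams.from_array(np.asarray(c, dtype=float))
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    s = data._stacked()
    if model == "eq2_eq3" and s["fc"] is None:
        raise ValueError("model eq2_eq3 needs a constitutive trajectory")
    pA_free = regmodel.free_fliA(s["x1"], s["x2"], c.K)
    pred = np.asarray(regmodel.hill_activity(pA_free, c))
    if model == "eq2_eq3":
        pred = s["fc"] * pred
    dev = np.abs(s["f"] - pred)
    if loss == "square":
        dev = dev**2
    return float(np.sum(dev * s["w"]))


def search_box(data: FitDataset) -> list[tuple[float, float]]:
    """Physiologically plausible box C from the data ranges.

    0 ≤ k0 ≤ max f̄, 0 ≤ k1 ≤ 10·max f̄, 1 ≤ n ≤ 4, 0 ≤ θ ≤ max x̄1,
    0 ≤ K ≤ 20·max x̄2, maxima over all conditions and times.
    """
    fmax = max(float(np.max(cd.f_target)) for cd in data.conditions.values())
    x1max = max(float(np.max(cd.x1)) for cd in data.conditions.values())
    x2max = max(float(np.max(cd.x2)) for cd in data.conditions.values())
    return [
        (0.0, fmax),
        (0.0, 10.0 * fmax),
        (1.0, 4.0),
        (0.0, x1max),
        (0.0, 20.0 * x2max),
    ]


def _clamp_box(
    box: list[tuple[float, float]], fixed: Mapping[str, float] | None
) -> list[tuple[float, float]]:
    if not fixed:
        return box
    box = list(box)
    for name, value in fixed.items():
        i = PARAM_NAMES.index(name)
        box[i] = (float(value), float(value))
    return box


def fit_from_starts(
    data: FitDataset,
    model: str,
    starts: np.ndarray,
    loss: str = "abs",
    maxiter: int | None = None,
) -> FitResult:
    """Best-of local minimizations of Q from explicit start points.

    Local solver: bounded Powell (derivative-free; the printed objective is
    a weighted absolute deviation, hence non-smooth). Deterministic.
    """
    box = _clamp_box(search_box(data), None)
    starts = np.atleast_2d(np.asarray(starts, dtype=float))
    return _fit_core(data, model, starts, box, loss, maxiter, None, None)


def _fit_core(data, model, starts, box, loss, maxiter, seed, fixed):
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])
    free = hi > lo

    def q_of(z):
        c = np.array(z, dtype=float)
        return objective_Q(np.clip(c, lo, hi), data, model, loss)

    def q_free(zf):
        z = lo.copy()
        z[free] = zf
        return q_of(z)

    best = None
    start_Qs = []
    options = {"maxiter": maxiter} if maxiter else None
    for s in starts:
        s = np.clip(s, lo, hi)
        res = minimize(
            q_free,
            s[free],
            method="Powell",
            bounds=[(l, h) for l, h, fr in zip(lo, hi, free) if fr],
            options=options,
        )
        start_Qs.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("no start points supplied")
    z = lo.copy()
    z[free] = np.clip(best.x, lo[free], hi[free])
    c_hat = RegulationParams.from_array(z)
    result = FitResult(
        params=c_hat,
        Q=float(best.fun),
        model=model,
        n_starts=len(starts),
        seed=seed,
        start_Qs=np.asarray(start_Qs),
    )
    for name, cd in data.conditions.items():
        pred = _predict(c_hat, cd, model)
        result.predictions[name] = pred
        result.residuals[name] = cd.f_target - pred
    return result


def _lhs_starts(box, n_starts, seed, fixed=None):
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])
    sampler = qmc.LatinHypercube(d=len(box), seed=seed)
    u = sampler.random(n_starts)
    return lo + u * (hi - lo)


def fit_regulation(
    data: FitDataset,
    model: str = "eq2_eq3",
    n_starts: int = 20,
    seed: int = 0,
    loss: str = "abs",
    fixed: Mapping[str, float] | None = None,
    theta_min_observed: bool = False,
    maxiter: int | None = None,
) -> FitResult:
    """Multistart estimate of c over the search box.

    Start points are a seeded Latin-hypercube sample of C; each start is
    refined by bounded Powell; the best local optimum is returned, with the
    per-start objective values recorded. ``fixed`` clamps named parameters
    (e.g. ``{"K": 14615}``); ``theta_min_observed`` raises the θ lower
    bound to the smallest observed FliA regressor value, reflecting the
    requirement that the threshold lie within the range of observed
    concentrations.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    box = _clamp_box(search_box(data), fixed)
    if theta_min_observed and not (fixed and "theta" in fixed):
        x1min = min(float(np.min(cd.x1)) for cd in data.conditions.values())
        box[3] = (min(x1min, box[3][1]), box[3][1])
    starts = _lhs_starts(box, n_starts, seed)
    res = _fit_core(data, model, starts, box, loss, maxiter, seed, fixed)
    return res


def fit_flgM_variant(
    data: FitDataset,
    K_fixed: float,
    model: str = "eq2_eq3",
    n_starts: int = 20,
    seed: int = 0,
    excluded_condition: str = "WT-LB",
    **kwargs,
) -> FitResult:
    """Fit for the flgM target: WT-LB excluded, K clamped.

    For the flgM promoter the WT-LB condition is not usable and the
    dissociation constant is fixed, for biological consistency, to the
    value inferred from fitting the tar promoter.
    """
    if K_fixed < 0:
        raise ValueError("K_fixed must be non-negative")
    if excluded_condition in data.conditions:
        raise ValueError(
            f"condition {excluded_condition!r} must be excluded from the flgM fit"
        )
    return fit_regulation(
        data, model, n_starts, seed, fixed={"K": float(K_fixed)}, **kwargs
    )


# ---------------------------------------------------------------------------
# Joint half-life estimation


def _dataset_at(
    targets: Mapping[str, ConditionData],
    profiles: Mapping[tuple[str, str, float], "object"],
    assignment: Mapping[str, tuple[float, float]],
) -> FitDataset:
    conds = {}
    for name, cd in targets.items():
        tau_A, tau_M = assignment[name]
        pA = profiles[("fliA", name, float(tau_A))]
        pM = profiles[("flgM", name, float(tau_M))]
        conds[name] = ConditionData(
            time=cd.time,
            f_target=cd.f_target,
            epsilon=cd.epsilon,
            x1=np.interp(cd.time, pA.time, pA.p),
            x2=np.interp(cd.time, pM.time, pM.p),
            f_const=cd.f_const,
        )
    return FitDataset(conditions=conds)


def fit_with_halflives(
    targets: Mapping[str, ConditionData],
    profiles: Mapping[tuple[str, str, float], "object"],
    grid: HalfLifeGrid,
    mode: str = "shared",
    model: str = "eq2_eq3",
    n_starts: int = 10,
    seed: int = 0,
    n_restarts: int = 10,
    **kwargs,
) -> FitResult:
    """Estimate regulation parameters and FliA/FlgM half-lives jointly.

    ``targets`` maps condition to its target trajectories (x1/x2 entries
    are ignored and replaced from ``profiles``, the precomputed map
    (regulator, condition, half_life) -> ProteinProfile).

    shared mode: exhaustive search over grid × grid half-life combinations
    with an inner multistart fit per combination; returns the argmin.
    per_condition mode: greedy coordinate descent over per-condition
    (τ_A, τ_M) assignments — cycle over conditions, replace each pair by
    its local grid argmin at the current parameters' best refit — with
    ``n_restarts`` random restarts from seeded assignments.
    """
    if len(grid) == 0:
        raise ValueError("half-life grid is empty")
    values = [float(v) for v in grid]
    names = list(targets)
    if mode == "shared":
        best: FitResult | None = None
        for tau_A in values:
            for tau_M in values:
                ds = _dataset_at(targets, profiles, {n: (tau_A, tau_M) for n in names})
                res = fit_regulation(ds, model, n_starts, seed, **kwargs)
                if best is None or res.Q < best.Q:
                    best = res
                    best.half_lives = {"FliA": tau_A, "FlgM": tau_M}
        return best
    if mode != "per_condition":
        raise ValueError("mode must be 'shared' or 'per_condition'")

    rng = np.random.default_rng(seed)
    best = None
    for restart in range(n_restarts):
        if restart == 0:
            assign = {n: (values[len(values) // 2], values[len(values) // 2]) for n in names}
        else:
            assign = {
                n: (values[rng.integers(len(values))], values[rng.integers(len(values))])
                for n in names
            }
        res = fit_regulation(
            _dataset_at(targets, profiles, assign), model, n_starts, seed, **kwargs
        )
        improved = True
        while improved:
            improved = False
            for n in names:
                for tau_A in values:
                    for tau_M in values:
                        if (tau_A, tau_M) == assign[n]:
                            continue
                        trial = dict(assign)
                        trial[n] = (tau_A, tau_M)
                        r = fit_regulation(
                            _dataset_at(targets, profiles, trial),
                            model,
                            n_starts,
                            seed,
                            **kwargs,
                        )
                        if r.Q < res.Q - 1e-12:
                            res, assign, improved = r, trial, True
        if best is None or res.Q < best.Q:
            best = res
            best.half_lives = {
                n: {"FliA": a, "FlgM": m} for n, (a, m) in assign.items()
            }
    return best


# ---------------------------------------------------------------------------
# Bootstrap confidence intervals


def bootstrap_cis(
    data: FitDataset,
    fit: FitResult,
    B: int = 200,
    seed: int = 0,
    n_starts: int = 3,
    max_failure_rate: float = 0.2,
    replicate_curves: Mapping[str, np.ndarray] | None = None,
) -> dict[str, tuple[float, float]]:
    """Bootstrap-like 95% parameter intervals by resampling the activities.

    Each of ``B`` pseudo-datasets perturbs the target activity at every
    time point: nonparametrically, by resampling replicate curves when
    ``replicate_curves`` (condition -> replicates × time array) is given;
    otherwise from a Gaussian with mean f̄ and SD ε/2 (ε being the 2·SEM
    band). Each pseudo-dataset is refit warm-started at the original
    optimum plus ``n_starts − 1`` fresh Latin-hypercube starts; 2.5/97.5
    percentiles per parameter are returned and attached to ``fit.ci``.
    """
    if B < 100:
        raise ValueError("B must be >= 100 for stable percentile intervals")
    rng = np.random.default_rng(seed)
    box = search_box(data)
    samples = []
    failures = 0
    for b in range(B):
        conds = {}
        for name, cd in data.conditions.items():
            if replicate_curves is not None and name in replicate_curves:
                reps = np.asarray(replicate_curves[name])
                idx = rng.integers(reps.shape[0], size=reps.shape[0])
                f_new = reps[idx].mean(axis=0)
            else:
                f_new = cd.f_target + rng.normal(0.0, cd.epsilon / 2.0)
            conds[name] = ConditionData(
                cd.time, np.clip(f_new, 0.0, None), cd.epsilon, cd.x1, cd.x2, cd.f_const
            )
        ds = FitDataset(conds, f_const_mean=data.f_const_mean)
        starts = np.vstack(
            [fit.params.as_array()]
            + ([_lhs_starts(box, n_starts - 1, int(rng.integers(2**31)))] if n_starts > 1 else [])
        )
        try:
            res = _fit_core(ds, fit.model, starts, box, "abs", None, None, None)
            samples.append(res.params.as_array())
        except Exception:
            failures += 1
    if failures > max_failure_rate * B:
        raise RuntimeError(
            f"bootstrap refit failure rate {failures}/{B} exceeds "
            f"{max_failure_rate:.0%}"
        )
    arr = np.array(samples)
    ci = {
        name: (float(np.percentile(arr[:, i], 2.5)), float(np.percentile(arr[:, i], 97.5)))
        for i, name in enumerate(PARAM_NAMES)
    }
    fit.ci = ci
    return ci
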