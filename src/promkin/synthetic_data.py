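"""Forward generator of microplate reporter datasets for the motility module.

No machine-readable data were deposited for the study this package
re-implements, so the generator emulates the statistical structure of the
experiments: five growth conditions (three mutant strains in M9 minimal
medium, two strains in LB rich medium), logistic growth to stationary phase,
pulse-shaped promoter activities of *fliA*, *flgM* and the constitutive pRM
promoter with condition-dependent timing and amplitude (LB conditions induce
late, after several generations; peak *tar* activity spans over 10-fold
across conditions), a *tar* activity generated mechanistically from the
titration/Hill regulation model, slow reporter degradation, replicate
measurements and additive measurement noise with autofluorescence and
medium backgrounds.

Ground truth (activities, protein profiles, regulation parameters) is
emitted next to the plate data; no analysis stage reads it. All randomness
flows from the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from . import regmodel
from .preprocess import GAMMA_R_DEFAULT, ActivityProfile, PlateTimeSeries
from .reconstruct import LN2, PRECULTURE_HALF_LIVES, protein_concentration

__all__ = [
    "GrowthParams",
    "PulseParams",
    "NoiseModel",
    "ConditionSpec",
    "SyntheticScenario",
    "SyntheticTruth",
    "default_scenario",
    "make_growth_curve",
    "make_activity_pulse",
    "make_activity",
    "simulate_reporter_fluorescence",
    "simulate_module_scenario",
    "make_fit_dataset",
]

REGULATORS = ("fliA", "flgM")
REPORTERS = ("fliA", "flgM", "tar", "pRM")


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth: A0 initial OD, rate min^-1, capacity (carrying OD)."""

    A0: float
    rate: float
    capacity: float

    def __post_init__(self) -> None:
        if not 0 < self.A0 < self.capacity:
            raise ValueError("need 0 < A0 < capacity")
        if self.rate <= 0:
            raise ValueError("growth rate must be positive")


@dataclass(frozen=True)
class PulseParams:
    """Log-normal activity bump: basal + height·exp(−ln²((t−onset)/width)/(2s²)).

    The peak sits at t = onset + width; ``shape`` controls the relative
    pulse duration. Activity returns to ``basal`` after growth arrest.
    """

    onset: float  # minutes
    width: float  # minutes (mode offset from onset)
    height: float  # RFU/min
    basal: float = 0.0  # RFU/min
    shape: float = 0.5

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height < 0 or self.basal < 0:
            raise ValueError("width must be > 0; height and basal >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise and backgrounds of the plate reader."""

    absorbance_sd: float = 0.005  # OD units
    fluorescence_rel: float = 0.02  # multiplicative component on signal
    fluorescence_floor: float = 2.0  # RFU, additive floor
    medium_absorbance: float = 0.04  # OD of blank medium
    medium_fluorescence: float = 30.0  # RFU of blank medium
    autofluorescence_per_od: float = 60.0  # RFU per OD unit of biomass


@dataclass(frozen=True)
class ConditionSpec:
    name: str
    growth: GrowthParams
    pulses: dict  # promoter -> PulseParams (or tuple of them) for fliA, flgM, pRM
    tau_A: float = 30.0  # FliA half-life, minutes
    tau_M: float = 18.0  # FlgM half-life, minutes
    t_max: float = 960.0  # minutes
    n_points: int = 150


@dataclass(frozen=True)
class SyntheticScenario:
    conditions: tuple
    c_true: regmodel.RegulationParams
    alpha: float = 1.0
    gamma_r: float = GAMMA_R_DEFAULT
    noise: NoiseModel = field(default_factory=NoiseModel)
    n_replicates: int = 6
    seed: int = 0


@dataclass
class SyntheticTruth:
    """Noise-free ground truth for one condition on its reading grid."""

    time: np.ndarray
    A: np.ndarray
    mu: np.ndarray
    activities: dict  # promoter -> RFU/min array (incl. generated 'tar')
    proteins: dict  # 'FliA'/'FlgM' -> RFU array
    r0: dict  # promoter -> initial reporter concentration
    tau_A: float = 30.0
    tau_M: float = 18.0


def default_scenario(seed: int = 0, alpha: float = 1.0) -> SyntheticScenario:
    """The default five-condition study scenario.

    M9 conditions grow slowly (doubling ~70 min); the motility genes there
    are already expressed in the preculture, so expression runs from the
    start of the experiment and the regulator proteins begin above their
    exponential-phase quasi-steady level (the stationary-phase half-lives
    that set the initial condition are much longer than the in-growth
    ones) and decrease over the window. LB conditions grow fast (doubling
    ~35-45 min) and induce only after several generations. Condition
    geometries differ the way the real module's do: one M9 condition
    carries a strong FlgM burst against a rising fliA background, the
    strong LB condition pairs a sharply decaying constitutive signal with
    a late saturating fliA pulse, and the weak LB condition's target is
    dominated by the constitutive signal. Peak tar activity spans well
    over 10-fold across conditions. Regulation parameters put the Hill
    threshold inside the traversed free-FliA range with appreciable FlgM
    titration (a well-excited, identifiable regime).
    """
    m9 = GrowthParams(A0=0.05, rate=0.010, capacity=0.7)
    lb = GrowthParams(A0=0.02, rate=0.015, capacity=1.5)

    def P(onset, width, height, basal=0.04, shape=0.45):
        return PulseParams(onset=onset, width=width, height=height, basal=basal, shape=shape)

    conds = (
        # expressed since preculture; proteins decay from a high initial level
        ConditionSpec("drpoS-M9", m9, {
            "fliA": P(-60.0, 40.0, 30.0, 0.05),
            "flgM": P(-80.0, 40.0, 14.0, 0.04),
            "pRM": P(-20.0, 150.0, 0.9, 0.4),
        }, t_max=960.0),
        ConditionSpec("dcpxR-M9", m9, {
            "fliA": P(-70.0, 50.0, 18.0, 0.05),
            "flgM": P(-90.0, 45.0, 9.0, 0.04),
            "pRM": P(-30.0, 120.0, 0.7, 0.4),
        }, t_max=960.0),
        # slow fliA induction with a sharp, sustained FlgM burst on top
        ConditionSpec("dcsgD-M9", m9, {
            "fliA": P(60.0, 220.0, 6.0, 0.05, 0.5),
            "flgM": (P(230.0, 25.0, 30.0, 0.04, 0.40),
                     P(230.0, 125.0, 25.0, 0.0, 1.0)),
            "pRM": P(40.0, 220.0, 0.8, 0.4, 0.5),
        }, t_max=960.0),
        # sharply decaying constitutive signal, late saturating fliA pulse
        ConditionSpec("dcsgD-LB", lb, {
            "fliA": P(230.0, 120.0, 50.0, 0.05, 0.5),
            "flgM": P(100.0, 40.0, 20.0, 0.04, 0.40),
            "pRM": P(120.0, 60.0, 1.3, 0.25),
        }, t_max=600.0),
        # weak late induction; target dominated by the constitutive signal
        ConditionSpec("WT-LB", lb, {
            "fliA": P(200.0, 50.0, 0.8, 0.05),
            "flgM": P(180.0, 40.0, 1.8, 0.04),
            "pRM": P(150.0, 250.0, 0.6, 0.4, 0.5),
        }, t_max=600.0),
    )
    c_true = regmodel.RegulationParams(k0=0.15, k1=6.0, n=2.0, theta=300.0, K=150.0)
    return SyntheticScenario(conditions=conds, c_true=c_true, alpha=alpha, seed=seed)


def make_growth_curve(g: GrowthParams) -> tuple[Callable, Callable]:
    """Closed-form logistic absorbance A(t) and its growth rate mu(t)."""

    def A(t):
        t = np.asarray(t, dtype=float)
        return g.A0 * g.capacity / (g.A0 + (g.capacity - g.A0) * np.exp(-g.rate * t))

    def mu(t):
        return g.rate * (1.0 - A(t) / g.capacity)

    return A, mu


def make_activity_pulse(p: PulseParams) -> Callable:
    """Smooth non-negative promoter activity pulse; see :class:`PulseParams`."""

    def f(t):
        t = np.asarray(t, dtype=float)
        u = t - p.onset
        with np.errstate(divide="ignore", invalid="ignore"):
            lg = np.where(u > 0, np.log(np.where(u > 0, u, 1.0) / p.width), 0.0)
            bump = np.where(u > 0, np.exp(-0.5 * (lg / p.shape) ** 2), 0.0)
        out = p.basal + p.height * bump
        return out if out.ndim else float(out)

    return f


def make_activity(pulses: PulseParams | tuple) -> Callable:
    """Activity curve from one pulse or a sum of pulses (shared basal).

    Real promoter activities are not always unimodal (expression can come
    in successive waves within one growth curve); a tuple of pulse
    parameters yields the first pulse's basal plus all bumps.
    """
    if isinstance(pulses, PulseParams):
        return make_activity_pulse(pulses)
    funs = [make_activity_pulse(p) for p in pulses]
    basals = [p.basal for p in pulses]

    def f(t):
        out = funs[0](t)
        for fi, b in zip(funs[1:], basals[1:]):
            out = out + fi(t) - b
        return out

    return f


def _integrate_fluorescence(
    f: Callable, A: Callable, gamma_r: float, t: np.ndarray, I0: float
) -> np.ndarray:
    sol = solve_ivp(
        lambda tt, I: f(tt) * A(tt) - gamma_r * I,
        (t[0], t[-1]),
        [I0],
        method="LSODA",
        t_eval=t,
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise RuntimeError(f"fluorescence integration failed: {sol.message}")
    return sol.y[0]


def simulate_reporter_fluorescence(
    f: Callable,
    A: Callable,
    gamma_r: float,
    noise: NoiseModel,
    n_replicates: int,
    seed: int,
    t: np.ndarray,
    r0: float = 0.0,
    condition_id: str = "cond",
    reporter: str = "gene",
) -> list[PlateTimeSeries]:
    """Render one reporter construct into noisy plate wells.

    Integrates dI/dt = f(t)·A(t) − gamma_r·I — the unique fluorescence
    dynamics for which r = I/A obeys dr/dt = f − (gamma_r + mu)·r — from
    I(0) = r0·A(0), then adds per-replicate Gaussian noise, the medium
    background and biomass-proportional autofluorescence. Also emits one
    background_medium and one background_strain well.
    """
    if gamma_r < 0:
        raise ValueError("gamma_r must be non-negative")
    t = np.asarray(t, dtype=float)
    rng = np.random.default_rng(seed)
    I_true = _integrate_fluorescence(f, A, gamma_r, t, r0 * float(A(t[0])))
    A_true = A(t)
    autofluo = noise.autofluorescence_per_od * A_true
    out: list[PlateTimeSeries] = []
    for rep in range(n_replicates):
        A_meas = (
            A_true
            + noise.medium_absorbance
            + rng.normal(0.0, noise.absorbance_sd, t.shape)
        )
        I_sd = noise.fluorescence_floor + noise.fluorescence_rel * np.abs(I_true)
        I_meas = (
            I_true
            + autofluo
            + noise.medium_fluorescence
            + rng.normal(0.0, 1.0, t.shape) * I_sd
        )
        out.append(
            PlateTimeSeries(
                condition_id=condition_id,
                well_id=f"{condition_id}:{reporter}:r{rep}",
                replicate=rep,
                role="reporter",
                reporter=reporter,
                time=t,
                absorbance=A_meas,
                fluorescence=I_meas,
            )
        )
    for rep in range(2):
        out.append(
            PlateTimeSeries(
                condition_id=condition_id,
                well_id=f"{condition_id}:{reporter}:medium{rep}",
                replicate=rep,
                role="background_medium",
                reporter="",
                time=t,
                absorbance=noise.medium_absorbance
                + rng.normal(0.0, noise.absorbance_sd, t.shape),
                fluorescence=noise.medium_fluorescence
                + rng.normal(0.0, noise.fluorescence_floor, t.shape),
            )
        )
        out.append(
            PlateTimeSeries(
                condition_id=condition_id,
                well_id=f"{condition_id}:{reporter}:auto{rep}",
                replicate=rep,
                role="background_strain",
                reporter="",
                time=t,
                absorbance=A_true
                + noise.medium_absorbance
                + rng.normal(0.0, noise.absorbance_sd, t.shape),
                fluorescence=autofluo
                + noise.medium_fluorescence
                + rng.normal(0.0, noise.fluorescence_floor, t.shape),
            )
        )
    return out


def _condition_truth(
    cond: ConditionSpec, scenario: SyntheticScenario, f_const_mean: float
) -> SyntheticTruth:
    t = np.linspace(0.0, cond.t_max, cond.n_points)
    A, mu = make_growth_curve(cond.growth)
    f_fliA = make_activity(cond.pulses["fliA"])
    f_flgM = make_activity(cond.pulses["flgM"])
    f_pRM = make_activity(cond.pulses["pRM"])
    gamma_r = scenario.gamma_r
    proteins = {}
    for reg, f_reg, tau in (
        ("FliA", f_fliA, cond.tau_A),
        ("FlgM", f_flgM, cond.tau_M),
    ):
        # preculture steady state at basal activity, stationary phase (mu_T=0)
        r_T = f_reg(0.0) / gamma_r
        gamma_pre = LN2 / PRECULTURE_HALF_LIVES[reg]
        p0 = gamma_r / gamma_pre * r_T
        proteins[reg] = protein_concentration(
            f_reg, mu, tau, p0, t_eval=t, condition_id=cond.name, regulator=reg
        ).p
    r0 = {"fliA": f_fliA(0.0) / gamma_r, "flgM": f_flgM(0.0) / gamma_r}
    pA_free = regmodel.free_fliA(proteins["FliA"], proteins["FlgM"], scenario.c_true.K)
    f_const = f_pRM(t)
    if scenario.alpha == 1.0:
        f_tar = regmodel.global_activity(f_const, pA_free, scenario.c_true)
    else:
        f_tar = regmodel.alpha_activity(
            f_const, f_const_mean, scenario.alpha, pA_free, scenario.c_true
        )
    activities = {
        "fliA": f_fliA(t),
        "flgM": f_flgM(t),
        "pRM": f_const,
        "tar": np.asarray(f_tar),
    }
    r0["pRM"] = f_pRM(0.0) / gamma_r
    r0["tar"] = float(np.atleast_1d(f_tar)[0]) / gamma_r
    return SyntheticTruth(
        time=t,
        A=A(t),
        mu=mu(t),
        activities=activities,
        proteins=proteins,
        r0=r0,
        tau_A=cond.tau_A,
        tau_M=cond.tau_M,
    )


def pooled_f_const_mean(scenario: SyntheticScenario) -> float:
    """Temporal mean of the constitutive activity pooled over all conditions."""
    vals = []
    for cond in scenario.conditions:
        t = np.linspace(0.0, cond.t_max, cond.n_points)
        vals.append(make_activity(cond.pulses["pRM"])(t))
    return float(np.mean(np.concatenate(vals)))


def simulate_module_scenario(
    scenario: SyntheticScenario,
) -> tuple[list[PlateTimeSeries], dict]:
    """Full forward simulation: plate wells for all reporters and conditions.

    Returns ``(plate_series, truth)`` where ``truth`` maps condition name to
    a :class:`SyntheticTruth` and additionally records the scenario under
    ``truth["__scenario__"]``. The tar activity is generated mechanistically
    from the reconstructed FliA/FlgM proteins and the constitutive activity
    via the regulation model at ``c_true`` (α-rescaled when alpha != 1).
    """
    fbar = pooled_f_const_mean(scenario)
    plate: list[PlateTimeSeries] = []
    truth: dict = {"__scenario__": scenario, "__f_const_mean__": fbar}
    for i, cond in enumerate(scenario.conditions):
        ct = _condition_truth(cond, scenario, fbar)
        truth[cond.name] = ct
        A, _ = make_growth_curve(cond.growth)
        for j, rep_name in enumerate(REPORTERS):
            f_interp = ct.activities[rep_name]
            tt = ct.time
            f_fun = lambda x, y=f_interp, tg=tt: np.interp(x, tg, y)  # noqa: E731
            plate.extend(
                simulate_reporter_fluorescence(
                    f_fun,
                    A,
                    scenario.gamma_r,
                    scenario.noise,
                    scenario.n_replicates,
                    seed=scenario.seed + 1000 * i + 100 * j,
                    t=ct.time,
                    r0=ct.r0[rep_name],
                    condition_id=cond.name,
                    reporter=rep_name,
                )
            )
    return plate, truth


def make_fit_dataset(
    scenario: SyntheticScenario,
    regressors: str = "proteins",
    noise_rel: float = 0.05,
    seed: int | None = None,
    grid_step: float = 6.0,
    include_const: bool = True,
    half_lives: tuple[float, float] | None = None,
):
    """Analysis-level dataset for the fitting stage, straight from truth.

    Emulates the measured profiles after preprocessing: per condition, the
    target tar activity is the mean of ``n_replicates`` replicate curves
    with epsilon = 2·SEM. Replicate curves differ by smooth perturbations —
    a multiplicative amplitude factor plus a low-order random trend of
    magnitude ``noise_rel`` × condition peak — because each replicate is a
    spline-smoothed well trajectory, not white noise (between-well
    variability in microplate kinetics is dominated by smooth offsets in
    inoculum, volume and timing). Regressor trajectories are the noise-free
    protein concentrations (``regressors="proteins"``, optionally
    reconstructed at ``half_lives`` instead of the generating ones) or the
    fliA/flgM promoter activities (``regressors="activities"``).
    Returns ``(FitDataset, truth)``.
    """
    from .fitting import ConditionData, FitDataset

    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    fbar = pooled_f_const_mean(scenario)
    conditions: dict[str, "ConditionData"] = {}
    truth: dict = {"__scenario__": scenario, "__f_const_mean__": fbar}
    for cond in scenario.conditions:
        ct = _condition_truth(cond, scenario, fbar)
        truth[cond.name] = ct
        grid = np.arange(0.0, cond.t_max + 0.5 * grid_step, grid_step)
        tar = np.interp(grid, ct.time, ct.activities["tar"])
        peak = float(np.max(tar))
        if noise_rel > 0:
            u = 2.0 * (grid - grid[0]) / (grid[-1] - grid[0]) - 1.0
            nrep = scenario.n_replicates
            amp = rng.normal(0.0, noise_rel, nrep)  # smooth amplitude factor
            coef = rng.normal(0.0, noise_rel * peak, (nrep, 3))
            trend = (
                coef[:, [0]]
                + coef[:, [1]] * u
                + coef[:, [2]] * (2.0 * u**2 - 1.0)
            ) / np.sqrt(3.0)
            reps = (1.0 + amp)[:, None] * tar + trend
            f_target = reps.mean(axis=0)
            eps = 2.0 * reps.std(axis=0, ddof=1) / np.sqrt(nrep)
            eps = np.maximum(eps, 1e-3 * peak)
        else:
            f_target = tar
            eps = np.full_like(tar, max(0.01 * peak, 1e-9))
        if regressors == "proteins":
            if half_lives is None:
                pA = np.interp(grid, ct.time, ct.proteins["FliA"])
                pM = np.interp(grid, ct.time, ct.proteins["FlgM"])
            else:
                spec_c = replace(cond, tau_A=half_lives[0], tau_M=half_lives[1])
                ct2 = _condition_truth(spec_c, scenario, fbar)
                pA = np.interp(grid, ct2.time, ct2.proteins["FliA"])
                pM = np.interp(grid, ct2.time, ct2.proteins["FlgM"])
        elif regressors == "activities":
            pA = np.interp(grid, ct.time, ct.activities["fliA"])
            pM = np.interp(grid, ct.time, ct.activities["flgM"])
        else:
            raise ValueError("regressors must be 'proteins' or 'activities'")
        f_const = (
            np.interp(grid, ct.time, ct.activities["pRM"]) if include_const else None
        )
        conditions[cond.name] = ConditionData(
            time=grid,
            f_target=np.clip(f_target, 0.0, None),
            epsilon=eps,
            x1=pA,
            x2=pM,
            f_const=f_const,
        )
    return FitDataset(conditions=conditions), truth
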