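"""Reconstruction of regulator protein concentrations from promoter activities.

A protein of interest expressed from the same promoter as the reporter obeys

    dp/dt = f(t) - (gamma_p + mu(t)) * p(t),    p(0) = p0,

where ``gamma_p = ln2 / half_life`` combines proteolysis and (for FlgM)
secretion, and ``mu`` is the growth-dilution rate. The initial condition
comes from the preculture steady state,

    p0 = (mu_T + gamma_r) / (mu_T + gamma_p') * r_T,

with ``r_T`` the reporter concentration at the end of the preculture and
``gamma_p'`` the stationary-phase degradation constant (FliA and FlgM are
markedly more stable out of exponential growth: 2 h and 3 h half-lives).

Because the relevant half-lives are uncertain, profiles are typically
precomputed over a grid of candidate half-lives (the study setting: 27
values between 7 min and 4 h) and screened downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .preprocess import ActivityProfile, GAMMA_R_DEFAULT

__all__ = [
    "ProteinProfile",
    "PrecultureSpec",
    "HalfLifeGrid",
    "half_life_grid",
    "initial_protein",
    "protein_concentration",
    "backextrapolate_activity",
    "precompute_profiles",
    "analysis_window",
]

LN2 = float(np.log(2.0))

#: stationary-phase (preculture) half-lives, minutes
PRECULTURE_HALF_LIVES = {
    "FliA": 120.0,
    "FlgM": 180.0,
    "fliA": 120.0,
    "flgM": 180.0,
}


@dataclass
class ProteinProfile:
    """Reconstructed regulator concentration for one half-life hypothesis."""

    condition_id: str
    regulator: str
    time: np.ndarray  # minutes
    p: np.ndarray  # RFU
    half_life: float  # minutes

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.half_life <= 0:
            raise ValueError("half_life must be positive")
        if np.any(self.p < -1e-9):
            raise ValueError("protein concentration must be non-negative")
        self.p = np.clip(self.p, 0.0, None)

    @property
    def gamma_p(self) -> float:
        return LN2 / self.half_life


@dataclass
class PrecultureSpec:
    """State at the end of the preculture (default: stationary phase)."""

    r_T: float  # reporter concentration at preculture end, RFU
    mu_T: float = 0.0  # growth rate at preculture end, min^-1
    gamma_p_preculture: float = LN2 / 120.0  # stationary-phase gamma_p', min^-1

    def __post_init__(self) -> None:
        if self.r_T < 0 or self.mu_T < 0:
            raise ValueError("r_T and mu_T must be non-negative")


@dataclass
class HalfLifeGrid:
    """Strictly increasing candidate half-lives in minutes."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values <= 0) or np.any(np.diff(self.values) <= 0):
            raise ValueError("half-life grid must be positive, strictly increasing")

    def __iter__(self):
        return iter(self.values)

    def __len__(self):
        return len(self.values)


def half_life_grid(n: int = 27, lo: float = 7.0, hi: float = 240.0) -> HalfLifeGrid:
    """Log-spaced half-life grid; defaults span 7 min to 4 h with 27 values.

    Log spacing because half-life effects on the reconstructed profiles are
    multiplicative.
    """
    return HalfLifeGrid(np.geomspace(lo, hi, n))


def initial_protein(spec: PrecultureSpec, gamma_r: float = GAMMA_R_DEFAULT) -> float:
    """Steady-state initial protein concentration from preculture reporter data.

    p0 = (mu_T + gamma_r) / (mu_T + gamma_p') * r_T. With identical kinetics
    (gamma_p' = gamma_r) the protein simply equals the reporter; with strong
    dilution (mu_T dominating) the ratio again tends to 1.
    """
    denom = spec.mu_T + spec.gamma_p_preculture
    if denom <= 0:
        raise ValueError("mu_T + gamma_p_preculture must be positive")
    return (spec.mu_T + gamma_r) / denom * spec.r_T


def protein_concentration(
    f: ActivityProfile | Callable,
    mu: Callable | np.ndarray | float,
    half_life: float,
    p0: float,
    t_eval: np.ndarray | None = None,
    condition_id: str = "",
    regulator: str = "",
) -> ProteinProfile:
    """Integrate dp/dt = f(t) − (gamma_p + mu(t))·p(t) from p(0) = p0.

    ``f`` may be an :class:`ActivityProfile` (linearly interpolated) or any
    callable on the window; ``mu`` a callable, an array on the profile grid,
    or a constant. Uses an adaptive, stiffness-switching solver (LSODA) with
    rtol 1e-8 / atol 1e-10 so that the profiles are smooth functions of the
    half-life for the outer optimization.
    """
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    if isinstance(f, ActivityProfile):
        t_eval = f.time if t_eval is None else np.asarray(t_eval, float)
        condition_id = condition_id or f.condition_id
        f_fun = f.interpolator()
    else:
        if t_eval is None:
            raise ValueError("t_eval is required when f is a bare callable")
        t_eval = np.asarray(t_eval, dtype=float)
        f_fun = f
    if callable(mu):
        mu_fun = mu
    elif np.ndim(mu) == 0:
        mu_c = float(mu)
        mu_fun = lambda t: mu_c  # noqa: E731
    else:
        mu_arr = np.asarray(mu, dtype=float)
        if mu_arr.shape != t_eval.shape:
            raise ValueError("mu array must be on the evaluation grid")
        tg = t_eval
        mu_fun = lambda t: np.interp(t, tg, mu_arr)  # noqa: E731
    gamma_p = LN2 / half_life

    def rhs(t, p):
        return f_fun(t) - (gamma_p + mu_fun(t)) * p

    sol = solve_ivp(
        rhs,
        (t_eval[0], t_eval[-1]),
        [float(p0)],
        method="LSODA",
        t_eval=t_eval,
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise RuntimeError(f"protein kinetics integration failed: {sol.message}")
    return ProteinProfile(
        condition_id=condition_id,
        regulator=regulator,
        time=t_eval,
        p=np.clip(sol.y[0], 0.0, None),
        half_life=float(half_life),
    )


def backextrapolate_activity(
    f: ActivityProfile, detect_time: float, ramp: float | None = None
) -> ActivityProfile:
    """Zero out below-detection early activity, ramping up to detection.

    When the fluorescence of a reporter strain is indistinguishable from
    background early in the experiment (typical in rich media where motility
    genes induce only after several generations), the promoter activity is
    taken to be 0 there and back-extrapolated towards 0 before
    ``detect_time``. The imputed segment gets epsilon = 0 (and is therefore
    excluded from fitting objectives); measured points keep their band.
    """
    t = f.time
    if detect_time > t[-1]:
        raise ValueError("detect_time lies after the profile window")
    if detect_time <= t[0]:
        return f  # already above detection from the start
    ramp = float(np.median(np.diff(t))) if ramp is None else float(ramp)
    f_det = float(np.interp(detect_time, t, f.f_mean))
    new_f = np.array(f.f_mean, copy=True)
    new_eps = np.array(f.epsilon, copy=True)
    pre = t < detect_time - ramp
    on_ramp = (~pre) & (t < detect_time)
    new_f[pre] = 0.0
    new_f[on_ramp] = f_det * (t[on_ramp] - (detect_time - ramp)) / ramp
    new_eps[pre | on_ramp] = 0.0
    return ActivityProfile(
        condition_id=f.condition_id,
        time=t,
        f_mean=new_f,
        epsilon=new_eps,
        n_replicates=f.n_replicates,
        reporter=f.reporter,
        epsilon_defined=f.epsilon_defined,
        meta=dict(f.meta),
    )


def analysis_window(
    mu: np.ndarray,
    below_detection: np.ndarray | None = None,
    arrest_fraction: float = 0.1,
) -> np.ndarray:
    """Boolean mask of the regulator-expression time frame.

    The downstream analyses (regulation-function fitting, sign-pattern
    inference over half-life grids) are restricted to the window in which
    the regulator genes are expressed: from the first detection of the
    signal (all points before the last below-detection reading are
    excluded, when a detection mask is available) to growth arrest, defined
    as the growth rate falling below ``arrest_fraction`` of its maximum.
    """
    mu = np.asarray(mu, dtype=float)
    mask = np.ones(mu.shape, dtype=bool)
    # growth arrest: first crossing below the threshold after the peak
    thresh = arrest_fraction * float(np.max(mu))
    peak = int(np.argmax(mu))
    after = np.where(mu[peak:] < thresh)[0]
    if after.size:
        mask[peak + after[0]:] = False
    if below_detection is not None:
        det = np.where(~np.asarray(below_detection, dtype=bool))[0]
        if det.size:
            mask[: det[0]] = False
        else:
            mask[:] = False
    return mask


def precompute_profiles(
    activities: Mapping[tuple[str, str], ActivityProfile],
    grid: HalfLifeGrid,
    precultures: Mapping[tuple[str, str], PrecultureSpec],
    mu: Mapping[str, np.ndarray | Callable | float] | None = None,
    gamma_r: float = GAMMA_R_DEFAULT,
) -> dict[tuple[str, str, float], ProteinProfile]:
    """One reconstructed profile per (regulator, condition, half-life).

    ``activities`` maps (condition, regulator) to the regulator promoter's
    activity profile; ``precultures`` provides the matching preculture state
    (missing entries default to r_T = r(0) inferred as 0). ``mu`` maps
    condition to a growth-rate curve; profiles carrying a ``"mu"`` entry in
    their metadata (as produced by preprocessing) need no explicit entry.
    Deterministic and order-independent.
    """
    out: dict[tuple[str, str, float], ProteinProfile] = {}
    for (cond, reg), prof in activities.items():
        if mu is not None and cond in mu:
            mu_c = mu[cond]
        elif "mu" in prof.meta:
            mu_c = prof.meta["mu"]
        else:
            mu_c = 0.0
        spec = precultures.get(
            (cond, reg),
            PrecultureSpec(
                r_T=0.0,
                gamma_p_preculture=LN2 / PRECULTURE_HALF_LIVES.get(reg, 120.0),
            ),
        )
        p0 = initial_protein(spec, gamma_r)
        for hl in grid:
            out[(reg, cond, float(hl))] = protein_concentration(
                prof, mu_c, float(hl), p0, regulator=reg
            )
    return out
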