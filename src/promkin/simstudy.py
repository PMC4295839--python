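"""In-silico studies: when do protein kinetics and global effects matter?

Two misfit scans, each generating target activities from the full
mechanistic model and re-identifying them with a deliberately impoverished
model:

* half-life scan — tar activities are generated from FliA/FlgM protein
  profiles simulated over a grid of half-lives (default 33 log-spaced
  values, 7 min to 16 h) with the global multiplier; identification uses
  promoter activities as protein proxies (kinetics ignored). The misfit
  grows with the FliA half-life: slow proteins decorrelate from their
  promoter activity.
* α scan — tar activities are generated with the global-effect variability
  rescaled by α ∈ [0, 1.25] (default 26 values) at reference half-lives
  (30, 18) min; identification uses the reconstructed proteins but no
  global multiplier. The misfit grows with the strength α of the ignored
  effects.

Q values are normalized by the maximum over the scanned grid, as in a
heatmap presentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import regmodel
from .fitting import ConditionData, FitDataset, fit_regulation
from .regmodel import ALPHA_MAX, RegulationParams

__all__ = [
    "HeatmapResult",
    "sim_half_life_grid",
    "alpha_grid",
    "rescale_params",
    "halflife_misfit_scan",
    "alpha_misfit_scan",
]


@dataclass
class HeatmapResult:
    """Misfit scan result: Q over the scanned axes, max-normalized."""

    axis_A: np.ndarray  # tau_A values (rows), or alpha values for 1-D scans
    axis_M: np.ndarray | None  # tau_M values (columns); None for alpha scans
    Q: np.ndarray

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)

    @property
    def Q_normalized(self) -> np.ndarray:
        return self.Q / np.max(self.Q)


def sim_half_life_grid(n: int = 33, lo: float = 7.0, hi: float = 960.0) -> np.ndarray:
    """Log-spaced simulation half-life axis; default 33 values, 7 min–16 h."""
    return np.geomspace(lo, hi, n)


def alpha_grid(n: int = 26) -> np.ndarray:
    """Equally spaced global-effect strengths on [0, 1.25]."""
    return np.linspace(0.0, ALPHA_MAX, n)


def rescale_params(
    c_ref: RegulationParams,
    ranges_ref: tuple[float, float],
    ranges_new: tuple[float, float],
) -> RegulationParams:
    """Map θ and K so their relative position in the search box is conserved.

    The box intervals for θ and K scale with the maxima of the FliA and
    FlgM regressor trajectories; changing half-lives changes those maxima.
    ``ranges_ref``/``ranges_new`` are (max x1, max x2) pairs. k0, k1 and n
    are unchanged; the map is a bijection (round trips are exact).
    """
    x1_ref, x2_ref = ranges_ref
    x1_new, x2_new = ranges_new
    if min(x1_ref, x2_ref, x1_new, x2_new) <= 0:
        raise ValueError("regressor ranges must be positive")
    return RegulationParams(
        k0=c_ref.k0,
        k1=c_ref.k1,
        n=c_ref.n,
        theta=c_ref.theta * x1_new / x1_ref,
        K=c_ref.K * x2_new / x2_ref,
    )


def halflife_misfit_scan(
    inputs,
    sim_grid_A: np.ndarray,
    sim_grid_M: np.ndarray,
    c_ref: RegulationParams,
    ref_half_lives: tuple[float, float] = (30.0, 18.0),
    n_starts: int = 5,
    seed: int = 0,
    eps_rel: float = 0.02,
    maxiter: int | None = None,
) -> HeatmapResult:
    """Misfit of the kinetics-ignoring fit over generating half-lives.

    ``inputs`` supplies measured-style promoter activities: a mapping of
    condition -> dict with ``time``, ``fliA``, ``flgM``, ``f_const``, ``mu``
    arrays (as produced from the synthetic scenario truth). For each
    (τ_A, τ_M) cell, FliA/FlgM concentration profiles are simulated at
    those half-lives, θ and K are rescaled to keep their relative box
    position (referenced to the profiles at ``ref_half_lives``), tar
    activities are generated with the global multiplier, and a model using
    the promoter activities as regressors (global effects included) is
    refit from scratch. Q is recorded per cell and max-normalized.
    """
    from .reconstruct import protein_concentration

    names = list(inputs)

    def proteins_at(tau_A, tau_M):
        out = {}
        for name in names:
            d = inputs[name]
            pA = protein_concentration(
                lambda t, d=d: np.interp(t, d["time"], d["fliA"]),
                lambda t, d=d: np.interp(t, d["time"], d["mu"]),
                tau_A,
                p0=d.get("p0_A", 0.0),
                t_eval=d["time"],
            ).p
            pM = protein_concentration(
                lambda t, d=d: np.interp(t, d["time"], d["flgM"]),
                lambda t, d=d: np.interp(t, d["time"], d["mu"]),
                tau_M,
                p0=d.get("p0_M", 0.0),
                t_eval=d["time"],
            ).p
            out[name] = (pA, pM)
        return out

    ref = proteins_at(*ref_half_lives)
    ref_ranges = (
        max(float(np.max(v[0])) for v in ref.values()),
        max(float(np.max(v[1])) for v in ref.values()),
    )
    Q = np.zeros((len(sim_grid_A), len(sim_grid_M)))
    for i, tau_A in enumerate(sim_grid_A):
        for j, tau_M in enumerate(sim_grid_M):
            prot = proteins_at(float(tau_A), float(tau_M))
            ranges = (
                max(float(np.max(v[0])) for v in prot.values()),
                max(float(np.max(v[1])) for v in prot.values()),
            )
            c_cell = rescale_params(c_ref, ref_ranges, ranges)
            conds = {}
            for name in names:
                d = inputs[name]
                pA, pM = prot[name]
                pA_free = regmodel.free_fliA(pA, pM, c_cell.K)
                tar = np.asarray(
                    regmodel.global_activity(d["f_const"], pA_free, c_cell)
                )
                eps = np.maximum(eps_rel * float(np.max(tar)), 1e-9)
                conds[name] = ConditionData(
                    time=d["time"],
                    f_target=tar,
                    epsilon=np.full_like(tar, eps),
                    x1=d["fliA"],
                    x2=d["flgM"],
                    f_const=d["f_const"],
                )
            res = fit_regulation(
                FitDataset(conds), "eq2_eq3", n_starts, seed, maxiter=maxiter
            )
            Q[i, j] = res.Q
    return HeatmapResult(axis_A=np.asarray(sim_grid_A), axis_M=np.asarray(sim_grid_M), Q=Q)


def alpha_misfit_scan(
    inputs,
    alphas: np.ndarray,
    c_ref: RegulationParams,
    half_lives: tuple[float, float] = (30.0, 18.0),
    n_starts: int = 5,
    seed: int = 0,
    eps_rel: float = 0.02,
    maxiter: int | None = None,
) -> HeatmapResult:
    """Misfit of the global-effects-ignoring fit over the strength α.

    For each α, tar activities are generated with the α-rescaled global
    prefactor from protein profiles at ``half_lives``; a model using those
    same protein concentrations but no global multiplier is then refit. At
    α = 0 the prefactor is constant and can be absorbed into (k0, k1), so
    the misfit is minimal there and grows with α.
    """
    from .reconstruct import protein_concentration

    alphas = np.asarray(alphas, dtype=float)
    if np.any(alphas < 0) or np.any(alphas > ALPHA_MAX):
        raise ValueError(f"alpha values must lie in [0, {ALPHA_MAX}]")
    names = list(inputs)
    prot = {}
    for name in names:
        d = inputs[name]
        prot[name] = tuple(
            protein_concentration(
                lambda t, d=d, k=k: np.interp(t, d["time"], d[k]),
                lambda t, d=d: np.interp(t, d["time"], d["mu"]),
                tau,
                p0=d.get(p0k, 0.0),
                t_eval=d["time"],
            ).p
            for k, tau, p0k in (
                ("fliA", half_lives[0], "p0_A"),
                ("flgM", half_lives[1], "p0_M"),
            )
        )
    fbar = float(np.mean(np.concatenate([inputs[n]["f_const"] for n in names])))
    Q = np.zeros(len(alphas))
    for i, a in enumerate(alphas):
        conds = {}
        for name in names:
            d = inputs[name]
            pA, pM = prot[name]
            pA_free = regmodel.free_fliA(pA, pM, c_ref.K)
            tar = np.asarray(
                regmodel.alpha_activity(d["f_const"], fbar, float(a), pA_free, c_ref)
            )
            eps = np.maximum(eps_rel * float(np.max(tar)), 1e-9)
            conds[name] = ConditionData(
                time=d["time"],
                f_target=tar,
                epsilon=np.full_like(tar, eps),
                x1=pA,
                x2=pM,
                f_const=None,
            )
        res = fit_regulation(
            FitDataset(conds), "eq1_eq2", n_starts, seed, maxiter=maxiter
        )
        Q[i] = res.Q
    return HeatmapResult(axis_A=alphas, axis_M=None, Q=Q)
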