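"""Mechanistic promoter regulation functions for the FliA-FlgM module.

The sigma factor FliA activates class-3 motility promoters (such as p*tar*);
the anti-sigma factor FlgM sequesters FliA in an inactive complex. Under a
quasi-equilibrium assumption for the association/dissociation reaction, the
free FliA concentration follows from total FliA, total FlgM and the
dissociation constant ``K`` by mass action. Promoter activity is a Hill
function of free FliA, optionally multiplied by the activity of a
constitutive promoter that reads out the global state of the gene expression
machinery.

All concentrations are in RFU, activities in RFU·min⁻¹ (the arbitrary scale
of GFP reporter measurements).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RegulationParams",
    "free_fliA",
    "hill_activity",
    "global_activity",
    "alpha_activity",
]

ALPHA_MAX = 1.25  # larger rescalings can drive the activity prefactor negative


@dataclass(frozen=True)
class RegulationParams:
    """Parameters c = (k0, k1, n, theta, K) of the regulation function.

    k0 : basal synthesis rate [RFU·min⁻¹]
    k1 : maximal minus basal synthesis rate [RFU·min⁻¹]
    n : Hill exponent (dimensionless, ≥ 1)
    theta : activation threshold [RFU]
    K : FliA-FlgM dissociation constant [RFU]
    """

    k0: float
    k1: float
    n: float
    theta: float
    K: float

    def __post_init__(self) -> None:
        if min(self.k0, self.k1, self.theta, self.K) < 0:
            raise ValueError("k0, k1, theta and K must be non-negative")
        if self.n < 1:
            raise ValueError(f"Hill exponent n must be >= 1, got {self.n}")

    def as_array(self) -> np.ndarray:
        return np.array([self.k0, self.k1, self.n, self.theta, self.K])

    @classmethod
    def from_array(cls, c: np.ndarray) -> "RegulationParams":
        return cls(*(float(v) for v in c))


def free_fliA(pA, pM, K):
    """Free FliA concentration at the FliA-FlgM binding quasi-equilibrium.

    Solves the mass-action equilibrium for the uncomplexed sigma factor:

        pA_free = ½·(−b + √(b² + 4·K·pA)),   b = K + pM − pA.

    When ``b`` is large and positive the quoted form loses precision to
    cancellation, so the algebraically equivalent conjugate form
    ``2·K·pA / (b + √(b² + 4·K·pA))`` is used there.

    Parameters are total FliA ``pA``, total FlgM ``pM`` and the dissociation
    constant ``K`` (all RFU, scalar or broadcastable arrays).
    Returns a value in ``[0, pA]``.
    """
    pA = np.asarray(pA, dtype=float)
    pM = np.asarray(pM, dtype=float)
    K = np.asarray(K, dtype=float)
    if np.any(pA < 0) or np.any(pM < 0) or np.any(K < 0):
        raise ValueError("pA, pM and K must be non-negative")
    b = K + pM - pA
    disc = np.sqrt(b * b + 4.0 * K * pA)
    direct = 0.5 * (-b + disc)
    with np.errstate(divide="ignore", invalid="ignore"):
        conjugate = np.where(b + disc > 0, 2.0 * K * pA / (b + disc), 0.0)
    out = np.where(b > 0, conjugate, direct)
    # guard against tiny negative round-off and overshoot beyond pA
    out = np.clip(out, 0.0, pA)
    if out.ndim == 0:
        return float(out)
    return out


def hill_activity(pA_free, c: RegulationParams):
    """Hill regulation function f = k0 + k1·pA_free^n / (θ^n + pA_free^n).

    Monotone nondecreasing in ``pA_free``, bounded in [k0, k0+k1]. The
    degenerate corner θ = 0, pA_free = 0 is defined as f = k0 (continuity
    along pA_free → 0 first).
    """
    x = np.asarray(pA_free, dtype=float)
    if np.any(x < 0):
        raise ValueError("pA_free must be non-negative")
    xn = np.power(x, c.n)
    tn = c.theta**c.n
    denom = tn + xn
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denom > 0, xn / denom, 0.0)
    out = c.k0 + c.k1 * ratio
    if out.ndim == 0:
        return float(out)
    return out


def global_activity(f_const, pA_free, c: RegulationParams):
    """Regulation function scaled by global physiological effects.

    Multiplies the Hill term by ``f_const``, the measured activity of a
    constitutive promoter (here phage λ pRM), which quantifies the activity
    of the gene expression machinery: f = f_const·(k0 + k1·h(pA_free)).
    """
    f_const = np.asarray(f_const, dtype=float)
    if np.any(f_const < 0):
        raise ValueError("f_const must be non-negative")
    out = f_const * hill_activity(pA_free, c)
    if out.ndim == 0:
        return float(out)
    return out


def alpha_activity(f_const, f_const_mean, alpha, pA_free, c: RegulationParams):
    """Regulation function with rescaled global-effect variability.

    The variations of ``f_const`` around its temporal mean across all
    conditions, ``f_const_mean``, are scaled by ``alpha`` in [0, 1.25]:

        f = (α·(f_const − f̄_const) + f̄_const) · (k0 + k1·h(pA_free))

    α = 0 freezes global effects at their mean, α = 1 recovers
    :func:`global_activity`. The upper bound avoids negative prefactors.
    """
    if not 0 <= alpha <= ALPHA_MAX:
        raise ValueError(f"alpha must lie in [0, {ALPHA_MAX}], got {alpha}")
    f_const = np.asarray(f_const, dtype=float)
    prefactor = alpha * (f_const - f_const_mean) + f_const_mean
    if np.any(prefactor < 0):
        raise ValueError(
            "rescaled global prefactor is negative; the alpha upper bound of "
            f"{ALPHA_MAX} exists to avoid this — reduce alpha"
        )
    out = prefactor * hill_activity(pA_free, c)
    if out.ndim == 0:
        return float(out)
    return out
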