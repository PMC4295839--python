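"""Monotone sign-pattern invalidation and minimal-pattern enumeration.

A sign pattern assigns each candidate regulator a role: +1 (activator),
−1 (repressor) or 0 (no effect). Under the assumption that a promoter's
activity is monotone nondecreasing in its activators and nonincreasing in
its repressors, a pattern is *inconsistent* with time-series data if two
time points within one condition exist at which every signed regulator
moved in the direction that should not decrease the target, yet the target
activity decreased — beyond noise tolerances derived from the 2·SEM bands.
Patterns that survive are *consistent*; a consistent pattern is *minimal*
if zeroing any of its nonzero entries breaks consistency (while adding
regulators always preserves it).

With m regulators there are 3^m candidate patterns; here m = 3 (FliA,
FlgM, global physiology) so exhaustive enumeration is exact and cheap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SignPattern",
    "PatternVerdict",
    "SignData",
    "is_consistent",
    "minimal_sign_patterns",
    "classify_expected",
    "halflife_pattern_map",
    "single_pair_robustness",
]

MAX_REGULATORS = 8  # 3^m enumeration bound

EXPECTED_TAR = ("fliA", "flgM", "global")


@dataclass(frozen=True)
class SignPattern:
    """Entries in {−1, 0, +1}, one per named regulator (order fixed)."""

    entries: tuple
    regulators: tuple = ()

    def __post_init__(self) -> None:
        if any(e not in (-1, 0, 1) for e in self.entries):
            raise ValueError("sign pattern entries must be in {-1, 0, +1}")
        if self.regulators and len(self.regulators) != len(self.entries):
            raise ValueError("one entry per regulator required")

    def zeroed(self, i: int) -> "SignPattern":
        e = list(self.entries)
        e[i] = 0
        return SignPattern(tuple(e), self.regulators)


@dataclass
class PatternVerdict:
    pattern: SignPattern
    consistent: bool
    minimal: bool = False
    violating_pairs: list = field(default_factory=list)  # (condition, i, j)
    pairs_collected: bool = True  # False when the scan stopped at first violation

    def __post_init__(self) -> None:
        if self.consistent and self.violating_pairs:
            raise ValueError("consistent verdicts must have no violating pairs")
        if self.pairs_collected and not self.consistent and not self.violating_pairs:
            raise ValueError("inconsistent verdicts must report violating pairs")
        if self.minimal and not self.consistent:
            raise ValueError("minimal implies consistent")


@dataclass
class SignData:
    """Per-condition regulator and target series on shared grids.

    ``conditions`` maps a condition label to a dict with keys
    ``f`` (target activity), ``eps_f`` (its 2·SEM band, or zeros), ``X``
    (regulator name -> series) and optionally ``eps_X`` (regulator name ->
    band). All series within a condition share that condition's grid.
    """

    regulators: tuple
    conditions: dict

    def __post_init__(self) -> None:
        for name, cd in self.conditions.items():
            n = len(cd["f"])
            if len(cd.get("eps_f", cd["f"])) != n:
                raise ValueError(f"eps_f grid mismatch in condition {name!r}")
            for reg in self.regulators:
                if len(cd["X"][reg]) != n:
                    raise ValueError(
                        f"regulator {reg!r} not on the grid of condition {name!r}"
                    )


def _violation_matrix(pattern: Sequence[int], cd: Mapping, regulators) -> np.ndarray:
    """Boolean matrix V[i, j]: the ordered pair (t_i, t_j) violates the pattern."""
    f = np.asarray(cd["f"], dtype=float)
    eps_f = np.asarray(cd.get("eps_f", np.zeros_like(f)), dtype=float)
    tol_f = eps_f[:, None] + eps_f[None, :]
    # target decreased beyond tolerance from t_i to t_j
    drop = f[None, :] < f[:, None] - tol_f
    ok = np.ones_like(drop, dtype=bool)
    eps_X = cd.get("eps_X", {})
    for s, reg in zip(pattern, regulators):
        if s == 0:
            continue
        x = np.asarray(cd["X"][reg], dtype=float)
        ex = np.asarray(eps_X.get(reg, np.zeros_like(x)), dtype=float)
        tol_x = ex[:, None] + ex[None, :]
        move = s * (x[None, :] - x[:, None])
        ok &= move >= -tol_x
    return drop & ok


def is_consistent(
    pattern: SignPattern | Sequence[int],
    data: SignData,
    collect_pairs: bool = True,
) -> PatternVerdict:
    """Test a sign pattern against the monotonicity of the data.

    Only within-condition time-point pairs are compared. The empty pattern
    is consistent only with targets constant up to tolerance (a function of
    no regulators cannot change). Returns all violating pairs as
    (condition, i, j) index triples when ``collect_pairs``.
    """
    if not isinstance(pattern, SignPattern):
        pattern = SignPattern(tuple(pattern), tuple(data.regulators))
    if len(pattern.entries) != len(data.regulators):
        raise ValueError("pattern length must equal the number of regulators")
    pairs: list = []
    consistent = True
    for name, cd in data.conditions.items():
        V = _violation_matrix(pattern.entries, cd, data.regulators)
        if V.any():
            consistent = False
            if not collect_pairs:
                break
            for i, j in np.argwhere(V):
                pairs.append((name, int(i), int(j)))
    return PatternVerdict(
        pattern=pattern,
        consistent=consistent,
        violating_pairs=pairs,
        pairs_collected=collect_pairs,
    )


def minimal_sign_patterns(
    data: SignData, collect_pairs: bool = False
) -> list[SignPattern]:
    """All minimal consistent sign patterns, by exhaustive 3^m enumeration.

    Minimal: consistent, and zeroing any nonzero entry yields an
    inconsistent pattern. Adding regulators to a consistent pattern can
    only tighten the violation predicate, so consistency is monotone under
    adding signs — enumeration over all 3^m patterns is exact.
    """
    m = len(data.regulators)
    if m > MAX_REGULATORS:
        raise ValueError(
            f"enumeration limited to {MAX_REGULATORS} regulators, got {m}"
        )
    verdicts: dict[tuple, bool] = {}
    for entries in itertools.product((-1, 0, 1), repeat=m):
        verdicts[entries] = is_consistent(
            SignPattern(entries, tuple(data.regulators)), data, collect_pairs=False
        ).consistent
    minimal = []
    for entries, ok in verdicts.items():
        if not ok:
            continue
        if all(
            not verdicts[tuple(0 if k == i else e for k, e in enumerate(entries))]
            for i in range(m)
            if entries[i] != 0
        ):
            minimal.append(SignPattern(entries, tuple(data.regulators)))
    return minimal


def classify_expected(data: SignData, expected: SignPattern | Sequence[int]) -> str:
    """Verdict for an expected pattern: 'green', 'yellow' or 'red'.

    green — expected pattern is among the minimal sign patterns;
    yellow — consistent with the data but not minimal;
    red — inconsistent with the data.
    """
    if not isinstance(expected, SignPattern):
        expected = SignPattern(tuple(expected), tuple(data.regulators))
    if not is_consistent(expected, data, collect_pairs=False).consistent:
        return "red"
    minimal = {p.entries for p in minimal_sign_patterns(data)}
    return "green" if expected.entries in minimal else "yellow"


def halflife_pattern_map(
    targets: Mapping[str, Mapping],
    profiles: Mapping[tuple[str, str, float], "object"],
    grid,
    expected: Sequence[int] = (1, -1, 1),
    regulators: tuple = EXPECTED_TAR,
) -> dict[tuple[str, float, float], str]:
    """Green/yellow/red classification over a FliA × FlgM half-life grid.

    ``targets`` maps condition to {"f": target activity, "eps_f": band,
    "f_const": constitutive activity, "time": grid}; ``profiles`` is the
    precomputed (regulator, condition, half_life) -> ProteinProfile map.
    For each (τ_A, τ_M) the expected pattern (FliA activator, FlgM
    repressor, global activator by default) is classified per condition and
    for the pooled data (key ``"Intersection"``), where one pattern must
    satisfy all conditions at once — a strictly more constraining test than
    intersecting individual verdicts, though pairs are still compared only
    within conditions.
    """
    out: dict[tuple[str, float, float], str] = {}
    values = [float(v) for v in grid]
    names = list(targets)
    for tau_A in values:
        for tau_M in values:
            conds = {}
            for name in names:
                td = targets[name]
                t = np.asarray(td["time"], dtype=float)
                pA = profiles[("fliA", name, tau_A)]
                pM = profiles[("flgM", name, tau_M)]
                conds[name] = {
                    "f": td["f"],
                    "eps_f": td.get("eps_f", np.zeros_like(t)),
                    "X": {
                        "fliA": np.interp(t, pA.time, pA.p),
                        "flgM": np.interp(t, pM.time, pM.p),
                        "global": td["f_const"],
                    },
                }
            for name in names:
                data = SignData(regulators, {name: conds[name]})
                out[(name, tau_A, tau_M)] = classify_expected(data, expected)
            pooled = SignData(regulators, conds)
            out[("Intersection", tau_A, tau_M)] = classify_expected(pooled, expected)
    return out


def single_pair_robustness(verdict: PatternVerdict) -> dict:
    """Robustness diagnostic: is the invalidation carried by one pair only?

    An inconsistent verdict supported by a single violating measurement
    pair is fragile (one outlier could flip it) and is flagged.
    """
    if verdict.consistent:
        raise ValueError("robustness diagnostic applies to inconsistent verdicts")
    n = len(verdict.violating_pairs)
    return {"n_violating_pairs": n, "fragile": n == 1}
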