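"""Optimization objectives: gain, group coancestry, progeny inbreeding.

All objectives are functions of the proportional contribution vector ``x``
(``x >= 0``, ``sum(x) = 1``; gendered problems contribute 0.5 per role) and
the coancestry matrix ``C``:

* genetic gain ``x' a`` with ``a`` the standardized selection criterion;
* group coancestry ``x' C x`` — the expected mean coancestry (including
  self) of the future cohort, whose growth measures diversity loss;
* mean expected progeny inbreeding — the mean parental coancestry over the
  actual matings, which depends on mate allocation, unlike ``x' C x``.

Target balances between gain and coancestry can be stated as an absolute
coancestry, a rate of coancestry, a percentage of the achievable span, or
trigonometric degrees; :func:`resolve_coancestry_target` maps any of these
onto a single coancestry bound which is enforced as an exact penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MODES = ("max_gain", "min_coancestry", "min_inbreeding", "target", "frontier")
TARGET_FORMS = ("coancestry_value", "coancestry_rate", "percent_of_min", "degrees")


@dataclass
class ObjectiveValues:
    """Raw objective components plus the penalized scalar the evolver sees.

    ``scalar`` is oriented so that larger is better in every mode;
    ``penalty`` is zero for a plan satisfying all constraints and targets.
    """

    gain: float
    coancestry: float
    inbreeding: float
    penalty: float
    scalar: float

    def __float__(self) -> float:
        return self.scalar


@dataclass
class TargetSpec:
    """A gain/diversity balance target in one of four equivalent forms."""

    form: str
    value: float
    resolved_constraint: float | None = None

    def __post_init__(self) -> None:
        if self.form not in TARGET_FORMS:
            raise ValueError(f"unknown target form {self.form!r}")
        if self.form == "degrees" and not 0.0 <= self.value <= 90.0:
            raise ValueError("degrees target must lie in [0, 90]")
        if self.form == "percent_of_min" and not 0.0 <= self.value <= 100.0:
            raise ValueError("percent target must lie in [0, 100]")
        if self.form == "coancestry_rate" and not -1.0 < self.value < 1.0:
            raise ValueError("coancestry rate must lie in (-1, 1)")


def standardize_criterion(a: np.ndarray) -> np.ndarray:
    """Center and scale a criterion to mean 0, population SD 1."""
    a = np.asarray(a, dtype=float)
    if a.size < 2:
        raise ValueError("criterion needs at least two values")
    sd = float(a.std())
    if sd == 0.0:
        raise ValueError("criterion has zero variance")
    return (a - a.mean()) / sd


def genetic_gain(x: np.ndarray, a_std: np.ndarray) -> float:
    """Expected mean standardized merit of the next cohort, ``x' a``."""
    return float(np.dot(x, a_std))


def group_coancestry(x: np.ndarray, C: np.ndarray) -> float:
    """Group coancestry ``x' C x`` of contribution proportions ``x``."""
    return float(x @ C @ x)


def mean_progeny_inbreeding(matings: np.ndarray, C: np.ndarray) -> float:
    """Mean parental coancestry over matings = expected progeny inbreeding.

    ``matings`` is an ``(M, 2)`` integer array of candidate indices; a
    selfing pair ``(i, i)`` contributes the self-coancestry ``C[i, i]``.
    """
    m = np.asarray(matings)
    return float(C[m[:, 0], m[:, 1]].mean())


def resolve_coancestry_target(
    target: TargetSpec,
    c_min: float,
    c_at_gmax: float,
    c_current: float | None = None,
) -> float:
    """Convert any target form into an absolute coancestry bound ``C*``.

    Degrees measure the position along the normalized frontier span from
    the pure-gain solution: ``C* = C_min + cos(theta) * (C_at_Gmax -
    C_min)``, so 0 degrees is the unconstrained max-gain solve and 90
    degrees the pure-diversity solve.  Percent targets use the same span
    (``p = 0`` is ``C_min``).  Rate targets grow the current group
    coancestry: ``C* = C_cur + dC * (1 - C_cur)``.

    The resolved bound is clamped into ``[C_min, C_at_Gmax]``.
    """
    if c_at_gmax < c_min - 1e-9:
        raise ValueError("degenerate objective bounds: C_at_Gmax < C_min")
    span = c_at_gmax - c_min
    if target.form == "coancestry_value":
        c = target.value
    elif target.form == "coancestry_rate":
        if c_current is None:
            raise ValueError("rate target requires the current group coancestry")
        c = c_current + target.value * (1.0 - c_current)
    elif target.form == "percent_of_min":
        c = c_min + (target.value / 100.0) * span
    else:  # degrees
        c = c_min + np.cos(np.deg2rad(target.value)) * span
    return float(min(max(c, c_min), c_at_gmax))


def penalized_objective(
    gain: float,
    coancestry: float,
    inbreeding: float,
    violations: float,
    *,
    mode: str,
    n_matings: int,
    penalty_weight: float = 1e4,
    target_coancestry: float | None = None,
    span: float | None = None,
) -> tuple[float, float]:
    """Scalarize the objectives for one mode; returns ``(scalar, penalty)``.

    The scalar is maximized.  Residual constraint breaches (``violations``,
    counts left after repair) are normalized by the number of matings; in
    target mode the coancestry excess over ``C*`` is normalized by the
    frontier span so the penalty weight is portable across problems.
    """
    if mode not in ("max_gain", "min_coancestry", "min_inbreeding", "target"):
        raise ValueError(f"unknown optimization mode {mode!r}")
    w = penalty_weight
    penalty = w * violations / n_matings
    if mode == "max_gain":
        base = gain
    elif mode == "min_coancestry":
        base = -coancestry
    elif mode == "min_inbreeding":
        base = -inbreeding
    else:
        if target_coancestry is None:
            raise ValueError("target mode requires a resolved coancestry bound")
        s = span if span is not None and span > 1e-12 else 1.0
        penalty += w * max(0.0, coancestry - target_coancestry) / s
        base = gain
    return base - penalty, penalty
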