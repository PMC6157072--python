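"""Two-step multi-objective optimization of gain versus group coancestry.

Following the epsilon-constraint recipe: first solve the two single
objectives separately (max gain, min coancestry) to find the bounds of the
objective space and the normalization span; then maximize gain subject to
a coancestry bound ``C*`` — expressed through an exact penalty — either
for one targeted balance or swept over a grid of trigonometric degrees to
trace the whole Pareto frontier.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .encoding import MatingPlan
from .evolver import DEConfig, OptLog, evolve
from .objectives import TargetSpec, resolve_coancestry_target
from .problem import MatingProblem


@dataclass
class ObjectiveBounds:
    """Corners of the gain/coancestry objective space."""

    g_max: float
    c_at_gmax: float
    c_min: float
    g_at_cmin: float

    @property
    def span(self) -> float:
        return self.c_at_gmax - self.c_min

    @property
    def gain_span(self) -> float:
        return self.g_max - self.g_at_cmin


@dataclass
class FrontierPoint:
    """One solution on (or near) the Pareto frontier."""

    degrees: float
    gain: float
    coancestry: float
    inbreeding: float
    gain_norm: float
    coancestry_norm: float
    plan: MatingPlan
    log: OptLog | None = None
    constraint_met: bool = True


def _point(problem: MatingProblem, plan: MatingPlan, bounds: ObjectiveBounds,
           degrees: float, log: OptLog | None = None,
           target_c: float | None = None) -> FrontierPoint:
    vals = problem.evaluate_plan(plan, "min_coancestry")  # any mode: raw parts
    gspan = bounds.gain_span if abs(bounds.gain_span) > 1e-12 else 1.0
    cspan = bounds.span if abs(bounds.span) > 1e-12 else 1.0
    met = True
    if target_c is not None:
        met = vals.coancestry <= target_c + 1e-6 * max(cspan, 1e-12)
    gain = problem.plan_gain(plan)
    return FrontierPoint(
        degrees=degrees,
        gain=gain,
        coancestry=vals.coancestry,
        inbreeding=vals.inbreeding,
        gain_norm=(gain - bounds.g_at_cmin) / gspan,
        coancestry_norm=(vals.coancestry - bounds.c_min) / cspan,
        plan=plan,
        log=log,
        constraint_met=met,
    )


def find_bounds(
    problem: MatingProblem, config: DEConfig
) -> tuple[ObjectiveBounds, dict[str, tuple[MatingPlan, OptLog]]]:
    """Solve max-gain and min-coancestry separately under one constraint set.

    Returns the bounds and the two solutions (keyed ``"max_gain"`` and
    ``"min_coancestry"``); the two solves use consecutive derived seeds.
    """
    zg, log_g = evolve(problem.objective("max_gain"), problem.dim, config)
    cfg2 = replace(config, seed=config.seed + 1)
    zc, log_c = evolve(problem.objective("min_coancestry"), problem.dim, cfg2)
    plan_g = problem.decode(zg)
    plan_c = problem.decode(zc)
    vg = problem.evaluate_plan(plan_g, "max_gain")
    vc = problem.evaluate_plan(plan_c, "min_coancestry")
    bounds = ObjectiveBounds(
        g_max=vg.gain, c_at_gmax=vg.coancestry,
        c_min=vc.coancestry, g_at_cmin=vc.gain,
    )
    return bounds, {"max_gain": (plan_g, log_g), "min_coancestry": (plan_c, log_c)}


def solve_target(
    problem: MatingProblem,
    target: TargetSpec,
    config: DEConfig,
    bounds: ObjectiveBounds | None = None,
) -> FrontierPoint:
    """Maximize gain under the coancestry bound the target resolves to."""
    if bounds is None:
        bounds, _ = find_bounds(problem, config)
    c_current = None
    if target.form == "coancestry_rate":
        c_current = problem.uniform_group_coancestry()
    c_star = resolve_coancestry_target(target, bounds.c_min, bounds.c_at_gmax, c_current)
    target.resolved_constraint = c_star
    obj = problem.objective("target", target_coancestry=c_star, span=bounds.span)
    z, log = evolve(obj, problem.dim, config)
    plan = problem.decode(z)
    degrees = target.value if target.form == "degrees" else float("nan")
    return _point(problem, plan, bounds, degrees, log, target_c=c_star)


def sweep_frontier(
    problem: MatingProblem,
    steps: int,
    config: DEConfig,
    bounds: ObjectiveBounds | None = None,
    solutions: dict | None = None,
) -> list[FrontierPoint]:
    """Trace the Pareto frontier over ``steps`` degree targets in [0, 90].

    The endpoint targets reuse the bound solutions (guaranteeing endpoint
    consistency); each interior target gets a seed derived from the base
    seed and its angle so points are independent yet reproducible.  Pass
    ``solutions`` (as returned by :func:`find_bounds`) along with
    ``bounds`` to keep endpoint reuse with precomputed bounds.
    """
    if steps < 2:
        raise ValueError("a frontier needs at least 2 steps")
    sols = solutions
    if bounds is None:
        bounds, sols = find_bounds(problem, config)
    if abs(bounds.span) < 1e-12:
        # degenerate objective space: single point
        if sols is None:
            bounds, sols = find_bounds(problem, config)
        plan, log = sols["max_gain"]
        return [_point(problem, plan, bounds, 0.0, log)]
    thetas = np.linspace(0.0, 90.0, steps)
    points: list[FrontierPoint] = []
    for theta in thetas:
        if sols is not None and theta in (0.0, 90.0):
            key = "max_gain" if theta == 0.0 else "min_coancestry"
            plan, log = sols[key]
            c_star = bounds.c_at_gmax if theta == 0.0 else bounds.c_min
            points.append(_point(problem, plan, bounds, float(theta), log,
                                 target_c=c_star))
            continue
        cfg = replace(config, seed=config.seed + int(round(theta * 1000)))
        points.append(
            solve_target(problem, TargetSpec("degrees", float(theta)), cfg, bounds)
        )
    return sorted(points, key=lambda p: p.degrees)


def pareto_filter(points: list[FrontierPoint], tol: float = 1e-9) -> list[FrontierPoint]:
    """Drop points dominated by another (gain >= and coancestry <=, one strict)."""
    kept: list[FrontierPoint] = []
    ordered = sorted(points, key=lambda p: (p.degrees if np.isfinite(p.degrees) else 1e9))
    for p in ordered:
        dominated = False
        for q in ordered:
            if q is p:
                continue
            if (
                q.gain >= p.gain - tol
                and q.coancestry <= p.coancestry + tol
                and (q.gain > p.gain + tol or q.coancestry < p.coancestry - tol)
            ):
                dominated = True
                break
        if not dominated and not any(
            abs(k.gain - p.gain) <= tol and abs(k.coancestry - p.coancestry) <= tol
            for k in kept
        ):
            kept.append(p)
    return kept
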