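"""Run orchestration: spec -> problem -> optimization -> output files."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import io as mio
from .coancestry import coancestry_from_markers, coancestry_from_pedigree
from .data import CandidateSet, CoancestryMatrix, DataError, MatingConstraints, RoleLimits
from .editing import EditConfig
from .encoding import MatingPlan
from .evolver import DEConfig, OptLog, evolve
from .frontier import FrontierPoint, ObjectiveBounds, find_bounds, solve_target, sweep_frontier
from .objectives import ObjectiveValues, TargetSpec
from .problem import MatingProblem


@dataclass
class RunResult:
    mode: str
    problem: MatingProblem
    seed: int
    plan: MatingPlan | None = None
    values: ObjectiveValues | None = None
    log: OptLog | None = None
    bounds: ObjectiveBounds | None = None
    target: TargetSpec | None = None
    frontier: list[FrontierPoint] | None = None


def build_problem(spec: mio.RunSpec) -> MatingProblem:
    """Read the input files a spec names and assemble the problem."""
    cand = mio.read_candidates(spec.candidate_file)
    if spec.matrix_file is not None:
        C = mio.read_coancestry_matrix(spec.matrix_file, cand.ids)
    elif spec.pedigree_file is not None:
        ped = mio.read_pedigree(spec.pedigree_file)
        C = coancestry_from_pedigree(ped).aligned_to(cand.ids, strict=False)
    else:
        gids, G = mio.read_genotypes(spec.genotype_file)
        C = coancestry_from_markers(G, gids).aligned_to(cand.ids)
    constraints = _constraints_from_spec(spec, cand)
    edit = None
    if spec.edit_budget > 0:
        editable = cand.males if cand.gendered else np.arange(cand.n)
        edit = EditConfig(budget=spec.edit_budget, editable=editable)
    return MatingProblem(cand, C, constraints, edit=edit,
                         penalty_weight=spec.penalty_weight)


def _constraints_from_spec(spec: mio.RunSpec, cand: CandidateSet) -> MatingConstraints:
    if cand.gendered:
        male = RoleLimits(
            spec.max_parents_male if spec.max_parents_male is not None else spec.max_parents,
            spec.min_contrib, spec.max_contrib,
        )
        female = RoleLimits(
            spec.max_parents_female if spec.max_parents_female is not None else spec.max_parents,
            spec.min_contrib, spec.max_contrib,
        )
        return MatingConstraints.gendered(spec.n_matings, male=male, female=female)
    return MatingConstraints.generic(
        spec.n_matings,
        max_parents=spec.max_parents,
        min_contrib=spec.min_contrib,
        max_contrib=spec.max_contrib,
        allow_selfing=spec.allow_selfing,
    )


def de_config_from_spec(spec: mio.RunSpec, seed: int) -> DEConfig:
    return DEConfig(
        pop_size=spec.pop_size,
        iterations=spec.iterations,
        F_range=spec.F_range,
        CR_values=spec.CR_values,
        tol=spec.tol,
        window=spec.window,
        seed=seed,
    )


def run(spec: mio.RunSpec, seed: int | None = None) -> RunResult:
    """Execute the optimization a spec describes; no files are written."""
    if seed is None:
        seed = spec.seed
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31 - 1))
    problem = build_problem(spec)
    config = de_config_from_spec(spec, seed)
    mode = spec.mode
    result = RunResult(mode=mode, problem=problem, seed=seed, target=spec.target)

    if mode in ("max_gain", "min_coancestry", "min_inbreeding"):
        z, log = evolve(problem.objective(mode), problem.dim, config)
        result.plan = problem.decode(z)
        result.values = problem.evaluate_plan(result.plan, mode)
        result.log = log
    elif mode == "target":
        if spec.target is None:
            raise DataError("mode Target requires a target keyword")
        bounds, _ = find_bounds(problem, config)
        point = solve_target(problem, spec.target, config, bounds)
        result.bounds = bounds
        result.plan = point.plan
        result.log = point.log
        result.values = problem.evaluate_plan(
            point.plan, "target",
            target_coancestry=spec.target.resolved_constraint, span=bounds.span,
        )
    elif mode == "frontier":
        bounds, sols = find_bounds(problem, config)
        points = sweep_frontier(problem, spec.frontier_steps, config, bounds, sols)
        result.bounds = bounds
        result.frontier = points
        # representative single plan: the mid-frontier point
        mid = points[len(points) // 2]
        result.plan = mid.plan
        result.log = mid.log if mid.log is not None else sols["max_gain"][1]
        result.values = problem.evaluate_plan(mid.plan, "min_coancestry")
    else:
        raise DataError(f"unknown mode {mode!r}")
    return result


def run_and_write(spec: mio.RunSpec, seed: int | None = None) -> tuple[RunResult, list[str]]:
    """Run the optimization and write the standard output files."""
    result = run(spec, seed)
    files = mio.write_results(result, spec)
    return result, files
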