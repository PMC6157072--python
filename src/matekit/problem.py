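"""Problem container tying candidates, coancestry, constraints and editing.

:class:`MatingProblem` owns the standardized criterion vectors, decodes
chromosomes into plans and evaluates the penalized scalar objective for a
given mode.  It is the single object the evolver and the frontier driver
operate on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CandidateSet, CoancestryMatrix, DataError, MatingConstraints
from .editing import EditConfig, gain_with_edits
from .encoding import MatingPlan, chromosome_dim, decode, validate_constraints
from .objectives import (
    ObjectiveValues,
    mean_progeny_inbreeding,
    penalized_objective,
    standardize_criterion,
)


@dataclass
class MatingProblem:
    candidates: CandidateSet
    coancestry: CoancestryMatrix
    constraints: MatingConstraints
    edit: EditConfig | None = None
    penalty_weight: float = 1e4

    def __post_init__(self) -> None:
        if self.coancestry.ids != self.candidates.ids:
            self.coancestry = self.coancestry.aligned_to(self.candidates.ids)
        problems = validate_constraints(self.constraints, self.candidates)
        if problems:
            raise DataError("infeasible mating constraints: " + "; ".join(problems))
        self.C = self.coancestry.values
        if self.candidates.criterion is not None:
            a = np.asarray(self.candidates.criterion, float)
            self._a_mean, self._a_sd = float(a.mean()), float(a.std())
            self.a_std = standardize_criterion(a)
        else:
            self._a_mean = self._a_sd = 0.0
            self.a_std = None
        self.a_std_edited = None
        if self.edit is not None and self.edit.budget > 0:
            ae = self.candidates.criterion_edited
            if ae is None:
                raise DataError("editing enabled but candidates lack an edited criterion")
            # same location/scale as the non-edited criterion, by design
            self.a_std_edited = (np.asarray(ae, float) - self._a_mean) / self._a_sd

    @property
    def n_editable(self) -> int:
        return self.edit.editable.size if self.edit is not None and self.edit.budget > 0 else 0

    @property
    def dim(self) -> int:
        return chromosome_dim(self.candidates, self.constraints, self.n_editable)

    def decode(self, z: np.ndarray) -> MatingPlan:
        editable = self.edit.editable if self.n_editable else None
        budget = self.edit.budget if self.n_editable else 0
        return decode(z, self.candidates, self.constraints, editable, budget)

    def plan_gain(self, plan: MatingPlan) -> float:
        if self.a_std is None:
            return 0.0
        if self.a_std_edited is not None:
            return gain_with_edits(plan.x, self.a_std, self.a_std_edited, plan.edited)
        return float(np.dot(plan.x, self.a_std))

    def evaluate_plan(
        self,
        plan: MatingPlan,
        mode: str,
        target_coancestry: float | None = None,
        span: float | None = None,
    ) -> ObjectiveValues:
        gain = self.plan_gain(plan)
        nz = np.flatnonzero(plan.n_contrib)
        xs = plan.x[nz]
        coa = float(xs @ self.C[np.ix_(nz, nz)] @ xs)
        inb = mean_progeny_inbreeding(plan.matings, self.C)
        scalar, penalty = penalized_objective(
            gain, coa, inb, plan.violations,
            mode=mode, n_matings=self.constraints.n_matings,
            penalty_weight=self.penalty_weight,
            target_coancestry=target_coancestry, span=span,
        )
        return ObjectiveValues(gain=gain, coancestry=coa, inbreeding=inb,
                               penalty=penalty, scalar=scalar)

    def objective(
        self,
        mode: str,
        target_coancestry: float | None = None,
        span: float | None = None,
    ):
        """Chromosome -> :class:`ObjectiveValues` closure for the evolver."""
        if mode in ("max_gain", "target") and self.a_std is None:
            raise DataError(f"mode {mode!r} requires a selection criterion")

        def _objective(z: np.ndarray) -> ObjectiveValues:
            return self.evaluate_plan(self.decode(z), mode, target_coancestry, span)

        return _objective

    def uniform_group_coancestry(self) -> float:
        """Group coancestry under uniform contributions from all candidates
        (the default reference point for rate-of-coancestry targets)."""
        x = np.full(self.candidates.n, 1.0 / self.candidates.n)
        return float(x @ self.C @ x)
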