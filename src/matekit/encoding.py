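"""Chromosome <-> mating-plan decoding.

A mating plan is encoded as a real-valued chromosome in the style of
Kinghorn's mate-selection representation: one block of contribution genes
per role (ranking decides who contributes and how much), one block of
mate-permutation keys (argsort decides who mates whom), and, when genome
editing is enabled, one block of edit-rank genes.

The decoder is *total*: every real vector decodes to a plan whose per-role
contribution sums are exact.  Constraint breaches that cannot be repaired
deterministically (trim/round to limits, selfing swap pass) are counted in
``MatingPlan.violations`` and penalized by the objective, never raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np

from .data import CandidateSet, MatingConstraints, RoleLimits


@dataclass
class MatingPlan:
    """A decoded plan: matings, contribution counts and proportions.

    ``matings`` holds candidate indices into the originating
    :class:`~matekit.data.CandidateSet`; ``n_contrib`` are integer
    contribution counts per candidate (summing to the number of parent
    slots per role); ``x`` are proportional contributions summing to 1
    overall (0.5 per role in gendered mode).
    """

    matings: np.ndarray
    n_contrib: np.ndarray
    x: np.ndarray
    violations: float = 0.0
    edited: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def chromosome_dim(candidates: CandidateSet, constraints: MatingConstraints,
                   n_editable: int = 0) -> int:
    """Total chromosome length for a problem."""
    M = constraints.n_matings
    if constraints.is_gendered:
        contrib = len(candidates.males) + len(candidates.females)
        mate = M
    else:
        contrib = candidates.n
        mate = 2 * M
    return contrib + mate + n_editable


def integerize_contributions(
    genes: np.ndarray,
    limits: RoleLimits,
    n_slots: int,
    *,
    min_parents: int = 1,
) -> tuple[np.ndarray, float]:
    """Rank, trim and round contribution genes to integers summing to ``n_slots``.

    The decoding is scale-invariant: only the ranks and the positive parts
    of the genes matter.  Candidates are ranked by gene value (ties broken
    by index); the number of parents kept adapts to how many genes are
    positive, bounded by ``max_parents`` and by what the contribution cap
    requires.  Raw shares are the positive gene parts normalized over the
    kept set (uniform if none is positive); targets are the shares scaled
    to ``n_slots``, trimmed to ``[min_contrib, max_contrib]`` and rounded
    by largest remainder so the total is exact.  Rounding increments only
    candidates below the cap and decrements only those above the floor;
    when the limits make that impossible the forced units are counted as
    violations.

    Returns
    -------
    (counts, violations)
        ``counts`` has one integer per candidate in the role (role-local
        indexing); ``violations`` is the number of forced limit breaches.
    """
    genes = np.asarray(genes, dtype=float)
    n = genes.size
    max_p = limits.max_parents if limits.max_parents is not None else n
    max_c = limits.max_contrib if limits.max_contrib is not None else n_slots
    min_c = limits.min_contrib

    order = np.argsort(-genes, kind="stable")
    n_pos = int(np.count_nonzero(genes > 0))
    need = ceil(n_slots / max_c)
    # genes switch parents on/off; all-off falls back to the full kept width
    width = n_pos if n_pos > 0 else min(max_p, n, n_slots)
    keep = min(max_p, n, n_slots, max(width, need, min_parents))
    if min_c > 0:
        # the contribution floor binds every kept parent: never keep more
        # parents than the floor allows (deselection is not a breach)
        keep = min(keep, n_slots // min_c) if n_slots >= min_c else keep
    keep = max(keep, 1)
    kept = order[:keep]

    u = np.maximum(genes[kept], 0.0)
    tot = u.sum()
    shares = u / tot if tot > 0 else np.full(keep, 1.0 / keep)
    t = np.clip(shares * n_slots, min_c, max_c)
    base = np.floor(t).astype(int)
    rem = t - base

    violations = 0.0
    b = base.tolist()
    diff = n_slots - sum(b)
    # kept is already in rank order: position == rank priority.  Each unit
    # goes to the largest remainder still below the cap (ties favour the
    # higher-ranked parent); remainders cycle by whole passes, so a pass
    # in the initial remainder order is equivalent to unit-by-unit picks.
    if diff > 0:
        inc_order = sorted(range(keep), key=lambda i: (-rem[i], i))
        while diff > 0:
            progressed = False
            for i in inc_order:
                if diff == 0:
                    break
                if b[i] < max_c:
                    b[i] += 1
                    diff -= 1
                    progressed = True
            if not progressed:  # cap binds everywhere: forced breach
                b[0] += 1
                diff -= 1
                violations += 1.0
    elif diff < 0:
        # smallest remainder first; ties drop the lowest-ranked parent
        dec_order = sorted(range(keep), key=lambda i: (rem[i], -i))
        while diff < 0:
            progressed = False
            for i in dec_order:
                if diff == 0:
                    break
                if b[i] > min_c:
                    b[i] -= 1
                    diff += 1
                    progressed = True
            if not progressed:  # floor binds: forced breach
                for i in reversed(range(keep)):
                    if b[i] > 0:
                        b[i] -= 1
                        diff += 1
                        violations += 1.0
                        break
    base = np.array(b, dtype=int)

    counts = np.zeros(n, dtype=int)
    counts[kept] = base
    return counts, violations


def allocate_mates_gendered(
    n_male: np.ndarray, n_female: np.ndarray, mate_genes: np.ndarray
) -> np.ndarray:
    """Pair male and female parent slots using permutation keys.

    Male slots are the males repeated by contribution in candidate order;
    likewise female slots.  Mating ``k`` pairs male slot ``k`` with female
    slot ``perm[k]`` where ``perm`` is the stable argsort of the keys.
    Returns an ``(M, 2)`` array of role-local indices.
    """
    male_slots = np.repeat(np.arange(n_male.size), n_male)
    female_slots = np.repeat(np.arange(n_female.size), n_female)
    if male_slots.size != female_slots.size or male_slots.size != mate_genes.size:
        raise ValueError("slot counts and mate genes must all equal the number of matings")
    perm = np.argsort(mate_genes, kind="stable")
    return np.column_stack([male_slots, female_slots[perm]])


def allocate_mates_generic(n_contrib: np.ndarray, mate_genes: np.ndarray) -> np.ndarray:
    """Pair the ``2M`` generic parent slots after permuting them.

    The full slot list (candidates repeated by contribution, candidate
    order) is permuted by the stable argsort of the ``2M`` keys and read
    off two slots per mating, so every perfect matching of the slot
    multiset is reachable.
    """
    slots = np.repeat(np.arange(n_contrib.size), n_contrib)
    if slots.size != mate_genes.size:
        raise ValueError("mate genes must have one key per parent slot")
    perm = np.argsort(mate_genes, kind="stable")
    return slots[perm].reshape(-1, 2)


def repair_selfing(matings: np.ndarray, allow_selfing: bool) -> tuple[np.ndarray, float]:
    """Deterministically swap away selfing pairs; count what remains.

    A single left-to-right pass: each selfing pair swaps second members
    with the first other mating for which the swap removes the selfing
    without creating a new one.  Irreparable selfings are returned as a
    violation count, to be penalized rather than raised.
    """
    if allow_selfing:
        return matings, 0.0
    m = matings.copy()
    violations = 0.0
    for k in range(m.shape[0]):
        if m[k, 0] != m[k, 1]:
            continue
        for j in range(m.shape[0]):
            if j == k:
                continue
            if m[j, 1] != m[k, 0] and m[j, 0] != m[k, 1]:
                m[k, 1], m[j, 1] = m[j, 1], m[k, 1]
                break
        else:
            violations += 1.0
    return m, violations


def decode(
    z: np.ndarray,
    candidates: CandidateSet,
    constraints: MatingConstraints,
    editable: np.ndarray | None = None,
    edit_budget: int = 0,
) -> MatingPlan:
    """Decode a chromosome into a mating plan (deterministic, total).

    Composes per-role contribution integerization, mate allocation by
    permutation keys, the selfing repair pass and, when editing is
    enabled, edit-rank decoding (see :mod:`matekit.editing`).
    """
    from .editing import decode_edits  # local import to avoid a cycle

    z = np.asarray(z, dtype=float)
    M = constraints.n_matings
    n = candidates.n
    n_edit = editable.size if editable is not None else 0
    if z.size != chromosome_dim(candidates, constraints, n_edit):
        raise ValueError("chromosome length does not match problem dimension")

    n_contrib = np.zeros(n, dtype=int)
    violations = 0.0
    if constraints.is_gendered:
        males, females = candidates.males, candidates.females
        gm = z[: males.size]
        gf = z[males.size: males.size + females.size]
        cm, vm = integerize_contributions(gm, constraints.limits["male"], M)
        cf, vf = integerize_contributions(gf, constraints.limits["female"], M)
        n_contrib[males] = cm
        n_contrib[females] = cf
        violations += vm + vf
        mate_genes = z[males.size + females.size: males.size + females.size + M]
        local = allocate_mates_gendered(cm, cf, mate_genes)
        matings = np.column_stack([males[local[:, 0]], females[local[:, 1]]])
    else:
        min_parents = 2 if (not constraints.allow_selfing and n >= 2) else 1
        cg, vg = integerize_contributions(
            z[:n], constraints.limits["generic"], 2 * M, min_parents=min_parents
        )
        n_contrib[:] = cg
        violations += vg
        matings = allocate_mates_generic(cg, z[n: n + 2 * M])
        matings, vs = repair_selfing(matings, constraints.allow_selfing)
        violations += vs

    x = n_contrib / (2.0 * M)
    edited = np.empty(0, dtype=int)
    if editable is not None and edit_budget > 0:
        edited = decode_edits(z[z.size - n_edit:], n_contrib, editable, edit_budget)
    return MatingPlan(matings=matings, n_contrib=n_contrib, x=x,
                      violations=violations, edited=edited)


def validate_constraints(
    constraints: MatingConstraints, candidates: CandidateSet
) -> list[str]:
    """Check that a valid plan can exist; return all problems found."""
    problems: list[str] = []
    if constraints.is_gendered != candidates.gendered:
        problems.append("gendered constraints require gendered candidates (and vice versa)")
        return problems
    for role in constraints.roles:
        lim = constraints.limits[role]
        n_role = candidates.role_indices(role).size
        slots = constraints.slots(role)
        if n_role == 0:
            problems.append(f"no candidates in role {role!r}")
            continue
        max_p = lim.max_parents if lim.max_parents is not None else n_role
        max_c = lim.max_contrib if lim.max_contrib is not None else slots
        if max_p * max_c < slots:
            problems.append(
                f"role {role!r}: max_parents x max_contrib = {max_p * max_c} < {slots} slots"
            )
        if n_role * max_c < slots:
            problems.append(
                f"role {role!r}: {n_role} candidates x max_contrib {max_c} < {slots} slots"
            )
        if lim.min_contrib > 0:
            keep = min(max_p, n_role, slots, max(ceil(slots / max_c), 1))
            if lim.min_contrib == lim.max_contrib and slots % lim.min_contrib != 0:
                problems.append(
                    f"role {role!r}: equal contributions of {lim.min_contrib} "
                    f"do not divide {slots} slots"
                )
            elif keep * lim.min_contrib > slots:
                problems.append(
                    f"role {role!r}: minimum contributions force more than {slots} slots"
                )
    if (
        not constraints.is_gendered
        and not constraints.allow_selfing
        and candidates.n < 2
    ):
        problems.append("selfing disallowed but only one candidate available")
    return problems
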