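"""Synthetic populations, a brute-force oracle and a toy selection demo.

This module generates the test beds the rest of the package is exercised
on: random marker panels with additive merit (and the merit editing the
top unfavourable loci would give), random pedigrees under an
infinitesimal model, a brute-force enumerator of all valid mating plans
on tiny instances (the independent optimum the evolutionary search is
checked against), and a toy recurrent-selection simulation that compares
truncation selection with balanced gain/diversity optimization over
breeding cycles.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .data import CandidateSet, CoancestryMatrix, MatingConstraints, RoleLimits
from .coancestry import coancestry_from_markers
from .editing import EditConfig
from .encoding import MatingPlan, repair_selfing
from .evolver import DEConfig, evolve
from .frontier import ObjectiveBounds, solve_target
from .objectives import TargetSpec
from .problem import MatingProblem


@dataclass
class SyntheticConfig:
    """Sizes and rates of the synthetic populations.

    ``n_founders`` is both the founder count of pedigree simulations and
    the cohort size of single-cohort marker simulations.  Marker allele
    frequencies are drawn uniformly from ``freq_range``; per-locus effects
    are standard normal, rescaled so the genic variance is 1.
    ``n_edit_loci`` is how many top unfavourable loci editing repairs per
    individual.
    """

    n_founders: int = 32
    n_generations: int = 2
    n_per_generation: int = 32
    n_loci: int = 200
    freq_range: tuple[float, float] = (0.1, 0.9)
    n_edit_loci: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_founders, self.n_per_generation, self.n_loci) < 1:
            raise ValueError("population sizes and n_loci must be >= 1")
        lo, hi = self.freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("allele frequencies must lie in (0, 1)")


@dataclass
class Trajectory:
    """Per-cycle cohort statistics of a recurrent-selection scheme."""

    mean: np.ndarray
    genic_sd: np.ndarray
    scheme: str


def genic_sd(freqs: np.ndarray, effects: np.ndarray) -> float:
    """Genic standard deviation ``sqrt(sum 2 p (1-p) alpha^2)``."""
    p = np.asarray(freqs, float)
    a = np.asarray(effects, float)
    return float(np.sqrt(np.sum(2.0 * p * (1.0 - p) * a**2)))


def edited_criterion(G: np.ndarray, effects: np.ndarray, n_edit_loci: int) -> np.ndarray:
    """Merit after editing each individual's top unfavourable loci.

    The improvement available at a locus is ``|alpha| * (unfavourable
    dosage)`` — flipping the genotype to the favourable homozygote.  Each
    individual has its ``n_edit_loci`` largest improvements applied.
    """
    a = np.asarray(effects, float)
    unfav = np.where(a > 0, 2.0 - G, G)  # unfavourable allele count per locus
    improvement = np.abs(a) * unfav
    q = min(n_edit_loci, improvement.shape[1])
    if q == 0:
        return G @ a
    top = np.sort(improvement, axis=1)[:, -q:]
    return G @ a + top.sum(axis=1)


def simulate_marker_population(
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
    effects: np.ndarray | None = None,
) -> tuple[CandidateSet, np.ndarray, np.ndarray, np.ndarray]:
    """One unstructured cohort of genotyped candidates with additive merit.

    Returns ``(candidates, genotypes, effects, freqs)``.  Genotypes are
    independent per-locus ``Binomial(2, p_l)`` draws; the criterion is the
    true additive merit ``G @ alpha`` and the edited criterion applies
    :func:`edited_criterion`.  Effects may be supplied explicitly;
    otherwise they are drawn standard normal and scaled to genic variance
    1 at the drawn frequencies.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n, L = cfg.n_founders, cfg.n_loci
    p = rng.uniform(*cfg.freq_range, size=L)
    G = rng.binomial(2, p, size=(n, L)).astype(float)
    if effects is None:
        a = rng.standard_normal(L)
        gv = np.sum(2.0 * p * (1.0 - p) * a**2)
        a = a / np.sqrt(gv) if gv > 0 else a
    else:
        a = np.asarray(effects, float)
    crit = G @ a
    crit_ed = edited_criterion(G, a, cfg.n_edit_loci)
    ids = [f"I{k + 1}" for k in range(n)]
    cand = CandidateSet(ids, criterion=crit, criterion_edited=crit_ed)
    return cand, G, a, p


def simulate_pedigree_population(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[CandidateSet, list[tuple[str, str, str]]]:
    """Random pedigree under an infinitesimal additive model.

    Founders are unrelated with breeding values ``N(0, 1)``; each later
    generation draws random parent pairs from the previous one and a
    child's value is the parent mean plus a Mendelian-sampling deviate
    ``N(0, 0.5)`` (inbreeding adjustment of the sampling variance is
    deliberately omitted).  Returns all individuals as candidates plus
    the 3-column pedigree (``"0"`` marks unknown parents).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    ids: list[str] = []
    bv: list[float] = []
    pedigree: list[tuple[str, str, str]] = []
    prev: list[int] = []
    counter = 0
    for g in range(cfg.n_generations + 1):
        cur: list[int] = []
        size = cfg.n_founders if g == 0 else cfg.n_per_generation
        for _ in range(size):
            ident = f"P{counter + 1}"
            if g == 0:
                pedigree.append((ident, "0", "0"))
                bv.append(float(rng.standard_normal()))
            else:
                si, di = rng.choice(prev, size=2, replace=False)
                pedigree.append((ident, ids[si], ids[di]))
                bv.append(float((bv[si] + bv[di]) / 2.0
                                + rng.normal(0.0, np.sqrt(0.5))))
            ids.append(ident)
            cur.append(counter)
            counter += 1
        prev = cur
    cand = CandidateSet(ids, criterion=np.array(bv))
    return cand, pedigree


# ---------------------------------------------------------------------------
# Brute-force oracle


def _contribution_vectors(n: int, slots: int, lim) -> list[tuple[int, ...]]:
    max_p = lim.max_parents if lim.max_parents is not None else n
    max_c = lim.max_contrib if lim.max_contrib is not None else slots
    min_c = max(lim.min_contrib, 1)
    out: list[tuple[int, ...]] = []

    def rec(i: int, remaining: int, npos: int, cur: list[int]) -> None:
        if i == n:
            if remaining == 0:
                out.append(tuple(cur))
            return
        if remaining > (n - i) * max_c:
            return
        rec(i + 1, remaining, npos, cur + [0])
        if npos < max_p:
            for c in range(min_c, min(max_c, remaining) + 1):
                rec(i + 1, remaining - c, npos + 1, cur + [c])

    rec(0, slots, 0, [])
    return out


def _matchings(slots: tuple[int, ...]):
    """Distinct perfect matchings (as pair multisets) of a sorted slot tuple."""
    if not slots:
        yield ()
        return
    first, rest = slots[0], slots[1:]
    seen: set[int] = set()
    for k, partner in enumerate(rest):
        if partner in seen:
            continue
        seen.add(partner)
        for sub in _matchings(rest[:k] + rest[k + 1:]):
            yield ((first, partner),) + sub


def _distinct_perms(items: tuple[int, ...]):
    if not items:
        yield ()
        return
    prev = object()
    for k, v in enumerate(items):
        if v == prev:
            continue
        prev = v
        for rest in _distinct_perms(items[:k] + items[k + 1:]):
            yield (v,) + rest


def enumerate_valid_plans(problem: MatingProblem):
    """Yield every valid (violation-free) mating plan of a tiny problem.

    A plan is one integer contribution vector per role combined with one
    distinct mate pairing.  Selfing pairings are excluded when disallowed.
    """
    cons = problem.constraints
    cand = problem.candidates
    M = cons.n_matings
    if cand.n > 6 or M > 4:
        raise ValueError("instance too large for exhaustive enumeration")
    if cons.is_gendered:
        males, females = cand.males, cand.females
        vm = _contribution_vectors(males.size, M, cons.limits["male"])
        vf = _contribution_vectors(females.size, M, cons.limits["female"])
        for cm in vm:
            mslots = tuple(males[np.repeat(np.arange(males.size), cm)])
            for cf in vf:
                fslots = tuple(females[np.repeat(np.arange(females.size), cf)])
                n_contrib = np.zeros(cand.n, dtype=int)
                n_contrib[males] = cm
                n_contrib[females] = cf
                seen: set[tuple] = set()
                for perm in _distinct_perms(tuple(sorted(fslots))):
                    pairs = tuple(sorted(zip(mslots, perm)))
                    if pairs in seen:
                        continue
                    seen.add(pairs)
                    yield _plan(n_contrib, pairs, M)
    else:
        for cg in _contribution_vectors(cand.n, 2 * M, cons.limits["generic"]):
            slots = tuple(np.repeat(np.arange(cand.n), cg))
            n_contrib = np.array(cg, dtype=int)
            for pairing in _matchings(slots):
                if not cons.allow_selfing and any(a == b for a, b in pairing):
                    continue
                yield _plan(n_contrib, pairing, M)


def _plan(n_contrib: np.ndarray, pairs, M: int) -> MatingPlan:
    return MatingPlan(
        matings=np.array(pairs, dtype=int).reshape(M, 2),
        n_contrib=n_contrib.copy(),
        x=n_contrib / (2.0 * M),
        violations=0.0,
    )


def brute_force_optimum(
    problem: MatingProblem,
    mode: str,
    target_coancestry: float | None = None,
    span: float | None = None,
) -> tuple[float, list[MatingPlan]]:
    """Global optimum of the penalized scalar by exhaustive enumeration.

    Enumerates every valid plan (and, when editing is enabled, every
    admissible edit subset) and evaluates the *same* penalized scalar the
    evolver maximizes.  Returns the best scalar and all plans attaining
    it (within 1e-12).
    """
    best = -np.inf
    arg: list[MatingPlan] = []
    edit = problem.edit
    pairing_sensitive = mode == "min_inbreeding"
    seen_x: set[tuple] = set()
    for plan in enumerate_valid_plans(problem):
        if not pairing_sensitive:
            # scalar depends on the pairing only through inbreeding
            key = tuple(plan.n_contrib)
            if key in seen_x:
                continue
        for edited in _edit_subsets(plan, edit):
            plan.edited = edited
            s = problem.evaluate_plan(plan, mode, target_coancestry, span).scalar
            if s > best + 1e-12:
                best = s
                arg = [_copy_plan(plan)]
            elif s >= best - 1e-12:
                arg.append(_copy_plan(plan))
        if not pairing_sensitive:
            seen_x.add(tuple(plan.n_contrib))
    if not np.isfinite(best):
        raise ValueError("no valid mating plan exists under these constraints")
    return best, arg


def _edit_subsets(plan: MatingPlan, edit):
    if edit is None or edit.budget == 0:
        yield np.empty(0, dtype=int)
        return
    selected = [i for i in edit.editable if plan.n_contrib[i] > 0]
    r = min(edit.budget, len(selected))
    if r == 0:
        yield np.empty(0, dtype=int)
        return
    for sub in combinations(selected, r):
        yield np.array(sub, dtype=int)


def _copy_plan(plan: MatingPlan) -> MatingPlan:
    return MatingPlan(
        matings=plan.matings.copy(),
        n_contrib=plan.n_contrib.copy(),
        x=plan.x.copy(),
        violations=plan.violations,
        edited=plan.edited.copy(),
    )


def oracle_bounds(problem: MatingProblem) -> ObjectiveBounds:
    """Exact objective-space corners of a tiny instance by enumeration."""
    g_max, plans_g = brute_force_optimum(problem, "max_gain")
    neg_c, plans_c = brute_force_optimum(problem, "min_coancestry")
    c_at_gmax = min(
        problem.evaluate_plan(p, "min_coancestry").coancestry for p in plans_g
    )
    g_at_cmin = max(problem.plan_gain(p) for p in plans_c)
    return ObjectiveBounds(g_max=g_max, c_at_gmax=c_at_gmax,
                           c_min=-neg_c, g_at_cmin=g_at_cmin)


def random_tiny_problem(
    rng: np.random.Generator,
    *,
    with_editing: bool = False,
    gendered: bool | None = None,
) -> MatingProblem:
    """A random brute-forceable instance: small pedigree, random constraints.

    Candidates come from a two-generation random pedigree (so the
    coancestry matrix has real structure), constraints are drawn from the
    feasible combinations of matings, contribution limits (including
    equal-contribution cases), parent caps and selfing allowance.
    """
    from .coancestry import coancestry_from_pedigree

    for _ in range(1000):
        n = int(rng.integers(4, 7))
        cfg = SyntheticConfig(
            n_founders=max(2, n - int(rng.integers(1, 3))),
            n_generations=1, n_per_generation=n, seed=int(rng.integers(2**31 - 1)),
        )
        cand_all, ped = simulate_pedigree_population(cfg, rng)
        idx = rng.choice(cand_all.n, size=n, replace=False)
        ids = [cand_all.ids[i] for i in sorted(idx)]
        crit = cand_all.criterion[sorted(idx)]
        if np.std(crit) < 1e-9:
            continue
        C = coancestry_from_pedigree(ped).aligned_to(ids, strict=False)
        is_gendered = bool(rng.integers(0, 2)) if gendered is None else gendered
        M = int(rng.integers(2, 5))
        if is_gendered:
            gender = np.array([1 + (k % 2) for k in range(n)])
            cand = CandidateSet(ids, gender=gender, criterion=crit,
                                criterion_edited=crit + np.abs(rng.normal(0.5, 0.3, n)))
            lims = {}
            for role in ("male", "female"):
                max_c = int(rng.integers(1, 5))
                equal = rng.random() < 0.25
                if equal:
                    divisors = [c for c in range(1, min(max_c, M) + 1) if M % c == 0]
                    c = int(rng.choice(divisors))
                    lims[role] = RoleLimits(None, c, c)
                else:
                    lims[role] = RoleLimits(int(rng.integers(1, n)) or None, 0, max_c)
            cons = MatingConstraints(M, lims, allow_selfing=False)
        else:
            cand = CandidateSet(ids, criterion=crit,
                                criterion_edited=crit + np.abs(rng.normal(0.5, 0.3, n)))
            S = 2 * M
            max_c = int(rng.integers(1, 5))
            equal = rng.random() < 0.25
            allow_selfing = bool(rng.integers(0, 2))
            if equal:
                divisors = [c for c in range(1, min(max_c, S) + 1) if S % c == 0]
                c = int(rng.choice(divisors))
                cons = MatingConstraints.generic(M, min_contrib=c, max_contrib=c,
                                                 allow_selfing=allow_selfing)
            else:
                cons = MatingConstraints.generic(
                    M, max_parents=int(rng.integers(2, n + 1)),
                    max_contrib=max_c, allow_selfing=allow_selfing,
                )
        edit = None
        if with_editing:
            editable = cand.males if is_gendered else np.arange(n)
            if editable.size == 0:
                continue
            edit = EditConfig(budget=int(rng.integers(1, min(3, editable.size) + 1)),
                              editable=editable)
        from .encoding import validate_constraints

        if validate_constraints(cons, cand):
            continue
        try:
            prob = MatingProblem(cand, C, cons, edit=edit)
            next(iter(enumerate_valid_plans(prob)))
        except (ValueError, StopIteration):
            continue
        return prob
    raise RuntimeError("failed to draw a feasible tiny instance")


# ---------------------------------------------------------------------------
# Toy recurrent-selection demo


def _mate_progeny(
    G: np.ndarray, pairs: np.ndarray, n_progeny: int, rng: np.random.Generator
) -> np.ndarray:
    """Mendelian gamete sampling at unlinked loci for each cross."""
    out = []
    for p1, p2 in pairs:
        gam1 = rng.binomial(1, G[p1] / 2.0, size=(n_progeny, G.shape[1]))
        gam2 = rng.binomial(1, G[p2] / 2.0, size=(n_progeny, G.shape[1]))
        out.append(gam1 + gam2)
    return np.vstack(out).astype(float)


def _select_pairs(
    G: np.ndarray,
    merit: np.ndarray,
    scheme: str | float,
    n_crosses: int,
    max_contrib: int,
    rng: np.random.Generator,
    de_config: DEConfig | None,
) -> np.ndarray:
    n_parents = 2 * n_crosses
    if scheme == "truncation-1":
        top = np.argsort(-merit, kind="stable")[:n_parents]
        perm = rng.permutation(top)
        return perm.reshape(n_crosses, 2)
    if scheme == "truncation-4":
        k = n_parents // 4
        top = np.argsort(-merit, kind="stable")[:k]
        slots = np.repeat(top, 4)
        pairs = rng.permutation(slots).reshape(n_crosses, 2)
        pairs, _ = repair_selfing(pairs, allow_selfing=False)
        return pairs
    theta = float(scheme)
    ids = [str(i) for i in range(G.shape[0])]
    cand = CandidateSet(ids, criterion=merit)
    C = coancestry_from_markers(G, ids)
    cons = MatingConstraints.generic(
        n_crosses, max_contrib=max_contrib, allow_selfing=False
    )
    prob = MatingProblem(cand, C, cons)
    from dataclasses import replace as _replace
    from .frontier import find_bounds

    cfg = de_config or DEConfig(pop_size=40, iterations=220, window=60)
    # the bounds only set the target scale: a lighter solve suffices
    bounds_cfg = _replace(cfg, pop_size=30, iterations=max(cfg.iterations // 2, 50),
                          seed=int(rng.integers(2**31 - 1)))
    bounds, _ = find_bounds(prob, bounds_cfg)
    cfg = _replace(cfg, seed=int(rng.integers(2**31 - 1)))
    point = solve_target(prob, TargetSpec("degrees", theta), cfg, bounds)
    return point.plan.matings


def toy_recurrent_selection(
    cfg: SyntheticConfig,
    scheme: str | float,
    cycles: int,
    *,
    n_crosses: int = 16,
    n_progeny: int = 10,
    max_contrib: int = 4,
    de_config: DEConfig | None = None,
    seed: int | None = None,
) -> Trajectory:
    """Recurrent selection on true merit over ``cycles`` breeding cycles.

    Each cycle selects parents from the current cohort of
    ``n_crosses * n_progeny`` individuals — by truncation (top
    ``2 * n_crosses`` with one cross each, or top quarter with four
    crosses each) or by balanced optimization at a degree target with at
    most ``max_contrib`` crosses per parent — then generates the next
    cohort by Mendelian sampling at unlinked loci.  Records the cohort
    genetic mean and genic SD, base cohort included.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    cohort_cfg = SyntheticConfig(
        n_founders=n_crosses * n_progeny, n_loci=cfg.n_loci,
        freq_range=cfg.freq_range, n_edit_loci=cfg.n_edit_loci, seed=cfg.seed,
    )
    _, G, alpha, _ = simulate_marker_population(cohort_cfg, rng)
    means = [float((G @ alpha).mean())]
    sds = [genic_sd(G.mean(axis=0) / 2.0, alpha)]
    for _ in range(cycles):
        merit = G @ alpha
        pairs = _select_pairs(G, merit, scheme, n_crosses, max_contrib, rng, de_config)
        G = _mate_progeny(G, pairs, n_progeny, rng)
        means.append(float((G @ alpha).mean()))
        sds.append(genic_sd(G.mean(axis=0) / 2.0, alpha))
    return Trajectory(np.array(means), np.array(sds), str(scheme))


def conversion_efficiency(traj: Trajectory) -> float:
    """Gain per unit of genic SD lost, from a per-trajectory regression.

    Fits genetic mean against genic SD across cycles and returns the
    negated slope; larger means more gain extracted per unit of diversity
    spent.  If the trajectory lost essentially no diversity the
    efficiency is infinite.
    """
    sd, mean = traj.genic_sd, traj.mean
    if sd[0] - sd[-1] < 1e-9:
        return float("inf")
    slope = np.polyfit(sd, mean, 1)[0]
    return float(-slope)
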