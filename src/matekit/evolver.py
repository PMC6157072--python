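"""Differential evolution with anti-stagnation restarts.

The engine is classic DE/rand/1/bin, maximizing, with three guards against
premature convergence on the plateau-heavy landscapes that rank-based
plan decoding produces:

* the differential weight ``F`` is dithered — redrawn uniformly from
  ``F_range`` each generation;
* the crossover rate cycles through ``CR_values`` generation by
  generation (a low and a high rate by default, mixing fine moves with
  large ones);
* when the best objective stalls for ``window`` generations, the worst
  fraction of the population is re-initialized inside the population's
  coordinate-wise bounding box inflated two-fold (the incumbent best is
  always kept).  Two consecutive restarts without improvement terminate
  the run.

Trials that tie the incumbent replace it, so the population drifts across
flat regions instead of freezing.  All randomness flows from a single
generator seeded once, which makes runs bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class DEConfig:
    """Evolver controls.

    ``pop_size=None`` resolves to ``10 * dim`` clipped to ``[8, 200]``.
    """

    pop_size: int | None = None
    iterations: int = 10000
    F_range: tuple[float, float] = (0.1, 0.9)
    CR_values: tuple[float, ...] = (0.2, 0.9)
    tol: float = 1e-9
    window: int = 500
    restart_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.F_range
        if not (0.0 < lo <= hi < 2.0):
            raise ValueError("F_range must satisfy 0 < lo <= hi < 2")
        if any(not 0.0 <= cr <= 1.0 for cr in self.CR_values):
            raise ValueError("CR values must lie in [0, 1]")
        if not 0.0 <= self.restart_fraction < 1.0:
            raise ValueError("restart_fraction must lie in [0, 1)")

    def resolved_pop_size(self, dim: int) -> int:
        if self.pop_size is not None:
            if self.pop_size < 4:
                raise ValueError("DE needs a population of at least 4")
            return self.pop_size
        return int(np.clip(10 * dim, 8, 200))


@dataclass
class OptLog:
    """Per-generation optimization trace."""

    generation: list[int] = field(default_factory=list)
    best: list[float] = field(default_factory=list)
    mean: list[float] = field(default_factory=list)
    gain: list[float] = field(default_factory=list)
    coancestry: list[float] = field(default_factory=list)
    inbreeding: list[float] = field(default_factory=list)
    penalty: list[float] = field(default_factory=list)
    restarts: list[int] = field(default_factory=list)
    seed: int = 0
    termination: str = ""

    def record(self, gen: int, best: float, mean: float, values) -> None:
        self.generation.append(gen)
        self.best.append(best)
        self.mean.append(mean)
        self.gain.append(getattr(values, "gain", float("nan")))
        self.coancestry.append(getattr(values, "coancestry", float("nan")))
        self.inbreeding.append(getattr(values, "inbreeding", float("nan")))
        self.penalty.append(getattr(values, "penalty", float("nan")))


def has_converged(log: OptLog, config: DEConfig) -> bool:
    """True iff the best trace stalled over the last window after a restart."""
    w = config.window
    if len(log.best) < w + 1:
        return False
    if not log.restarts:
        return False
    return (log.best[-1] - log.best[-1 - w]) < config.tol


def _distinct_rows(rng: np.random.Generator, npop: int) -> tuple[np.ndarray, ...]:
    """Three random index vectors, rowwise distinct from each other and i."""
    idx = np.arange(npop)
    rs = [rng.integers(0, npop, npop) for _ in range(3)]
    for _ in range(64):
        clash = (
            (rs[0] == idx) | (rs[1] == idx) | (rs[2] == idx)
            | (rs[0] == rs[1]) | (rs[0] == rs[2]) | (rs[1] == rs[2])
        )
        if not clash.any():
            break
        for r in rs:
            r[clash] = rng.integers(0, npop, int(clash.sum()))
    return tuple(rs)


def evolve(objective, dim: int, config: DEConfig) -> tuple[np.ndarray, OptLog]:
    """Maximize ``objective`` over real chromosomes of length ``dim``.

    ``objective`` must accept any real vector and return a float or an
    object convertible via ``float()`` (e.g.
    :class:`~matekit.objectives.ObjectiveValues`, whose raw components are
    then logged).  Returns the best chromosome found and the full
    :class:`OptLog`.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    npop = config.resolved_pop_size(dim)
    rng = np.random.default_rng(config.seed)
    log = OptLog(seed=config.seed)

    X = rng.random((npop, dim))
    vals = [objective(x) for x in X]
    scal = np.array([float(v) for v in vals])
    best_i = int(np.argmax(scal))
    best_z = X[best_i].copy()
    best_s = float(scal[best_i])
    best_v = vals[best_i]
    log.record(0, best_s, float(scal.mean()), best_v)

    last_event_gen = 0          # generation of last restart or improvement
    best_at_event = best_s
    failed_restarts = 0

    ncr = len(config.CR_values)
    for gen in range(1, config.iterations + 1):
        F = rng.uniform(*config.F_range)
        CR = config.CR_values[(gen - 1) % ncr]
        r1, r2, r3 = _distinct_rows(rng, npop)
        V = X[r1] + F * (X[r2] - X[r3])
        mask = rng.random((npop, dim)) < CR
        mask[np.arange(npop), rng.integers(0, dim, npop)] = True
        U = np.where(mask, V, X)
        for i in range(npop):
            v = objective(U[i])
            s = float(v)
            if s >= scal[i]:  # accept ties: drift across plateaus
                X[i] = U[i]
                scal[i] = s
                vals[i] = v
        gi = int(np.argmax(scal))
        if scal[gi] > best_s:
            if scal[gi] - best_at_event >= config.tol:
                last_event_gen = gen
                best_at_event = float(scal[gi])
                failed_restarts = 0
            best_s = float(scal[gi])
            best_z = X[gi].copy()
            best_v = vals[gi]
        log.record(gen, best_s, float(scal.mean()), best_v)

        if gen - last_event_gen >= config.window:
            failed_restarts += 1
            if failed_restarts >= 2:
                log.termination = "converged"
                break
            # partial re-initialization of the worst solutions
            k = int(config.restart_fraction * npop)
            if k > 0:
                lo, hi = X.min(axis=0), X.max(axis=0)
                center = (lo + hi) / 2.0
                half = np.maximum(hi - lo, 1e-3)  # inflate range x2
                worst = np.argsort(scal)[:k]
                keep_best = int(np.argmax(scal))
                worst = worst[worst != keep_best]
                X[worst] = rng.uniform(
                    center - half, center + half, size=(worst.size, dim)
                )
                for i in worst:
                    v = objective(X[i])
                    vals[i] = v
                    scal[i] = float(v)
            log.restarts.append(gen)
            last_event_gen = gen
            best_at_event = best_s
    else:
        log.termination = "iterations"
    return best_z, log
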