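"""File formats: candidates, coancestry, pedigree, genotypes, run specs, results.

All inputs are plain delimited text (whitespace or comma).  A single
keyword–value specification file controls a run; every optimization writes
five outputs — input summary, contributor list, mating plan, optimization
log and the random seed used — so a run can be audited and reproduced
byte-for-byte.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import CandidateSet, CoancestryMatrix, DataError
from .objectives import TargetSpec

_SPLIT = re.compile(r"[,\s]+")


def _tokens(line: str) -> list[str]:
    return [t for t in _SPLIT.split(line.strip()) if t]


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_candidates(path: str | Path) -> CandidateSet:
    """Read a candidate file: ``Id [Gender] [Criterion] [CriterionEdited]``.

    Column meaning is determined by count: one column is IDs only, three
    are ``Id Gender Criterion`` and four add the edited criterion.  A
    two-column file is ``Id Gender`` when every second field is a gender
    code in {0, 1, 2}, otherwise ``Id Criterion``.  A header line is
    skipped when any field after the first fails to parse as a number.
    """
    lines = [ln for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise DataError(f"empty candidate file {path}")
    rows = [_tokens(ln) for ln in lines]
    start = 0
    if len(rows[0]) >= 2 and any(not _is_number(t) for t in rows[0][1:]):
        start = 1
    rows = rows[start:]
    if not rows:
        raise DataError(f"candidate file {path} has a header but no data")
    ncol = len(rows[0])
    for k, r in enumerate(rows):
        if len(r) != ncol:
            raise DataError(f"line {start + k + 1}: expected {ncol} fields, got {len(r)}")

    ids = [r[0] for r in rows]
    gender = criterion = criterion_edited = None
    if ncol == 2:
        second = [r[1] for r in rows]
        if all(t in ("0", "1", "2") for t in second):
            gender = [int(t) for t in second]
        else:
            criterion = _parse_column(rows, 1, start, "criterion")
    elif ncol >= 3:
        gender = []
        for k, r in enumerate(rows):
            if r[1] not in ("0", "1", "2"):
                raise DataError(f"line {start + k + 1}: invalid gender code {r[1]!r}")
            gender.append(int(r[1]))
        criterion = _parse_column(rows, 2, start, "criterion")
        if ncol >= 4:
            criterion_edited = _parse_column(rows, 3, start, "edited criterion")
    return CandidateSet(ids, gender=None if gender is None else np.array(gender),
                        criterion=criterion, criterion_edited=criterion_edited)


def _parse_column(rows, col, start, what) -> np.ndarray:
    out = []
    for k, r in enumerate(rows):
        try:
            out.append(float(r[col]))
        except ValueError:
            raise DataError(
                f"line {start + k + 1}: non-numeric {what} {r[col]!r}"
            ) from None
    return np.array(out)


def read_coancestry_matrix(path: str | Path, ids: list[str]) -> CoancestryMatrix:
    """Read a square coancestry matrix with a leading ID column.

    Rows may come in any order; columns are assumed to follow the file's
    row order.  The matrix is reordered to ``ids`` (exact string match;
    unmatched IDs on either side are an error) and symmetrized as
    ``(V + V') / 2`` provided the asymmetry does not exceed 1e-6.
    """
    rows = [_tokens(ln) for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")]
    if rows and any(not _is_number(t) for t in rows[0][1:]):
        rows = rows[1:]
    file_ids = [r[0] for r in rows]
    n = len(file_ids)
    V = np.empty((n, n))
    for i, r in enumerate(rows):
        if len(r) != n + 1:
            raise DataError(f"matrix row {r[0]!r} has {len(r) - 1} values, expected {n}")
        V[i] = [float(t) for t in r[1:]]
    asym = float(np.abs(V - V.T).max()) if n else 0.0
    if asym > 1e-6:
        raise DataError(f"coancestry matrix asymmetry {asym:g} exceeds 1e-6")
    V = (V + V.T) / 2.0
    return CoancestryMatrix(file_ids, V).aligned_to(list(ids))


def write_coancestry_matrix(path: str | Path, matrix: CoancestryMatrix) -> None:
    with open(path, "w") as fh:
        for ident, row in zip(matrix.ids, matrix.values):
            fh.write(ident + " " + " ".join(f"{v:.12g}" for v in row) + "\n")


def read_pedigree(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a 3-column pedigree (``Id Sire Dam``; ``0`` marks unknown)."""
    out = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        t = _tokens(ln)
        if len(t) != 3:
            raise DataError(f"pedigree line needs 3 fields, got {len(t)}: {ln!r}")
        out.append((t[0], t[1], t[2]))
    if out and [t.lower() for t in out[0]] == ["id", "sire", "dam"]:
        out = out[1:]
    return out


def read_genotypes(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read ``Id`` plus integer allele dosages (0/1/2) per line."""
    ids, rows = [], []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        t = _tokens(ln)
        ids.append(t[0])
        rows.append([float(v) for v in t[1:]])
    G = np.array(rows)
    return ids, G


def write_genotypes(path: str | Path, ids: list[str], G: np.ndarray) -> None:
    with open(path, "w") as fh:
        for ident, row in zip(ids, np.asarray(G, int)):
            fh.write(ident + " " + " ".join(str(int(v)) for v in row) + "\n")


def write_candidates(path: str | Path, cand: CandidateSet) -> None:
    with open(path, "w") as fh:
        for k, ident in enumerate(cand.ids):
            parts = [ident]
            if cand.criterion is not None or cand.gendered:
                parts.append(str(int(cand.gender[k])))
            if cand.criterion is not None:
                parts.append(f"{cand.criterion[k]:.10g}")
            if cand.criterion_edited is not None:
                parts.append(f"{cand.criterion_edited[k]:.10g}")
            fh.write(" ".join(parts) + "\n")


def write_pedigree(path: str | Path, pedigree: list[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for ident, sire, dam in pedigree:
            fh.write(f"{ident} {sire or '0'} {dam or '0'}\n")


# ---------------------------------------------------------------------------
# Run specification


MODE_NAMES = {
    "maxgain": "max_gain",
    "mincoancestry": "min_coancestry",
    "mininbreeding": "min_inbreeding",
    "target": "target",
    "frontier": "frontier",
}

_KEYWORDS = {
    "candidatefile", "coancestrymatrixfile", "pedigreefile", "genotypefile",
    "numberofmatings", "maxparentsmale", "maxparentsfemale", "maxparents",
    "mincontributions", "maxcontributions", "equalcontributions",
    "allowselfing", "mode", "targetcoancestry", "targetcoancestryrate",
    "targetpercent", "targetdegrees", "editbudget", "evolpopsize",
    "evoliterations", "evolf", "evolcr", "convergencetolerance",
    "convergencewindow", "penaltyweight", "seed", "outputbasename",
    "frontiersteps",
}


@dataclass
class RunSpec:
    """Fully resolved run specification (defaults filled in)."""

    candidate_file: str = ""
    matrix_file: str | None = None
    pedigree_file: str | None = None
    genotype_file: str | None = None
    n_matings: int = 0
    max_parents: int | None = None
    max_parents_male: int | None = None
    max_parents_female: int | None = None
    min_contrib: int = 0
    max_contrib: int | None = None
    allow_selfing: bool = True
    mode: str = "min_coancestry"
    target: TargetSpec | None = None
    edit_budget: int = 0
    pop_size: int | None = None
    iterations: int = 10000
    F_range: tuple[float, float] = (0.1, 0.9)
    CR_values: tuple[float, ...] = (0.2, 0.9)
    tol: float = 1e-9
    window: int = 500
    penalty_weight: float = 1e4
    seed: int | None = None
    output_basename: str = "matekit"
    frontier_steps: int = 10
    raw_lines: list[str] = field(default_factory=list)


def parse_spec(path: str | Path) -> RunSpec:
    """Parse a keyword–value specification file into a :class:`RunSpec`.

    One setting per line, case-insensitive keywords, ``#`` comments.
    Unknown keywords, conflicting coancestry sources and ambiguous
    targets are errors.
    """
    spec = RunSpec()
    targets: list[TargetSpec] = []
    base = Path(path).parent
    for ln in Path(path).read_text().splitlines():
        stripped = ln.split("#", 1)[0].strip()
        if not stripped:
            continue
        spec.raw_lines.append(stripped)
        toks = _tokens(stripped)
        key, vals = toks[0].lower(), toks[1:]
        if key not in _KEYWORDS:
            raise DataError(f"unknown specification keyword {toks[0]!r}")
        if not vals:
            raise DataError(f"keyword {toks[0]!r} needs a value")
        v = vals[0]
        if key == "candidatefile":
            spec.candidate_file = str(base / v)
        elif key == "coancestrymatrixfile":
            spec.matrix_file = str(base / v)
        elif key == "pedigreefile":
            spec.pedigree_file = str(base / v)
        elif key == "genotypefile":
            spec.genotype_file = str(base / v)
        elif key == "numberofmatings":
            spec.n_matings = int(v)
        elif key == "maxparentsmale":
            spec.max_parents_male = int(v)
        elif key == "maxparentsfemale":
            spec.max_parents_female = int(v)
        elif key == "maxparents":
            spec.max_parents = int(v)
        elif key == "mincontributions":
            spec.min_contrib = int(v)
        elif key == "maxcontributions":
            spec.max_contrib = int(v)
        elif key == "equalcontributions":
            spec.min_contrib = spec.max_contrib = int(v)
        elif key == "allowselfing":
            if v.lower() not in ("yes", "no"):
                raise DataError("AllowSelfing must be Yes or No")
            spec.allow_selfing = v.lower() == "yes"
        elif key == "mode":
            name = v.lower()
            if name not in MODE_NAMES:
                raise DataError(f"unknown mode {v!r}")
            spec.mode = MODE_NAMES[name]
        elif key == "targetcoancestry":
            targets.append(TargetSpec("coancestry_value", float(v)))
        elif key == "targetcoancestryrate":
            targets.append(TargetSpec("coancestry_rate", float(v)))
        elif key == "targetpercent":
            targets.append(TargetSpec("percent_of_min", float(v)))
        elif key == "targetdegrees":
            targets.append(TargetSpec("degrees", float(v)))
        elif key == "editbudget":
            spec.edit_budget = int(v)
        elif key == "evolpopsize":
            spec.pop_size = int(v)
        elif key == "evoliterations":
            spec.iterations = int(v)
        elif key == "evolf":
            f = [float(x) for x in vals]
            spec.F_range = (f[0], f[-1])
        elif key == "evolcr":
            spec.CR_values = tuple(float(x) for x in vals)
        elif key == "convergencetolerance":
            spec.tol = float(v)
        elif key == "convergencewindow":
            spec.window = int(v)
        elif key == "penaltyweight":
            spec.penalty_weight = float(v)
        elif key == "seed":
            spec.seed = int(v)
        elif key == "outputbasename":
            spec.output_basename = str(base / v)
        elif key == "frontiersteps":
            spec.frontier_steps = int(v)

    sources = [s for s in (spec.matrix_file, spec.pedigree_file, spec.genotype_file)
               if s is not None]
    if len(sources) > 1:
        raise DataError("conflicting coancestry sources: specify exactly one of "
                        "CoancestryMatrixFile, PedigreeFile, GenotypeFile")
    if not sources:
        raise DataError("no coancestry source specified")
    if not spec.candidate_file:
        raise DataError("CandidateFile is required")
    if spec.n_matings < 1:
        raise DataError("NumberOfMatings must be a positive integer")
    if spec.mode == "target":
        if len(targets) != 1:
            raise DataError("mode Target requires exactly one target keyword")
        spec.target = targets[0]
    elif targets:
        if len(targets) > 1:
            raise DataError("multiple target keywords given")
        spec.target = targets[0]
    return spec


# ---------------------------------------------------------------------------
# Results


def _fmt(v) -> str:
    return f"{v:.6f}" if v == v else "NA"  # NaN-safe


def write_results(result, spec: RunSpec) -> list[str]:
    """Write the five run outputs (plus frontier files when applicable).

    ``result`` is a :class:`matekit.run.RunResult`.  Returns the list of
    files written.  Output is deterministically formatted, so two runs
    with the same spec and seed produce byte-identical files.
    """
    base = spec.output_basename
    problem = result.problem
    cand = problem.candidates
    written: list[str] = []

    def _write_plan(path: str, plan) -> None:
        C = problem.C
        with open(path, "w") as fh:
            fh.write("Mating Parent1 Parent2 ExpectedInbreeding\n")
            for k, (i, j) in enumerate(plan.matings, start=1):
                fh.write(f"{k} {cand.ids[i]} {cand.ids[j]} {_fmt(C[i, j])}\n")
        written.append(path)

    # (i) input data summary
    path = f"{base}_Summary.txt"
    with open(path, "w") as fh:
        fh.write("matekit run summary\n")
        fh.write(f"Mode {result.mode}\n")
        fh.write(f"Candidates {cand.n}\n")
        fh.write(f"Gendered {'Yes' if cand.gendered else 'No'}\n")
        fh.write(f"Matings {problem.constraints.n_matings}\n")
        if cand.criterion is not None:
            fh.write(f"CriterionMean {_fmt(float(cand.criterion.mean()))}\n")
            fh.write(f"CriterionSD {_fmt(float(cand.criterion.std()))}\n")
        C = problem.C
        fh.write(f"CoancestryMeanSelf {_fmt(float(np.diag(C).mean()))}\n")
        off = C[~np.eye(cand.n, dtype=bool)]
        fh.write(f"CoancestryMeanPair {_fmt(float(off.mean())) if off.size else 'NA'}\n")
        if result.bounds is not None:
            b = result.bounds
            fh.write(f"GainMax {_fmt(b.g_max)}\n")
            fh.write(f"CoancestryAtGainMax {_fmt(b.c_at_gmax)}\n")
            fh.write(f"CoancestryMin {_fmt(b.c_min)}\n")
            fh.write(f"GainAtCoancestryMin {_fmt(b.g_at_cmin)}\n")
        if result.target is not None and result.target.resolved_constraint is not None:
            fh.write(f"TargetCoancestry {_fmt(result.target.resolved_constraint)}\n")
        if result.values is not None:
            v = result.values
            fh.write(f"AchievedGain {_fmt(v.gain)}\n")
            if cand.criterion is not None and result.plan is not None:
                raw = float(result.plan.x @ cand.criterion)
                fh.write(f"AchievedGainRawScale {_fmt(raw)}\n")
            fh.write(f"AchievedCoancestry {_fmt(v.coancestry)}\n")
            fh.write(f"AchievedInbreeding {_fmt(v.inbreeding)}\n")
            fh.write(f"Penalty {_fmt(v.penalty)}\n")
        fh.write("Specification\n")
        for ln in spec.raw_lines:
            fh.write(f"  {ln}\n")
    written.append(path)

    # (ii) contributors
    if result.plan is not None:
        path = f"{base}_Contributors.txt"
        with open(path, "w") as fh:
            fh.write("Id Gender Criterion nContributions xContribution Edited\n")
            edited = set(result.plan.edited.tolist())
            for k in range(cand.n):
                nc = int(result.plan.n_contrib[k])
                if nc == 0:
                    continue
                crit = _fmt(cand.criterion[k]) if cand.criterion is not None else "NA"
                fh.write(
                    f"{cand.ids[k]} {int(cand.gender[k])} {crit} {nc} "
                    f"{_fmt(result.plan.x[k])} {'Yes' if k in edited else 'No'}\n"
                )
        written.append(path)

        # (iii) mating plan
        _write_plan(f"{base}_MatingPlan.txt", result.plan)

    # (iv) optimization log
    if result.log is not None:
        path = f"{base}_OptimisationLog.txt"
        with open(path, "w") as fh:
            fh.write("Iteration BestObjective MeanObjective Gain Coancestry "
                     "Inbreeding Penalty\n")
            lg = result.log
            for k in range(len(lg.generation)):
                fh.write(
                    f"{lg.generation[k]} {lg.best[k]:.9g} {lg.mean[k]:.9g} "
                    f"{_fmt(lg.gain[k])} {_fmt(lg.coancestry[k])} "
                    f"{_fmt(lg.inbreeding[k])} {_fmt(lg.penalty[k])}\n"
                )
        written.append(path)

    # (v) seed
    path = f"{base}_Seed.txt"
    with open(path, "w") as fh:
        fh.write(f"{result.seed}\n")
    written.append(path)

    if result.frontier is not None:
        path = f"{base}_Frontier.txt"
        with open(path, "w") as fh:
            fh.write("Degrees Gain Coancestry GainNorm CoancestryNorm Inbreeding\n")
            for p in result.frontier:
                fh.write(
                    f"{p.degrees:g} {_fmt(p.gain)} {_fmt(p.coancestry)} "
                    f"{_fmt(p.gain_norm)} {_fmt(p.coancestry_norm)} "
                    f"{_fmt(p.inbreeding)}\n"
                )
            written.append(path)
        for p in result.frontier:
            _write_plan(f"{base}_MatingPlan_{p.degrees:g}.txt", p.plan)
    return written
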