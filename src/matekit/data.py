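"""Core data containers: candidates, coancestry matrices and mating constraints.

The central objects of a mate-selection problem are

* a :class:`CandidateSet` — the individuals available as parents, with
  optional gender codes and selection criteria (e.g. estimated breeding
  values), and optionally the criterion each candidate would have after
  genome editing;
* a :class:`CoancestryMatrix` — pairwise kinship coefficients
  ``theta[i, j]`` on the 0–1 scale, where the self-coancestry of a
  non-inbred individual is 0.5 and the expected inbreeding of the
  offspring of ``i`` and ``j`` equals ``theta[i, j]``;
* :class:`MatingConstraints` — what makes a mating plan valid: the number
  of matings, per-role caps on the number of parents, per-parent
  contribution limits, and whether selfing is allowed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Gender codes: 0 = generic (monoecious / unknown), 1 = male, 2 = female.
GENERIC, MALE, FEMALE = 0, 1, 2


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass
class CandidateSet:
    """Selection candidates with optional gender and selection criteria.

    Parameters
    ----------
    ids
        Unique string identifiers, in file order.
    gender
        Per-candidate code in ``{0, 1, 2}``.  Either all 0 (generic
        reproductive system) or all in ``{1, 2}`` (gendered); mixing is
        rejected.  ``None`` means all generic.
    criterion
        Per-candidate selection criterion on an arbitrary scale (larger is
        better), or ``None`` when only diversity objectives are used.
    criterion_edited
        Criterion each candidate would achieve after genome editing;
        requires ``criterion`` to be present.
    """

    ids: list[str]
    gender: np.ndarray | None = None
    criterion: np.ndarray | None = None
    criterion_edited: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        n = len(self.ids)
        seen: set[str] = set()
        for i in self.ids:
            if i in seen:
                raise DataError(f"duplicate ID {i}")
            seen.add(i)
        if self.gender is None:
            self.gender = np.zeros(n, dtype=int)
        else:
            self.gender = np.asarray(self.gender, dtype=int)
            if self.gender.shape != (n,):
                raise DataError("gender length does not match ids")
            codes = set(self.gender.tolist())
            if not codes <= {GENERIC, MALE, FEMALE}:
                raise DataError(f"invalid gender codes {sorted(codes - {0, 1, 2})}")
            if GENERIC in codes and codes != {GENERIC}:
                raise DataError("cannot mix generic gender code 0 with gendered codes 1/2")
        for name in ("criterion", "criterion_edited"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (n,):
                    raise DataError(f"{name} length does not match ids")
                setattr(self, name, v)
        if self.criterion_edited is not None and self.criterion is None:
            raise DataError("criterion_edited requires criterion")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def gendered(self) -> bool:
        return bool(np.any(self.gender != GENERIC))

    @property
    def males(self) -> np.ndarray:
        """Indices of male candidates (empty in generic mode)."""
        return np.flatnonzero(self.gender == MALE)

    @property
    def females(self) -> np.ndarray:
        return np.flatnonzero(self.gender == FEMALE)

    def role_indices(self, role: str) -> np.ndarray:
        if role == "male":
            return self.males
        if role == "female":
            return self.females
        return np.arange(self.n)

    def index_of(self, ident: str) -> int:
        try:
            return self.ids.index(ident)
        except ValueError:
            raise DataError(f"unknown ID {ident}") from None


@dataclass
class CoancestryMatrix:
    """Symmetric matrix of pairwise coancestry (kinship) coefficients.

    ``values[i, j]`` is the probability that random alleles drawn one from
    ``i`` and one from ``j`` are identical, on the 0–1 scale.  For
    pedigree-derived matrices the diagonal is ``0.5 * (1 + F_i)``; for
    marker (identity-by-state) matrices the diagonal is the within-
    individual allele sharing, 0.5 for a fully heterozygous individual.
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        n = len(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n):
            raise DataError("coancestry matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise DataError("coancestry matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def aligned_to(self, ids: list[str], strict: bool = True) -> "CoancestryMatrix":
        """Return a copy with rows/columns permuted to the given ID order.

        With ``strict`` (the default) the ID sets must match exactly;
        otherwise extra individuals (e.g. pedigree ancestors that are not
        candidates) are silently dropped.
        """
        pos = {ident: k for k, ident in enumerate(self.ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise DataError(f"missing ID {missing[0]} in coancestry matrix")
        extra = [i for i in self.ids if i not in set(ids)]
        if strict and extra:
            raise DataError(f"unknown ID {extra[0]} in coancestry matrix")
        perm = np.array([pos[i] for i in ids])
        return CoancestryMatrix(list(ids), self.values[np.ix_(perm, perm)])


@dataclass(frozen=True)
class RoleLimits:
    """Per-role parent and contribution limits.

    ``max_parents`` and ``max_contrib`` of ``None`` mean unlimited; equal
    contributions are expressed as ``min_contrib == max_contrib``.
    """

    max_parents: int | None = None
    min_contrib: int = 0
    max_contrib: int | None = None

    def __post_init__(self) -> None:
        if self.max_parents is not None and self.max_parents < 1:
            raise DataError("max_parents must be positive")
        if self.min_contrib < 0:
            raise DataError("min_contrib must be >= 0")
        if self.max_contrib is not None and self.max_contrib < max(1, self.min_contrib):
            raise DataError("max_contrib must be >= max(1, min_contrib)")


@dataclass
class MatingConstraints:
    """Definition of a valid mating plan.

    A plan consists of ``n_matings`` parent pairs.  In gendered mode each
    pair is (male, female) and each role contributes ``n_matings`` parent
    slots; in generic mode a single candidate pool fills ``2 * n_matings``
    slots and ``allow_selfing`` controls whether a pair may repeat one
    individual.
    """

    n_matings: int
    limits: dict[str, RoleLimits] = field(default_factory=dict)
    allow_selfing: bool = True

    def __post_init__(self) -> None:
        if self.n_matings < 1:
            raise DataError("n_matings must be positive")
        roles = set(self.limits)
        if roles not in ({"generic"}, {"male", "female"}):
            raise DataError("limits must cover either 'generic' or both 'male' and 'female'")

    @classmethod
    def generic(
        cls,
        n_matings: int,
        *,
        max_parents: int | None = None,
        min_contrib: int = 0,
        max_contrib: int | None = None,
        allow_selfing: bool = True,
    ) -> "MatingConstraints":
        lim = RoleLimits(max_parents, min_contrib, max_contrib)
        return cls(n_matings, {"generic": lim}, allow_selfing)

    @classmethod
    def gendered(
        cls,
        n_matings: int,
        *,
        male: RoleLimits | None = None,
        female: RoleLimits | None = None,
    ) -> "MatingConstraints":
        return cls(
            n_matings,
            {"male": male or RoleLimits(), "female": female or RoleLimits()},
            allow_selfing=False,
        )

    @property
    def is_gendered(self) -> bool:
        return "male" in self.limits

    @property
    def roles(self) -> tuple[str, ...]:
        return ("male", "female") if self.is_gendered else ("generic",)

    def slots(self, role: str) -> int:
        """Number of parent slots the role must fill."""
        return self.n_matings if self.is_gendered else 2 * self.n_matings

    def with_matings(self, n_matings: int) -> "MatingConstraints":
        return replace(self, n_matings=n_matings)
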