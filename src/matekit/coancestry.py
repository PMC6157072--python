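"""Coancestry construction from pedigrees and genome-wide markers.

Two standard sources of the kinship matrix are supported:

* **Pedigree** — the tabular method for the numerator relationship matrix
  ``A``; coancestry is reported as kinship, ``theta = A / 2``, so that the
  matrix semantics are identical across sources.
* **Markers** — pairwise identity-by-state allele sharing: the proportion
  of marker alleles two individuals have in common, averaged over loci.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .data import CoancestryMatrix, DataError

UNKNOWN_PARENT = {"0", "", ".", "na", "NA", None}


def _topological_order(pedigree: list[tuple[str, str | None, str | None]]) -> list[str]:
    """Order ids so parents precede offspring; raise on cycles.

    Parents that never appear as individuals are added as implicit
    founders (unknown parents, non-inbred, unrelated).
    """
    parents: dict[str, tuple[str | None, str | None]] = {}
    for ident, sire, dam in pedigree:
        ident = str(ident)
        if ident in parents:
            raise DataError(f"duplicate ID {ident} in pedigree")
        s = None if sire in UNKNOWN_PARENT or str(sire) in UNKNOWN_PARENT else str(sire)
        d = None if dam in UNKNOWN_PARENT or str(dam) in UNKNOWN_PARENT else str(dam)
        if s == ident or d == ident:
            raise DataError(f"individual {ident} listed as its own parent")
        parents[ident] = (s, d)
    for ident in list(parents):
        for p in parents[ident]:
            if p is not None and p not in parents:
                parents[p] = (None, None)
    # Kahn's algorithm on distinct parent -> offspring edges.
    indeg = {i: len({p for p in ps if p is not None}) for i, ps in parents.items()}
    children: dict[str, list[str]] = {i: [] for i in parents}
    for ident, ps in parents.items():
        for p in {p for p in ps if p is not None}:
            children[p].append(ident)
    order = [i for i, d in indeg.items() if d == 0]
    head = 0
    while head < len(order):
        cur = order[head]
        head += 1
        for ch in children[cur]:
            indeg[ch] -= 1
            if indeg[ch] == 0:
                order.append(ch)
    if len(order) != len(parents):
        raise DataError("pedigree cycle detected (individual is its own ancestor)")
    return order


def coancestry_from_pedigree(
    pedigree: list[tuple[str, str | None, str | None]],
) -> CoancestryMatrix:
    """Kinship matrix from a 3-column pedigree by the tabular method.

    Parameters
    ----------
    pedigree
        Iterable of ``(id, sire, dam)``; ``"0"``, ``""`` or ``None`` mark
        unknown parents.  Rows may be in any order; parents that never
        occur as individuals are treated as unknown.

    Returns
    -------
    CoancestryMatrix
        Kinship ``theta = A / 2`` where ``A`` is the numerator
        relationship matrix.  Founders are assumed non-inbred and
        unrelated, so ``theta_ii = 0.5 * (1 + F_i)``.

    Notes
    -----
    The tabular recurrences are ``A[i, j] = 0.5 * (A[j, s_i] + A[j, d_i])``
    for previously processed ``j`` and ``A[i, i] = 1 + 0.5 * A[s_i, d_i]``,
    with unknown-parent terms equal to zero.
    """
    pedigree = [(str(i), s, d) for i, s, d in pedigree]
    order = _topological_order(pedigree)
    parents: dict[str, tuple[str | None, str | None]] = {}
    for ident, sire, dam in pedigree:
        s = None if sire in UNKNOWN_PARENT or str(sire) in UNKNOWN_PARENT else str(sire)
        d = None if dam in UNKNOWN_PARENT or str(dam) in UNKNOWN_PARENT else str(dam)
        parents[ident] = (s, d)
    for ident in order:
        parents.setdefault(ident, (None, None))

    pos = {ident: k for k, ident in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for ident in order:
        i = pos[ident]
        s, d = parents[ident]
        si = pos[s] if s is not None else None
        di = pos[d] if d is not None else None
        row = np.zeros(n)
        if si is not None:
            row += 0.5 * A[si]
        if di is not None:
            row += 0.5 * A[di]
        A[i, :] = row
        A[:, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)

    listed = [str(i) for i, _, _ in pedigree]
    implicit = [i for i in order if i not in set(listed)]
    out_ids = listed + implicit
    perm = np.array([pos[i] for i in out_ids])
    return CoancestryMatrix(out_ids, A[np.ix_(perm, perm)] / 2.0)


def coancestry_from_markers(
    genotypes: np.ndarray, ids: list[str] | None = None
) -> CoancestryMatrix:
    """Identity-by-state allele-sharing matrix from biallelic genotypes.

    Parameters
    ----------
    genotypes
        ``(n, L)`` array of allele dosages in ``{0, 1, 2}``; no missing
        values are allowed.
    ids
        Identifiers for the rows; defaults to ``"1".."n"``.

    Returns
    -------
    CoancestryMatrix
        Mean over loci of the allele-sharing score ``s(a, b)``, where
        ``s = (2 - |a - b|) / 2`` except that two heterozygotes share an
        expected 0.5 (one random allele each).  Values lie in ``[0, 1]``;
        the diagonal is 1 for a fully homozygous individual and 0.5 for a
        fully heterozygous one.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2 or G.shape[1] < 1:
        raise DataError("genotypes must be an (n, L) matrix with L >= 1")
    if np.isnan(G).any():
        raise DataError("missing genotype values are not supported")
    if not np.isin(G, (0.0, 1.0, 2.0)).all():
        bad = G[~np.isin(G, (0.0, 1.0, 2.0))][0]
        raise DataError(f"genotype value {bad!r} outside {{0, 1, 2}}")
    n, L = G.shape
    D = cdist(G, G, "cityblock")
    het = (G == 1.0).astype(float)
    both_het = het @ het.T
    values = ((2.0 * L - D) / 2.0 - 0.5 * both_het) / L
    values = (values + values.T) / 2.0  # cdist is symmetric up to fp noise
    if ids is None:
        ids = [str(k + 1) for k in range(n)]
    return CoancestryMatrix(list(ids), values)
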