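"""Genome-editing extension: joint optimization of who is edited.

The optimizer carries one 'edit rank' gene per editable candidate.  Among
the editable candidates that are actually *selected* in a plan
(contribution > 0), the budget's worth with the highest edit ranks are
edited; the gain objective then substitutes their edited merit.  Editing a
non-contributor would waste budget, so non-contributors never consume it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EditConfig:
    """Editing resources: how many individuals, and which are eligible.

    ``editable`` holds candidate indices (into the CandidateSet).  The
    default eligible set is chosen by the problem builder — all males in a
    gendered problem, all candidates otherwise.
    """

    budget: int
    editable: np.ndarray

    def __post_init__(self) -> None:
        self.editable = np.asarray(self.editable, dtype=int)
        if self.budget < 0:
            raise ValueError("edit budget must be >= 0")
        if self.budget > self.editable.size:
            raise ValueError("edit budget exceeds the number of editable candidates")


def decode_edits(
    edit_genes: np.ndarray,
    n_contrib: np.ndarray,
    editable: np.ndarray,
    budget: int,
) -> np.ndarray:
    """Pick which selected editable candidates are edited.

    Among editable candidates with ``n_contrib > 0``, returns the
    ``budget`` with the highest edit-rank genes (ties broken by candidate
    index).  If fewer than ``budget`` editable candidates are selected,
    all of them are returned — the budget is not forced onto
    non-contributors.
    """
    editable = np.asarray(editable, dtype=int)
    if edit_genes.size != editable.size:
        raise ValueError("one edit gene per editable candidate required")
    if budget <= 0:
        return np.empty(0, dtype=int)
    sel = np.flatnonzero(n_contrib[editable] > 0)
    if sel.size <= budget:
        return np.sort(editable[sel])
    order = sel[np.argsort(-np.asarray(edit_genes, float)[sel], kind="stable")]
    return np.sort(editable[order[:budget]])


def gain_with_edits(
    x: np.ndarray,
    a_std: np.ndarray,
    a_std_edited: np.ndarray,
    edited: np.ndarray,
) -> float:
    """Genetic gain with edited merit substituted for edited individuals.

    Both merit vectors must be standardized with the *non-edited*
    criterion's mean and SD so the two scales are directly comparable.
    """
    edited = np.asarray(edited, dtype=int)
    if edited.size == 0:
        return float(np.dot(x, a_std))
    m = a_std.copy()
    m[edited] = a_std_edited[edited]
    return float(np.dot(x, m))
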