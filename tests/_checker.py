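"""Independent mating-plan checker: recounts everything from the matings.

Deliberately shares no code with the decoder; used to verify that
``MatingPlan.violations == 0`` exactly when the plan satisfies every
constraint.
"""

from collections import Counter

import numpy as np


def check_plan(plan, constraints, candidates) -> list[str]:
    errs: list[str] = []
    M = constraints.n_matings
    m = np.asarray(plan.matings)
    if m.shape != (M, 2):
        return [f"expected {M} matings, got {m.shape}"]

    if constraints.is_gendered:
        role_of = {1: "male", 2: "female"}
        for col, role in ((0, "male"), (1, "female")):
            for idx in m[:, col]:
                if role_of.get(int(candidates.gender[idx])) != role:
                    errs.append(f"candidate {idx} in {role} column has wrong gender")
        counts = {"male": Counter(m[:, 0].tolist()),
                  "female": Counter(m[:, 1].tolist())}
        slots = {"male": M, "female": M}
    else:
        counts = {"generic": Counter(m.ravel().tolist())}
        slots = {"generic": 2 * M}
        if not constraints.allow_selfing:
            for a, b in m:
                if a == b:
                    errs.append(f"selfing pair ({a}, {b})")

    for role, cnt in counts.items():
        lim = constraints.limits[role]
        total = sum(cnt.values())
        if total != slots[role]:
            errs.append(f"{role}: {total} slots filled, expected {slots[role]}")
        if lim.max_parents is not None and len(cnt) > lim.max_parents:
            errs.append(f"{role}: {len(cnt)} parents exceed cap {lim.max_parents}")
        for idx, c in cnt.items():
            if lim.max_contrib is not None and c > lim.max_contrib:
                errs.append(f"{role}: candidate {idx} contributes {c} > {lim.max_contrib}")
            if c < lim.min_contrib:
                errs.append(f"{role}: candidate {idx} contributes {c} < {lim.min_contrib}")

    # n_contrib must agree with the matings themselves
    recount = Counter(np.asarray(plan.matings).ravel().tolist()) if not constraints.is_gendered else None
    if recount is not None:
        for idx in range(candidates.n):
            if recount.get(idx, 0) != int(plan.n_contrib[idx]):
                errs.append(f"n_contrib[{idx}] inconsistent with matings")
    else:
        both = Counter(m[:, 0].tolist()) + Counter(m[:, 1].tolist())
        for idx in range(candidates.n):
            if both.get(idx, 0) != int(plan.n_contrib[idx]):
                errs.append(f"n_contrib[{idx}] inconsistent with matings")
    return errs
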