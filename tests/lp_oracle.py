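"""Brute-force LP oracle: vertex enumeration of the flux polytope.

Independent of the scipy-based solver in xyloflux.fba: every vertex of
{v : S v = 0, lb <= v <= ub} is enumerated by fixing n - rank(S)
coordinates at a bound and solving the remaining square-ish linear
system.  For bounded feasible LPs the optimum lies at a vertex, so the
maximum objective over vertices is the exact LP optimum.  Only usable
at toy scale (a dozen reactions).
"""

import itertools

import numpy as np


def vertex_optimum(model, objective, tol=1e-8):
    """Exact max of c'v over the flux polytope by vertex enumeration.

    Returns None if no feasible vertex exists (empty polytope).
    """
    S, _, rxn_ids = model.stoichiometric_matrix()
    n = len(rxn_ids)
    lbs = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ubs = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    c = np.zeros(n)
    for rid, w in objective.items():
        c[rxn_ids.index(rid)] = w
    rank = np.linalg.matrix_rank(S)
    k = n - rank
    best = None
    for fixed_idx in itertools.combinations(range(n), k):
        fixed_idx = list(fixed_idx)
        free_idx = [j for j in range(n) if j not in fixed_idx]
        A = S[:, free_idx]
        if np.linalg.matrix_rank(A) < len(free_idx):
            continue  # not a basis; this vertex appears under another choice
        for choice in itertools.product((0, 1), repeat=k):
            vals = np.array(
                [lbs[j] if ch == 0 else ubs[j] for j, ch in zip(fixed_idx, choice)]
            )
            b = -S[:, fixed_idx] @ vals
            sol, *_ = np.linalg.lstsq(A, b, rcond=None)
            if np.max(np.abs(A @ sol - b)) > tol:
                continue  # inconsistent: no vertex with this active set
            v = np.empty(n)
            v[fixed_idx] = vals
            v[free_idx] = sol
            if np.any(v < lbs - 1e-7) or np.any(v > ubs + 1e-7):
                continue
            value = float(c @ v)
            if best is None or value > best:
                best = value
    return best
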