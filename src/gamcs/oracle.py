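"""Independent brute-force references for small problem instances.

These routines deliberately avoid the production code paths (double
description, Berge transversals, the GA): they exhaust the search space
directly and serve as ground truth in tests, in synthetic ground-truth
tables and in the acceptance checks.  They are only usable at desk scale
(2^r subset scans), which is exactly their point.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import null_space

from .network import MetabolicNetwork

__all__ = [
    "brute_force_efm_supports",
    "brute_force_hitting_sets",
    "exhaustive_best_fitness",
]


def brute_force_efm_supports(net: MetabolicNetwork) -> set[frozenset[int]]:
    """All EFM supports of an irreversible network by exhaustive subset scan.

    For every candidate support S (ascending size, pruning supersets of
    accepted supports): S carries an admissible steady-state flux with
    support exactly S iff null(N[:, S]) is one-dimensional with a strictly
    nonzero, single-signed basis vector.  Support-minimality of accepted
    sets follows because a strict superset of an accepted support has a
    nullspace of dimension >= 2.
    """
    if any(net.reversible):
        raise ValueError("brute-force support scan requires an irreversible network")
    N = net.stoich_array
    r = net.n_reactions
    accepted: list[int] = []  # bitmasks
    supports: set[frozenset[int]] = set()
    for size in range(1, r + 1):
        for combo in itertools.combinations(range(r), size):
            mask = 0
            for j in combo:
                mask |= 1 << j
            if any(a & mask == a for a in accepted):
                continue
            ns = null_space(N[:, combo])
            if ns.shape[1] != 1:
                continue
            v = ns[:, 0]
            if np.min(np.abs(v)) < 1e-9:
                continue
            if np.all(v > 0) or np.all(v < 0):
                accepted.append(mask)
                supports.add(frozenset(combo))
    return supports


def brute_force_hitting_sets(
    targets: Iterable[frozenset[int]],
    n_reactions: int,
    max_cardinality: int | None = None,
    forbidden: frozenset[int] = frozenset(),
) -> set[frozenset[int]]:
    """All minimal hitting sets of a hypergraph by vectorised powerset scan."""
    target_masks = []
    forb_mask = 0
    for j in forbidden:
        forb_mask |= 1 << j
    for t in targets:
        m = 0
        for j in t:
            m |= 1 << j
        m &= ~forb_mask
        if m == 0:
            raise ValueError(f"target {sorted(t)} consists only of forbidden reactions")
        target_masks.append(m)
    if not target_masks:
        return {frozenset()}
    all_masks = np.arange(1 << n_reactions, dtype=np.int64)
    allowed = (all_masks & forb_mask) == 0
    hits = allowed.copy()
    for t in set(target_masks):
        hits &= (all_masks & t) != 0
    hits_arr = hits  # boolean indexed by mask
    out: set[frozenset[int]] = set()
    for mask in np.nonzero(hits_arr)[0]:
        mask = int(mask)
        card = bin(mask).count("1")
        if max_cardinality is not None and card > max_cardinality:
            continue
        minimal = True
        mm = mask
        while mm:
            bit = mm & -mm
            if hits_arr[mask ^ bit]:
                minimal = False
                break
            mm ^= bit
        if minimal:
            out.add(frozenset(j for j in range(n_reactions) if mask >> j & 1))
    return out


def exhaustive_best_fitness(
    efms,
    spec,
    w_k: float,
    max_cut_cardinality: int,
    forbidden: frozenset[int] | None = None,
    candidate_modes: Sequence[int] | None = None,
):
    """Optimum fitness over every keep/kill partition of the EFM set.

    Exhausts the GA's entire search space: for each keep-subset D of
    ``candidate_modes`` (default: all modes), builds the intervention
    problem with k = ceil(w_k |D|), solves it, and evaluates every resulting
    survivor pattern.  Returns ``(best_fitness, best_patterns)`` where
    ``best_patterns`` maps each optimum survivor pattern (frozenset of mode
    indices) to its minimal-cardinality cut sets.

    Only feasible at desk scale (2^n partitions).
    """
    from .cmcs import InterventionProblem, default_forbidden, solve_intervention
    from .ga import pattern_fitness_of_group

    if forbidden is None:
        forbidden = default_forbidden(efms.network)
    indices = list(candidate_modes) if candidate_modes is not None else list(range(efms.n))
    supports = efms.supports()
    best = 0.0
    best_patterns: dict[frozenset[int], tuple[float, set[frozenset[int]]]] = {}
    for size in range(1, len(indices) + 1):
        for keep in itertools.combinations(indices, size):
            keep_set = set(keep)
            kill = [i for i in range(efms.n) if i not in keep_set]
            problem = InterventionProblem(
                targets=[supports[i] for i in kill],
                desired=[supports[i] for i in keep],
                keep_min=math.ceil(w_k * len(keep)),
            )
            try:
                solutions = solve_intervention(
                    problem, max_cut_cardinality, forbidden=forbidden
                )
            except ValueError:
                continue
            groups: dict[frozenset[int], list] = {}
            for cut, surv in solutions:
                pattern = frozenset(
                    i for i in keep if not (cut.reactions & supports[i])
                )
                groups.setdefault(pattern, []).append(cut)
            for pattern, cuts in groups.items():
                fit, min_cuts = pattern_fitness_of_group(
                    pattern, cuts, efms, spec
                )
                if fit > best + 1e-12:
                    best = fit
                    best_patterns = {pattern: (fit, set(c.reactions for c in min_cuts))}
                elif abs(fit - best) <= 1e-12 and best > 0:
                    entry = best_patterns.setdefault(pattern, (fit, set()))
                    entry[1].update(c.reactions for c in min_cuts)
    return best, best_patterns
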