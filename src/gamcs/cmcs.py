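"""Constrained minimal cut sets via Berge's transversal algorithm.

A cut set C "hits" a target mode T when C ∩ supp(T) ≠ ∅; knocking out C
blocks flux through every hit mode.  A minimal cut set (MCS) is an
inclusion-minimal hitting set of the target hypergraph.  A *constrained*
MCS additionally leaves at least ``keep_min`` of the desired modes
untouched (survivors: desired supports disjoint from C).

The transversal computation is Berge's incremental algorithm over bitmask
candidate sets: fold in one target at a time (pre-sorted by ascending
support size), extend the candidates that miss it by one element each, and
prune non-minimal or over-budget candidates.  Role reactions (substrate
uptake, product secretion, biomass) are forbidden cut members by default —
knocking them out satisfies hitting constraints trivially while destroying
the design objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .network import MetabolicNetwork

__all__ = [
    "InterventionProblem",
    "CutSet",
    "SurvivorSet",
    "InfeasibleTargetError",
    "minimal_hitting_sets",
    "survivors",
    "solve_intervention",
    "default_forbidden",
    "write_cut_sets",
    "read_cut_sets",
]

DEFAULT_MAX_CARDINALITY = 8


class InfeasibleTargetError(ValueError):
    """A target consists only of forbidden reactions and cannot be hit."""


@dataclass(frozen=True)
class CutSet:
    """A set of reaction indices to knock out."""

    reactions: frozenset[int]

    @property
    def cardinality(self) -> int:
        return len(self.reactions)

    def sorted(self) -> tuple[int, ...]:
        return tuple(sorted(self.reactions))


@dataclass(frozen=True)
class SurvivorSet:
    """The desired supports untouched by a given cut set."""

    surviving: tuple[frozenset[int], ...]

    def __len__(self) -> int:
        return len(self.surviving)


@dataclass
class InterventionProblem:
    """Targets to kill, desired modes to preserve, and the keep count.

    ``keep_min`` is k: at least this many desired modes must survive a
    valid cut set.  Targets and desired must be disjoint support sets and
    k may not exceed |desired|.
    """

    targets: Sequence[frozenset[int]]
    desired: Sequence[frozenset[int]]
    keep_min: int = 0

    def __post_init__(self):
        if self.keep_min > len(self.desired):
            raise ValueError(
                f"keep_min={self.keep_min} exceeds |desired|={len(self.desired)}"
            )
        if self.keep_min < 0:
            raise ValueError("keep_min must be non-negative")
        if set(map(frozenset, self.targets)) & set(map(frozenset, self.desired)):
            raise ValueError("targets and desired share a support set")


def _to_mask(s: Iterable[int]) -> int:
    mask = 0
    for j in s:
        mask |= 1 << j
    return mask


def _from_mask(mask: int) -> frozenset[int]:
    out = []
    j = 0
    while mask:
        if mask & 1:
            out.append(j)
        mask >>= 1
        j += 1
    return frozenset(out)


def _bits(mask: int) -> list[int]:
    out = []
    j = 0
    while mask:
        if mask & 1:
            out.append(j)
        mask >>= 1
        j += 1
    return out


def minimal_hitting_sets(
    targets: Iterable[frozenset[int]],
    max_cardinality: int = DEFAULT_MAX_CARDINALITY,
    forbidden: Iterable[int] | None = None,
) -> list[CutSet]:
    """Every minimal hitting set of the target hypergraph, up to a budget.

    Returns exactly the inclusion-minimal sets of cardinality
    <= ``max_cardinality`` that intersect every target and avoid
    ``forbidden`` reactions.  An empty target collection yields the single
    empty cut set.  Raises :class:`InfeasibleTargetError` when a target is
    entirely forbidden.
    """
    if max_cardinality < 1:
        raise ValueError("max_cardinality must be >= 1")
    forb = _to_mask(forbidden or ())
    masks = []
    for t in targets:
        m = _to_mask(t) & ~forb
        if m == 0:
            raise InfeasibleTargetError(
                f"target {sorted(t)} consists only of forbidden reactions"
            )
        masks.append(m)
    if not masks:
        return [CutSet(frozenset())]
    # dedupe and drop supersets: hitting a support also hits any superset
    masks = sorted(set(masks), key=lambda m: bin(m).count("1"))
    reduced: list[int] = []
    for m in masks:
        if not any(kept & m == kept for kept in reduced):
            reduced.append(m)

    transversals: list[int] = [1 << j for j in _bits(reduced[0])]
    for target in reduced[1:]:
        hitters = [t for t in transversals if t & target]
        missers = [t for t in transversals if not (t & target)]
        candidates = list(hitters)
        for t in missers:
            if bin(t).count("1") >= max_cardinality:
                continue
            for j in _bits(target):
                candidates.append(t | (1 << j))
        # minimality sweep over the merged candidate pool
        candidates = sorted(set(candidates), key=lambda m: bin(m).count("1"))
        kept: list[int] = []
        for c in candidates:
            if not any(k & c == k for k in kept):
                kept.append(c)
        transversals = [t for t in kept if bin(t).count("1") <= max_cardinality]
        if not transversals:
            return []
    return sorted(
        (CutSet(_from_mask(t)) for t in transversals),
        key=lambda c: (c.cardinality, c.sorted()),
    )


def survivors(cutset: CutSet, desired: Sequence[frozenset[int]]) -> SurvivorSet:
    """Desired supports disjoint from the cut set (order preserved)."""
    return SurvivorSet(
        tuple(d for d in desired if not (cutset.reactions & d))
    )


def solve_intervention(
    problem: InterventionProblem,
    max_cardinality: int = DEFAULT_MAX_CARDINALITY,
    forbidden: Iterable[int] | None = None,
) -> list[tuple[CutSet, SurvivorSet]]:
    """All constrained MCSs of the intervention problem within the budget.

    Returns every minimal hitting set C of the targets with
    |C| <= ``max_cardinality`` that lets at least ``keep_min`` desired
    modes survive, paired with its survivor set.  An empty list means the
    problem is infeasible within the budget — a valid outcome, not an
    error.
    """
    cuts = minimal_hitting_sets(problem.targets, max_cardinality, forbidden)
    out = []
    for cut in cuts:
        surv = survivors(cut, problem.desired)
        if len(surv) >= problem.keep_min:
            out.append((cut, surv))
    return out


def default_forbidden(net: MetabolicNetwork) -> frozenset[int]:
    """Role reactions (uptake, product exporter, biomass) as forbidden cuts."""
    out = set()
    for role in ("substrate_uptake", "product_secretion", "biomass"):
        idx = net.role_index(role)
        if idx is not None:
            out.add(idx)
    return frozenset(out)


# ---------------------------------------------------------------------------
# cut-set interchange format: cardinality<TAB>fitness<TAB>reaction ids
# ---------------------------------------------------------------------------

def write_cut_sets(
    path: str | Path,
    cuts: Sequence[CutSet],
    net: MetabolicNetwork,
    fitnesses: Sequence[float] | None = None,
) -> None:
    lines = []
    for i, cut in enumerate(cuts):
        fit = fitnesses[i] if fitnesses is not None else float("nan")
        ids = " ".join(net.reaction_ids[j] for j in cut.sorted())
        lines.append(f"{cut.cardinality}\t{fit:.6g}\t{ids}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_cut_sets(path: str | Path, net: MetabolicNetwork) -> list[tuple[CutSet, float]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        card, fit, ids = line.split("\t")
        reactions = frozenset(net.reaction_index(rid) for rid in ids.split())
        if len(reactions) != int(card):
            raise ValueError(f"cardinality mismatch in line {line!r}")
        out.append((CutSet(reactions), float(fit)))
    return out
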