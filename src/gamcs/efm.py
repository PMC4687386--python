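"""Elementary flux mode (EFM) enumeration by double description.

An EFM is a nonzero steady-state flux vector ``v`` (``N v = 0``, ``v_j >= 0``
for irreversible ``j``) whose support — the set of reactions carrying flux —
is minimal: no other admissible flux vector has a support that is a proper
subset.  The full EFM set spans every steady-state behaviour of the network,
which is what makes keep/kill partitions of it a complete design space.

Enumeration runs the double description method on the pointed cone
``{v >= 0 : N v = 0}`` of the reversible-split network: start from the
standard basis rays of the positive orthant and intersect with one
metabolite balance hyperplane at a time, combining adjacent positive/negative
ray pairs.  Arithmetic is exact (integer rays, rows scaled to integers), so
elementarity never hinges on a tolerance during enumeration; tolerances only
matter when validating externally supplied float vectors.

Spurious two-cycles (a reversible reaction's forward and backward split
halves cancelling each other) are removed before the split supports are
merged back to original reaction indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .network import MetabolicNetwork, split_reversible

__all__ = [
    "FluxMode",
    "EFMSet",
    "CapacityError",
    "enumerate_efms",
    "is_elementary",
    "normalize_mode",
    "write_efm_matrix",
    "read_efm_matrix",
]

TOL_ZERO = 1e-9
TOL_BALANCE = 1e-9


class CapacityError(RuntimeError):
    """Raised when the intermediate ray tableau exceeds the configured cap."""


@dataclass(frozen=True)
class FluxMode:
    """One elementary mode: a flux vector and its support."""

    flux: tuple[float, ...]
    support: frozenset[int]

    @classmethod
    def from_flux(cls, flux: Sequence[float]) -> "FluxMode":
        flux = tuple(float(v) for v in flux)
        support = frozenset(j for j, v in enumerate(flux) if abs(v) > TOL_ZERO)
        return cls(flux=flux, support=support)

    def flux_through(self, j: int) -> float:
        return self.flux[j]


@dataclass
class EFMSet:
    """The complete EFM collection of one network."""

    modes: list[FluxMode]
    network: MetabolicNetwork

    @property
    def n(self) -> int:
        return len(self.modes)

    def supports(self) -> list[frozenset[int]]:
        return [m.support for m in self.modes]

    def __iter__(self) -> Iterator[FluxMode]:
        return iter(self.modes)

    def __len__(self) -> int:
        return len(self.modes)


# ---------------------------------------------------------------------------
# exact double description
# ---------------------------------------------------------------------------

def _integer_rows(net: MetabolicNetwork) -> list[list[int]]:
    rows = []
    for row in net.stoich:
        denom_lcm = 1
        for c in row:
            denom_lcm = denom_lcm * c.denominator // math.gcd(denom_lcm, c.denominator)
        rows.append([int(c * denom_lcm) for c in row])
    return rows


def _reduce(ray: list[int]) -> tuple[int, ...]:
    g = 0
    for v in ray:
        g = math.gcd(g, abs(v))
    if g > 1:
        ray = [v // g for v in ray]
    return tuple(ray)


def _support_mask(ray: Sequence[int]) -> int:
    mask = 0
    for j, v in enumerate(ray):
        if v != 0:
            mask |= 1 << j
    return mask


def _double_description(rows: list[list[int]], r: int, max_rays: int) -> list[tuple[int, ...]]:
    rays: list[tuple[int, ...]] = [
        tuple(1 if k == j else 0 for k in range(r)) for j in range(r)
    ]
    for row in rows:
        scores = [sum(a * v for a, v in zip(row, ray)) for ray in rays]
        zero = [ray for ray, s in zip(rays, scores) if s == 0]
        pos = [(ray, s) for ray, s in zip(rays, scores) if s > 0]
        neg = [(ray, s) for ray, s in zip(rays, scores) if s < 0]
        masks = [_support_mask(ray) for ray in rays]
        new: list[tuple[int, ...]] = list(zero)
        for rp, sp in pos:
            mp = _support_mask(rp)
            for rn, sn in neg:
                union = mp | _support_mask(rn)
                # combinatorial adjacency: no third ray's support inside union
                adjacent = True
                for other_mask, other in zip(masks, rays):
                    if other is rp or other is rn:
                        continue
                    if other_mask | union == union:
                        adjacent = False
                        break
                if adjacent:
                    combo = [sp * b - sn * a for a, b in zip(rp, rn)]
                    new.append(_reduce(combo))
                if len(new) > max_rays:
                    raise CapacityError(
                        f"intermediate ray count exceeded cap of {max_rays}"
                    )
        # support-minimality sweep keeps exactly the extreme rays
        new = list(dict.fromkeys(new))
        kept_masks = [_support_mask(ray) for ray in new]
        rays = [
            ray
            for ray, mask in zip(new, kept_masks)
            if not any(
                other != mask and other | mask == mask for other in kept_masks
            )
        ]
    return rays


def enumerate_efms(net: MetabolicNetwork, max_rays: int = 100_000) -> EFMSet:
    """Enumerate every EFM of ``net`` exactly once, up to positive scaling.

    Reversible reactions are handled by splitting; the forward/backward
    two-cycles this introduces are discarded, and when a mode's support lies
    entirely on reversible reactions only one direction (canonical sign:
    positive flux at the lowest support index) is reported, since the
    reversed vector has the identical support.

    Modes are normalised so the substrate-uptake flux equals 1 when that
    reaction is in the support, and to max |flux| = 1 otherwise; output order
    is lexicographic by support, making mode indices deterministic.

    A network admitting no nonzero steady-state flux yields an empty set.
    Raises :class:`CapacityError` when the intermediate tableau exceeds
    ``max_rays``.
    """
    split_map = split_reversible(net)
    split = split_map.split_network
    rows = _integer_rows(split)
    rays = _double_description(rows, split.n_reactions, max_rays)

    two_cycles = {
        frozenset((split_map.forward_index[rid], split_map.backward_index[rid]))
        for rid in split_map.forward_index
    }
    fwd = split_map.forward_index
    bwd = split_map.backward_index
    col_of: list[tuple[int, int]] = []  # original j -> (fwd col, bwd col or -1)
    k = 0
    for j, rid in enumerate(net.reaction_ids):
        if net.reversible[j]:
            col_of.append((fwd[rid], bwd[rid]))
            k += 2
        else:
            col_of.append((k, -1))
            k += 1

    uptake = net.role_index("substrate_uptake")
    seen: dict[frozenset[int], FluxMode] = {}
    for ray in rays:
        supp_split = frozenset(j for j, v in enumerate(ray) if v != 0)
        if supp_split in two_cycles:
            continue
        merged = []
        for f, b in col_of:
            v = Fraction(ray[f])
            if b >= 0:
                v -= ray[b]
            merged.append(v)
        support = frozenset(j for j, v in enumerate(merged) if v != 0)
        if not support:
            continue
        first = min(support)
        if merged[first] < 0:
            merged = [-v for v in merged]
        if support in seen:
            continue
        if uptake is not None and uptake in support:
            scale = merged[uptake]
        else:
            scale = max(abs(v) for v in merged)
        flux = tuple(float(v / scale) for v in merged)
        seen[support] = FluxMode(flux=flux, support=support)

    modes = sorted(seen.values(), key=lambda m: tuple(sorted(m.support)))
    return EFMSet(modes=modes, network=net)


def is_elementary(net: MetabolicNetwork, flux: Sequence[float]) -> bool:
    """Rank test for non-decomposability of an admissible flux vector.

    True iff rank of the stoichiometric submatrix on the support equals
    |support| - 1 (one-dimensional nullspace: the mode cannot be written as a
    combination of admissible vectors with strictly smaller supports).

    Raises ``ValueError`` when ``flux`` is zero, violates steady state or
    breaks an irreversibility constraint.
    """
    flux = np.asarray(flux, dtype=float)
    scale = np.max(np.abs(flux))
    if scale <= TOL_ZERO:
        raise ValueError("flux vector is zero; an EFM must be nonzero")
    v = flux / scale
    N = net.stoich_array
    if np.max(np.abs(N @ v)) > TOL_BALANCE * max(1.0, np.max(np.abs(N))):
        raise ValueError("flux vector violates steady state N v = 0")
    for j, rev in enumerate(net.reversible):
        if not rev and v[j] < -TOL_ZERO:
            raise ValueError(
                f"irreversible reaction {net.reaction_ids[j]} carries negative flux"
            )
    support = [j for j in range(len(v)) if abs(v[j]) > TOL_ZERO]
    rank = np.linalg.matrix_rank(N[:, support])
    return rank == len(support) - 1


def normalize_mode(mode: FluxMode, reference: int) -> FluxMode:
    """Rescale so the flux through reaction index ``reference`` equals 1."""
    ref = mode.flux[reference]
    if abs(ref) <= TOL_ZERO:
        raise ValueError(
            f"cannot normalise: reference reaction {reference} carries zero flux"
        )
    return FluxMode.from_flux(tuple(v / ref for v in mode.flux))


# ---------------------------------------------------------------------------
# flux-matrix interchange format: header of reaction ids, one EFM per line
# ---------------------------------------------------------------------------

def write_efm_matrix(efms: EFMSet, path: str | Path) -> None:
    lines = ["\t".join(efms.network.reaction_ids)]
    for mode in efms.modes:
        lines.append("\t".join(
            "0" if v == 0 else f"{v:.12g}" for v in mode.flux
        ))
    Path(path).write_text("\n".join(lines) + "\n")


def read_efm_matrix(path: str | Path, network: MetabolicNetwork) -> EFMSet:
    """Read a precomputed flux matrix (columns matched to ``network`` order)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty EFM matrix")
    header = lines[0].split("\t")
    if header != list(network.reaction_ids):
        raise ValueError(f"{path}: header does not match network reaction ids")
    modes = []
    for line in lines[1:]:
        if not line.strip():
            continue
        modes.append(FluxMode.from_flux([float(x) for x in line.split("\t")]))
    return EFMSet(modes=modes, network=network)
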