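"""Toy metabolic networks with analytically known EFM structure.

Every generator here produces a branched source→sink network whose EFMs
are forced by construction — one independent conversion branch per mode —
so cut-set solvers and the GA can be tested against exhaustive oracles
without any external model.  Stoichiometry is integer-only, keeping exact
rational EFM checks available, and carbon counts mirror the
glucose(6C)/ethanol(2C) scale so C-mol yields land on familiar values
(a 2-products-per-substrate branch has yield 2·2/6 = 0.6667).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Literal, Sequence

import numpy as np
from scipy.linalg import null_space

from .network import MetabolicNetwork

__all__ = [
    "Branch",
    "ToySpec",
    "GroundTruthRow",
    "make_parallel_paths",
    "make_cell_factory",
    "make_random_network",
    "DEFAULT_BRANCHES",
]

BranchKind = Literal["product", "biomass", "byproduct", "mixed"]


@dataclass(frozen=True)
class Branch:
    """One conversion branch: ``substrate_coef`` S → products.

    ``product_coef``/``biomass_coef`` are molecules of product/biomass
    precursor formed per ``substrate_coef`` substrate consumed.
    """

    kind: BranchKind
    substrate_coef: int = 1
    product_coef: int = 0
    biomass_coef: int = 0

    def __post_init__(self):
        if self.substrate_coef < 1:
            raise ValueError("substrate_coef must be a positive integer")
        if self.kind == "product" and self.product_coef < 1:
            raise ValueError("a product branch needs product_coef >= 1")
        if self.kind == "biomass" and self.biomass_coef < 1:
            raise ValueError("a biomass branch needs biomass_coef >= 1")
        if self.kind == "mixed" and (self.product_coef < 1 or self.biomass_coef < 1):
            raise ValueError("a mixed branch needs both coefficients >= 1")


#: default cell-factory layout: two max-yield producers, one low-yield
#: producer, two growth-coupled (mixed) branches, one pure-growth branch
#: and two waste byproduct branches — 8 EFMs, 5 of them product-forming.
DEFAULT_BRANCHES: tuple[Branch, ...] = (
    Branch("product", 1, product_coef=2),
    Branch("product", 1, product_coef=2),
    Branch("product", 1, product_coef=1),
    Branch("mixed", 2, product_coef=2, biomass_coef=1),
    Branch("mixed", 3, product_coef=2, biomass_coef=2),
    Branch("biomass", 1, biomass_coef=1),
    Branch("byproduct", 1),
    Branch("byproduct", 1),
)


@dataclass
class ToySpec:
    """Specification of a synthetic cell factory."""

    branches: Sequence[Branch] = DEFAULT_BRANCHES
    substrate_carbons: int = 6
    product_carbons: int = 2
    seed: int | None = None

    def __post_init__(self):
        if len(self.branches) < 1:
            raise ValueError("at least one branch is required")
        if self.substrate_carbons < 1 or self.product_carbons < 1:
            raise ValueError("carbon counts must be positive integers")


@dataclass(frozen=True)
class GroundTruthRow:
    """Oracle-computed description of one EFM of a toy network."""

    support: frozenset[int]
    reaction_ids: tuple[str, ...]
    yield_product: float
    yield_biomass: float

    @property
    def efficiency(self) -> float:
        return self.yield_product * self.yield_biomass


def make_parallel_paths(k: int) -> MetabolicNetwork:
    """k independent source→sink chains sharing one uptake: exactly k EFMs."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rids = ["R_UP"]
    cols: list[list[tuple[str, int]]] = [[("S", 1)]]  # uptake: -> S
    for i in range(1, k + 1):
        cols.append([("S", -1), (f"X{i}", 1)])
        rids.append(f"R_CHAIN{i}")
        cols.append([(f"X{i}", -1)])
        rids.append(f"R_SINK{i}")
    mets: list[str] = []
    for col in cols:
        for met, _ in col:
            if met not in mets:
                mets.append(met)
    stoich = [[Fraction(0)] * len(rids) for _ in mets]
    for j, col in enumerate(cols):
        for met, coef in col:
            stoich[mets.index(met)][j] += coef
    return MetabolicNetwork(
        reaction_ids=rids,
        metabolite_ids=mets,
        stoich=stoich,
        reversible=[False] * len(rids),
        roles={"substrate_uptake": "R_UP"},
    )


def make_cell_factory(spec: ToySpec | None = None) -> tuple[MetabolicNetwork, list[GroundTruthRow]]:
    """A branched cell factory plus its oracle-computed ground-truth table.

    Layout: one substrate uptake feeding S; each branch converts S into the
    shared product pool E (secreted by the product exporter), the biomass
    precursor B (consumed by the biomass drain), and/or its own waste sink.
    Each branch forces exactly one EFM, so mode supports, yields and
    efficiencies are known analytically; the returned table recomputes them
    with the exhaustive subset-scan oracle, independent of the production
    enumerator.
    """
    spec = spec or ToySpec()
    oversized = len(spec.branches) > 20
    if oversized:
        warnings.warn(
            f"{len(spec.branches)} branches imply {len(spec.branches)} EFMs; "
            "exhaustive partition scans cost 2^rho",
            stacklevel=2,
        )
    rids = ["R_SUB_UP"]
    cols: list[list[tuple[str, int]]] = [[("S", 1)]]
    uses_product = any(b.product_coef for b in spec.branches)
    uses_biomass = any(b.biomass_coef for b in spec.branches)
    n_waste = 0
    for i, branch in enumerate(spec.branches, start=1):
        col = [("S", -branch.substrate_coef)]
        if branch.kind == "byproduct":
            n_waste += 1
            col.append((f"W{n_waste}", 1))
            cols.append(col)
            rids.append(f"R_B{i}")
            cols.append([(f"W{n_waste}", -1)])
            rids.append(f"R_W{n_waste}_EX")
            continue
        if branch.product_coef:
            col.append(("E", branch.product_coef))
        if branch.biomass_coef:
            col.append(("B", branch.biomass_coef))
        cols.append(col)
        rids.append(f"R_B{i}")
    roles = {"substrate_uptake": "R_SUB_UP"}
    if uses_product:
        cols.append([("E", -1)])
        rids.append("R_PROD_EX")
        roles["product_secretion"] = "R_PROD_EX"
    if uses_biomass:
        cols.append([("B", -1)])
        rids.append("R_BIO")
        roles["biomass"] = "R_BIO"
    mets: list[str] = []
    for col in cols:
        for met, _ in col:
            if met not in mets:
                mets.append(met)
    stoich = [[Fraction(0)] * len(rids) for _ in mets]
    for j, col in enumerate(cols):
        for met, coef in col:
            stoich[mets.index(met)][j] += coef
    net = MetabolicNetwork(
        reaction_ids=rids,
        metabolite_ids=mets,
        stoich=stoich,
        reversible=[False] * len(rids),
        roles=roles,
        carbon={
            "substrate_carbons": spec.substrate_carbons,
            "product_carbons": spec.product_carbons,
        },
    )
    # beyond oracle scale the table falls back to the analytic per-branch
    # yields (each branch forces exactly one EFM by construction)
    truth = (_ground_truth_analytic(net, spec) if oversized
             else _ground_truth(net, spec))
    return net, truth


def _ground_truth_analytic(net: MetabolicNetwork, spec: ToySpec) -> list[GroundTruthRow]:
    cfac = spec.product_carbons / spec.substrate_carbons
    uptake = "R_SUB_UP"
    rows = []
    n_waste = 0
    for i, branch in enumerate(spec.branches, start=1):
        ids = [uptake, f"R_B{i}"]
        if branch.kind == "byproduct":
            n_waste += 1
            ids.append(f"R_W{n_waste}_EX")
            y_p = y_b = 0.0
        else:
            if branch.product_coef:
                ids.append("R_PROD_EX")
            if branch.biomass_coef:
                ids.append("R_BIO")
            y_p = branch.product_coef / branch.substrate_coef * cfac
            y_b = branch.biomass_coef / branch.substrate_coef
        support = frozenset(net.reaction_index(rid) for rid in ids)
        rows.append(GroundTruthRow(
            support=support,
            reaction_ids=tuple(net.reaction_ids[j] for j in sorted(support)),
            yield_product=float(y_p),
            yield_biomass=float(y_b),
        ))
    rows.sort(key=lambda r: tuple(sorted(r.support)))
    return rows


def _ground_truth(net: MetabolicNetwork, spec: ToySpec) -> list[GroundTruthRow]:
    # Independent oracle: exhaustive subset scan for supports, then the
    # one-dimensional nullspace vector of each support gives the fluxes.
    from .oracle import brute_force_efm_supports

    supports = brute_force_efm_supports(net)
    N = net.stoich_array
    uptake = net.role_index("substrate_uptake")
    prod = net.role_index("product_secretion")
    bio = net.role_index("biomass")
    cfac = spec.product_carbons / spec.substrate_carbons
    rows = []
    for support in sorted(supports, key=lambda s: tuple(sorted(s))):
        cols = sorted(support)
        v_small = null_space(N[:, cols])[:, 0]
        if v_small.sum() < 0:
            v_small = -v_small
        flux = dict(zip(cols, v_small))
        v_up = flux.get(uptake, 0.0)
        if abs(v_up) > 1e-12:
            y_p = (flux.get(prod, 0.0) / v_up) * cfac if prod is not None else 0.0
            y_b = flux.get(bio, 0.0) / v_up if bio is not None else 0.0
        else:
            y_p = y_b = 0.0
        rows.append(
            GroundTruthRow(
                support=frozenset(support),
                reaction_ids=tuple(net.reaction_ids[j] for j in cols),
                yield_product=float(y_p),
                yield_biomass=float(y_b),
            )
        )
    return rows


def make_random_network(
    m: int,
    r: int,
    density: float = 0.4,
    seed: int | None = None,
    reversible_fraction: float = 0.0,
) -> MetabolicNetwork:
    """Random sparse integer network with a guaranteed uptake and sink.

    Intended only for property tests against brute-force oracles; keep
    m <= 8 and r <= 15 so exhaustive scans stay tractable.  Deterministic
    under a fixed seed.
    """
    if m < 1 or r < 2:
        raise ValueError("need m >= 1 and r >= 2")
    rng = np.random.default_rng(seed)
    stoich = [[Fraction(0)] * r for _ in range(m)]
    stoich[0][0] = Fraction(1)  # uptake: -> M0
    stoich[m - 1][r - 1] = Fraction(-1)  # sink: M_last ->
    for j in range(1, r - 1):
        col = np.zeros(m, dtype=int)
        for i in range(m):
            if rng.random() < density:
                col[i] = int(rng.choice([-2, -1, 1, 2]))
        if not col.any() or (col >= 0).all() or (col <= 0).all():
            # degenerate column: replace with a chain link
            a = j % m
            b = (j + 1) % m if (j + 1) % m != a else (a + 1) % m
            col[:] = 0
            col[a], col[b] = -1, 1
        for i in range(m):
            stoich[i][j] = Fraction(int(col[i]))
    reversible = [
        bool(rng.random() < reversible_fraction) if 0 < j < r - 1 else False
        for j in range(r)
    ]
    return MetabolicNetwork(
        reaction_ids=[f"R{j}" for j in range(r)],
        metabolite_ids=[f"M{i}" for i in range(m)],
        stoich=stoich,
        reversible=reversible,
    )
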