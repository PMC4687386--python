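"""Per-mode yields/efficiencies and the fitness functions F1–F3.

Yield of a mode is product (or biomass) flux per unit substrate-uptake
flux; with C-mol normalisation the product yield is additionally scaled by
product_carbons / substrate_carbons (the glucose→ethanol configuration
prints a maximum of 2 × 2/6 = 0.6667).  Efficiency η is the product of the
product and biomass yields — a growth-coupling score.

The three maximised fitness functions, for a survivor group with cut set C
over a network of n reactions and an EFM set of size |E|:

    F1 = w1·min Y        + w3·(1 − |C|/n)
    F2 = w2·min η        + w3·(1 − |C|/n)
    F3 = w1·min Y × w2·max η + w3·(1 − |C|/n) + w4·|D^C|/|E|

min/max are taken over the surviving modes' metrics: min Y is the
worst-case guaranteed yield of the designed strain, max η its best
surviving growth-coupled mode.  All objectives share the (1 − |C|/n) term
favouring low-cardinality knockout sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .efm import FluxMode
from .network import MetabolicNetwork

__all__ = ["FitnessSpec", "ModeMetrics", "mode_metrics", "pattern_fitness"]

_REQUIRED_WEIGHTS = {
    "F1": ("w1", "w3"),
    "F2": ("w2", "w3"),
    "F3": ("w1", "w2", "w3", "w4"),
}


@dataclass
class FitnessSpec:
    """Objective choice, weights and normalisation context.

    ``n_total`` is n, the reaction count used in the |C|/n penalty
    (exchange reactions included; overridable); ``total_modes`` is |E|.
    """

    objective: str
    network: MetabolicNetwork
    w1: float = 1.0
    w2: float = 0.0
    w3: float = 1.0
    w4: float = 0.0
    normalization: str = "cmol"
    n_total: int = 0
    total_modes: int = 1

    def __post_init__(self):
        if self.objective not in _REQUIRED_WEIGHTS:
            raise ValueError(f"objective must be F1|F2|F3, got {self.objective!r}")
        for name in _REQUIRED_WEIGHTS[self.objective]:
            w = getattr(self, name)
            if not (w >= 0 and w == w and w != float("inf")):
                raise ValueError(f"{name} must be finite and non-negative for {self.objective}")
        if self.normalization not in ("molar", "cmol"):
            raise ValueError("normalization must be 'molar' or 'cmol'")
        if self.n_total == 0:
            self.n_total = self.network.n_reactions
        if self.n_total < 1 or self.total_modes < 1:
            raise ValueError("n_total and total_modes must be >= 1")

    @property
    def carbon_factor(self) -> float:
        if self.normalization == "molar":
            return 1.0
        sc = self.network.carbon.get("substrate_carbons")
        pc = self.network.carbon.get("product_carbons")
        if not sc or not pc:
            raise ValueError(
                "cmol normalization requires substrate_carbons and product_carbons"
            )
        return pc / sc


@dataclass(frozen=True)
class ModeMetrics:
    """Yields of one mode; efficiency = yield_product × yield_biomass."""

    yield_product: float
    yield_biomass: float

    @property
    def efficiency(self) -> float:
        return self.yield_product * self.yield_biomass


def mode_metrics(mode: FluxMode, spec: FitnessSpec) -> ModeMetrics:
    """Product and biomass yields of one mode per unit substrate uptake.

    Modes without substrate uptake get all-zero metrics.  Biomass yield is
    always a molar flux ratio (biomass is not a carbon-countable species);
    the product yield is C-mol scaled when the spec says so.
    """
    net = spec.network
    uptake = net.role_index("substrate_uptake")
    if uptake is None:
        raise ValueError("FitnessSpec network lacks a substrate_uptake role")
    v_up = mode.flux[uptake] if uptake < len(mode.flux) else 0.0
    if abs(v_up) < 1e-12:
        return ModeMetrics(0.0, 0.0)
    y_p = 0.0
    prod = net.role_index("product_secretion")
    if prod is not None:
        y_p = mode.flux[prod] / v_up
        if y_p < -1e-12:
            raise ValueError(
                f"negative product yield: reaction {net.roles['product_secretion']} "
                "carries flux of the wrong sign"
            )
        y_p = max(y_p, 0.0) * spec.carbon_factor
    y_b = 0.0
    bio = net.role_index("biomass")
    if bio is not None:
        y_b = mode.flux[bio] / v_up
        if y_b < -1e-12:
            raise ValueError(
                f"negative biomass yield: reaction {net.roles['biomass']} "
                "carries flux of the wrong sign"
            )
        y_b = max(y_b, 0.0)
    return ModeMetrics(y_p, y_b)


def pattern_fitness(
    surviving: Iterable[ModeMetrics],
    cut_cardinality: int,
    survivor_count: int,
    spec: FitnessSpec,
) -> float:
    """Evaluate the configured objective on one survivor group.

    ``surviving`` are the metrics of the modes left alive by a cut set of
    the given cardinality.  Empty survivor groups never reach this function
    (infeasible partitions score 0 upstream).
    """
    metrics = list(surviving)
    if not metrics or survivor_count < 1:
        raise ValueError("pattern_fitness requires at least one surviving mode")
    if cut_cardinality > spec.n_total:
        raise ValueError("cut cardinality exceeds the reaction count n")
    size_term = spec.w3 * (1.0 - cut_cardinality / spec.n_total)
    if spec.objective == "F1":
        return spec.w1 * min(m.yield_product for m in metrics) + size_term
    if spec.objective == "F2":
        return spec.w2 * min(m.efficiency for m in metrics) + size_term
    # F3
    min_y = min(m.yield_product for m in metrics)
    max_eta = max(m.efficiency for m in metrics)
    return (
        spec.w1 * min_y * spec.w2 * max_eta
        + size_term
        + spec.w4 * survivor_count / spec.total_modes
    )
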