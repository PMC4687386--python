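"""Stoichiometric metabolic networks with reaction role annotations.

A network is the pair (N, Irrev): an m x r stoichiometric matrix over the
*internal* metabolites and the index set of irreversible reactions.  External
metabolites are implicit — exchange reactions simply have one empty side, so
their unbalanced rows never appear in N.  Up to three reactions can carry a
design role: the substrate uptake, the product secretion and the biomass
drain; these drive yield computation and are protected from knockout by
default.

Coefficients are stored as exact :class:`fractions.Fraction` values (sources
provide integers or decimals, and elementarity tests are rank computations
that benefit from exactness at desk scale); ``stoich_array`` exposes the
float view used by numerics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MetabolicNetwork",
    "ReversibleSplitMap",
    "NetworkFormatError",
    "NetworkValidationError",
    "load_network",
    "load_roles",
    "write_tsv",
    "split_reversible",
    "validate_network",
]

#: role labels recognised in role configuration files
ROLE_LABELS = ("substrate_uptake", "product_secretion", "biomass")


class NetworkFormatError(ValueError):
    """Raised when a network file cannot be parsed."""


class NetworkValidationError(ValueError):
    """Raised when a parsed network violates a structural invariant."""


@dataclass
class MetabolicNetwork:
    """An (m x r) stoichiometric network.

    Parameters
    ----------
    reaction_ids
        Unique reaction identifiers, in file/column order.
    metabolite_ids
        Unique internal-metabolite identifiers, in row order.
    stoich
        m x r matrix of exact ``Fraction`` coefficients (list of rows).
    reversible
        Per-reaction reversibility flags; the complement of Irrev.
    roles
        Partial map from role label to reaction id.
    carbon
        Optional carbon-atom counts, keys ``substrate_carbons`` /
        ``product_carbons``, for C-mol yield normalisation.
    """

    reaction_ids: Sequence[str]
    metabolite_ids: Sequence[str]
    stoich: Sequence[Sequence[Fraction]]
    reversible: Sequence[bool]
    roles: Mapping[str, str] = field(default_factory=dict)
    carbon: Mapping[str, int] = field(default_factory=dict)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def stoich_array(self) -> np.ndarray:
        """Float view of the stoichiometric matrix (m x r)."""
        return np.array(
            [[float(c) for c in row] for row in self.stoich], dtype=float
        ).reshape(self.n_metabolites, self.n_reactions)

    def reaction_index(self, rid: str) -> int:
        try:
            return list(self.reaction_ids).index(rid)
        except ValueError:
            raise KeyError(f"unknown reaction id {rid!r}") from None

    def role_index(self, role: str) -> int | None:
        """Column index of the reaction carrying ``role``, or None."""
        rid = self.roles.get(role)
        return None if rid is None else self.reaction_index(rid)

    def validate(self) -> None:
        violations = validate_network(self)
        if violations:
            raise NetworkValidationError("; ".join(violations))


@dataclass
class ReversibleSplitMap:
    """Irreversible view of a network, every reversible reaction split in two.

    ``forward_index[rid]``/``backward_index[rid]`` give the two column indices
    of the split network standing in for reversible reaction ``rid``; the
    backward column is the negated forward column.
    """

    split_network: MetabolicNetwork
    forward_index: Mapping[str, int]
    backward_index: Mapping[str, int]


def validate_network(net: MetabolicNetwork) -> list[str]:
    """Check every structural invariant; return a (possibly empty) report.

    Each violation names the offending field.  An empty list means the
    network is well-formed.
    """
    out: list[str] = []
    r, m = len(net.reaction_ids), len(net.metabolite_ids)
    if r < 1:
        out.append("reaction_ids: at least one reaction required")
    if m < 1:
        out.append("metabolite_ids: at least one internal metabolite required")
    if len(set(net.reaction_ids)) != r:
        out.append("reaction_ids: duplicate identifiers")
    if len(set(net.metabolite_ids)) != m:
        out.append("metabolite_ids: duplicate identifiers")
    if len(net.stoich) != m:
        out.append(f"stoich: expected {m} rows, found {len(net.stoich)}")
    else:
        for i, row in enumerate(net.stoich):
            if len(row) != r:
                out.append(f"stoich: row {i} has {len(row)} columns, expected {r}")
    if len(net.reversible) != r:
        out.append("reversible: length must equal number of reactions")
    known = set(net.reaction_ids)
    for role, rid in net.roles.items():
        if role not in ROLE_LABELS:
            out.append(f"roles: unknown role label {role!r}")
        if rid not in known:
            out.append(f"roles: {role} references unknown reaction {rid!r}")
    for key, count in net.carbon.items():
        if not (isinstance(count, int) and count > 0):
            out.append(f"carbon: {key} must be a positive integer")
    return out


# ---------------------------------------------------------------------------
# TSV dialect
#
# One reaction per line:  id<TAB>equation<TAB>rev
# equation: "[coef] met + [coef] met ... (->|<->) ...", either side may be
# empty (exchange reaction).  The third column is optional and redundant with
# the arrow ("rev"/"irrev"); "<->" always means reversible.
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"^(?:(\d+(?:\.\d+)?|\d+/\d+)\s+)?(\S+)$")


def _parse_side(side: str, lineno: int) -> list[tuple[Fraction, str]]:
    side = side.strip()
    if not side:
        return []
    terms = []
    for part in side.split("+"):
        part = part.strip()
        if not part:
            raise NetworkFormatError(f"line {lineno}: empty term in equation")
        match = _TOKEN.match(part)
        if match is None:
            raise NetworkFormatError(f"line {lineno}: cannot parse term {part!r}")
        coef = Fraction(match.group(1)) if match.group(1) else Fraction(1)
        terms.append((coef, match.group(2)))
    return terms


def _parse_equation(eq: str, lineno: int) -> tuple[list, list, bool]:
    if "<->" in eq:
        lhs, rhs = eq.split("<->", 1)
        rev = True
    elif "->" in eq:
        lhs, rhs = eq.split("->", 1)
        rev = False
    else:
        raise NetworkFormatError(f"line {lineno}: equation lacks '->' or '<->'")
    return _parse_side(lhs, lineno), _parse_side(rhs, lineno), rev


def _network_from_reactions(
    reactions: list[tuple[str, list, list, bool]],
    roles: Mapping[str, str] | None,
    carbon: Mapping[str, int] | None,
) -> MetabolicNetwork:
    rids = [r[0] for r in reactions]
    mets: list[str] = []
    for _, lhs, rhs, _ in reactions:
        for _, met in lhs + rhs:
            if met not in mets:
                mets.append(met)
    stoich = [[Fraction(0)] * len(rids) for _ in mets]
    midx = {met: i for i, met in enumerate(mets)}
    for j, (_, lhs, rhs, _) in enumerate(reactions):
        for coef, met in lhs:
            stoich[midx[met]][j] -= coef
        for coef, met in rhs:
            stoich[midx[met]][j] += coef
    net = MetabolicNetwork(
        reaction_ids=rids,
        metabolite_ids=mets,
        stoich=stoich,
        reversible=[r[3] for r in reactions],
        roles=dict(roles or {}),
        carbon=dict(carbon or {}),
    )
    net.validate()
    return net


def load_network(
    path: str | Path,
    format: str = "tsv",
    roles: Mapping[str, str] | None = None,
    carbon: Mapping[str, int] | None = None,
) -> MetabolicNetwork:
    """Load a network from ``path`` in the named format (``tsv`` or ``sbml``).

    Coefficients are preserved exactly as written and reaction order follows
    file order.  Role annotations are supplied separately (``roles``), never
    parsed from the model file.
    """
    path = Path(path)
    if format == "tsv":
        reactions = []
        seen = set()
        for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise NetworkFormatError(
                    f"line {lineno}: expected 'id<TAB>equation[<TAB>rev]'"
                )
            rid, eq = fields[0].strip(), fields[1].strip()
            if rid in seen:
                raise NetworkValidationError(
                    f"line {lineno}: duplicate reaction id {rid!r}"
                )
            seen.add(rid)
            lhs, rhs, rev = _parse_equation(eq, lineno)
            if len(fields) >= 3 and fields[2].strip():
                flag = fields[2].strip().lower()
                if flag not in ("rev", "irrev"):
                    raise NetworkFormatError(
                        f"line {lineno}: reversibility flag must be rev|irrev"
                    )
                rev = flag == "rev"
            reactions.append((rid, lhs, rhs, rev))
        if not reactions:
            raise NetworkFormatError(f"{path}: no reactions found")
        return _network_from_reactions(reactions, roles, carbon)
    if format == "sbml":
        return _load_sbml(path, roles, carbon)
    raise ValueError(f"unknown format {format!r} (expected 'sbml' or 'tsv')")


def _load_sbml(path: Path, roles, carbon) -> MetabolicNetwork:
    # cobra drops boundary-condition species and resolves FBC reversibility.
    import cobra.io

    model = cobra.io.read_sbml_model(str(path))
    reactions = []
    for rxn in model.reactions:
        lhs = [(Fraction(-c).limit_denominator(10**6), met.id)
               for met, c in rxn.metabolites.items() if c < 0]
        rhs = [(Fraction(c).limit_denominator(10**6), met.id)
               for met, c in rxn.metabolites.items() if c > 0]
        reactions.append((rxn.id, lhs, rhs, rxn.reversibility))
    return _network_from_reactions(reactions, roles, carbon)


def _format_coef(coef: Fraction) -> str:
    if coef == 1:
        return ""
    if coef.denominator == 1:
        return f"{coef.numerator} "
    return f"{coef} "


def write_tsv(net: MetabolicNetwork, path: str | Path) -> None:
    """Write the TSV dialect; integer coefficients round-trip bit-exactly."""
    lines = []
    for j, rid in enumerate(net.reaction_ids):
        lhs, rhs = [], []
        for i, met in enumerate(net.metabolite_ids):
            coef = net.stoich[i][j]
            if coef < 0:
                lhs.append(f"{_format_coef(-coef)}{met}")
            elif coef > 0:
                rhs.append(f"{_format_coef(coef)}{met}")
        arrow = "<->" if net.reversible[j] else "->"
        eq = f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()
        flag = "rev" if net.reversible[j] else "irrev"
        lines.append(f"{rid}\t{eq}\t{flag}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_roles(path: str | Path) -> tuple[dict[str, str], dict[str, int]]:
    """Read a ``key=value`` role-configuration file.

    Recognised keys: ``substrate_reaction``, ``product_reaction``,
    ``biomass_reaction``, ``substrate_carbons``, ``product_carbons``.
    """
    roles: dict[str, str] = {}
    carbon: dict[str, int] = {}
    key_to_role = {
        "substrate_reaction": "substrate_uptake",
        "product_reaction": "product_secretion",
        "biomass_reaction": "biomass",
    }
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise NetworkFormatError(f"line {lineno}: expected key=value")
        key, value = (part.strip() for part in line.split("=", 1))
        if key in key_to_role:
            roles[key_to_role[key]] = value
        elif key in ("substrate_carbons", "product_carbons"):
            carbon[key] = int(value)
        else:
            raise NetworkFormatError(f"line {lineno}: unknown role key {key!r}")
    return roles, carbon


def split_reversible(net: MetabolicNetwork) -> ReversibleSplitMap:
    """Split every reversible reaction into a forward/backward pair.

    Irreversible reactions keep their single column unchanged; the split
    network is entirely irreversible with r + #reversible columns.
    """
    rids: list[str] = []
    cols: list[list[Fraction]] = []  # column-major build
    forward: dict[str, int] = {}
    backward: dict[str, int] = {}
    for j, rid in enumerate(net.reaction_ids):
        col = [net.stoich[i][j] for i in range(net.n_metabolites)]
        if net.reversible[j]:
            forward[rid] = len(rids)
            rids.append(f"{rid}__fwd")
            cols.append(col)
            backward[rid] = len(rids)
            rids.append(f"{rid}__bwd")
            cols.append([-c for c in col])
        else:
            rids.append(rid)
            cols.append(col)
    stoich = [[cols[j][i] for j in range(len(cols))]
              for i in range(net.n_metabolites)]
    split = MetabolicNetwork(
        reaction_ids=rids,
        metabolite_ids=list(net.metabolite_ids),
        stoich=stoich,
        reversible=[False] * len(rids),
        roles={},
        carbon=dict(net.carbon),
    )
    return ReversibleSplitMap(split, forward, backward)
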