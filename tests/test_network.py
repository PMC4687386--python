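"""Network loading, validation, TSV round-trips and reversible splitting."""

from fractions import Fraction

import numpy as np
import pytest
from scipy.linalg import null_space

from gamcs import (
    MetabolicNetwork,
    load_network,
    load_roles,
    split_reversible,
    validate_network,
    write_tsv,
)
from gamcs.network import NetworkFormatError, NetworkValidationError
from gamcs.synthetic import make_random_network

from conftest import net_from_tsv


@pytest.mark.parametrize(
    "tsv, rid, expected_col, expected_rev",
    [
        ("R1\t-> A\tirrev\nR2\tA ->\tirrev\n", "R1", {"A": 1}, False),
        ("R1\t-> A\tirrev\nR2\tA ->\tirrev\n", "R2", {"A": -1}, False),
        ("R3\tA <-> B\trev\nRx\t-> A\tirrev\n", "R3", {"A": -1, "B": 1}, True),
        ("R4\t2 A -> B\tirrev\nRx\t-> A\tirrev\n", "R4", {"A": -2, "B": 1}, False),
        ("R5\tA + B -> 3 C\tirrev\nRx\t-> A\tirrev\n", "R5",
         {"A": -1, "B": -1, "C": 3}, False),
    ],
)
def test_tsv_dialect_columns(tmp_path, tsv, rid, expected_col, expected_rev):
    net = net_from_tsv(tmp_path, tsv)
    j = net.reaction_index(rid)
    col = {met: net.stoich[i][j] for i, met in enumerate(net.metabolite_ids)
           if net.stoich[i][j] != 0}
    assert col == {k: Fraction(v) for k, v in expected_col.items()}
    assert net.reversible[j] is expected_rev


def test_arrow_implies_reversibility_without_flag(tmp_path):
    net = net_from_tsv(tmp_path, "R1\tA <-> B\nR2\t-> A\n")
    assert net.reversible[0] and not net.reversible[1]


def test_reaction_order_follows_file_order(tmp_path):
    net = net_from_tsv(tmp_path, "RB\t-> A\tirrev\nRA\tA ->\tirrev\n")
    assert list(net.reaction_ids) == ["RB", "RA"]


def test_roundtrip_preserves_everything(tmp_path, factory):
    net, _ = factory
    out = tmp_path / "rt.tsv"
    write_tsv(net, out)
    back = load_network(out, roles=dict(net.roles), carbon=dict(net.carbon))
    assert list(back.reaction_ids) == list(net.reaction_ids)
    assert list(back.metabolite_ids) == list(net.metabolite_ids)
    assert [list(r) for r in back.stoich] == [list(r) for r in net.stoich]
    assert list(back.reversible) == list(net.reversible)
    assert dict(back.roles) == dict(net.roles)


@pytest.mark.parametrize(
    "tsv, exc",
    [
        ("R1\tA + -> B\tirrev\n", NetworkFormatError),       # empty term
        ("R1\tA = B\tirrev\n", NetworkFormatError),          # no arrow
        ("R1\t-> A\tmaybe\n", NetworkFormatError),           # bad flag
        ("R1\t-> A\tirrev\nR1\tA ->\tirrev\n", NetworkValidationError),
        ("just one field\n", NetworkFormatError),
    ],
)
def test_parse_errors_name_the_line(tmp_path, tsv, exc):
    with pytest.raises(exc, match="line|field|id"):
        net_from_tsv(tmp_path, tsv)


def test_role_referencing_unknown_reaction_rejected(tmp_path):
    with pytest.raises(NetworkValidationError, match="unknown reaction"):
        net_from_tsv(tmp_path, "R1\t-> A\tirrev\nR2\tA ->\tirrev\n",
                     roles={"substrate_uptake": "NOPE"})


def test_validate_reports_each_violation():
    net = MetabolicNetwork(
        reaction_ids=["R1", "R1"],
        metabolite_ids=["A"],
        stoich=[[Fraction(1), Fraction(-1)], [Fraction(0), Fraction(0)]],
        reversible=[False, False],
        carbon={"substrate_carbons": -2},
    )
    report = validate_network(net)
    assert any("duplicate" in v for v in report)
    assert any("stoich" in v for v in report)
    assert any("carbon" in v for v in report)


def test_validate_clean_network_is_empty(diamond):
    assert validate_network(diamond) == []


def test_load_roles_config(tmp_path):
    cfg = tmp_path / "roles.cfg"
    cfg.write_text(
        "substrate_reaction=R_UP\nproduct_reaction=R_P\n"
        "biomass_reaction=R_B\nsubstrate_carbons=6\nproduct_carbons=2\n"
    )
    roles, carbon = load_roles(cfg)
    assert roles == {
        "substrate_uptake": "R_UP",
        "product_secretion": "R_P",
        "biomass": "R_B",
    }
    assert carbon == {"substrate_carbons": 6, "product_carbons": 2}


def test_split_without_reversible_is_identity(diamond):
    split = split_reversible(diamond)
    assert split.split_network.n_reactions == diamond.n_reactions
    assert split.backward_index == {}
    assert split.split_network.stoich == diamond.stoich


def test_split_one_reversible_among_three(tmp_path):
    net = net_from_tsv(tmp_path, "R1\t-> A\tirrev\nR2\tA <-> B\trev\nR3\tB ->\tirrev\n")
    split = split_reversible(net)
    sn = split.split_network
    assert sn.n_reactions == 4
    assert not any(sn.reversible)
    f, b = split.forward_index["R2"], split.backward_index["R2"]
    for i in range(sn.n_metabolites):
        assert sn.stoich[i][b] == -sn.stoich[i][f]


def test_split_all_reversible(tmp_path):
    net = net_from_tsv(tmp_path, "R1\t<-> A\trev\nR2\tA <-> B\trev\n")
    split = split_reversible(net)
    assert split.split_network.n_reactions == 4
    assert len(split.forward_index) == len(split.backward_index) == 2


def test_split_preserves_nullspace_dimension():
    # dim null(N) = dim null(N_split) - #reversible on random networks
    for seed in range(5):
        net = make_random_network(4, 8, seed=seed, reversible_fraction=0.4)
        split = split_reversible(net)
        n_rev = sum(net.reversible)
        d = null_space(net.stoich_array).shape[1]
        d_split = null_space(split.split_network.stoich_array).shape[1]
        assert d == d_split - n_rev


def test_sbml_roundtrip(tmp_path):
    cobra = pytest.importorskip("cobra")
    model = cobra.Model("toy")
    a = cobra.Metabolite("A", compartment="c")
    b = cobra.Metabolite("B", compartment="c")
    r1 = cobra.Reaction("R1", lower_bound=0.0)
    r1.add_metabolites({a: 1})
    r2 = cobra.Reaction("R2", lower_bound=-1000.0)
    r2.add_metabolites({a: -1, b: 1})
    r3 = cobra.Reaction("R3", lower_bound=0.0)
    r3.add_metabolites({b: -1})
    model.add_reactions([r1, r2, r3])
    path = tmp_path / "toy.xml"
    cobra.io.write_sbml_model(model, str(path))
    net = load_network(path, format="sbml", roles={"substrate_uptake": "R1"})
    assert net.n_reactions == 3 and net.n_metabolites == 2
    assert net.reversible[net.reaction_index("R2")]
    assert not net.reversible[net.reaction_index("R1")]
    j = net.reaction_index("R2")
    col = {met: net.stoich[i][j] for i, met in enumerate(net.metabolite_ids)}
    assert col == {"A": Fraction(-1), "B": Fraction(1)}
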