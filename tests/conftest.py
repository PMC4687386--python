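import pathlib

import pytest

from gamcs import (
    FitnessSpec,
    enumerate_efms,
    load_network,
    make_cell_factory,
)


def net_from_tsv(tmp_path: pathlib.Path, text: str, roles=None, carbon=None):
    path = tmp_path / "net.tsv"
    path.write_text(text)
    return load_network(path, format="tsv", roles=roles, carbon=carbon)


DIAMOND_TSV = (
    "R1\t-> A\tirrev\n"
    "R2\tA -> B\tirrev\n"
    "R3\tA -> C\tirrev\n"
    "R4\tB ->\tirrev\n"
    "R5\tC ->\tirrev\n"
)

CHAIN_TSV = (
    "R1\t-> A\tirrev\n"
    "R2\tA -> B\tirrev\n"
    "R3\tB ->\tirrev\n"
)


@pytest.fixture
def diamond(tmp_path):
    return net_from_tsv(tmp_path, DIAMOND_TSV)


@pytest.fixture
def chain(tmp_path):
    return net_from_tsv(tmp_path, CHAIN_TSV)


@pytest.fixture(scope="session")
def factory():
    """Default synthetic cell factory with its ground-truth table."""
    return make_cell_factory()


@pytest.fixture(scope="session")
def factory_efms(factory):
    net, _ = factory
    return enumerate_efms(net)


@pytest.fixture(scope="session")
def factory_spec_f1(factory, factory_efms):
    net, _ = factory
    return FitnessSpec(
        objective="F1", network=net, w1=1.0, w3=1.0,
        total_modes=factory_efms.n,
    )
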