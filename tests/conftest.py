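"""Shared fixtures: tiny hand-built meshes and databases."""

from __future__ import annotations

import numpy as np
import pytest

import stringnet as sn


@pytest.fixture
def single_string_mesh() -> sn.Mesh:
    """One horizontal Latex string: grounded at the origin, input at (100, 0)."""
    return sn.Mesh(
        name="single",
        material=sn.LATEX,
        nodes=[sn.Node(0, 0.0, 0.0, "output", True),
               sn.Node(1, 100.0, 0.0, "input")],
        strings=[sn.StringElement(0, 0, 1, 100.0, 4.0)],
    )


@pytest.fixture
def v_mesh() -> sn.Mesh:
    """Symmetric two-string V: two grounded tops, one loaded tip below."""
    return sn.Mesh(
        name="vee",
        material=sn.LATEX,
        nodes=[sn.Node(0, -50.0, 100.0, "output", True),
               sn.Node(1, 50.0, 100.0, "output", True),
               sn.Node(2, 0.0, 20.0, "input")],
        strings=[sn.StringElement(0, 0, 2, 90.0, 4.0),
                 sn.StringElement(1, 1, 2, 90.0, 4.0)],
    )


@pytest.fixture(scope="session")
def target_mesh() -> sn.Mesh:
    """Deterministic all-in-all 5-node, 6-string ground truth."""
    return sn.build_target_network("random", 3)


@pytest.fixture(scope="session")
def ideal_protocol() -> sn.Protocol:
    return sn.Protocol.for_kind("afh").ideal()


@pytest.fixture(scope="session")
def ideal_db(target_mesh, ideal_protocol) -> sn.LoadSetDatabase:
    """Noise- and quantization-free database measured from the target."""
    return sn.build_database(target_mesh, ideal_protocol, np.random.default_rng(0))


@pytest.fixture(scope="session")
def quantized_db(target_mesh) -> sn.LoadSetDatabase:
    proto = sn.Protocol.for_kind("afh")
    return sn.build_database(target_mesh, proto, np.random.default_rng(0))
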