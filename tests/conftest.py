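"""Shared fixtures: small molecules and file-format fixtures built in code."""

import numpy as np
import pytest

from stericds import (
    Atom,
    Structure,
    assign_parameters,
    minimize,
    perceive_topology,
)
from stericds.synthetic_data import MoleculeSpec, gen_molecule

ETHANE_MOL = """ethane
  test

  8  7  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5260    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.3630    1.0280    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.3630   -0.5140    0.8900 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.3630   -0.5140   -0.8900 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.8890   -1.0280    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.8890    0.5140    0.8900 H   0  0  0  0  0  0  0  0  0  0  0  0
    1.8890    0.5140   -0.8900 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0  0  0  0
  1  3  1  0  0  0  0
  1  4  1  0  0  0  0
  1  5  1  0  0  0  0
  2  6  1  0  0  0  0
  2  7  1  0  0  0  0
  2  8  1  0  0  0  0
M  END
$$$$
"""


@pytest.fixture
def ethane_file(tmp_path):
    path = tmp_path / "ethane.sdf"
    path.write_text(ETHANE_MOL)
    return path


@pytest.fixture
def water():
    """Water with O-H = 0.96 A and H...H = 1.51 A."""
    return Structure([
        Atom("O", (0.0, 0.0, 0.0), partial_charge=-0.6),
        Atom("H", (0.96, 0.0, 0.0), partial_charge=0.3),
        Atom("H", (-0.2404, 0.9294, 0.0), partial_charge=0.3),
    ], name="water")


@pytest.fixture
def diatomic():
    """A single C-C bond, slightly stretched."""
    return Structure([Atom("C", (0.0, 0.0, 0.0)),
                      Atom("C", (0.0, 0.0, 1.7))], [(0, 1, 1)])


def relaxed_system(spec: MoleculeSpec):
    """Generate, parameterize, and minimize a toy molecule."""
    s = gen_molecule(spec)
    system = assign_parameters(s)
    coords, _, _ = minimize(system, s.coords, tol=0.05, max_iter=3000)
    return system, coords


@pytest.fixture(scope="session")
def relaxed_chain4():
    return relaxed_system(MoleculeSpec("chain", 4, 1))


@pytest.fixture(scope="session")
def relaxed_polar2():
    return relaxed_system(MoleculeSpec("polar-probe", 2, 3))
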