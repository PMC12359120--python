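import math

import numpy as np
import pytest

from ffcraft.chem_core import set_dihedral_in_degrees
from ffcraft.interpolation_ff import IMDatabase, add_point, build_internal_coordinates
from ffcraft.toy_oracles import fixture_molecule, torsion_oracle

PEROXIDE_QUAD = (0, 1, 2, 3)
PEROXIDE_TERMS = [(10.0, 2, 0.0), (4.0, 1, 0.0)]


@pytest.fixture
def water():
    return fixture_molecule("water")


@pytest.fixture
def butane():
    return fixture_molecule("butane")


@pytest.fixture
def ethane():
    return fixture_molecule("ethane")


@pytest.fixture
def peroxide():
    return fixture_molecule("peroxide")


@pytest.fixture
def biphenyl():
    return fixture_molecule("biphenyl_like")


@pytest.fixture
def peroxide_oracle(peroxide):
    """Analytic torsional potential on the H-O-O-H chain."""
    return torsion_oracle(peroxide, PEROXIDE_QUAD, PEROXIDE_TERMS)


@pytest.fixture
def peroxide_db(peroxide, peroxide_oracle):
    """Six-point IM database spanning the full torsion rotation."""
    db = IMDatabase(build_internal_coordinates(peroxide))
    for ang in (0.0, 60.0, 120.0, 180.0, -120.0, -60.0):
        m = peroxide.copy()
        set_dihedral_in_degrees(m, PEROXIDE_QUAD, ang)
        add_point(m.coordinates, peroxide_oracle, db)
    return db


def finite_difference_gradient(fn, x, h=1e-5):
    """Central-difference gradient of a scalar function of an (N, 3) array."""
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x).reshape(-1)
    flat = x.reshape(-1)
    for t in range(flat.size):
        xp, xm = flat.copy(), flat.copy()
        xp[t] += h
        xm[t] -= h
        g[t] = (fn(xp.reshape(x.shape)) - fn(xm.reshape(x.shape))) / (2 * h)
    return g.reshape(x.shape)


def periodic_fd(fn, x, h=1e-6):
    """Finite differences of an angle-valued function, wrap-aware."""
    x = np.asarray(x, dtype=float)
    g = np.zeros(x.size)
    flat = x.reshape(-1)
    for t in range(flat.size):
        xp, xm = flat.copy(), flat.copy()
        xp[t] += h
        xm[t] -= h
        d = fn(xp.reshape(x.shape)) - fn(xm.reshape(x.shape))
        if abs(d) > math.pi:
            d -= math.copysign(2 * math.pi, d)
        g[t] = d / (2 * h)
    return g.reshape(x.shape)
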