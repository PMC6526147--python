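import itertools

import numpy as np
import pytest

from cidval.chem import default_table, parse_formula
from cidval.pattern import InstrumentModel


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def semet():
    return parse_formula("C5H11NO2Se")


@pytest.fixture(scope="session")
def methionine():
    return parse_formula("C5H11NO2S")


@pytest.fixture(scope="session")
def inst120():
    return InstrumentModel(resolving_power=120000.0)


@pytest.fixture(scope="session")
def inst30():
    return InstrumentModel(resolving_power=30000.0)


def enumerate_fine_pattern(formula, table):
    """Independent brute-force oracle: Cartesian enumeration over every
    atom's isotope choice, species keyed by exact mass.  Exponential in
    atom count — only for tiny formulas."""
    atoms = []
    for el, n in sorted(formula.counts.items()):
        iso = table[el]
        atoms.extend([list(zip(iso.masses, iso.abundances))] * n)
    raw = []
    for combo in itertools.product(*atoms):
        mass = sum(m for m, _ in combo)
        prob = 1.0
        for _, a in combo:
            prob *= a
        raw.append((mass, prob))
    raw.sort()
    # species separated by less than 1e-9 Da are the same isotopologue
    # up to floating-point noise in the summation order
    masses, abunds = [raw[0][0]], [raw[0][1]]
    for m, p in raw[1:]:
        if m - masses[-1] < 1e-9:
            tot = abunds[-1] + p
            masses[-1] = (masses[-1] * abunds[-1] + m * p) / tot
            abunds[-1] = tot
        else:
            masses.append(m)
            abunds.append(p)
    return np.array(masses), np.array(abunds)
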