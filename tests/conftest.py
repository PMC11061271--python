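import numpy as np
import pytest

import famseg as fs
from famseg.pedigree import (AFFECTED, CARRIER, FEMALE, MALE, NON_CARRIER,
                             UNAFFECTED, UNTESTED)


def make_individual(iid, fa=None, mo=None, sex=MALE, aff=UNAFFECTED,
                    age=None, car=UNTESTED, proband=False):
    return fs.Individual(iid, fa, mo, sex, aff, age, car, proband)


@pytest.fixture(scope="session")
def default_model():
    return fs.default_disease_model()


@pytest.fixture(scope="session")
def incidence_tables():
    carrier = [fs.default_carrier_incidence(s) for s in (MALE, FEMALE)]
    population = [fs.default_population_incidence(s) for s in (MALE, FEMALE)]
    return carrier, population


@pytest.fixture(scope="session")
def strong_pedigree():
    """Three-generation family in which the variant tracks disease closely:
    five affected carriers, six unaffected (mostly elderly) non-carriers."""
    I = make_individual
    return fs.Pedigree("STRONG", [
        I("g1", sex=MALE, aff=AFFECTED, age=62, car=CARRIER),
        I("g2", sex=FEMALE, aff=UNAFFECTED, age=80, car=NON_CARRIER),
        I("p1", "g1", "g2", MALE, AFFECTED, 48, CARRIER),
        I("s1", None, None, FEMALE, UNAFFECTED, 70, NON_CARRIER),
        I("p2", "g1", "g2", FEMALE, AFFECTED, 52, CARRIER, True),
        I("s2", None, None, MALE, UNAFFECTED, 72, NON_CARRIER),
        I("p3", "g1", "g2", FEMALE, UNAFFECTED, 68, NON_CARRIER),
        I("k1", "p1", "s1", FEMALE, AFFECTED, 33, CARRIER),
        I("k2", "p1", "s1", MALE, UNAFFECTED, 40, NON_CARRIER),
        I("k3", "s2", "p2", MALE, AFFECTED, 36, CARRIER),
        I("k4", "s2", "p2", FEMALE, UNAFFECTED, 42, NON_CARRIER),
    ])


@pytest.fixture(scope="session")
def trio():
    I = make_individual
    return fs.Pedigree("TRIO", [
        I("f", sex=MALE, aff=AFFECTED, age=50, car=CARRIER),
        I("m", sex=FEMALE, aff=UNAFFECTED, age=48, car=NON_CARRIER),
        I("c", "f", "m", FEMALE, AFFECTED, 25, CARRIER, proband=True),
    ])
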