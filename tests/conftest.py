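import numpy as np
import pytest
from hypothesis import settings

from sgmfilter import (
    FixtureSpec,
    MassInterval,
    ProteinIndex,
    ResidueAlphabet,
    build_composition_table,
    build_spectrum_graph,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def alphabet():
    return ResidueAlphabet()


@pytest.fixture(scope="session")
def table(alphabet):
    """Composition table covering gaps up to alpha=350 Da at eps=0.02 Da."""
    return build_composition_table(alphabet, 35002, tol=2)


@pytest.fixture(scope="session")
def exact_table(alphabet):
    """Zero-tolerance table up to 35000 integer units."""
    return build_composition_table(alphabet, 35000, tol=0)


@pytest.fixture(scope="session")
def noisy_lnrvsg_masses():
    """Fragment masses of the LNRVSG example spectrum: the LNR prefix is
    missing and 326.19 is a noise mass between LN and LNRV."""
    return np.array([113.08, 227.12, 326.19, 482.29, 569.32])


@pytest.fixture()
def noisy_lnrvsg_graph(noisy_lnrvsg_masses, table):
    itv = MassInterval(lo=100.0, hi=600.0, masses=noisy_lnrvsg_masses,
                       intensities=np.ones(noisy_lnrvsg_masses.size))
    return build_spectrum_graph(itv, table, alpha=350.0, epsilon=0.02, d=3)


@pytest.fixture(scope="session")
def lnrvsg_index(alphabet):
    return ProteinIndex.build([("prot1", "LNRVSG")], alphabet)


def make_random_instance(seed, table, alphabet, max_nodes=10, d=3):
    """A seeded small search instance: a two-protein index and a spectrum
    graph built from a noisy partial fragment ladder of the first protein."""
    from sgmfilter import RESIDUE_MASSES, build_spectrum_graph, generate_spectrum

    rng = np.random.default_rng(seed)
    aas = sorted(RESIDUE_MASSES)
    target = "".join(rng.choice(aas, int(rng.integers(15, 31))))
    other = "".join(rng.choice(aas, int(rng.integers(10, 41))))
    index = ProteinIndex.build([("t", target), ("o", other)], alphabet)
    sp = generate_spectrum(
        target,
        FixtureSpec(miss_prob=0.3, n_noise=3, seed=int(seed)),
        rng=rng,
    )
    masses = sp.masses
    if masses.size > max_nodes:
        start = int(rng.integers(0, masses.size - max_nodes + 1))
        masses = masses[start : start + max_nodes]
    itv = MassInterval(lo=float(masses[0]), hi=float(masses[-1]) + 1.0,
                       masses=masses, intensities=np.ones(masses.size))
    graph = build_spectrum_graph(itv, table, alpha=350.0,
                                 epsilon=table.tol / alphabet.scale, d=d)
    beta = float(rng.choice([50.0, 150.0, 250.0, 400.0]))
    return graph, beta, index
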