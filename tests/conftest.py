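import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import allonet as an
from allonet import library as lib
from allonet.species import make_monomer

settings.register_profile(
    "default", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def adaptor_model():
    return lib.build("divalent_adaptor")


@pytest.fixture(scope="session")
def adaptor_network(adaptor_model):
    return an.enumerate_network(adaptor_model)


@pytest.fixture(scope="session")
def concerted_model():
    return lib.build("concerted_tetramer", ligands=("L0",))


@pytest.fixture(scope="session")
def concerted_network(concerted_model):
    return an.enumerate_network(concerted_model)


@pytest.fixture(scope="session")
def sequential_model():
    return lib.build("sequential_tetramer_tetrahedral", ligands=("L0",))


@pytest.fixture(scope="session")
def sequential_network(sequential_model):
    return an.enumerate_network(sequential_model)


@pytest.fixture(scope="session")
def quartic_model():
    return lib.build("gpcr_quartic", ligands=("L1",), gproteins=("G1",))


@pytest.fixture(scope="session")
def quartic_network(quartic_model):
    return an.enumerate_network(quartic_model)


def monomer_label(network, structure):
    return network.canonicalizer.label(make_monomer(network.model, structure))


def initial_concentrations(network, totals):
    return {monomer_label(network, s): v for s, v in totals.items()}


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def adaptor_partition_oracle(K_RT, K_RX, K_TX, K_RY, K_TY, x, y):
    """Brute-force 8-state partition sum of the adaptor cube at clamped free
    ligand concentrations; returns state probabilities keyed (conf, bX, bY)."""
    w = {}
    for conf, kc in (("R", 1.0), ("T", K_RT)):
        KX = K_RX if conf == "R" else K_TX
        KY = K_RY if conf == "R" else K_TY
        for bx in (0, 1):
            for by in (0, 1):
                w[(conf, bx, by)] = kc * (KX * x) ** bx * (KY * y) ** by
    Z = sum(w.values())
    return {k: v / Z for k, v in w.items()}


def adaptor_theta_oracle(K_RT, K_RX, K_TX, K_RY, K_TY):
    """Fold-change of the apparent Y affinity caused by X occupancy, measured
    from the 8-state equilibrium at asymptotic X and infinitesimal Y."""
    eps = 1e-9

    def K_app_Y(x):
        p = adaptor_partition_oracle(K_RT, K_RX, K_TX, K_RY, K_TY, x, eps)
        bound = sum(v for (c, bx, by), v in p.items() if by)
        return bound / ((1.0 - bound) * eps)

    return K_app_Y(1e12) / K_app_Y(0.0)


def mwc_occupancy(l, L, K_R, K_T, n=4):
    """Closed-form MWC bound-ligand count for an n-site concerted protein."""
    fR, fT = 1.0 + K_R * l, 1.0 + K_T * l
    Z = fR**n + L * fT**n
    return n * (K_R * l * fR ** (n - 1) + L * K_T * l * fT ** (n - 1)) / Z
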