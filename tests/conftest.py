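import numpy as np
import pytest

from micromr import peptide
from micromr.model_core import Atom, Model, Residue
from micromr.rebuild import make_default_library
from micromr.synthetic import make_standard_fixture
from micromr.xray_core import compute_map, set_f_calc


@pytest.fixture(scope="session")
def std_fixture():
    """The standard toy crystal: 30-res helix-turn-helix, P1, 1 copy,
    d_min 2.5 Å, 5% amplitude noise, 30% identity homolog template."""
    return make_standard_fixture(0)


@pytest.fixture(scope="session")
def true_map(std_fixture):
    fx = std_fixture
    refl_fc = set_f_calc(fx["refl"], fx["target"], fx["sym"])
    return compute_map(refl_fc, "fc")


@pytest.fixture(scope="session")
def frag_lib():
    return make_default_library()


def helix_model(n=12, chain="A", resname="ALA", b=15.0):
    """Ideal poly-residue alpha helix used across tests."""
    phis = np.full(n, -57.0)
    psis = np.full(n, -47.0)
    omegas = np.full(n, 180.0)
    m = peptide.build_chain_model(phis, psis, omegas, [resname] * n, chain,
                                  b_factor=b)
    return m


def toy_residue(resname, seqnum, topo_atoms, origin=(0.0, 0.0, 0.0)):
    """Residue carrying main chain + the given side-chain atoms at dummy
    positions (1 Å apart so every atom is distinct)."""
    names = ["N", "CA", "C", "O"] + list(topo_atoms)
    atoms = []
    for i, nm in enumerate(names):
        el = nm[0] if nm[0] in "CNOS" else "C"
        atoms.append(Atom(nm, el, np.array(origin) + [i * 1.0, 0.3 * i, 0.0]))
    return Residue(resname, seqnum, atoms)


def single_residue_model(resname, topo_atoms):
    return Model({"A": [toy_residue(resname, 1, topo_atoms)]})
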