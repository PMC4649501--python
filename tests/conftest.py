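import numpy as np
import pytest

from pentaef import structure as st
from pentaef.synthetic import HelixSpec, build_helix, helix_ca_coords


@pytest.fixture
def rng():
    return np.random.default_rng(20150918)


@pytest.fixture
def ideal_helix_coords():
    return helix_ca_coords(HelixSpec(n_residues=12))


def make_residue(chain, seq, name, atoms):
    """atoms: list of (atom_name, element, xyz, is_hetero)."""
    res = st.Residue(chain_id=chain, auth_seq_id=seq, res_name=name)
    for atom_name, element, xyz, *rest in atoms:
        het = rest[0] if rest else False
        res.add_atom(st.AtomRecord(atom_name, element, np.asarray(xyz, float), is_hetero=het))
    return res


@pytest.fixture
def tiny_structure():
    """One chain, one residue, three atoms."""
    res = make_residue("A", 1, "GLY", [
        ("N", "N", (0.0, 0.0, 0.0)),
        ("CA", "C", (1.46, 0.0, 0.0)),
        ("C", "C", (2.0, 1.4, 0.0)),
    ])
    return st.Structure(entry_id="TINY", chains={"A": [res]})
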