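"""Shared fixtures: synthetic structures and small hand-built models."""

import numpy as np
import pytest

from amgkit.structure_io import Atom, Chain, Residue, Structure
from amgkit.synthetic_data import GeometrySpec, make_structure


def build_residue(name, seq, chain_id, atoms, kind="polymer"):
    """Residue from {atom_name: (element, xyz)} in input order."""
    res = Residue(name, seq, "", chain_id)
    for i, (aname, (element, xyz)) in enumerate(atoms.items()):
        a = Atom(i + 1, aname, element, "", name, chain_id, seq, "",
                 np.asarray(xyz, dtype=float))
        a.record_kind = kind
        res.atoms.append(a)
    return res


def single_chain_structure(residues, chain_id="A", sid="toy"):
    return Structure(sid, [Chain(chain_id, list(residues))])


@pytest.fixture(scope="session")
def ideal_helix():
    return make_structure(GeometrySpec("ideal_helix", n_residues=12))


@pytest.fixture(scope="session")
def sheet_pair():
    return make_structure(GeometrySpec("ideal_sheet_pair", n_residues=8))


@pytest.fixture(scope="session")
def two_sphere_touching():
    return make_structure(GeometrySpec("two_sphere_dimer", separation=4.0))


@pytest.fixture(scope="session")
def two_sphere_far():
    # separation beyond 2 * (r_vdw + probe) = 6.54: no burial possible
    return make_structure(GeometrySpec("two_sphere_dimer", separation=9.0))
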