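import numpy as np
import pytest

from nitrosite import (Atom, Chain, Residue, StructureModel, ToySiteSpec,
                       make_reaction_states, make_toy_site)


@pytest.fixture(scope="session")
def toy_site():
    return make_toy_site(ToySiteSpec(seed=0))


@pytest.fixture(scope="session")
def toy_frame(toy_site):
    """Coordinates of the toy site in topology row order."""
    idx = toy_site.topology.match_model(toy_site.model)
    return toy_site.model.coords()[idx]


@pytest.fixture(scope="session")
def toy_states(toy_site):
    return make_reaction_states(toy_site)


def build_model(atom_specs, chain="A"):
    """atom_specs: (resnum, resname, atomname, element, xyz[, hetero])."""
    ch = Chain(chain)
    current = None
    serial = 0
    for spec in atom_specs:
        resnum, resname, atomname, element, xyz = spec[:5]
        hetero = spec[5] if len(spec) > 5 else False
        serial += 1
        if current is None or current.seqid != resnum:
            current = Residue(chain, resnum, resname, [], "")
            ch.residues.append(current)
        current.atoms.append(Atom(serial, atomname, element,
                                  np.asarray(xyz, float), 1.0, "", hetero))
    return StructureModel([ch])


@pytest.fixture
def tiny_model_factory():
    return build_model


def random_protein_chain(n_residues, cid="A", seed=0, delete=()):
    """Linear chain of random residues with N/CA/C/O backbones."""
    rng = np.random.default_rng(seed)
    names = ["ALA", "GLY", "SER", "LEU", "VAL", "THR", "LYS", "ASP"]
    ch = Chain(cid)
    serial = 0
    for i in range(n_residues):
        base = np.array([3.5 * i, 0.0, 0.0]) + 0.3 * rng.normal(size=3)
        name = names[int(rng.integers(len(names)))]
        if i + 1 in delete:
            continue
        res = Residue(cid, i + 1, name, [], "")
        for j, (nm, el) in enumerate([("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]):
            serial += 1
            res.atoms.append(Atom(serial, nm, el, base + np.array([0.8 * j, 0.4 * (j % 2), 0.1 * j])))
        ch.residues.append(res)
    return ch
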