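import numpy as np
import pytest

from oligoqa import (
    Atom,
    Chain,
    Residue,
    Structure,
    make_idealized_multimer,
    parse_stoichiometry,
)


def build_structure(chains: dict[str, list[dict[str, tuple[float, float, float]]]],
                    name: str = "toy") -> Structure:
    """Assemble a Structure from {chain_id: [{atom_name: xyz, ...}, ...]}.

    Every residue is alanine unless it lacks a CB, in which case glycine.
    """
    s = Structure(name, [])
    for cid, residues in chains.items():
        ch = Chain(cid, [])
        for i, atoms in enumerate(residues, start=1):
            aa = "A" if "CB" in atoms else "G"
            res = Residue(index=i, seq_id=i, aa=aa)
            for aname, xyz in atoms.items():
                el = aname[0] if aname[0] in "NOCS" else "C"
                res.atoms.append(Atom(aname, el, np.array(xyz, float)))
            ch.residues.append(res)
        s.chains.append(ch)
    return s


def random_isometry(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random proper rotation and a random translation."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q, rng.normal(scale=20.0, size=3)


@pytest.fixture
def dimer():
    """A small idealized homodimer (two 12-residue helices in contact)."""
    return make_idealized_multimer(parse_stoichiometry("A2"), 12, seed=11)


@pytest.fixture
def heterodimer():
    return make_idealized_multimer(parse_stoichiometry("A1B1"), 10, seed=7)


@pytest.fixture
def tetramer():
    return make_idealized_multimer(parse_stoichiometry("A2B2"), 10, seed=3)
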