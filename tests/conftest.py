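"""Shared fixtures: deterministic toy complexes and hand-built micro-structures."""

import numpy as np
import pytest

from abddg.fixtures import ToyComplexSpec, make_toy_complex
from abddg.model import FeatureConfig, Featurizer
from abddg.structure_io import Atom, Complex, Residue


@pytest.fixture(scope="session")
def toy_complex():
    """12+12-residue two-chain complex with a 4.5 Å interface."""
    return make_toy_complex(ToyComplexSpec(seed=1))


@pytest.fixture(scope="session")
def toy_complexes():
    """Several distinct toy complexes keyed by id (shared across model tests)."""
    return {
        f"TOY{i}": make_toy_complex(ToyComplexSpec(seed=100 + i)) for i in range(5)
    }


@pytest.fixture(scope="session")
def featurizer():
    return Featurizer(FeatureConfig())


def single_atom_complex(positions, chain_sides=None, name3="GLY", atom_name="CA",
                        element="C"):
    """Complex of single-atom residues at given positions.

    `chain_sides` assigns each residue to chain 'H' (antibody) or 'A'
    (antigen); default: first residue antibody, rest antigen.
    """
    positions = np.asarray(positions, dtype=float)
    if chain_sides is None:
        chain_sides = ["H"] + ["A"] * (len(positions) - 1)
    residues = []
    counters = {"H": 0, "A": 0}
    specs = name3 if isinstance(name3, list) else [name3] * len(positions)
    atoms = atom_name if isinstance(atom_name, list) else [atom_name] * len(positions)
    elems = element if isinstance(element, list) else [element] * len(positions)
    for pos, chain, n3, an, el in zip(positions, chain_sides, specs, atoms, elems):
        counters[chain] += 1
        residues.append(
            Residue(chain, counters[chain], "", n3, [Atom(an, el, pos)])
        )
    return Complex(residues, {"H"}, {"A"})
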