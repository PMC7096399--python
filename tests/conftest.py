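import numpy as np
import pytest

from ifacemap.structure_io import AtomRecord, ModelSet


def make_modelset(models, atoms):
    """Stack per-model coordinate arrays over a shared atom list."""
    return ModelSet(atoms=list(atoms), coords=np.stack(models))


def two_chain_atoms(ligand_spec, receptor_spec):
    """Build atom records from [(resid, resname, [(name, element), ...]), ...]."""
    atoms, serial = [], 1
    for chain, spec in (("L", ligand_spec), ("R", receptor_spec)):
        for resid, resname, atom_list in spec:
            for name, element in atom_list:
                atoms.append(AtomRecord(serial, name, element, resname,
                                        chain, resid))
                serial += 1
    return atoms


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_pair_atoms():
    """Ligand LYS 54 (CA+NZ); receptor GLU 560 (CA+OE1) plus two anchor
    residues so the receptor fit selection has three non-collinear atoms."""
    return two_chain_atoms(
        [(54, "LYS", [("CA", "C"), ("NZ", "N")])],
        [(560, "GLU", [("CA", "C"), ("OE1", "O")]),
         (561, "ALA", [("CA", "C")]),
         (562, "ALA", [("CA", "C")])])
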