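import numpy as np
import pytest

from catres.fixtures import FixtureSpec, make_labeled_dataset
from catres.net import TrainingConfig, train_network
from catres.structure import AA_1TO3, Atom, ProteinChain, Residue


def atom_line(serial, name, resname, chain, resnum, xyz, altloc=" ", occ=1.0,
              element=None, record="ATOM", icode=" "):
    """Format one fixed-column PDB ATOM/HETATM record."""
    element = element or name[0]
    field_name = f" {name:<3s}" if len(name) < 4 else name
    x, y, z = xyz
    return (
        f"{record:<6s}{serial:5d} {field_name}{altloc}{resname:>3s} {chain}"
        f"{resnum:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture
def three_residue_pdb():
    """Ala-Gly-His on chain A, backbone only, ~3.8 Å Cα spacing."""
    lines = []
    serial = 1
    for i, res in enumerate(("ALA", "GLY", "HIS")):
        base = np.array([3.8 * i, 0.0, 0.0])
        for name, off in (("N", (-1.2, 0.6, 0.0)), ("CA", (0.0, 0.0, 0.0)),
                          ("C", (1.2, 0.6, 0.0)), ("O", (1.3, 1.8, 0.0))):
            lines.append(atom_line(serial, name, res, "A", i + 1, base + np.array(off)))
            serial += 1
    return "\n".join(lines) + "\nEND\n"


def chain_from_positions(per_residue, aas=None):
    """Build a bare ProteinChain from [(element, xyz), ...] lists per residue.

    The first atom of each residue doubles as its Cα.
    """
    from catres.structure import ATOMIC_MASSES

    residues = []
    for i, atoms in enumerate(per_residue):
        aa = (aas[i] if aas else "A")
        objs = []
        for k, (elem, xyz) in enumerate(atoms):
            name = "CA" if k == 0 else f"{elem}X{k}"
            objs.append(Atom(name, elem, ATOMIC_MASSES[elem], np.asarray(xyz, float), i))
        residues.append(Residue("A", i + 1, "", aa, objs, objs[0].coord))
    return ProteinChain(residues, source_id="testA")


@pytest.fixture(scope="session")
def fixture_dataset():
    """Eight toy structures through the full feature pipeline."""
    specs = [FixtureSpec(seed=s, structure_id=f"S{s}") for s in range(8)]
    return specs, make_labeled_dataset(specs)


@pytest.fixture(scope="session")
def trained_model(fixture_dataset):
    """A model trained on six fixture structures, verified on two."""
    specs, table = fixture_dataset
    train_ids = {f"S{s}" for s in range(6)}
    ver_ids = {"S6", "S7"}
    model = train_network(
        table[table["structure_id"].isin(train_ids)],
        table[table["structure_id"].isin(ver_ids)],
        TrainingConfig(seed=0),
    )
    return model
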