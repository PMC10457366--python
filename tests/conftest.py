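import numpy as np
import pytest


def pdb_atom_line(serial, name, resname, chain, resseq, xyz,
                  altloc=" ", occ=1.0, element=" C", record="ATOM  "):
    """One fixed-column PDB coordinate line."""
    x, y, z = xyz
    return (
        f"{record}{serial:5d} {name:^4s}{altloc}{resname:>3s} {chain}"
        f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def make_ca_pdb(residues, path):
    """Write a CA-only PDB file from (resname, chain, resseq, xyz) tuples."""
    lines = [
        pdb_atom_line(i + 1, "CA", rn, ch, rs, xyz)
        for i, (rn, ch, rs, xyz) in enumerate(residues)
    ]
    lines += ["TER", "END"]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_res_pdb(tmp_path):
    return make_ca_pdb(
        [("ALA", "A", 1, (0.0, 0.0, 0.0)),
         ("GLY", "A", 2, (3.8, 0.0, 0.0)),
         ("LYS", "A", 3, (7.6, 0.0, 0.0))],
        tmp_path / "three.pdb",
    )


def random_rigid_transform(rng, reflect=False):
    """A uniform random rotation (optionally improper) and translation."""
    from scipy.stats import special_ortho_group
    R = special_ortho_group.rvs(3, random_state=np.random.RandomState(
        int(rng.integers(2**31 - 1))))
    if reflect:
        R = R @ np.diag([1.0, 1.0, -1.0])
    t = rng.uniform(-50, 50, size=3)
    return R, t
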