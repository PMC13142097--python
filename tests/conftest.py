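import numpy as np
import pytest

from pdzflex.structure import build_ensemble, extract_domain
from pdzflex.synthetic import SyntheticEnsembleSpec, make_crystal_set


def pdb_atom_line(
    serial, name, resname, chain, resnum, x, y, z,
    occ=1.0, b=10.0, element=None, altloc=" ", icode=" ",
):
    """Format one fixed-column PDB ATOM record."""
    element = element or name[0]
    return (
        f"ATOM  {serial:5d} {name:^4s}{altloc}{resname:>3s} {chain}"
        f"{resnum:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture
def write_pdb(tmp_path):
    def _write(lines, name="fixture.pdb"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\nEND\n")
        return path

    return _write


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticEnsembleSpec(seed=0)


@pytest.fixture(scope="session")
def crystal_models(default_spec):
    models, truth = make_crystal_set(default_spec)
    return models, truth


@pytest.fixture(scope="session")
def pdz1_ensemble(crystal_models):
    """20 PDZ1-like members: 10 structures x 2 chains."""
    models, _ = crystal_models
    instances = [
        extract_domain(m, chain, 114, 193, "PDZ1")
        for m in models
        for chain in ("A", "B")
    ]
    return build_ensemble(instances)


def random_rotation(rng):
    """Uniform-ish random proper rotation from a normal 3x3 via QR."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
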