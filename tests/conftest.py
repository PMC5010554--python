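"""Shared fixtures: tiny PDB texts and small bead models, all built in-memory."""

import io

import numpy as np
import pytest

from trxs.models import StructureModel


GLY_PDB = """\
HEADER    TOY GLYCINE
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.100   1.400   0.000  1.00  0.00           C
END
"""

TWO_CHAIN_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA B   5       0.000   3.800   0.000  1.00  0.00           C
ATOM      4  CA  ALA B   7       3.800   3.800   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def gly_pdb():
    return io.StringIO(GLY_PDB)


@pytest.fixture
def two_chain_pdb():
    return io.StringIO(TWO_CHAIN_PDB)


def bead_model(coords, weights=None, model_id="toy", state=None):
    """StructureModel from bare coordinates: chain A, one residue per bead."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    kwargs = {}
    if state is not None:
        kwargs["state"] = state
    return StructureModel(
        coords=coords,
        weights=np.ones(n) if weights is None else np.asarray(weights, float),
        residue_ids=np.arange(1, n + 1),
        chain_ids=np.array(["A"] * n),
        atom_names=np.array(["CA"] * n),
        model_id=model_id,
        **kwargs,
    )


@pytest.fixture
def random_beads():
    def factory(n=50, seed=0, weights="random"):
        rng = np.random.default_rng(seed)
        coords = rng.normal(0.0, 1.5, size=(n, 3))
        w = rng.uniform(0.5, 2.0, n) if weights == "random" else None
        return bead_model(coords, w, model_id=f"beads{n}")
    return factory


def random_rotation(rng):
    """Uniform random rotation matrix via QR decomposition."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
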