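import numpy as np
import pytest

import contactstack as cs
from contactstack.features import FeatureConfig
from contactstack.stack import StackConfig


# ---------------------------------------------------------------------------
# hand-written PDB fixture: three residues with typed-in coordinates.
# ALA-1 has CB at (1, 0, 0); GLY-2 only CA at (1, 2, 3); LEU-3 CB at (9, 0, 0).
PDB_3RES = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.500   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       1.000   2.000   2.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       1.000   2.000   3.000  1.00  0.00           C
ATOM      6  N   LEU A   3       8.000   0.000   0.000  1.00  0.00           N
ATOM      7  CA  LEU A   3       8.500   0.000   0.000  1.00  0.00           C
ATOM      8  CB  LEU A   3       9.000   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def pdb_3res(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(PDB_3RES)
    return p


@pytest.fixture(scope="session")
def small_families():
    """A handful of small synthetic families for cheap stack tests."""
    return cs.generate_dataset(8, seed=42, length_range=(50, 60))


@pytest.fixture(scope="session")
def tiny_stack_config():
    """A fast configuration for unit tests of the stack machinery."""
    return StackConfig(
        n_layers=2,
        n_trees=20,
        min_samples_leaf=50,
        feature_config=FeatureConfig(n_base_maps=4, field_halfwidth=2),
        seed=3,
        max_train_samples=4000,
    )


@pytest.fixture(scope="session")
def tiny_trained_stack(small_families, tiny_stack_config):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cs.train_stack(small_families[:6], tiny_stack_config)


def random_contact_map(rng, L, density=0.08):
    """A random symmetric truth map (no structure; for oracle tests)."""
    m = rng.random((L, L)) < density
    m = np.triu(m, k=1)
    m = m | m.T
    return cs.ContactMap(matrix=m)


def random_prediction(rng, L):
    s = rng.random((L, L))
    s = (s + s.T) / 2.0
    np.fill_diagonal(s, 0.0)
    return s
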