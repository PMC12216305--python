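import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.100   0.200   0.300  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.100  1.00  0.00           C
ATOM      4  CA  GLY A   2       4.500   1.200   0.800  1.00  0.00           C
ATOM      5  CA  LYS A   3       7.900   2.000   1.500  1.00  0.00           C
END
"""

HETATM_ONLY_PDB = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00  0.00           O
END
"""

NO_CA_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  C   ALA A   1       1.500   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture
def hetatm_pdb(tmp_path):
    p = tmp_path / "het.pdb"
    p.write_text(HETATM_ONLY_PDB)
    return p


@pytest.fixture
def no_ca_pdb(tmp_path):
    p = tmp_path / "noca.pdb"
    p.write_text(NO_CA_PDB)
    return p


@pytest.fixture
def coil20():
    from scdistill import make_backbone

    return make_backbone(20, "random_coil", np.random.default_rng(7))


@pytest.fixture
def oracle():
    from scdistill import make_oracle

    return make_oracle(seed=3)


@pytest.fixture
def tiny_dataset(oracle):
    from scdistill import generate_synthetic_scored

    return generate_synthetic_scored(
        40, oracle, length_range=(20, 40), rng=np.random.default_rng(5))
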