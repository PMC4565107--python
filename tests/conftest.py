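import numpy as np
import pytest

from vorbind import pair_statistics as ps
from vorbind import synthetic_fixtures as fx
from vorbind.features_and_property import FEATURES


TOY_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.502   7.292  -4.870  1.00  0.00           C
ATOM      4  O   ALA A   1      13.415   7.581  -5.643  1.00  0.00           O
ATOM      5  CB  ALA A   1      10.521   5.949  -4.113  1.00  0.00           C
ATOM      6  N   GLY A   2      12.205   8.009  -3.785  1.00  0.00           N
ATOM      7  CA  GLY A   2      12.967   9.195  -3.419  1.00  0.00           C
ATOM      8  C   GLY A   2      12.059  10.409  -3.310  1.00  0.00           C
ATOM      9  O   GLY A   2      10.856  10.268  -3.102  1.00  0.00           O
ATOM     10  N   SER B   1       5.110   2.120   1.300  1.00  0.00           N
ATOM     11  CA  SER B   1       5.900   3.300   1.650  1.00  0.00           C
ATOM     12  C   SER B   1       7.350   3.020   1.980  1.00  0.00           C
ATOM     13  O   SER B   1       7.720   1.880   2.240  1.00  0.00           O
ATOM     14  OG  SER B   1       5.300   4.010   2.760  1.00  0.00           O
TER
END
"""


@pytest.fixture(scope="session")
def toy_complex():
    """Small two-chain pseudo-complex with a planted 4-pair interface."""
    return fx.make_toy_complex(10, 10, 4, seed=5)


@pytest.fixture(scope="session")
def single_feature_model():
    """One-feature model with a positively associated planted joint."""
    return ps.PairStatModel(
        marginals={"hydrophobicity": ps.NormalParams(0.0, 1.0)},
        joints={"hydrophobicity": ps.BivariateNormalParams(0.0, 0.0, 1.0, 1.0, 0.5)},
        weights={"hydrophobicity": 1.0},
    )


@pytest.fixture(scope="session")
def three_feature_model():
    """Full-feature model with planted association, usable end to end."""
    return ps.PairStatModel(
        marginals={f: ps.NormalParams(2.05, 2.0) for f in FEATURES},
        joints={f: ps.BivariateNormalParams(1.89, 2.21, 2.0, 2.0, 0.4) for f in FEATURES},
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
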