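"""Shared fixtures: the eight published peptides, their printed values,
and seeded random helpers."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from prpkit import beta_casein, parse_peptide

settings.register_profile(
    "repo",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repo")

# (label, peptide text, charge, printed m/z, neutral formula, casein span)
TABLE2 = [
    ("1", "pGlu-Pro-Leu-Pro-Pro-Thr", 1, 635.3392, "C30H46N6O9", (164, 169)),
    ("2", "pGlu-Pro-Leu-Pro-Pro", 1, 534.2915, "C26H39N5O7", (164, 168)),
    ("3", "Val-Val-Pro-Pro-Phe-Leu-Gln-Pro-Glu", 1, 1025.5657, "C50H76N10O13", (98, 106)),
    ("3(2+)", "Val-Val-Pro-Pro-Phe-Leu-Gln-Pro-Glu", 2, 513.2861, "C50H76N10O13", (98, 106)),
    ("4", "Val-Pro-Pro-Phe-Leu-Gln-Pro-Glu-Val", 1, 1025.5657, "C50H76N10O13", (99, 107)),
    ("5", "Pro-Phe-Pro-Gly-Pro-Ile-Pro", 1, 724.4020, "C37H53N7O8", (76, 82)),
    ("6", "Val-Pro-Pro-Phe-Leu-Gln-Pro-Glu", 1, 926.4953, "C45H67N9O12", (99, 106)),
    ("7", "Pro-Pro-Phe-Leu-Gln-Pro-Glu-Val", 1, 926.4953, "C45H67N9O12", (100, 107)),
    ("8", "Pro-Pro-Phe-Leu-Gln-Pro-Glu", 1, 827.4273, "C40H58N8O11", (100, 106)),
]


@pytest.fixture(scope="session")
def table2():
    return TABLE2


@pytest.fixture(scope="session")
def casein():
    return beta_casein()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_peptide(rng, min_len=2, max_len=15):
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    n = int(rng.integers(min_len, max_len + 1))
    seq = "".join(alphabet[i] for i in rng.integers(0, 20, n))
    return parse_peptide(seq)
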