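import numpy as np
import pytest

from abnovo.masses import DEFAULT_MASS_TABLE, ModifiedPeptide, ToleranceConfig


@pytest.fixture(scope="session")
def table():
    return DEFAULT_MASS_TABLE


@pytest.fixture(scope="session")
def tol():
    return ToleranceConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


_CODES = "ACDEFGHIKLMNPQRSTVWY"


def random_peptide(rng, min_len=5, max_len=20, with_mods=False):
    """A random peptide, optionally sprinkling modifications onto the
    residues that can carry them."""
    length = int(rng.integers(min_len, max_len + 1))
    residues = []
    for _ in range(length):
        code = _CODES[int(rng.integers(0, len(_CODES)))]
        mod = None
        if with_mods and rng.random() < 0.15:
            if code == "C":
                mod = "carbamidomethyl"
            elif code == "M":
                mod = "oxidation"
            elif code in ("N", "Q"):
                mod = "deamidation"
        residues.append((code, mod))
    return ModifiedPeptide(tuple(residues))
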