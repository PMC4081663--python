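import numpy as np
import pytest

import snmmkit as sk


@pytest.fixture(scope="session")
def table1():
    return sk.table1_matrix()


@pytest.fixture(scope="session")
def table2():
    return sk.table2_dataset()


@pytest.fixture(scope="session")
def snmm_scorer(table1):
    return sk.SNMMScorer.from_matrix(table1)


@pytest.fixture(scope="session")
def nfkb_pwm():
    return sk.nfkb_pwm()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_matrix_factory():
    """Random valid MutationMatrix generator for recovery / property tests."""

    def make(seed: int) -> sk.MutationMatrix:
        rng = np.random.default_rng(seed)
        ref = "".join(rng.choice(list("ACGT"), size=10))
        delta = np.round(rng.uniform(-60.0, 10.0, size=(4, 10)), 2)
        for pos, base in enumerate(ref):
            delta["ACGT".index(base), pos] = 0.0
        return sk.MutationMatrix(ref, delta, name=f"random-{seed}")

    return make
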