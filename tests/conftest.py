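import numpy as np
import pytest

from mixstock import ElementPanel, NurserySignature, SignatureSet, random_baseline


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def panel2():
    return ElementPanel(("a", "b"))


@pytest.fixture(scope="session")
def base4():
    """A 4-source, 7-variable synthetic baseline at intermediate separation."""
    return random_baseline(4, 7, target_sep=2.78, seed=7)


def make_set(mus, covs, panel=None, cohort="c", ns=None):
    """SignatureSet from raw arrays, for hand-constructed geometry tests."""
    mus = np.atleast_2d(np.asarray(mus, dtype=float))
    J = mus.shape[1]
    if panel is None:
        panel = ElementPanel(tuple(f"v{j}" for j in range(J)))
    sigs = tuple(
        NurserySignature(f"S{k + 1}", cohort, mus[k], np.asarray(covs[k], float),
                         0 if ns is None else ns[k])
        for k in range(mus.shape[0])
    )
    return SignatureSet(cohort, panel, sigs)
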