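import numpy as np
import pytest

from thresholdgp import OrdinalDataset, PriorSpec, ThresholdState, CoefficientState
from thresholdgp.ecm import e_step


def random_instance(seed: int, n: int = 50, p: int = 3, C: int = 4,
                    flat: bool = False):
    """A random model state with all categories observed and fresh E-step
    moments, for exercising the conditional-maximisation updates."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.concatenate([np.arange(1, C + 1),
                        rng.integers(1, C + 1, size=n - C)])
    rng.shuffle(y)
    data = OrdinalDataset(y=y, X=X, C=C)
    delta = np.concatenate([rng.normal(scale=0.8, size=1),
                            rng.uniform(0.4, 1.8, size=C - 2)])
    thr = ThresholdState(delta=delta, C=C)
    sig2 = None if flat else float(rng.uniform(0.2, 2.0))
    coef = CoefficientState(beta=rng.normal(scale=0.5, size=p),
                            sigma_beta2=sig2)
    coef.refresh_eta(X)
    if flat:
        prior = PriorSpec(flat=True)
    else:
        prior = PriorSpec(R2=0.5, v_beta=float(rng.uniform(10, 50)),
                          S_beta=float(rng.uniform(0.5, 5.0)))
    moments = e_step(data, thr, coef)
    return data, thr, coef, prior, moments


@pytest.fixture
def small_instance():
    return random_instance(seed=7)
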