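import numpy as np
import pytest

from exokin.kinetic_scheme import RateSet, StepRates, build_scheme


@pytest.fixture
def one_step_scheme():
    """Minimal ladder 7 -> 6: a single cleavable length."""
    return build_scheme(7, 6, RateSet({7: StepRates(kon_p=1e-3, koff_p=0.05, kf=0.02)}))


@pytest.fixture
def three_length_scheme():
    """Ladder 8 -> 6 with nonproductive binding on the first step."""
    return build_scheme(
        8, 6,
        RateSet({
            8: StepRates(kon_p=2e-3, koff_p=0.06, kf=0.02, kon_np=5e-3, koff_np=0.01),
            7: StepRates(kon_p=1e-3, koff_p=0.01, kf=0.05),
        }),
    )


def random_scheme(rng: np.random.Generator, n_cleavable: int = 3, nonproductive: bool = True):
    """Random small scheme with rates spanning plausible magnitudes."""
    full = 6 + n_cleavable
    steps = {}
    for n in range(full, 6, -1):
        kw = dict(
            kon_p=10 ** rng.uniform(-4, -2),
            koff_p=10 ** rng.uniform(-2.5, -0.5),
            kf=10 ** rng.uniform(-2.5, -0.5),
        )
        if nonproductive:
            kw.update(kon_np=10 ** rng.uniform(-4, -2), koff_np=10 ** rng.uniform(-3, -1))
        steps[n] = StepRates(**kw)
    return build_scheme(full, 6, RateSet(steps))
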