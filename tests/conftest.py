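import numpy as np
import pytest

from pvrank.catalog import PV_CATALOG
from pvrank.synth import SyntheticConfig, generate_cohort


def make_config(
    n_stays=300,
    seed=0,
    effects=None,
    diseases=("D1", "D2"),
    intercept=-0.5,
    **kwargs,
):
    """Small-cohort config builder; ``effects`` maps (disease, pv) -> beta."""
    B = np.zeros((len(diseases), len(PV_CATALOG)))
    for (d, pv), val in (effects or {}).items():
        B[diseases.index(d), PV_CATALOG.index(pv)] = val
    kwargs.setdefault("sampling_rate", 5.0)
    return SyntheticConfig(
        n_stays=n_stays,
        disease_catalog=tuple(diseases),
        effect_matrix=B,
        intercepts=np.full(len(diseases), float(intercept)),
        seed=seed,
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """300-stay cohort with a planted Glu effect on D1; shared across tests."""
    return generate_cohort(make_config(effects={("D1", "Glu"): 1.5}, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
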