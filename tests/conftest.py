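import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gramix import LigandParams, MixtureSpec, ReferenceScale

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def scale() -> ReferenceScale:
    return ReferenceScale(y0=0.0, m=100.0)


@pytest.fixture
def shifted_scale() -> ReferenceScale:
    """Non-trivial baseline/maximum, for affine-invariance checks."""
    return ReferenceScale(y0=5.0, m=180.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230)


def random_ligand(rng: np.random.Generator) -> LigandParams:
    """Draw plausible assay parameters (efficacy 0.5-2, slope 0.5-5)."""
    return LigandParams(
        a=float(rng.uniform(0.5, 2.0)),
        c=float(10.0 ** rng.uniform(-11, -5)),
        n=float(rng.uniform(0.5, 5.0)),
    )


def random_unit_mixture(rng: np.random.Generator, k: int) -> MixtureSpec:
    """Random mixture with all efficacies and slopes equal to 1."""
    fracs = rng.dirichlet(np.ones(k))
    comps = tuple(
        (f"C{i}", LigandParams(a=1.0, c=float(10.0 ** rng.uniform(-9, -5)), n=1.0))
        for i in range(k)
    )
    return MixtureSpec(components=comps, fractions=tuple(fracs))
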