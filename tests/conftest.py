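import numpy as np
import pytest

from neurocoupling.core import SampledSeries
from neurocoupling.synth import PerturbationSpec, SessionConfig, generate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_session():
    """One default synthetic session with two perturbations."""
    cfg = SessionConfig(
        seed=3,
        scd_true=0.3,
        perturbations=(
            PerturbationSpec(20.0, "mild", 1.0, 2.0),
            PerturbationSpec(40.0, "strong", 1.5, 3.0),
        ),
    )
    return generate_session(cfg)


@pytest.fixture
def session_dir(tmp_path, default_session):
    return default_session.write(tmp_path / "session")


def unit_series(values, fs=10.0, t0=0.0, **kw):
    """Shorthand for a SampledSeries over [0,1]-valued arrays."""
    return SampledSeries(t0=t0, fs=fs, values=np.asarray(values, dtype=float), **kw)
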