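import pytest

from photofvcb import KineticParameters, TemperatureResponse, standard_protocol


@pytest.fixture
def p():
    return KineticParameters()


@pytest.fixture
def tr_c():
    return TemperatureResponse.rubisco_default()


@pytest.fixture
def tr_j():
    return TemperatureResponse.etc_default()


@pytest.fixture
def short_protocol():
    """A scaled-down favorable/stress/favorable protocol for fast tests."""
    def _make(par, **kwargs):
        kwargs.setdefault("phase_duration", 120.0)
        return standard_protocol(par, **kwargs)
    return _make
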