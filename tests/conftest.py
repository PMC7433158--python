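import pytest

from careflow import ArrivalSeries, ModelParams


@pytest.fixture
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def constant_arrivals() -> ArrivalSeries:
    return ArrivalSeries.constant(10, 52)


@pytest.fixture
def intake_445() -> ArrivalSeries:
    """A deterministic year of arrivals summing to the reported 445 intake."""
    counts = [9] * 29 + [8] * 23  # 29*9 + 23*8 = 445
    return ArrivalSeries(counts=tuple(counts))
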