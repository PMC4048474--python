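import numpy as np
import pytest

from telosim import ModelSet, WernerParams, preset_case


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def case_a1():
    return preset_case("A1")


def werner_model(p_w: float, x: float, base: str = "A1") -> ModelSet:
    """Case preset with explicit Werner parameters attached."""
    ms = preset_case(base)
    return ModelSet(
        loss=ms.loss,
        division=ms.division,
        werner=WernerParams(p_w, x),
        threshold=ms.threshold,
        name=f"{base}+werner",
    )
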