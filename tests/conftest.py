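import numpy as np
import pytest

from lipoplex import synth, tem


@pytest.fixture(scope="session")
def radius_grid():
    """Standard radial grid: 0.2-40 nm at 0.2 nm steps (~7 repeats)."""
    return np.arange(0.2, 40.0, 0.2)


@pytest.fixture(scope="session")
def lamellar_presets():
    return {name: synth.lamellar_preset(name) for name in synth.LAMELLAR_PRESETS}


@pytest.fixture()
def clean_profile(radius_grid):
    def _make(model: tem.LamellarModel) -> tem.RadialProfile:
        return tem.RadialProfile(radius_grid, tem.evaluate_model(model, radius_grid))

    return _make
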