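import pytest

import azsim

MINI_BOX = (0.3, 0.3, 0.15)


def mini_preset(name: str, **overrides) -> "azsim.ScenarioConfig":
    """Desk-scale preset: small box, otherwise standard parameters."""
    cfg = azsim.make_preset(name, h=0.01)
    geo = cfg.geometry.with_(box_dims=MINI_BOX)
    return cfg.with_(geometry=geo, t_end=overrides.pop("t_end", 6.0e-3), **overrides)


@pytest.fixture(scope="session")
def tbar_spec():
    return azsim.GeometrySpec(box_dims=(0.2, 0.2, 0.1))


@pytest.fixture(scope="session")
def tbar_grid(tbar_spec):
    return azsim.build_geometry(tbar_spec, 0.01)


@pytest.fixture(scope="session")
def mini_first_peak_results():
    """The three anatomies simulated through the first 40 Hz peak on the
    desk-scale box; shared by ordering/ratio/sweep tests."""
    return {name: azsim.run_scenario(mini_preset(name)) for name in azsim.PRESET_NAMES}
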