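import pytest

import extrusim as ex


@pytest.fixture(scope="session")
def zsk26():
    return ex.load_machine("zsk26_like")


@pytest.fixture(scope="session")
def cb():
    return ex.load_material("cb")


@pytest.fixture(scope="session")
def hb():
    return ex.load_material("hb")


@pytest.fixture(scope="session")
def pf():
    return ex.load_material("pf")


@pytest.fixture(scope="session")
def cb_result(zsk26, cb):
    """Converged CB breakfast-cereal run (MC 15%, 500 rpm, 20 kg/h)."""
    sc = ex.get_scenario("cb_breakfast")
    return ex.solve_profile(zsk26, cb, sc.op)


@pytest.fixture(scope="session")
def hb_result(zsk26, hb):
    """Converged HB breakfast-cereal run under the same conditions."""
    sc = ex.get_scenario("hb_breakfast")
    return ex.solve_profile(zsk26, hb, sc.op)
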