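import numpy as np
import pytest

from hemekin import synth


@pytest.fixture(scope="session")
def table1():
    """Bundled phenomenological parameter sets keyed by protein name."""
    return synth.table1_fixtures()


@pytest.fixture(scope="session")
def reported():
    """Published K_H / F_H values as printed, for consistency checks."""
    return synth.table1_reported()


@pytest.fixture(scope="session")
def lfp_ladder():
    """Noiseless flash-photolysis [CO] ladder for a parameter set (cached)."""
    cache = {}

    def make(params, co_values=(50, 100, 200, 300, 800)):
        key = (id(params), tuple(co_values))
        if key not in cache:
            cache[key] = [synth.make_lfp_trace(params, c) for c in co_values]
        return cache[key]

    return make
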