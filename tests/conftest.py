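import copy
from dataclasses import replace

import pytest

import ppicea as pp


@pytest.fixture(scope="session")
def params():
    """Bundled default parameter set."""
    return pp.load_parameters()


@pytest.fixture(scope="session")
def base_realized(params):
    return params.base_map()


@pytest.fixture(scope="session")
def base_eval(params):
    return pp.evaluate_base_case(params)


def override_params(params, **replacements):
    """Copy of ``params`` with named base values (or ParameterValues) replaced."""
    values = dict(params.values)
    for name, value in replacements.items():
        if isinstance(value, pp.ParameterValue):
            values[name] = value
        else:
            pv = values[name]
            if pv.is_fixed:
                values[name] = replace(pv, base=float(value))
            else:
                values[name] = replace(
                    pv,
                    base=float(value),
                    low=min(pv.low, float(value)),
                    high=max(pv.high, float(value)),
                )
    out = copy.copy(params)
    out.values = values
    return out
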