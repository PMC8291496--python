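"""Shared fixtures: the three published Aβ40 kinetic conditions.

Rate constants are the fitted values for aggregation without inhibitor
and in the presence of compounds 18 and 21 (a = 10 μM in every assay);
the printed characteristic times for the same conditions are kept as
data for comparison tests.
"""

import pytest

from amylokin import KineticParameters

A_UM10 = 1e-5  # 10 uM in molar

TABLE_CONSTANTS = {
    "control": {"k_n": 3.09e-5, "k_e": 486.9},
    "cmp18": {"k_n": 1.45e-6, "k_e": 299.5},
    "cmp21": {"k_n": 1.41e-5, "k_e": 338.8},
}

# printed lag / half / end times (s), read off the fits to experimental data
PRINTED_TIMES = {
    "control": {"t0": 535.0, "t_half": 989.0, "t1": 1444.0},
    "cmp18": {"t0": 1855.0, "t_half": 2570.0, "t1": 3284.0},
    "cmp21": {"t0": 995.0, "t_half": 1710.0, "t1": 2424.0},
}


@pytest.fixture
def control_params() -> KineticParameters:
    return KineticParameters(a=A_UM10, **TABLE_CONSTANTS["control"])


@pytest.fixture(params=sorted(TABLE_CONSTANTS))
def condition(request) -> tuple[str, KineticParameters]:
    name = request.param
    return name, KineticParameters(a=A_UM10, **TABLE_CONSTANTS[name])
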