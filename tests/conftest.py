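import numpy as np
import pytest

from delaysum.circuit import (
    GROUPS,
    CircuitModel,
    GlutUnit,
    group_kinetics_at,
    make_ground_truth_cell,
)


@pytest.fixture(scope="session")
def default_circuit():
    """The package's reference 193-unit circuit (seed 0)."""
    return make_ground_truth_cell(seed=0)


@pytest.fixture(scope="session")
def grid_circuit():
    """12 well-separated units on a 4 x 3 grid (the planted ROI fixture)."""
    units = []
    k = 0
    for i in range(4):
        for j in range(3):
            g = GROUPS[k % 6]
            pos = (-45.0 + i * 30.0, -30.0 + j * 30.0)
            units.append(
                GlutUnit(group=g, pos_um=pos, kinetics=group_kinetics_at(g, pos[0]))
            )
            k += 1
    return CircuitModel(units=units, dendritic_diameter_um=160.0)


def two_unit_circuit(ds_um: float, dt_s: float, base_latency_s: float = 0.6):
    """Two identical-shape units separated by ds_um whose latencies differ by
    dt_s (preferred-side unit slower): the minimal preferred-direction
    enhancement pair with optimum ds/dt."""
    from delaysum.circuit import TemporalKinetics

    def kin(lat):
        return TemporalKinetics(lat, 0.02, 0.18, 0.03, 0.9)

    u1 = GlutUnit(group="G5", pos_um=(-ds_um / 2, 0.0),
                  kinetics=kin(base_latency_s + dt_s))
    u2 = GlutUnit(group="G1", pos_um=(+ds_um / 2, 0.0),
                  kinetics=kin(base_latency_s))
    return CircuitModel(units=[u1, u2], dendritic_diameter_um=max(400.0, 2 * ds_um + 50))
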