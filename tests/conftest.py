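import numpy as np
import pytest

from tdprisk.cardiac_sim import BeatSlice, TraceBundle
from tdprisk.invitro import QNET_CURRENTS


def make_beat(duration_ms=400.0, dt=0.1, vm_knots=None, cai_knots=None,
              current_knots=None, beat_index=0):
    """BeatSlice from piecewise-linear knot lists ((times), (values))."""
    t = np.arange(int(round(duration_ms / dt))) * dt
    vm = (np.interp(t, *vm_knots) if vm_knots is not None
          else np.full_like(t, -85.0))
    cai = (np.interp(t, *cai_knots) if cai_knots is not None
           else np.full_like(t, 1e-4))
    currents = {name: np.interp(t, *knots)
                for name, knots in (current_knots or {}).items()}
    return BeatSlice(time=t, vm=vm, cai=cai, currents=currents, dt=dt,
                     beat_index=beat_index)


@pytest.fixture
def trapezoid_beat():
    """Trapezoid AP: rest -85 mV, linear upstroke to +35 mV over 0-1 ms, flat
    plateau to 200 ms, linear fall back to -85 mV over 200-300 ms."""
    return make_beat(vm_knots=([0.0, 1.0, 200.0, 300.0], [-85.0, 35.0, 35.0, -85.0]))


@pytest.fixture
def triangle_ca_beat():
    """Triangular Ca transient: baseline 1e-4 mM, linear rise to 4e-4 mM over
    10 ms, linear decay back to baseline at 400 ms."""
    return make_beat(duration_ms=500.0,
                     cai_knots=([0.0, 10.0, 400.0], [1e-4, 4e-4, 1e-4]))


def bundle_from_beats(beats):
    """Concatenate equally-shaped BeatSlices into a TraceBundle."""
    dt = beats[0].dt
    cl = beats[0].time.size * dt
    currents = {name: np.concatenate([b.currents[name] for b in beats])
                for name in beats[0].currents}
    for name in QNET_CURRENTS:  # bundle contract needs all six
        currents.setdefault(name, np.zeros(sum(b.vm.size for b in beats)))
    return TraceBundle(dt=dt, cycle_length=cl,
                       vm=np.concatenate([b.vm for b in beats]),
                       cai=np.concatenate([b.cai for b in beats]),
                       currents=currents)
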