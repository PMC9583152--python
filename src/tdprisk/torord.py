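"""Optional CellML ionic-model backend (ToR-ORd or compatible).

Wraps a published CellML ventricular-myocyte model (endocardial ToR-ORd by
default) behind :class:`~tdprisk.cardiac_sim.CellModel` so the drug-block and
pacing protocol can run on a biophysical model instead of the packaged
surrogate.  Requires the optional ``myokit`` dependency
(``pip install tdprisk[torord]``) and a CellML 1.x model file supplied by the
user; neither ships with this package.

The conductance registry is mapped onto model variables via
``CONDUCTANCE_VARIABLES`` (override per model variant if the CellML component
names differ).  Output is resampled onto the fixed dt grid with dense/linear
interpolation regardless of internal adaptive solver steps, because the
feature definitions reference that grid.
"""
from __future__ import annotations

from typing import Mapping, Optional

import numpy as np

from .cardiac_sim import CellModel, TraceBundle

__all__ = ["ToROrdModel", "CONDUCTANCE_VARIABLES"]

#: channel -> CellML variable holding the maximal conductance/permeability
CONDUCTANCE_VARIABLES = {
    "INa": "INa.GNa",
    "INaL": "INaL.GNaL",
    "IKr": "IKr.GKr",
    "IKs": "IKs.GKs",
    "IK1": "IK1.GK1",
    "Ito": "Ito.Gto",
    "ICaL": "ICaL.PCa",
}

#: channel -> CellML variable holding the current itself (A/F)
CURRENT_VARIABLES = {
    "INaL": "INaL.INaL",
    "ICaL": "ICaL.ICaL",
    "IKr": "IKr.IKr",
    "IKs": "IKs.IKs",
    "IK1": "IK1.IK1",
    "Ito": "Ito.Ito",
}


def _require_myokit():
    try:
        import myokit  # noqa: F401
    except ImportError as e:  # pragma: no cover - exercised only without extra
        raise ImportError(
            "the CellML backend requires the optional dependency 'myokit' "
            "(pip install tdprisk[torord]) and a CellML model file"
        ) from e
    return myokit


class ToROrdModel(CellModel):
    """CellML-backed cell model (requires the ``myokit`` extra)."""

    is_periodic = False

    def __init__(self, cellml_path, scales: Optional[Mapping[str, float]] = None,
                 conductance_vars: Optional[Mapping[str, str]] = None,
                 current_vars: Optional[Mapping[str, str]] = None,
                 vm_var: str = "membrane.v", cai_var: str = "intracellular_ions.cai"):
        super().__init__(scales)
        if cellml_path is None:
            raise ValueError("cellml_path is required for the torord_cellml backend")
        self.myokit = _require_myokit()
        self.cellml_path = str(cellml_path)
        self.conductance_vars = dict(conductance_vars or CONDUCTANCE_VARIABLES)
        self.current_vars = dict(current_vars or CURRENT_VARIABLES)
        self.vm_var = vm_var
        self.cai_var = cai_var
        self._model = self.myokit.formats.importer("cellml").model(self.cellml_path)

    def _clone(self, scales):
        clone = object.__new__(ToROrdModel)
        CellModel.__init__(clone, scales)
        for attr in ("myokit", "cellml_path", "conductance_vars", "current_vars",
                     "vm_var", "cai_var", "_model"):
            setattr(clone, attr, getattr(self, attr))
        return clone

    def _identity_fields(self):
        return (self.cellml_path,)

    def _scaled_model(self):
        m = self._model.clone()
        for ch, var in self.conductance_vars.items():
            s = self._scales.get(ch, 1.0)
            if s != 1.0 and m.has_variable(var):
                v = m.get(var)
                v.set_rhs(self.myokit.Multiply(self.myokit.Number(s), v.rhs()))
        return m

    def initial_state(self) -> dict:
        m = self._model
        return {v.qname(): v.state_value() for v in m.states()}

    def _simulation(self, state=None):
        m = self._scaled_model()
        protocol = self.myokit.pacing.blocktrain(period=2000.0, duration=1.0)
        sim = self.myokit.Simulation(m, protocol)
        if state is not None:
            sim.set_state([state[v.qname()] for v in m.states()])
        return sim, m

    def advance(self, state, n_beats, cycle_length):
        sim, m = self._simulation(state)
        sim.set_protocol(self.myokit.pacing.blocktrain(period=cycle_length, duration=1.0))
        for beat in range(n_beats):
            try:
                sim.run(cycle_length, log=self.myokit.LOG_NONE)
            except self.myokit.SimulationError as e:
                raise RuntimeError(f"solver failure at beat {beat}: {e}") from e
        out = dict(zip((v.qname() for v in m.states()), sim.state()))
        if not all(np.isfinite(v) for v in out.values()):
            raise RuntimeError(f"non-finite state after beat {n_beats}")
        return out

    def run(self, n_beats, cycle_length, dt, initial_state=None, keep_last=None):
        keep = n_beats if keep_last is None else keep_last
        sim, m = self._simulation(initial_state)
        sim.set_protocol(self.myokit.pacing.blocktrain(period=cycle_length, duration=1.0))
        skip = n_beats - keep
        if skip:
            sim.run(skip * cycle_length, log=self.myokit.LOG_NONE)
        log_vars = [self.vm_var, self.cai_var] + list(self.current_vars.values())
        d = sim.run(keep * cycle_length, log=["engine.time"] + log_vars,
                    log_interval=dt)
        n = int(round(keep * cycle_length / dt))
        vm = np.asarray(d[self.vm_var][:n])
        cai = np.asarray(d[self.cai_var][:n])
        currents = {ch: np.asarray(d[var][:n]) for ch, var in self.current_vars.items()}
        return TraceBundle(dt=dt, cycle_length=cycle_length, vm=vm, cai=cai,
                           currents=currents)
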