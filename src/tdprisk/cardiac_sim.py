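"""Drug-block application and the pacing protocol on a ventricular cell model.

Drug block scales channel conductances multiplicatively:

    I'_ion = G'_ion * m_ion * (Vm - E_ion),   G'_ion = IF(D) * G_ion

with IF the Hill inhibition factor (fraction of conductance remaining).  The
protocol mirrors standard in silico proarrhythmia practice: a drug-free model
is paced to steady state (10,000 beats at a 2,000 ms cycle length, i.e. the
bradycardic 30 bpm condition under which repolarisation is longest), the
saved state seeds the drugged run (1,000 paced beats, 0.1 ms output grid),
and features are read from the retained last 250 beats.

Concrete ionic models plug in behind :class:`CellModel`; the packaged
analytic surrogate lives in :mod:`tdprisk.synthetic` and a CellML-backed
ToR-ORd adapter (optional ``myokit`` extra) in :mod:`tdprisk.torord`.
"""
from __future__ import annotations

import hashlib
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from .invitro import CHANNELS, QNET_CURRENTS, inhibition_factor

__all__ = [
    "ChannelSpec",
    "CellModel",
    "TraceBundle",
    "BeatSlice",
    "apply_drug_block",
    "run_to_steady_state",
    "paced_simulation",
]


@dataclass(frozen=True)
class ChannelSpec:
    """Static description of one conductance term: I = g_max * gate * (Vm - E)."""

    channel: str
    g_max: float
    gate_value: float = 1.0
    reversal_potential: float = 0.0

    def __post_init__(self):
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")
        if not 0.0 <= self.gate_value <= 1.0:
            raise ValueError("gate_value must lie in [0, 1]")


@dataclass
class BeatSlice:
    """One beat window cut from a TraceBundle; time is local (0 at stimulus)."""

    time: np.ndarray
    vm: np.ndarray
    cai: np.ndarray
    currents: dict
    dt: float
    beat_index: int


@dataclass
class TraceBundle:
    """Paced-simulation output: Vm, Cai and per-current traces plus beat grid.

    Beat windows are half-open [k*CL, (k+1)*CL) sample blocks; they partition
    the retained time axis exactly.  Units: dt and cycle_length ms, vm mV,
    cai mM, currents A/F.
    """

    dt: float
    cycle_length: float
    vm: np.ndarray
    cai: np.ndarray
    currents: dict
    beat_offsets: np.ndarray = field(default=None)

    def __post_init__(self):
        spb = self.cycle_length / self.dt
        if abs(spb - round(spb)) > 1e-9:
            raise ValueError("dt must divide cycle_length")
        spb = int(round(spb))
        n = self.vm.shape[0]
        if n % spb != 0:
            raise ValueError("trace length is not a whole number of beats")
        missing = [c for c in QNET_CURRENTS if c not in self.currents]
        if missing:
            raise ValueError(f"missing current(s): {', '.join(missing)}")
        for name, series in self.currents.items():
            if series.shape[0] != n:
                raise ValueError(f"current {name} length mismatch")
        if self.cai.shape[0] != n:
            raise ValueError("cai length mismatch")
        if self.beat_offsets is None:
            self.beat_offsets = np.arange(n // spb) * spb
        self.beat_offsets = np.asarray(self.beat_offsets, dtype=int)

    @property
    def samples_per_beat(self) -> int:
        return int(round(self.cycle_length / self.dt))

    @property
    def n_beats(self) -> int:
        return self.vm.shape[0] // self.samples_per_beat

    def beat(self, i: int) -> BeatSlice:
        spb = self.samples_per_beat
        if not 0 <= i < self.n_beats:
            raise IndexError(f"beat {i} out of range (0..{self.n_beats - 1})")
        sl = slice(i * spb, (i + 1) * spb)
        t = np.arange(spb) * self.dt
        return BeatSlice(
            time=t,
            vm=self.vm[sl],
            cai=self.cai[sl],
            currents={k: v[sl] for k, v in self.currents.items()},
            dt=self.dt,
            beat_index=i,
        )

    def beats(self):
        for i in range(self.n_beats):
            yield self.beat(i)


class CellModel(ABC):
    """Ventricular-myocyte model behind the drug-block/pacing protocol.

    Subclasses own the dynamics; this base class owns the per-channel
    conductance scale registry (all 1.0 drug-free, multiplied down by drug
    block) and identity hashing for the steady-state cache.
    """

    #: True if every paced beat is identical (no beat-to-beat memory).
    is_periodic: bool = False

    def __init__(self, scales: Optional[Mapping[str, float]] = None):
        self._scales = {ch: 1.0 for ch in CHANNELS}
        if scales:
            for ch, s in scales.items():
                if ch not in CHANNELS:
                    raise ValueError(
                        f"unknown channel {ch!r}; accepted names: {', '.join(CHANNELS)}"
                    )
                if not 0.0 <= s <= 1.0:
                    raise ValueError(f"conductance scale for {ch} must lie in [0, 1]")
                self._scales[ch] = float(s)

    @property
    def conductance_scales(self) -> dict:
        return dict(self._scales)

    def with_scales(self, scales: Mapping[str, float]) -> "CellModel":
        """Copy of this model with the given absolute conductance scales."""
        merged = dict(self._scales)
        merged.update(scales)
        return self._clone(merged)

    @abstractmethod
    def _clone(self, scales: Mapping[str, float]) -> "CellModel":
        """Construct a copy of this model carrying ``scales``."""

    @abstractmethod
    def initial_state(self) -> dict:
        """Published/default initial state (named reals incl. vm, cai)."""

    @abstractmethod
    def advance(self, state: dict, n_beats: int, cycle_length: float) -> dict:
        """Pace ``n_beats`` beats from ``state``; return the final state.

        Must raise ``RuntimeError`` naming the beat index if the state goes
        non-finite.
        """

    @abstractmethod
    def run(
        self,
        n_beats: int,
        cycle_length: float,
        dt: float,
        initial_state: Optional[dict] = None,
        keep_last: Optional[int] = None,
    ) -> TraceBundle:
        """Pace ``n_beats`` and return traces for the last ``keep_last`` beats."""

    def _identity_fields(self) -> tuple:
        return ()

    def identity_hash(self) -> str:
        payload = repr((type(self).__name__, sorted(self._scales.items()),
                        self._identity_fields())).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def apply_drug_block(model: CellModel, sample: Mapping[str, tuple], dose: float) -> CellModel:
    """Return a copy of ``model`` with drug block applied at ``dose`` (nM).

    ``sample`` maps channel name -> (ic50, hill_h); each listed channel's
    conductance scale is multiplied by its inhibition factor, channels not
    listed are untouched, and the original model is unmodified.  Successive
    applications compose multiplicatively and commute.
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    scales = model.conductance_scales
    for ch, (ic50, h) in sample.items():
        if ch not in CHANNELS:
            raise ValueError(
                f"unknown channel {ch!r}; accepted names: {', '.join(CHANNELS)}"
            )
        scales[ch] = scales[ch] * inhibition_factor(dose, ic50, h)
    return model.with_scales(scales)


def _steady_state_cache_file(cache_dir, key: str) -> Path:
    return Path(cache_dir) / f"steady_{key}.txt"


def run_to_steady_state(
    model: CellModel,
    n_beats: int = 10000,
    cycle_length: float = 2000.0,
    cache_dir=None,
) -> dict:
    """Pace the drug-free model ``n_beats`` beats; return the saved state.

    The state is cached as a flat named-vector text file keyed by
    (model identity hash, cycle length, beat count), so the long drug-free
    equilibration is computed once and reused as the initial condition of
    every drugged run.
    """
    if any(abs(s - 1.0) > 0 for s in model.conductance_scales.values()):
        raise ValueError("steady-state pacing requires a drug-free model (all scales 1)")
    if n_beats < 0:
        raise ValueError("n_beats must be >= 0")

    key = hashlib.sha256(
        f"{model.identity_hash()}|{cycle_length}|{n_beats}".encode()
    ).hexdigest()[:16]
    if cache_dir is not None:
        f = _steady_state_cache_file(cache_dir, key)
        if f.exists():
            state = {}
            for line in f.read_text().splitlines():
                name, value = line.split()
                state[name] = float(value)
            return state

    state = model.initial_state() if n_beats == 0 else model.advance(
        model.initial_state(), n_beats, cycle_length
    )
    if not all(np.isfinite(v) for v in state.values()):
        raise RuntimeError("steady-state pacing produced a non-finite state")

    if cache_dir is not None:
        Path(cache_dir).mkdir(parents=True, exist_ok=True)
        f = _steady_state_cache_file(cache_dir, key)
        f.write_text("".join(f"{k} {v:.17g}\n" for k, v in sorted(state.items())))
    return state


def paced_simulation(
    model: CellModel,
    initial_state: Optional[dict] = None,
    n_beats: int = 1000,
    cycle_length: float = 2000.0,
    dt: float = 0.1,
    keep_last: int = 250,
) -> TraceBundle:
    """Run the recorded pacing protocol and return the retained trace bundle.

    Integrates ``n_beats`` paced beats from ``initial_state`` and returns
    traces for only the last ``keep_last`` beats (the memory contract: at the
    default 2,000 ms / 0.1 ms grid a 250-beat window is 5,000,000 samples per
    series).
    """
    if keep_last > n_beats:
        raise ValueError("keep_last must be <= n_beats")
    if keep_last < 1 or n_beats < 1:
        raise ValueError("n_beats and keep_last must be >= 1")
    spb = cycle_length / dt
    if abs(spb - round(spb)) > 1e-9:
        raise ValueError("dt must divide cycle_length")

    bundle = model.run(
        n_beats=n_beats,
        cycle_length=cycle_length,
        dt=dt,
        initial_state=initial_state,
        keep_last=keep_last,
    )
    if not np.all(np.isfinite(bundle.vm)):
        bad = int(np.flatnonzero(~np.isfinite(bundle.vm))[0])
        raise RuntimeError(f"non-finite membrane potential at t = {bad * dt:.1f} ms")
    return bundle
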