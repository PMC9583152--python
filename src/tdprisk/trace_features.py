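"""The 12 in silico proarrhythmia features from paced-trace bundles.

Six action-potential features (upstroke velocity dVm/dt_max, steepest
repolarisation slope dVm/dt_max_repol, peak Vm, APD90, APD50, triangulation
APD90 - APD50), four calcium-transient features (peak Cai, CaD90, CaD50,
CaD_tri), and two ionic-charge features: qNet, the per-beat time integral of
INaL + ICaL + IKr + IKs + IK1 + Ito (uC/uF), and qInward, the mean fractional
change of the INaL and ICaL charges relative to a drug-free control beat.

Features are read from the *worst* retained beat — the one with the steepest
repolarisation (largest |min dVm/dt| after the AP peak), the beat closest to
early-afterdepolarisation behaviour — and averaged over the four simulated
concentrations (1-4x Cmax) before classification.

Conventions (recorded because they matter at the grid scale):
- slopes are centred first differences on the output grid (np.gradient);
  the default 0.1 ms grid is a recorded config item since the upstroke
  velocity is resolution-sensitive;
- activation time (and Cai onset) is the midpoint of the contiguous run of
  maximal slope — for smooth signals the maximum is unique and this is just
  its time, while on piecewise-linear fixtures it lands mid-upstroke;
- the APD reference amplitude is vm_peak minus vm at stimulus onset of the
  same beat;
- duration crossings are linearly interpolated between grid points;
- a beat whose Vm never recrosses the APD90 level (repolarisation failure)
  yields NaN for that duration, which propagates through the concentration
  average and drops the sample from regression for that feature.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cardiac_sim import BeatSlice, TraceBundle
from .invitro import QNET_CURRENTS

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "select_worst_beat",
    "ap_features",
    "ca_features",
    "qnet",
    "qinward",
    "extract_features",
    "average_over_concentrations",
]

FEATURE_NAMES = (
    "dvmdt_max",
    "dvmdt_max_repol",
    "vm_peak",
    "apd90",
    "apd50",
    "apd_tri",
    "ca_peak",
    "cad90",
    "cad50",
    "cad_tri",
    "qnet",
    "qinward",
)

#: minimum upstroke slope (mV/ms) for a window to count as containing an AP
DEFAULT_UPSTROKE_FLOOR = 5.0


@dataclass
class FeatureVector:
    """The 12 features for one (drug, uncertainty sample); NaN marks missing."""

    dvmdt_max: float
    dvmdt_max_repol: float
    vm_peak: float
    apd90: float
    apd50: float
    apd_tri: float
    ca_peak: float
    cad90: float
    cad50: float
    cad_tri: float
    qnet: float
    qinward: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "FeatureVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"expected {len(FEATURE_NAMES)} values")
        return cls(**dict(zip(FEATURE_NAMES, arr.tolist())))


def _slopes(series: np.ndarray, dt: float) -> np.ndarray:
    """Centred first differences (one-sided at the ends)."""
    return np.gradient(series, dt)


def _max_slope_run_midpoint(slopes: np.ndarray, time: np.ndarray) -> tuple:
    """(midpoint time, argmax index) of the contiguous maximal-slope run.

    The run is the block of samples around the argmax whose slope is equal to
    the maximum within a tiny relative tolerance; its midpoint is the
    activation/onset time.  Interior (centred) samples only.
    """
    n = slopes.size
    i0 = int(np.argmax(slopes[1:-1])) + 1 if n > 2 else int(np.argmax(slopes))
    smax = slopes[i0]
    atol = 1e-9 * max(1.0, abs(smax))
    lo = i0
    while lo - 1 >= 1 and abs(slopes[lo - 1] - smax) <= atol:
        lo -= 1
    hi = i0
    while hi + 1 <= n - 2 and abs(slopes[hi + 1] - smax) <= atol:
        hi += 1
    return 0.5 * (time[lo] + time[hi]), i0


def _first_crossing_below(time, series, level, start_idx) -> float:
    """Linearly interpolated time where ``series`` first falls below ``level``
    at or after ``start_idx``; NaN if it never does."""
    seg = series[start_idx:]
    below = np.flatnonzero(seg < level)
    if below.size == 0:
        return math.nan
    k = start_idx + int(below[0])
    if k == 0:
        return float(time[0])
    v0, v1 = series[k - 1], series[k]
    frac = (v0 - level) / (v0 - v1) if v0 != v1 else 1.0
    return float(time[k - 1] + frac * (time[k] - time[k - 1]))


def select_worst_beat(bundle: TraceBundle, upstroke_floor: float = DEFAULT_UPSTROKE_FLOOR) -> int:
    """Index of the retained beat with maximal repolarisation velocity.

    For each beat the repolarisation velocity is the most negative centred
    dVm/dt after the Vm peak; the beat maximising its magnitude wins and ties
    go to the latest such beat.
    """
    if bundle.n_beats < 1:
        raise ValueError("empty bundle")
    best_idx = 0
    best_val = math.inf
    for i in range(bundle.n_beats):
        beat = bundle.beat(i)
        slopes = _slopes(beat.vm, beat.dt)
        peak = int(np.argmax(beat.vm))
        window = slopes[peak + 1 : beat.vm.size - 1]
        val = float(window.min()) if window.size else float(slopes[-1])
        if val <= best_val:  # ties -> latest beat
            best_val = val
            best_idx = i
    return best_idx


def ap_features(beat: BeatSlice, upstroke_floor: float = DEFAULT_UPSTROKE_FLOOR) -> dict:
    """Six AP features of one beat.

    Raises ``ValueError("no AP")`` when no stimulus-triggered upstroke exceeds
    ``upstroke_floor`` (mV/ms).  Repolarisation failure (Vm never recrossing a
    duration level) yields NaN for that duration, not an exception.
    """
    vm, t, dt = beat.vm, beat.time, beat.dt
    slopes = _slopes(vm, dt)
    dvmdt_max = float(slopes[1:-1].max()) if vm.size > 2 else float(slopes.max())
    if dvmdt_max < upstroke_floor:
        raise ValueError("no AP: maximal upstroke slope below detection floor")

    t_act, i_act = _max_slope_run_midpoint(slopes, t)
    peak_idx = i_act + int(np.argmax(vm[i_act:]))
    vm_peak = float(vm[peak_idx])
    baseline = float(vm[0])  # stimulus-onset Vm of this beat
    amplitude = vm_peak - baseline

    repol = slopes[peak_idx + 1 : vm.size - 1]
    dvmdt_max_repol = float(repol.min()) if repol.size else math.nan

    def apd(frac):
        level = vm_peak - frac * amplitude
        t_cross = _first_crossing_below(t, vm, level, peak_idx)
        return t_cross - t_act if not math.isnan(t_cross) else math.nan

    apd90 = apd(0.90)
    apd50 = apd(0.50)
    return {
        "dvmdt_max": dvmdt_max,
        "dvmdt_max_repol": dvmdt_max_repol,
        "vm_peak": vm_peak,
        "apd90": apd90,
        "apd50": apd50,
        "apd_tri": apd90 - apd50,
    }


def ca_features(beat: BeatSlice) -> dict:
    """Four calcium-transient features of one beat.

    Durations run from transient onset (midpoint of the maximal dCai/dt run)
    until Cai first decays below peak - x% of (peak - diastolic), diastolic
    being Cai at beat start.  Raises ``ValueError("no transient")`` on flat
    Cai.
    """
    cai, t, dt = beat.cai, beat.time, beat.dt
    if np.ptp(cai) == 0:
        raise ValueError("no transient: flat Cai")
    slopes = _slopes(cai, dt)
    t_on, i_on = _max_slope_run_midpoint(slopes, t)
    peak_idx = int(np.argmax(cai))
    ca_peak = float(cai[peak_idx])
    diastolic = float(cai[0])
    amp = ca_peak - diastolic

    def cad(frac):
        level = ca_peak - frac * amp
        t_cross = _first_crossing_below(t, cai, level, peak_idx)
        return t_cross - t_on if not math.isnan(t_cross) else math.nan

    cad90 = cad(0.90)
    cad50 = cad(0.50)
    return {"ca_peak": ca_peak, "cad90": cad90, "cad50": cad50, "cad_tri": cad90 - cad50}


def qnet(beat: BeatSlice) -> float:
    """Net charge (uC/uF): trapezoidal integral over the beat of the six-net
    current sum, time in seconds, current in A/F."""
    for name in QNET_CURRENTS:
        if name not in beat.currents:
            raise ValueError(f"missing current: {name}")
    total = np.zeros_like(beat.vm)
    for name in QNET_CURRENTS:
        total = total + beat.currents[name]
    return float(np.trapezoid(total, dx=beat.dt * 1e-3))


def _abs_charge(beat: BeatSlice, name: str) -> float:
    if name not in beat.currents:
        raise ValueError(f"missing current: {name}")
    return abs(float(np.trapezoid(beat.currents[name], dx=beat.dt * 1e-3)))


def qinward(beat: BeatSlice, control_beat: BeatSlice) -> float:
    """Mean fractional change of the INaL and ICaL charges, drug vs control:
    0.5 * (qCaL_drug/qCaL_ctl + qNaL_drug/qNaL_ctl).

    Absolute charge magnitudes are used so the sign convention of inward
    currents cannot flip the ratio.  Equals 1.0 for a drug-free beat.
    """
    out = 0.0
    for name in ("ICaL", "INaL"):
        q_ctl = _abs_charge(control_beat, name)
        if q_ctl == 0.0:
            raise ValueError(f"degenerate control: zero {name} charge")
        out += _abs_charge(beat, name) / q_ctl
    return 0.5 * out


def extract_features(beat: BeatSlice, control_beat: BeatSlice,
                     upstroke_floor: float = DEFAULT_UPSTROKE_FLOOR) -> FeatureVector:
    """All 12 features of one beat against a drug-free control beat."""
    vals = ap_features(beat, upstroke_floor)
    vals.update(ca_features(beat))
    vals["qnet"] = qnet(beat)
    vals["qinward"] = qinward(beat, control_beat)
    return FeatureVector(**vals)


def average_over_concentrations(per_dose: Sequence[FeatureVector]) -> FeatureVector:
    """Component-wise mean of exactly four per-concentration feature vectors
    (1-4x Cmax).  A missing (NaN) component in any dose marks the component
    missing in the output."""
    if len(per_dose) != 4:
        raise ValueError(f"expected exactly 4 per-concentration vectors, got {len(per_dose)}")
    stacked = np.vstack([fv.to_array() for fv in per_dose])
    return FeatureVector.from_array(stacked.mean(axis=0))
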