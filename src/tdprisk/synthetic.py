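"""Synthetic inputs for every pipeline stage: an analytic surrogate myocyte
whose features have closed forms, dose-inhibition cohorts with known ground
truth, and class-structured feature banks.

The surrogate is a deliberately simple piecewise-linear beat generator, NOT a
biophysical model: its only physiological claims are directional (IKr block
prolongs the action potential and calcium transient and lowers net outward
charge; ICaL block shortens the AP and shrinks the calcium transient; INa
block slows the upstroke).  Its morphology is documented here so every
extracted feature can be checked against an exact closed form, which is what
makes the full pipeline testable without any downloaded ionic model.

Surrogate closed forms (scales s_X in [0, 1], 1 = no block):

    APD90 = base_apd90 * F,  APD50 = base_apd50 * F,
    F = 1 + 0.8*(1 - s_IKr) + 0.3*(1 - s_IKs) - 0.4*(1 - s_ICaL)

    upstroke duration  t_up = upstroke_ms / (0.25 + 0.75 * s_INa)
    peak Vm            vm_peak = vm_peak_base - peak_drop_ical * (1 - s_ICaL)
    Ca amplitude       amp = ca_amp_base * (0.2 + 0.8 * s_ICaL)
    Ca transient end   t_ca_end = ca_end_base * (1 + 0.3 * (1 - s_IKr))

Vm is rest -> linear upstroke (t_up) -> flat plateau -> linear repolarisation
placed so the interpolated APD50/APD90 crossings (measured from the upstroke
midpoint) hit the formulas exactly; Cai is a triangular transient; the six
net-charge currents are triangles/trapezoids whose amplitudes scale with
their conductance factors, so blocking IKr reduces qNet by construction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from ._seeding import named_rng
from .cardiac_sim import CellModel, TraceBundle
from .invitro import (
    CHANNELS,
    RISK_LEVELS,
    DrugChannelBlock,
    DrugRecord,
    hill_inhibition,
    load_reference_drugs,
)
from .trace_features import FEATURE_NAMES, FeatureVector

__all__ = [
    "SurrogateParams",
    "SurrogateModel",
    "SyntheticCohortSpec",
    "surrogate_trace",
    "surrogate_expected_features",
    "synth_invitro_cohort",
    "attach_synthetic_blocks",
    "cohort_from_reference",
    "synth_feature_bank",
]


@dataclass(frozen=True)
class SurrogateParams:
    """Fixed, documented constants of the surrogate beat (see module docs)."""

    base_apd90: float = 270.0     # ms, drug-free
    base_apd50: float = 230.0     # ms, drug-free
    vm_rest: float = -88.0        # mV
    vm_peak_base: float = 33.0    # mV
    upstroke_ms: float = 1.0      # ms, drug-free upstroke duration
    cai_base: float = 1e-4        # mM, diastolic Cai
    ca_amp_base: float = 3e-4     # mM, drug-free transient amplitude
    ca_rise_ms: float = 10.0      # ms
    ca_end_base: float = 400.0    # ms, drug-free return to baseline
    # sensitivity of the APD scale factor F to block of each channel
    apd_sens_ikr: float = 0.8
    apd_sens_iks: float = 0.3
    apd_sens_ical: float = 0.4    # enters F with a minus sign (shortening)
    ca_end_sens_ikr: float = 0.3
    ca_amp_floor: float = 0.2     # amp factor at full ICaL block
    peak_drop_ical: float = 4.0   # mV lost at full ICaL block
    upstroke_floor: float = 0.25  # upstroke-rate factor at full INa block
    # current amplitudes, A/F (outward positive, inward negative)
    a_ikr: float = 0.8
    a_iks: float = 0.3
    a_ik1: float = 0.05
    a_ito: float = 1.0
    a_inal: float = 0.2
    a_ical: float = 1.5
    ito_ms: float = 20.0          # transient-outward window
    ical_peak_ms: float = 5.0     # time-to-peak of ICaL
    inal_ramp_ms: float = 5.0     # INaL trapezoid shoulder

    def __post_init__(self):
        if not self.base_apd90 > self.base_apd50 > 0:
            raise ValueError("need base_apd90 > base_apd50 > 0")

    def apd_factor(self, scales: Mapping[str, float]) -> float:
        s = _full_scales(scales)
        return (1.0
                + self.apd_sens_ikr * (1.0 - s["IKr"])
                + self.apd_sens_iks * (1.0 - s["IKs"])
                - self.apd_sens_ical * (1.0 - s["ICaL"]))


def _full_scales(scales: Optional[Mapping[str, float]]) -> dict:
    full = {ch: 1.0 for ch in CHANNELS}
    if scales:
        for ch, v in scales.items():
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel {ch!r}")
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"conductance scale for {ch} must lie in [0, 1]")
            full[ch] = float(v)
    return full


def _geometry(scales: Mapping[str, float], p: SurrogateParams) -> dict:
    """Knot times/levels of the surrogate beat (all closed-form)."""
    s = _full_scales(scales)
    F = p.apd_factor(s)
    if F <= 0:
        raise ValueError("APD scale factor must stay positive")
    t_up = p.upstroke_ms / (p.upstroke_floor + (1.0 - p.upstroke_floor) * s["INa"])
    t_act = 0.5 * t_up
    vm_peak = p.vm_peak_base - p.peak_drop_ical * (1.0 - s["ICaL"])
    apd90 = p.base_apd90 * F
    apd50 = p.base_apd50 * F
    d = (apd90 - apd50) / 0.4          # repolarisation-ramp duration
    t1 = t_act + apd50 - 0.5 * d       # plateau end
    t_end = t1 + d                     # return to rest
    if t1 <= t_up:
        raise ValueError("surrogate geometry degenerate: plateau vanished")
    ca_amp = p.ca_amp_base * (p.ca_amp_floor + (1.0 - p.ca_amp_floor) * s["ICaL"])
    t_ca_end = p.ca_end_base * (1.0 + p.ca_end_sens_ikr * (1.0 - s["IKr"]))
    return {
        "s": s, "F": F, "t_up": t_up, "t_act": t_act, "vm_peak": vm_peak,
        "apd90": apd90, "apd50": apd50, "t1": t1, "t_end": t_end,
        "ca_amp": ca_amp, "t_ca_end": t_ca_end,
    }


def _current_knots(g: dict, p: SurrogateParams, cl: float) -> dict:
    """Piecewise-linear (time, value) knots of the six net-charge currents."""
    s = g["s"]
    t_up, t1, t_end = g["t_up"], g["t1"], g["t_end"]
    r = p.inal_ramp_ms
    return {
        "IKr": ([t_up, t1, t_end], [0.0, p.a_ikr * s["IKr"], 0.0]),
        "IKs": ([t_up, t1, t_end], [0.0, p.a_iks * s["IKs"], 0.0]),
        "IK1": ([t_end, t_end + 5.0, cl], [0.0, p.a_ik1 * s["IK1"], p.a_ik1 * s["IK1"]]),
        "Ito": ([t_up, t_up + 0.5 * p.ito_ms, t_up + p.ito_ms], [0.0, p.a_ito * s["Ito"], 0.0]),
        "INaL": ([t_up, t_up + r, t1 - r, t1], [0.0, -p.a_inal * s["INaL"], -p.a_inal * s["INaL"], 0.0]),
        "ICaL": ([t_up, t_up + p.ical_peak_ms, t1], [0.0, -p.a_ical * s["ICaL"], 0.0]),
    }


def surrogate_trace(
    scales: Optional[Mapping[str, float]] = None,
    params: Optional[SurrogateParams] = None,
    cycle_length: float = 2000.0,
    dt: float = 0.1,
) -> TraceBundle:
    """One deterministic surrogate beat as a TraceBundle (replicable to n)."""
    p = params or SurrogateParams()
    g = _geometry(scales or {}, p)
    spb = cycle_length / dt
    if abs(spb - round(spb)) > 1e-9:
        raise ValueError("dt must divide cycle_length")
    t = np.arange(int(round(spb))) * dt

    vm_knots_t = [0.0, g["t_up"], g["t1"], g["t_end"]]
    vm_knots_v = [p.vm_rest, g["vm_peak"], g["vm_peak"], p.vm_rest]
    vm = np.interp(t, vm_knots_t, vm_knots_v)

    cpk = p.cai_base + g["ca_amp"]
    cai = np.interp(t, [0.0, p.ca_rise_ms, g["t_ca_end"]], [p.cai_base, cpk, p.cai_base])

    currents = {}
    for name, (kt, kv) in _current_knots(g, p, cycle_length).items():
        currents[name] = np.interp(t, [0.0] + list(kt), [kv[0] if kt[0] == 0 else 0.0] + list(kv))

    return TraceBundle(dt=dt, cycle_length=cycle_length, vm=vm, cai=cai, currents=currents)


def _closed_form_charges(scales, p: SurrogateParams, cl: float, dt: float) -> dict:
    """Exact charge (uC/uF) per current over the grid span [0, cl - dt]."""
    g = _geometry(scales or {}, p)
    s = g["s"]
    t_up, t1, t_end = g["t_up"], g["t1"], g["t_end"]
    t_last = cl - dt
    r = p.inal_ramp_ms
    q = {
        "IKr": 0.5 * p.a_ikr * s["IKr"] * (t_end - t_up),
        "IKs": 0.5 * p.a_iks * s["IKs"] * (t_end - t_up),
        "Ito": 0.5 * p.a_ito * s["Ito"] * p.ito_ms,
        "INaL": -p.a_inal * s["INaL"] * (t1 - t_up - r),
        "ICaL": -0.5 * p.a_ical * s["ICaL"] * (t1 - t_up),
        # rectangle with a 5 ms shoulder, integrated to the last grid sample
        "IK1": p.a_ik1 * s["IK1"] * (t_last - t_end - 2.5),
    }
    return {k: v * 1e-3 for k, v in q.items()}  # ms * A/F -> uC/uF


def surrogate_expected_features(
    scales: Optional[Mapping[str, float]] = None,
    params: Optional[SurrogateParams] = None,
    cycle_length: float = 2000.0,
    dt: float = 0.1,
    control_scales: Optional[Mapping[str, float]] = None,
) -> FeatureVector:
    """Closed-form values of all 12 features of the surrogate beat.

    This is the analytic oracle the extraction code is tested against; it
    shares no code with :mod:`tdprisk.trace_features`.
    """
    p = params or SurrogateParams()
    g = _geometry(scales or {}, p)
    amp = g["vm_peak"] - p.vm_rest
    d = g["t_end"] - g["t1"]
    q = _closed_form_charges(scales, p, cycle_length, dt)
    q_ctl = _closed_form_charges(control_scales or {}, p, cycle_length, dt)
    cad90 = p.ca_rise_ms + 0.9 * (g["t_ca_end"] - p.ca_rise_ms) - 0.5 * p.ca_rise_ms
    cad50 = p.ca_rise_ms + 0.5 * (g["t_ca_end"] - p.ca_rise_ms) - 0.5 * p.ca_rise_ms
    return FeatureVector(
        dvmdt_max=amp / g["t_up"],
        dvmdt_max_repol=-amp / d,
        vm_peak=g["vm_peak"],
        apd90=g["apd90"],
        apd50=g["apd50"],
        apd_tri=g["apd90"] - g["apd50"],
        ca_peak=p.cai_base + g["ca_amp"],
        cad90=cad90,
        cad50=cad50,
        cad_tri=cad90 - cad50,
        qnet=sum(q.values()),
        qinward=0.5 * (abs(q["ICaL"]) / abs(q_ctl["ICaL"]) + abs(q["INaL"]) / abs(q_ctl["INaL"])),
    )


class SurrogateModel(CellModel):
    """CellModel wrapper over the analytic surrogate beat.

    Memoryless: every paced beat is identical, the drug-free steady state is
    its resting state, and pacing any number of beats reaches it immediately.
    """

    is_periodic = True

    def __init__(self, scales=None, params: Optional[SurrogateParams] = None):
        super().__init__(scales)
        self.params = params or SurrogateParams()

    def _clone(self, scales):
        return SurrogateModel(scales, self.params)

    def _identity_fields(self):
        return tuple(sorted(asdict(self.params).items()))

    def initial_state(self) -> dict:
        return {"vm": self.params.vm_rest, "cai": self.params.cai_base}

    def advance(self, state, n_beats, cycle_length):
        if n_beats < 0:
            raise ValueError("n_beats must be >= 0")
        if n_beats == 0:
            return dict(state)
        return self.initial_state()  # fixed point of a memoryless beat

    def run(self, n_beats, cycle_length, dt, initial_state=None, keep_last=None):
        keep = n_beats if keep_last is None else keep_last
        one = surrogate_trace(self._scales, self.params, cycle_length, dt)
        if keep == 1:
            return one
        return TraceBundle(
            dt=dt,
            cycle_length=cycle_length,
            vm=np.tile(one.vm, keep),
            cai=np.tile(one.cai, keep),
            currents={k: np.tile(v, keep) for k, v in one.currents.items()},
        )


# ---------------------------------------------------------------------------
# Synthetic in vitro cohorts
# ---------------------------------------------------------------------------

#: Class-conditional block tendencies: channel -> median of true IC50 / Cmax.
#: Every drug carries a graded multichannel fingerprint (as the reference
#: panel does): high-risk drugs block IKr near Cmax, low-risk drugs are
#: dominated by ICaL block (calcium-channel-blocker-like) with only weak IKr
#: affinity, and intermediates sit between.  Medians of adjacent classes are
#: about two drug-level log-SDs apart, so class feature clouds overlap —
#: without overlap a proportional-odds fit would face complete separation.
CLASS_BLOCK_TENDENCY = {
    "high": {"IKr": 1.0, "ICaL": 12.0, "INaL": 10.0, "INa": 20.0},
    "intermediate": {"IKr": 4.0, "ICaL": 5.0, "INaL": 6.0, "INa": 25.0},
    "low": {"IKr": 16.0, "ICaL": 3.0, "INaL": 4.0, "INa": 15.0},
}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Recipe for a synthetic dose-inhibition cohort.

    ``n_per_class`` are total drugs per risk class; ``train_per_class`` says
    how many of each are assigned to the training split (the rest are test).
    Assay doses sit at ``dose_grid`` multiples of the true IC50 (a
    concentration-response design spanning the active range), with Gaussian
    inhibition noise of SD ``noise_sd`` clipped to [0, 1].
    """

    n_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"high": 4, "intermediate": 4, "low": 4}
    )
    train_per_class: Optional[Mapping[str, int]] = None
    noise_sd: float = 0.05
    seed: int = 0
    ic50_sigma: float = 0.7        # lognormal spread of IC50/Cmax across drugs
    hill_sigma: float = 0.15       # lognormal spread of h around 1
    dose_grid: tuple = (0.3, 1.0, 3.0, 10.0)
    cmax_median: float = 100.0     # nM
    cmax_sigma: float = 1.0

    def __post_init__(self):
        if not all(self.n_per_class.get(c, 0) >= 1 for c in RISK_LEVELS):
            raise ValueError("at least one drug per class required")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")

    @classmethod
    def cipa_like(cls, seed: int = 0, noise_sd: float = 0.05) -> "SyntheticCohortSpec":
        """28 drugs split 8/11/9 with the standard 4/4/4 training design."""
        return cls(
            n_per_class={"high": 8, "intermediate": 11, "low": 9},
            train_per_class={"high": 4, "intermediate": 4, "low": 4},
            noise_sd=noise_sd,
            seed=seed,
        )


def _synth_blocks_for_drug(drug_name, cmax, risk, noise_sd, dose_grid,
                           ic50_sigma, hill_sigma, rng) -> tuple:
    blocks, truth_rows = {}, []
    for channel, median_mult in CLASS_BLOCK_TENDENCY[risk].items():
        true_ic50 = cmax * median_mult * math.exp(rng.normal(0.0, ic50_sigma))
        true_h = float(np.clip(math.exp(rng.normal(0.0, hill_sigma)), 0.4, 3.0))
        doses = true_ic50 * np.asarray(dose_grid, dtype=float)
        inhib = hill_inhibition(doses, true_ic50, true_h)
        if noise_sd > 0:
            inhib = np.clip(inhib + rng.normal(0.0, noise_sd, doses.size), 0.0, 1.0)
        blocks[channel] = DrugChannelBlock(
            drug_name, channel, true_ic50, true_h,
            raw_points=tuple(zip(doses.tolist(), inhib.tolist())),
        )
        truth_rows.append({"drug": drug_name, "channel": channel,
                           "true_ic50": true_ic50, "true_h": true_h})
    return blocks, truth_rows


def synth_invitro_cohort(spec: SyntheticCohortSpec) -> tuple:
    """Generate a cohort of DrugRecords with raw dose-inhibition points.

    Returns ``(records, truth)`` where ``truth`` is a DataFrame of the true
    (IC50, h) per drug-channel, retained for parameter-recovery tests.  Same
    spec (incl. seed) regenerates the cohort bit-identically.
    """
    records, truth_rows = [], []
    for risk in RISK_LEVELS:
        n_total = spec.n_per_class[risk]
        n_train = (spec.train_per_class or {}).get(risk, n_total)
        for i in range(n_total):
            name = f"{risk}_{i:02d}"
            rng = named_rng(spec.seed, "cohort", name)
            cmax = spec.cmax_median * math.exp(rng.normal(0.0, spec.cmax_sigma))
            blocks, rows = _synth_blocks_for_drug(
                name, cmax, risk, spec.noise_sd, spec.dose_grid,
                spec.ic50_sigma, spec.hill_sigma, rng,
            )
            split = "train" if i < n_train else "test"
            records.append(DrugRecord(name, cmax, risk, split, blocks))
            truth_rows.extend(rows)
    return records, pd.DataFrame(truth_rows)


def attach_synthetic_blocks(records, seed: int = 0, noise_sd: float = 0.05,
                            dose_grid=(0.3, 1.0, 3.0, 10.0),
                            ic50_sigma: float = 0.7,
                            hill_sigma: float = 0.15) -> tuple:
    """Give existing drug records (e.g. the packaged 28-drug reference list)
    class-conditional synthetic channel blocks; returns (records, truth)."""
    out, truth_rows = [], []
    for rec in records:
        rng = named_rng(seed, "cohort", rec.drug_name)
        blocks, rows = _synth_blocks_for_drug(
            rec.drug_name, rec.cmax, rec.risk_label, noise_sd, dose_grid,
            ic50_sigma, hill_sigma, rng,
        )
        out.append(DrugRecord(rec.drug_name, rec.cmax, rec.risk_label, rec.split, blocks))
        truth_rows.extend(rows)
    return out, pd.DataFrame(truth_rows)


def cohort_from_reference(seed: int = 0, noise_sd: float = 0.05) -> tuple:
    """The packaged 28-drug list (real Cmax, risk, split) with synthetic
    class-conditional blocks — the desk-scale stand-in for the external
    in vitro assay files."""
    return attach_synthetic_blocks(load_reference_drugs(), seed=seed, noise_sd=noise_sd)


# ---------------------------------------------------------------------------
# Class-structured feature banks
# ---------------------------------------------------------------------------


def synth_feature_bank(
    class_means: Mapping[str, np.ndarray],
    sds,
    n_per_drug: int = 2000,
    drugs_per_class: Optional[Mapping[str, int]] = None,
    seed: int = 0,
    drug_offset_sd=None,
    split: str = "test",
    dataset_name: str = "synthetic",
) -> pd.DataFrame:
    """Gaussian per-drug feature clouds around class means.

    ``class_means`` maps risk class to a 12-vector (FEATURE_NAMES order);
    ``sds`` is a scalar or 12-vector of within-drug sample SDs and
    ``drug_offset_sd`` (default: equal to ``sds``) the SD of per-drug mean
    offsets.  Returns the FeatureBank row format consumed by the classifier:
    dataset, drug, sample_index, risk, split + 12 feature columns.
    """
    if n_per_drug < 1:
        raise ValueError("n_per_drug must be >= 1")
    drugs_per_class = drugs_per_class or {"high": 4, "intermediate": 4, "low": 4}
    sds = np.broadcast_to(np.asarray(sds, dtype=float), (len(FEATURE_NAMES),))
    offs = sds if drug_offset_sd is None else np.broadcast_to(
        np.asarray(drug_offset_sd, dtype=float), (len(FEATURE_NAMES),))

    frames = []
    for risk in RISK_LEVELS:
        mean = np.asarray(class_means[risk], dtype=float)
        for i in range(drugs_per_class.get(risk, 0)):
            name = f"{risk}_{i:02d}"
            rng = named_rng(seed, "bank", dataset_name, name)
            centre = mean + rng.normal(0.0, 1.0, mean.size) * offs
            samples = centre + rng.normal(0.0, 1.0, (n_per_drug, mean.size)) * sds
            df = pd.DataFrame(samples, columns=list(FEATURE_NAMES))
            df.insert(0, "dataset", dataset_name)
            df.insert(1, "drug", name)
            df.insert(2, "sample_index", np.arange(n_per_drug))
            df.insert(3, "risk", risk)
            df.insert(4, "split", split)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)
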