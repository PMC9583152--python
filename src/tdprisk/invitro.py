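"""In vitro drug-block data: Hill curves, uncertainty resampling, drug tables.

A drug's effect on one ionic current is summarised by a Hill dose-inhibition
curve.  The *inhibition factor*

    IF(D) = 1 / (1 + (D / IC50)^h)

is the fraction of channel conductance REMAINING at free drug concentration D
(despite the name: IF(0) = 1, i.e. no block without drug).  Measured
inhibition is 1 - IF.  In vitro measurement uncertainty is propagated
downstream as a cloud of resampled (IC50, h) pairs per drug-channel
(residual bootstrap of the Hill fit, 2,000 draws by default).

Concentrations are nM throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin

from ._seeding import named_rng

__all__ = [
    "CHANNELS",
    "QNET_CURRENTS",
    "RISK_LEVELS",
    "DrugChannelBlock",
    "DrugRecord",
    "HillSampleSet",
    "HillCurve",
    "inhibition_factor",
    "hill_inhibition",
    "fit_hill",
    "sample_hill_uncertainty",
    "read_drug_table",
    "load_reference_drugs",
    "write_hill_samples",
    "read_hill_samples",
]

#: The seven currents with measured drug block.
CHANNELS = ("INa", "INaL", "IKr", "IKs", "IK1", "Ito", "ICaL")

#: The six currents entering the net-charge (qNet) integral.
QNET_CURRENTS = ("INaL", "ICaL", "IKr", "IKs", "IK1", "Ito")

#: Ordinal torsadogenic risk levels, low < intermediate < high.
RISK_LEVELS = ("low", "intermediate", "high")

DEFAULT_N_HILL_SAMPLES = 2000


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DrugChannelBlock:
    """Hill description of one drug x channel block.

    ``raw_points`` optionally holds the underlying (dose nM, fractional
    inhibition) measurements; they are required for bootstrap uncertainty
    sampling.
    """

    drug_name: str
    channel: str
    ic50: float
    hill_h: float
    raw_points: Optional[tuple] = None

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise ValueError(
                f"unknown channel {self.channel!r}; accepted names: {', '.join(CHANNELS)}"
            )
        if not np.isfinite(self.ic50) or self.ic50 <= 0:
            raise ValueError(f"{self.drug_name}/{self.channel}: ic50 must be positive")
        if not np.isfinite(self.hill_h) or self.hill_h <= 0:
            raise ValueError(f"{self.drug_name}/{self.channel}: hill_h must be positive")
        if self.raw_points is not None:
            pts = np.asarray(self.raw_points, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 2:
                raise ValueError("raw_points must be (dose, inhibition) pairs")
            if np.any(pts[:, 0] < 0):
                raise ValueError("raw doses must be non-negative")
            if np.any((pts[:, 1] < 0) | (pts[:, 1] > 1)):
                raise ValueError("raw inhibitions must lie in [0, 1]")
            object.__setattr__(self, "raw_points", tuple(map(tuple, pts.tolist())))


@dataclass
class DrugRecord:
    """One drug: Cmax, ordinal risk label, train/test split, measured blocks.

    Channels absent from ``blocks`` are "no block" (conductance untouched).
    Simulation doses are integer multiples k*Cmax, k in {1, 2, 3, 4}.
    """

    drug_name: str
    cmax: float
    risk_label: str
    split: str
    blocks: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.cmax) or self.cmax <= 0:
            raise ValueError(f"drug {self.drug_name!r}: cmax must be positive")
        if self.risk_label not in RISK_LEVELS:
            raise ValueError(
                f"drug {self.drug_name!r}: risk label {self.risk_label!r} not in {RISK_LEVELS}"
            )
        if self.split not in ("train", "test"):
            raise ValueError(f"drug {self.drug_name!r}: split must be 'train' or 'test'")
        for ch, blk in self.blocks.items():
            if ch not in CHANNELS:
                raise ValueError(
                    f"unknown channel {ch!r}; accepted names: {', '.join(CHANNELS)}"
                )
            if blk.channel != ch:
                raise ValueError(f"block channel {blk.channel!r} filed under {ch!r}")

    def doses(self, multiples: Sequence[int] = (1, 2, 3, 4)) -> np.ndarray:
        return np.asarray([k * self.cmax for k in multiples], dtype=float)


@dataclass
class HillSampleSet:
    """N resampled (ic50, hill_h) pairs quantifying in vitro uncertainty."""

    drug_name: str
    channel: str
    samples: np.ndarray  # shape (n, 2): columns ic50, hill_h
    seed: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 2:
            raise ValueError("samples must have shape (n, 2)")
        if np.any(self.samples <= 0) or not np.all(np.isfinite(self.samples)):
            raise ValueError("all sampled ic50 and hill_h must be positive and finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def ic50(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def hill_h(self) -> np.ndarray:
        return self.samples[:, 1]


# ---------------------------------------------------------------------------
# Hill curve math
# ---------------------------------------------------------------------------


def inhibition_factor(dose, ic50, hill_h):
    """Fraction of conductance remaining at ``dose``: 1 / (1 + (D/IC50)^h).

    Strictly decreasing in dose, mapping [0, inf) onto (0, 1]; equals 1 at
    zero dose and 0.5 at dose = IC50 for any h.  Vectorised in ``dose``.
    """
    dose = np.asarray(dose, dtype=float)
    ic50 = float(ic50)
    hill_h = float(hill_h)
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    if hill_h <= 0:
        raise ValueError("hill_h must be positive")
    if np.any(dose < 0):
        raise ValueError("dose must be non-negative")
    # 1/(1+(D/IC50)^h) = expit(-h * (ln D - ln IC50)); exact 1.0 at D = 0.
    with np.errstate(divide="ignore"):
        z = hill_h * (np.log(dose) - np.log(ic50))
    out = expit(-z)
    if out.ndim == 0:
        return float(out)
    return out


def hill_inhibition(dose, ic50, hill_h):
    """Measured fractional inhibition: 1 - inhibition_factor."""
    return 1.0 - inhibition_factor(dose, ic50, hill_h)


class HillCurve(BaseEstimator, RegressorMixin):
    """Least-squares Hill dose-inhibition fit, sklearn-estimator style.

    ``fit(X, y)`` takes doses (nM, shape (n,) or (n, 1)) and fractional
    inhibitions in [0, 1].  Parameters are optimised on the log scale so
    positivity is structural.

    Attributes
    ----------
    ic50_ : float
    hill_ : float
    residual_sd_ : float
        Residual standard deviation (n - 2 dof), fed to the bootstrap
        resampler.
    """

    def __init__(self, max_nfev: int = 200):
        self.max_nfev = max_nfev

    def fit(self, X, y):
        doses = np.asarray(X, dtype=float).reshape(-1)
        inhib = np.asarray(y, dtype=float).reshape(-1)
        if doses.shape != inhib.shape:
            raise ValueError("doses and inhibitions must have equal length")
        if np.any(doses <= 0):
            raise ValueError("doses must be positive")
        if np.any((inhib < 0) | (inhib > 1)):
            raise ValueError("inhibitions must lie in [0, 1]")
        if np.unique(doses).size < 3:
            raise ValueError("underdetermined: need >= 3 distinct positive doses")
        if np.ptp(inhib) == 0:
            raise ValueError("no dose response: all inhibitions identical")

        log_d = np.log(doses)

        def residuals(theta):
            log_ic50, log_h = theta
            z = np.exp(log_h) * (log_d - log_ic50)
            return expit(z) - inhib

        # Start IC50 near the dose whose inhibition is closest to one half.
        x0 = np.array([log_d[np.argmin(np.abs(inhib - 0.5))], 0.0])
        sol = least_squares(
            residuals, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15,
            max_nfev=self.max_nfev,
        )
        ic50, h = np.exp(sol.x)
        if not (np.isfinite(ic50) and np.isfinite(h)) or not (1e-9 < ic50 < 1e15):
            raise ValueError("Hill fit diverged")
        self.ic50_ = float(ic50)
        self.hill_ = float(h)
        dof = max(doses.size - 2, 1)
        self.residual_sd_ = float(np.sqrt(np.sum(sol.fun**2) / dof))
        return self

    def predict(self, X):
        doses = np.asarray(X, dtype=float).reshape(-1)
        return hill_inhibition(doses, self.ic50_, self.hill_)


def fit_hill(points: Iterable) -> tuple:
    """Fit a Hill curve to (dose, inhibition) pairs.

    Returns ``(ic50, hill_h, residual_sd)``.  Raises ``ValueError``
    ("underdetermined") below 3 distinct doses and ("no dose response") for
    flat data.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("underdetermined: need >= 3 (dose, inhibition) points")
    est = HillCurve().fit(pts[:, 0], pts[:, 1])
    return est.ic50_, est.hill_, est.residual_sd_


# ---------------------------------------------------------------------------
# Uncertainty resampling
# ---------------------------------------------------------------------------


def sample_hill_uncertainty(
    block: DrugChannelBlock,
    n: int = DEFAULT_N_HILL_SAMPLES,
    seed: int = 0,
    cv: Optional[float] = None,
    max_attempts: int = 20,
) -> HillSampleSet:
    """Draw ``n`` (ic50, h) pairs quantifying dose-inhibition uncertainty.

    With ``raw_points`` present, a residual bootstrap refits the Hill curve on
    resampled residuals per replicate, so IC50 and h are drawn jointly and
    their fit correlation is preserved.  Without raw points a lognormal
    parametric fallback with coefficient of variation ``cv`` is used.

    Same ``seed`` (and drug/channel names) reproduces the set bit-identically;
    the stream is named per (drug, channel) so per-drug results are
    order-independent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = named_rng(seed, "hill", block.drug_name, block.channel)

    if block.raw_points is None:
        if cv is None:
            raise ValueError(
                f"{block.drug_name}/{block.channel}: no raw points; "
                "a coefficient-of-variation prior (cv) is required"
            )
        sigma = np.sqrt(np.log1p(cv**2))
        # Median-preserving lognormal jitter around the point estimate.
        ic50 = block.ic50 * np.exp(rng.normal(0.0, sigma, n))
        h = block.hill_h * np.exp(rng.normal(0.0, sigma, n))
        return HillSampleSet(block.drug_name, block.channel, np.column_stack([ic50, h]), seed)

    pts = np.asarray(block.raw_points, dtype=float)
    doses, y = pts[:, 0], pts[:, 1]
    ic50_hat, h_hat, resid_sd = fit_hill(pts)
    yhat = hill_inhibition(doses, ic50_hat, h_hat)
    resid = y - yhat

    if np.allclose(resid, 0.0, atol=1e-12):
        samples = np.tile([ic50_hat, h_hat], (n, 1))
        return HillSampleSet(block.drug_name, block.channel, samples, seed)

    m = doses.size
    samples = np.empty((n, 2))
    first_try_failures = 0
    for i in range(n):
        ok = False
        for attempt in range(max_attempts):
            idx = rng.integers(0, m, m)
            ystar = np.clip(yhat + resid[idx], 0.0, 1.0)
            try:
                ic50_b, h_b, _ = fit_hill(np.column_stack([doses, ystar]))
            except ValueError:
                if attempt == 0:
                    first_try_failures += 1
                continue
            samples[i] = (ic50_b, h_b)
            ok = True
            break
        if not ok:
            raise ValueError(
                f"unstable uncertainty: {block.drug_name}/{block.channel} bootstrap "
                f"replicate {i} failed {max_attempts} times"
            )
    if first_try_failures > 0.5 * n:
        raise ValueError(
            f"unstable uncertainty: {block.drug_name}/{block.channel} bootstrap fit "
            f"diverged in {first_try_failures}/{n} replicates"
        )
    return HillSampleSet(block.drug_name, block.channel, samples, seed)


# ---------------------------------------------------------------------------
# Tabular IO
# ---------------------------------------------------------------------------

_DRUG_COL_ALIASES = {"drug": "drug", "drug_name": "drug", "cmax_nm": "cmax_nm",
                     "cmax": "cmax_nm", "risk": "risk", "risk_label": "risk",
                     "split": "split"}


def _normalise_columns(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def read_drug_table(path, blocks_path=None) -> list:
    """Read a drug-level CSV (drug, cmax_nM, risk, split) into DrugRecords.

    ``blocks_path`` optionally adds per-channel block rows
    (drug, channel, ic50_nM, hill[, dose_nM, inhibition]).  Rows carrying
    dose_nM/inhibition are collected as raw points; if ic50_nM is absent for a
    (drug, channel) the Hill parameters are fitted from the raw points.
    Channels never mentioned stay "no block".
    """
    df = _normalise_columns(pd.read_csv(path))
    df = df.rename(columns={c: _DRUG_COL_ALIASES.get(c, c) for c in df.columns})
    for col in ("drug", "cmax_nm", "risk", "split"):
        if col not in df.columns:
            raise ValueError(f"drug table missing required column {col!r}")
    if len(df) == 0:
        raise ValueError("no drug rows")

    blocks_by_drug: dict = {}
    if blocks_path is not None:
        blocks_by_drug = _read_blocks(blocks_path)

    records = []
    for _, row in df.iterrows():
        name = str(row["drug"]).strip()
        cmax = row["cmax_nm"]
        if pd.isna(cmax):
            raise ValueError(f"drug {name!r}: missing Cmax")
        risk = str(row["risk"]).strip().lower()
        split = str(row["split"]).strip().lower()
        records.append(
            DrugRecord(name, float(cmax), risk, split, blocks=blocks_by_drug.get(name, {}))
        )
    return records


def _read_blocks(path) -> dict:
    df = _normalise_columns(pd.read_csv(path))
    if "drug" not in df.columns or "channel" not in df.columns:
        raise ValueError("blocks table requires 'drug' and 'channel' columns")
    out: dict = {}
    for (drug, channel), grp in df.groupby(["drug", "channel"], sort=False):
        drug = str(drug).strip()
        channel = str(channel).strip()
        if channel not in CHANNELS:
            raise ValueError(
                f"unknown channel {channel!r}; accepted names: {', '.join(CHANNELS)}"
            )
        raw = None
        if "dose_nm" in grp.columns:
            raw_rows = grp.dropna(subset=["dose_nm", "inhibition"]) if "inhibition" in grp.columns else grp.iloc[0:0]
            if len(raw_rows):
                raw = tuple(zip(raw_rows["dose_nm"].astype(float), raw_rows["inhibition"].astype(float)))
        ic50 = h = None
        if "ic50_nm" in grp.columns and grp["ic50_nm"].notna().any():
            first = grp.loc[grp["ic50_nm"].notna()].iloc[0]
            ic50 = float(first["ic50_nm"])
            if ic50 <= 0:
                raise ValueError(f"{drug}/{channel}: negative or zero IC50")
            h = float(first["hill"]) if "hill" in grp.columns and pd.notna(first.get("hill")) else 1.0
        if ic50 is None:
            if raw is None:
                raise ValueError(f"{drug}/{channel}: neither ic50_nM nor raw points present")
            ic50, h, _ = fit_hill(raw)
        out.setdefault(drug, {})[channel] = DrugChannelBlock(drug, channel, ic50, h, raw)
    return out


def load_reference_drugs() -> list:
    """The packaged 28-drug CiPA reference list (Cmax, risk, split); no blocks."""
    with resources.as_file(resources.files("tdprisk.data") / "cipa_drugs.csv") as p:
        return read_drug_table(p)


def write_hill_samples(sample_sets: Iterable[HillSampleSet], path) -> None:
    """Serialize sample sets as CSV (drug, channel, sample_index, ic50_nM, hill)."""
    frames = []
    for s in sample_sets:
        frames.append(pd.DataFrame({
            "drug": s.drug_name,
            "channel": s.channel,
            "sample_index": np.arange(s.n_samples),
            "ic50_nM": s.ic50,
            "hill": s.hill_h,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.12g")


def read_hill_samples(path) -> dict:
    """Inverse of :func:`write_hill_samples`: {(drug, channel): HillSampleSet}."""
    df = pd.read_csv(path)
    out = {}
    for (drug, channel), grp in df.groupby(["drug", "channel"], sort=False):
        grp = grp.sort_values("sample_index")
        out[(drug, channel)] = HillSampleSet(
            drug, channel, np.column_stack([grp["ic50_nM"], grp["hill"]]), seed=-1
        )
    return out
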