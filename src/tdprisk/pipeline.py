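"""End-to-end orchestration: cohort -> Hill uncertainty -> drugged simulation
-> feature bank -> ordinal fits & thresholds -> repeated-test evaluation.

Every stage writes a plain-text artifact into the run directory and a
manifest records the configuration hash, seed, package versions and artifact
checksums, so a rerun with the same config is bit-identical on the
synthetic/surrogate backends.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .cardiac_sim import apply_drug_block, paced_simulation, run_to_steady_state
from .evaluation import FeatureBank, evaluate_repeats
from .invitro import (
    CHANNELS,
    read_drug_table,
    sample_hill_uncertainty,
    write_hill_samples,
    read_hill_samples,
)
from .risk_olr import OrdinalRiskClassifier, fit_olr
from .synthetic import SurrogateModel, cohort_from_reference
from .trace_features import (
    FEATURE_NAMES,
    average_over_concentrations,
    extract_features,
    select_worst_beat,
)

__all__ = ["RunConfig", "run_pipeline", "report", "build_feature_bank"]


@dataclass
class RunConfig:
    """Pipeline configuration (protocol constants default to the recorded
    study conditions: CL 2,000 ms, 10,000 pre-beats, 1,000 beats, 0.1 ms grid,
    last 250 beats kept, 2,000 Hill samples, doses 1-4x Cmax, 10,000 repeats).
    """

    outdir: str = "runs/demo"
    seed: int = 1
    backend: str = "surrogate"              # surrogate | torord_cellml
    dataset_name: str = "synthetic"
    drug_table: Optional[str] = None        # CSV paths; None -> packaged 28-drug
    blocks_table: Optional[str] = None      # reference list + synthetic blocks
    cohort_noise_sd: float = 0.05
    cycle_length_ms: float = 2000.0
    n_prebeats: int = 10000
    n_beats: int = 1000
    dt_ms: float = 0.1
    keep_last_beats: int = 250
    n_hill_samples: int = 2000
    dose_multiples: tuple = (1, 2, 3, 4)
    n_repeats: int = 10000
    features: tuple = FEATURE_NAMES
    cellml_path: Optional[str] = None

    def __post_init__(self):
        for name in ("n_prebeats", "n_beats", "keep_last_beats", "n_hill_samples", "n_repeats"):
            if getattr(self, name) < (0 if name == "n_prebeats" else 1):
                raise ValueError(f"{name} must be positive")
        if self.dt_ms <= 0 or self.cycle_length_ms <= 0:
            raise ValueError("dt_ms and cycle_length_ms must be positive")
        spb = self.cycle_length_ms / self.dt_ms
        if abs(spb - round(spb)) > 1e-9:
            raise ValueError("dt_ms must divide cycle_length_ms")
        if self.keep_last_beats > self.n_beats:
            raise ValueError("keep_last_beats must be <= n_beats")
        if not all(int(k) == k and k > 0 for k in self.dose_multiples):
            raise ValueError("dose_multiples must be positive integers")
        if self.backend not in ("surrogate", "torord_cellml"):
            raise ValueError("backend must be 'surrogate' or 'torord_cellml'")

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in dataclasses.asdict(self).items() if k != "outdir"},
            sort_keys=True, default=str,
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Flat key=value config file; unknown keys are rejected."""
        kwargs = {}
        valid = {f.name: f.type for f in dataclasses.fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in valid:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = _coerce(key, value)
        return cls(**kwargs)


def _coerce(key, value):
    if key in ("dose_multiples", "features"):
        parts = [p.strip() for p in value.split(",") if p.strip()]
        return tuple(int(p) for p in parts) if key == "dose_multiples" else tuple(parts)
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    if value.lower() in ("none", ""):
        return None
    return value


def _make_model(config: RunConfig):
    if config.backend == "surrogate":
        return SurrogateModel()
    from .torord import ToROrdModel  # optional extra; raises without myokit

    return ToROrdModel(config.cellml_path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_cohort(config: RunConfig, outdir: Path) -> list:
    if config.drug_table is not None:
        records = read_drug_table(config.drug_table, config.blocks_table)
    else:
        records, truth = cohort_from_reference(seed=config.seed,
                                               noise_sd=config.cohort_noise_sd)
        truth.to_csv(outdir / "cohort_truth.csv", index=False, float_format="%.12g")
    drug_rows, block_rows = [], []
    for rec in records:
        drug_rows.append({"drug": rec.drug_name, "cmax_nM": rec.cmax,
                          "risk": rec.risk_label, "split": rec.split})
        for ch, blk in rec.blocks.items():
            for dose, inhib in (blk.raw_points or ()):
                block_rows.append({"drug": rec.drug_name, "channel": ch,
                                   "ic50_nM": blk.ic50, "hill": blk.hill_h,
                                   "dose_nM": dose, "inhibition": inhib})
    pd.DataFrame(drug_rows).to_csv(outdir / "drugs.csv", index=False, float_format="%.12g")
    pd.DataFrame(block_rows).to_csv(outdir / "blocks.csv", index=False, float_format="%.12g")
    return records


def stage_hill(config: RunConfig, records, outdir: Path) -> dict:
    sample_sets = {}
    for rec in records:
        for ch, blk in rec.blocks.items():
            sample_sets[(rec.drug_name, ch)] = sample_hill_uncertainty(
                blk, n=config.n_hill_samples, seed=config.seed
            )
    write_hill_samples(sample_sets.values(), outdir / "hill_samples.csv")
    return sample_sets


def build_feature_bank(config: RunConfig, records, sample_sets, model=None,
                       log=None) -> pd.DataFrame:
    """Simulate every (drug, uncertainty sample, dose), extract the 12
    features from the worst retained beat, and average over the four doses.

    On a beat-periodic backend (the surrogate) a single simulated beat stands
    in for the 1,000-beat protocol: every beat is identical, so the worst
    beat equals any beat and the retained-window bookkeeping is exact.
    Simulation failures mark the sample's features missing instead of
    aborting the sweep.
    """
    model = model or _make_model(config)
    cache_dir = Path(config.outdir) / "cache"
    state0 = run_to_steady_state(model, n_beats=config.n_prebeats,
                                 cycle_length=config.cycle_length_ms,
                                 cache_dir=cache_dir)
    periodic = getattr(model, "is_periodic", False)
    n_beats = 1 if periodic else config.n_beats
    keep = 1 if periodic else config.keep_last_beats

    def worst_beat(bundle):
        i = select_worst_beat(bundle) if bundle.n_beats > 1 else 0
        return bundle.beat(i)

    control = paced_simulation(model, state0, n_beats=n_beats,
                               cycle_length=config.cycle_length_ms,
                               dt=config.dt_ms, keep_last=keep)
    control_beat = worst_beat(control)

    n_feat = len(FEATURE_NAMES)
    rows = []
    for rec in records:
        channels = [ch for ch in CHANNELS if (rec.drug_name, ch) in sample_sets]
        samples = {ch: sample_sets[(rec.drug_name, ch)].samples for ch in channels}
        n_samples = config.n_hill_samples
        values = np.full((n_samples, n_feat), np.nan)
        for i in range(n_samples):
            draw = {ch: (samples[ch][i, 0], samples[ch][i, 1]) for ch in channels}
            per_dose = []
            try:
                for k in config.dose_multiples:
                    blocked = apply_drug_block(model, draw, k * rec.cmax)
                    bundle = paced_simulation(blocked, state0, n_beats=n_beats,
                                              cycle_length=config.cycle_length_ms,
                                              dt=config.dt_ms, keep_last=keep)
                    per_dose.append(extract_features(worst_beat(bundle), control_beat))
                values[i] = average_over_concentrations(per_dose).to_array()
            except (ValueError, RuntimeError) as exc:
                if log is not None:
                    log(f"{rec.drug_name} sample {i}: {exc}")
        df = pd.DataFrame(values, columns=list(FEATURE_NAMES))
        df.insert(0, "dataset", config.dataset_name)
        df.insert(1, "drug", rec.drug_name)
        df.insert(2, "sample_index", np.arange(n_samples))
        df.insert(3, "risk", rec.risk_label)
        df.insert(4, "split", rec.split)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def stage_fit(config: RunConfig, bank: pd.DataFrame, outdir: Path) -> dict:
    """One single-feature ordinal fit per feature.

    A feature that cannot be fitted at all (constant values, a class absent
    after missing-value drops) yields a structured unfit row — the report
    prints a dash for it — rather than aborting the stage.
    """
    train = bank[bank["split"] == "train"]
    models, rows = {}, []
    for feat in config.features:
        try:
            m = fit_olr(train[feat].to_numpy(dtype=float), train["risk"].to_numpy())
        except ValueError as exc:
            rows.append({"feature": feat, "beta": math.nan, "zeta1": math.nan,
                         "zeta2": math.nan, "th1": math.nan, "th2": math.nan,
                         "converged": False, "n_dropped": math.nan,
                         "diagnostic": str(exc)})
            continue
        m.feature_name_ = feat
        models[feat] = m
        rows.append({"feature": feat, **m.to_dict(), "diagnostic": m.diagnostic_})
        _write_model(m, feat, outdir / "models" / f"{feat}.txt")
    pd.DataFrame(rows).to_csv(outdir / "thresholds.csv", index=False, float_format="%.10g")
    return models


def _write_model(m: OrdinalRiskClassifier, feature: str, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    d = {"feature": feature, **m.to_dict()}
    path.write_text("".join(f"{k} {v}\n" for k, v in d.items()))


def stage_evaluate(config: RunConfig, models: dict, bank: pd.DataFrame,
                   outdir: Path) -> pd.DataFrame:
    frames = []
    for feat, m in models.items():
        if not m.converged_:
            continue
        summary = evaluate_repeats(m, bank, feature=feat,
                                   n_repeats=config.n_repeats, seed=config.seed)
        t = summary.table.reset_index()
        t.insert(0, "feature", feat)
        frames.append(t)
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=["feature", "metric", "class",
                                      "median", "min", "max", "cell"]))
    out.to_csv(outdir / "metrics.csv", index=False, float_format="%.10g")
    return out


def run_pipeline(config: RunConfig, log=None) -> dict:
    """Run every stage into ``config.outdir``; returns the manifest dict.

    Existing stage artifacts are reused when the configuration hash matches
    (resume-after-partial-failure); pass a fresh outdir for a clean run.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    hash_file = outdir / "config_hash.txt"
    resume = hash_file.exists() and hash_file.read_text().strip() == chash
    hash_file.write_text(chash + "\n")

    records = stage_cohort(config, outdir)

    hill_file = outdir / "hill_samples.csv"
    if resume and hill_file.exists():
        sample_sets = read_hill_samples(hill_file)
    else:
        sample_sets = stage_hill(config, records, outdir)

    bank_file = outdir / "feature_bank.csv"
    if resume and bank_file.exists():
        bank = pd.read_csv(bank_file)
    else:
        bank = build_feature_bank(config, records, sample_sets, log=log)
        bank.to_csv(bank_file, index=False, float_format="%.12g")

    FeatureBank(bank, config.dataset_name)  # validate row contract
    models = stage_fit(config, bank, outdir)
    stage_evaluate(config, models, bank, outdir)

    n_doses = len(config.dose_multiples)
    manifest = {
        "package_version": _pkg_version,
        "config": dataclasses.asdict(config),
        "config_hash": chash,
        "seed": config.seed,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "counts": {
            "n_drugs": len(records),
            "n_train_rows": int((bank["split"] == "train").sum()),
            "n_test_rows": int((bank["split"] == "test").sum()),
            "biomarkers_per_drug": config.n_hill_samples * n_doses,
            "hill_samples_per_drug_channel": config.n_hill_samples,
            "test_set_size": int(bank.loc[bank["split"] == "test", "drug"].nunique()),
            "n_repeats": config.n_repeats,
        },
        "artifacts": {
            p.name: _sha256(p)
            for p in sorted(outdir.glob("*.csv"))
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def report(run_dir) -> str:
    """Render the run's thresholds and performance summaries as Markdown.

    Non-converged features print a dash in every cell.  Raises if a stage
    artifact is missing, naming the stage.
    """
    run_dir = Path(run_dir)
    thr_file = run_dir / "thresholds.csv"
    met_file = run_dir / "metrics.csv"
    if not thr_file.exists():
        raise FileNotFoundError(f"missing artifact of stage 'fit': {thr_file}")
    if not met_file.exists():
        raise FileNotFoundError(f"missing artifact of stage 'evaluate': {met_file}")
    thr = pd.read_csv(thr_file)
    met = pd.read_csv(met_file, keep_default_na=False)

    lines = ["# Run report", "", "## Risk thresholds per feature", "",
             "| feature | TH1 | TH2 |", "|---|---|---|"]
    for _, row in thr.iterrows():
        if bool(row["converged"]) and not (isinstance(row["th1"], float) and math.isnan(row["th1"])):
            lines.append(f"| {row['feature']} | {row['th1']:.4g} | {row['th2']:.4g} |")
        else:
            lines.append(f"| {row['feature']} | - | - |")

    lines += ["", "## Classification performance, median (min–max) over repeats", "",
              "| feature | Acc | AUC low | AUC inter | AUC high | F1 low | F1 inter | F1 high |",
              "|---|---|---|---|---|---|---|---|"]
    met["class"] = met["class"].fillna("") if "class" in met else ""

    def cell(feat, metric, cls):
        sel = met[(met["feature"] == feat) & (met["metric"] == metric) & (met["class"] == cls)]
        return sel["cell"].iloc[0] if len(sel) else "-"

    for feat in thr["feature"]:
        row = [feat, cell(feat, "accuracy", "")]
        for metric in ("auc", "f1"):
            for cls in ("low", "intermediate", "high"):
                row.append(cell(feat, metric, cls))
        lines.append("| " + " | ".join(str(v) for v in row) + " |")

    text = "\n".join(lines) + "\n"
    (run_dir / "report.md").write_text(text)
    return text
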