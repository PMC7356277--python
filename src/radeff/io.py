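"""CSV interchange for trial bundles.

All tables are plain comma-separated files with documented headers; model
parameters and statistical summaries are written as JSON.  Units are fixed
by convention: PAR MJ m^-2 d^-1, temperatures degC, reflectance unitless in
[0, 1], tuber mass g per plant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .synthetic import CanopyObservations, SyntheticTrial, TrialDesign
from .weather import validate_weather

__all__ = ["TrialData", "write_trial", "read_trial"]


@dataclass(frozen=True)
class TrialData:
    """Observed-data bundle (what a real trial provides: no ground truth)."""

    weather: pd.DataFrame
    design: TrialDesign
    canopy: dict[str, CanopyObservations]
    harvest: dict[str, pd.DataFrame]
    physiology: pd.DataFrame


def _require(df: pd.DataFrame, cols: set[str], name: str) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"{name} missing columns: {sorted(missing)}")


def write_trial(trial: SyntheticTrial | TrialData, outdir) -> Path:
    """Write the bundle as weather/design/canopy/harvest/physiology CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    validate_weather(trial.weather)
    trial.weather.to_csv(outdir / "weather.csv", index=False)
    trial.design.entries.to_csv(outdir / "design.csv", index=False)
    canopy_rows = []
    for plot_id, obs in trial.canopy.items():
        t = obs.table.copy()
        t.insert(0, "plot_id", plot_id)
        canopy_rows.append(t)
    pd.concat(canopy_rows, ignore_index=True).to_csv(outdir / "canopy.csv", index=False)
    harvest_rows = []
    for plot_id, t in trial.harvest.items():
        t = t.copy()
        t.insert(0, "plot_id", plot_id)
        harvest_rows.append(t)
    pd.concat(harvest_rows, ignore_index=True).to_csv(outdir / "harvest.csv", index=False)
    trial.physiology.to_csv(outdir / "physiology.csv", index=False)
    meta = {
        "plant_area_m2": trial.design.plant_area,
        "n_blocks": trial.design.n_blocks,
        "units": {
            "par_inc": "MJ m^-2 d^-1",
            "tmin/tmax": "degC",
            "reflectance": "[0,1]",
            "ty_obs": "g plant^-1",
        },
    }
    (outdir / "trial_meta.json").write_text(json.dumps(meta, indent=2))
    return outdir


def read_trial(indir) -> TrialData:
    """Load and schema-validate a trial bundle written by :func:`write_trial`."""
    indir = Path(indir)
    weather = pd.read_csv(indir / "weather.csv", parse_dates=["date"])
    validate_weather(weather)
    entries = pd.read_csv(indir / "design.csv")
    _require(
        entries,
        {"plot_id", "accession", "is_check", "block", "harvest_dap"},
        "design.csv",
    )
    meta = json.loads((indir / "trial_meta.json").read_text())
    design = TrialDesign(
        entries, plant_area=meta["plant_area_m2"], n_blocks=meta["n_blocks"]
    )
    canopy_df = pd.read_csv(indir / "canopy.csv")
    _require(canopy_df, {"plot_id", "dap", "green", "red", "nir"}, "canopy.csv")
    for col in ("green", "red", "nir"):
        bad = canopy_df.index[(canopy_df[col] < 0) | (canopy_df[col] > 1)]
        if len(bad):
            raise ValueError(f"canopy.csv: {col} outside [0,1] at row {bad[0]}")
    canopy = {
        pid: CanopyObservations(table=g.drop(columns="plot_id").reset_index(drop=True))
        for pid, g in canopy_df.groupby("plot_id")
    }
    harvest_df = pd.read_csv(indir / "harvest.csv")
    _require(harvest_df, {"plot_id", "dap", "ty_obs"}, "harvest.csv")
    bad = harvest_df.index[harvest_df["ty_obs"] <= 0]
    if len(bad):
        raise ValueError(f"harvest.csv: non-positive ty_obs at row {bad[0]}")
    harvest = {
        pid: g.drop(columns="plot_id").reset_index(drop=True)
        for pid, g in harvest_df.groupby("plot_id")
    }
    physiology = pd.read_csv(indir / "physiology.csv")
    return TrialData(
        weather=weather,
        design=design,
        canopy=canopy,
        harvest=harvest,
        physiology=physiology,
    )
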