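"""Structured outputs: trajectory CSV, calibration reports, run configs.

All writers validate their payload against small hand-written schemas
before touching disk, so a malformed report is an internal error rather
than a silently corrupt artifact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationResult, cohort_metrics
from .solver import Trajectory


class ReportError(RuntimeError):
    pass


_CASE_KEYS = {
    "case_id": str,
    "t_i_days": float,
    "r_c_per_s": float,
    "eps_pd_per_s": float,
    "V0_star_cm3": float,
    "dVs_star_cm3": float,
    "V0_cm3": float,
    "dVs_cm3": float,
    "AD_baseline_cm3": float,
    "AD_post_cm3": float,
    "rel_dev_baseline_percent": float,
    "rel_dev_post_percent": float,
    "label": str,
}


def _validate_case_dict(d: dict) -> None:
    for key, typ in _CASE_KEYS.items():
        if key not in d:
            raise ReportError(f"calibration record missing key {key!r}")
        if typ is float and not isinstance(d[key], (int, float)):
            raise ReportError(f"calibration record key {key!r} is not numeric: {d[key]!r}")
        if typ is str and not isinstance(d[key], str):
            raise ReportError(f"calibration record key {key!r} is not a string")
    if d["label"] not in ("TP", "miss"):
        raise ReportError(f"invalid label {d['label']!r}")


def write_trajectory(path: str | Path, trajectory: Trajectory) -> Path:
    """CSV with columns time_days, V_star_cm3, drug_mass_1..n."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trajectory.to_frame().to_csv(path, index=False, float_format="%.17g")
    return path


def read_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    drug_cols = [c for c in df.columns if c.startswith("drug_mass_")]
    return Trajectory(
        times_days=df["time_days"].to_numpy(),
        v_star_cm3=df["V_star_cm3"].to_numpy(),
        drug_mass=df[drug_cols].to_numpy()
        if drug_cols
        else np.zeros((len(df), 0)),
    )


def write_report(path: str | Path, results: list[CalibrationResult]) -> Path:
    """Cohort calibration report: per-case fits plus precision/sensitivity."""
    if not results:
        raise ReportError("cannot write a report for an empty result list")
    records = [r.to_dict() for r in results]
    for rec in records:
        _validate_case_dict(rec)
    payload = {
        "cases": records,
        "cohort": cohort_metrics([r.label for r in results]),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2))
    return path


def summary_table(results: list[CalibrationResult]) -> pd.DataFrame:
    """Per-case measured vs computed volumes with signed differences."""
    return pd.DataFrame(
        [
            {
                "patient": r.case_id,
                "V(0)_cm3": r.v0_cm3,
                "V*(0)_cm3": round(r.v0_star_cm3, 3),
                "AD(0)_cm3": round(r.ad_baseline_cm3, 3),
                "dVs_cm3": r.dvs_cm3,
                "dVs*_cm3": round(r.dvs_star_cm3, 3),
                "AD(dts)_cm3": round(r.ad_post_cm3, 3),
                "label": r.label,
            }
            for r in results
        ]
    )


def write_run_config(out_dir: str | Path, config: dict) -> Path:
    """Persist the fully resolved run configuration beside the outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "run_config.json"
    path.write_text(json.dumps(config, indent=2, sort_keys=True, default=str))
    return path
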