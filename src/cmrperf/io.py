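"""Curve CSV I/O, configuration files, and the packaged patient fixture.

Curve files are flat CSVs with columns ``time_s, value, region, subject,
state`` (``state`` in {stress, rest}); one row per sample, UTF-8, header
required. The blood-pool curve carries the region label ``AIF``.

The packaged fixture ``table4.csv`` holds the per-vessel stress flow and
perfusion-reserve values of a five-patient coronary-artery-disease cohort
together with the angiographic classification of each vessel (group 1
no/minor disease, 2 non-obstructive, 3 obstructive); it drives the
reduced-flow classification analysis without any image data.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Dict, List, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .cohort import TerritorySummary, classify_reduced_flow
from .curves import ConcentrationCurve, SignalCurve
from .signal import AcquisitionParams

__all__ = [
    "read_curves",
    "write_curves",
    "write_results",
    "load_table4",
    "table4_summaries",
    "load_acquisition_params",
    "CURVE_COLUMNS",
]

CURVE_COLUMNS = ["time_s", "value", "region", "subject", "state"]

CurveKey = Tuple[str, str, str]  # (subject, state, region)


def read_curves(
    path: Union[str, Path], kind: str = "signal"
) -> Dict[CurveKey, Union[SignalCurve, ConcentrationCurve]]:
    """Read a curve CSV into {(subject, state, region): curve}.

    ``kind`` selects the container: "signal" (scanner units) or
    "concentration" (mM). Malformed rows are reported with their line
    numbers.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    bad = df.index[
        pd.to_numeric(df["time_s"], errors="coerce").isna()
        | pd.to_numeric(df["value"], errors="coerce").isna()
    ]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise ValueError(f"{path}: non-numeric time/value at line(s) {lines}")
    bad_state = set(df["state"].unique()) - {"stress", "rest"}
    if bad_state:
        raise ValueError(f"{path}: invalid state value(s) {sorted(bad_state)}")
    cls = SignalCurve if kind == "signal" else ConcentrationCurve
    out: Dict[CurveKey, Union[SignalCurve, ConcentrationCurve]] = {}
    for (subject, state, region), grp in df.groupby(
        ["subject", "state", "region"], sort=True
    ):
        grp = grp.sort_values("time_s")
        out[(str(subject), str(state), str(region))] = cls(
            times=grp["time_s"].to_numpy(float),
            values=grp["value"].to_numpy(float),
            region_label=str(region),
        )
    return out


def write_curves(path: Union[str, Path], curves: Dict[CurveKey, object]) -> None:
    """Write {(subject, state, region): curve} to the curve CSV dialect."""
    rows = []
    for (subject, state, region), curve in curves.items():
        for t, v in zip(curve.times, curve.values):
            rows.append((t, v, region, subject, state))
    df = pd.DataFrame(rows, columns=CURVE_COLUMNS)
    df.to_csv(path, index=False)


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return float(f"{obj:.{ndigits}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, np.floating):
        return _round_floats(float(obj), ndigits)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    return obj


def write_results(path: Union[str, Path], results: dict) -> None:
    """Serialize a results dictionary to JSON, floats at 6 significant digits."""
    payload = {"schema_version": 1}
    payload.update(_round_floats(results))
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def load_table4(path: Union[str, Path, None] = None) -> pd.DataFrame:
    """The packaged per-vessel patient table (or an external file like it)."""
    if path is None:
        with resources.as_file(
            resources.files("cmrperf").joinpath("data/table4.csv")
        ) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"patient", "vessel", "group", "dp_mbf_stress", "fermi_mbf_stress"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"patient table missing column(s) {sorted(missing)}")
    if len(df) != df[["patient", "vessel"]].drop_duplicates().shape[0]:
        raise ValueError("duplicate patient/vessel rows in patient table")
    return df


def table4_summaries(
    model: str, df: pd.DataFrame = None, threshold: float = 2.5
) -> List[TerritorySummary]:
    """Territory summaries for one model from the patient table."""
    if model not in ("dp", "fermi"):
        raise ValueError(f"model must be 'dp' or 'fermi', got {model!r}")
    if df is None:
        df = load_table4()
    out = []
    for _, row in df.iterrows():
        mean = float(row[f"{model}_mbf_stress"])
        sd_col = f"{model}_sd_stress"
        out.append(
            TerritorySummary(
                territory=str(row["vessel"]),
                subject=str(row["patient"]),
                mean_mbf_stress=mean,
                sd_mbf_stress=float(row[sd_col]) if sd_col in df.columns else 0.0,
                mpr_mean=float(row[f"{model}_mpr"]) if f"{model}_mpr" in df.columns else None,
                group=int(row["group"]),
                reduced_flow=classify_reduced_flow(mean, threshold),
            )
        )
    return out


def load_acquisition_params(path: Union[str, Path]) -> AcquisitionParams:
    """Acquisition parameters from a YAML/JSON config with matching keys."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of acquisition parameters")
    allowed = set(AcquisitionParams.__dataclass_fields__)
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown key(s) {sorted(unknown)}")
    return AcquisitionParams(**data)
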