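"""Reading and writing the package's tabular text formats.

Curves travel as long-format CSV with one row per reading:

    sample_id, target, time_min, fluorescence
    [, dilution_factor, replicate, S_a_bp, c_p0_uM, temperature, condition]

Fit results, standard curves and experiment manifests are JSON.  Time is
minutes, concentrations uM, copies per ul throughout; decimal point is
".", encoding UTF-8.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import pandas as pd

from .curve_fit import AmplificationCurve, FitResult
from .quantification import StandardCurve

__all__ = [
    "read_curves",
    "write_curves",
    "write_fit_result",
    "read_standard_curve",
    "write_standard_curve",
    "write_manifest",
]

REQUIRED_COLUMNS = ["sample_id", "target", "time_min", "fluorescence"]
OPTIONAL_COLUMNS = {
    "dilution_factor": 1.0,
    "replicate": 0,
    "S_a_bp": 145.0,
    "c_p0_uM": 1.6,
    "temperature": "",
    "condition": "",
}

PathLike = Union[str, Path]


def read_curves(path: PathLike) -> List[AmplificationCurve]:
    """Load curves from long-format CSV, grouped by ``sample_id``.

    Row order within the file is irrelevant (grouping is key-based;
    readings are sorted by time within each sample).  Missing required
    columns, non-finite fluorescence, non-monotone or non-uniform time
    grids raise descriptive errors naming the offending row or sample.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = df.index[~np.isfinite(df["fluorescence"].astype(float))]
    if len(bad):
        raise ValueError(f"{path}: non-finite fluorescence at row {int(bad[0])}")
    for col, default in OPTIONAL_COLUMNS.items():
        if col not in df.columns:
            df[col] = default

    curves = []
    for sample_id, g in df.groupby("sample_id", sort=True):
        g = g.sort_values("time_min")
        times = g["time_min"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"{path}: duplicate or non-increasing times in sample {sample_id!r}")
        if np.ptp(np.diff(times)) > 1e-9:
            raise ValueError(f"{path}: mixed time grids within sample {sample_id!r}")
        curves.append(
            AmplificationCurve(
                times=times,
                fluorescence=g["fluorescence"].to_numpy(dtype=float),
                sample_id=str(sample_id),
                target=str(g["target"].iloc[0]),
                S_a=float(g["S_a_bp"].iloc[0]),
                c_p0=float(g["c_p0_uM"].iloc[0]),
                dilution_factor=float(g["dilution_factor"].iloc[0]),
                replicate=int(g["replicate"].iloc[0]),
                temperature=str(g["temperature"].iloc[0]),
                condition=str(g["condition"].iloc[0]),
            )
        )
    return curves


def write_curves(curves: Sequence[AmplificationCurve], path: PathLike) -> None:
    """Write curves in the CSV dialect :func:`read_curves` accepts."""
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": c.sample_id,
                    "target": c.target,
                    "time_min": c.times,
                    "fluorescence": c.fluorescence,
                    "dilution_factor": c.dilution_factor,
                    "replicate": c.replicate,
                    "S_a_bp": c.S_a,
                    "c_p0_uM": c.c_p0,
                    "temperature": c.temperature,
                    "condition": c.condition,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_fit_result(result: FitResult, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(result.to_dict(), fh, indent=2)


def write_standard_curve(curve: StandardCurve, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(curve.to_dict(), fh, indent=2)


def read_standard_curve(path: PathLike) -> StandardCurve:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    return StandardCurve(
        x=np.asarray(d["x"], dtype=float),
        y=np.asarray(d["y"], dtype=float),
        slope=float(d["slope_min_per_ln"]),
        intercept=float(d["intercept_min"]),
        r_squared=float(d["r_squared"]),
        T=float(d["T_min"]),
        excluded=list(d.get("excluded", [])),
    )


def write_manifest(manifest: dict, path: PathLike) -> None:
    """Write a provenance/truth record (generator or run parameters)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
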