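"""CSV and JSON plumbing shared by the command-line workflows.

Growth-curve measurements travel as long-format CSV with columns
``condition_id, e_in_uE_per_s, c0, time_h, od730``; attenuation
measurements as ``depth_cm, conc_cell_per_ml, rel_ppfd``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .core_model import CultureCondition, CultureGeometry, DEFAULT_GEOMETRY, ModelParams, cells_from_od
from .estimation import AttenuationMeasurement, CVReport, FitResult, MeasurementSeries

__all__ = [
    "write_measurements_csv",
    "read_measurements_csv",
    "write_attenuation_csv",
    "read_attenuation_csv",
    "params_to_dict",
    "fit_result_to_dict",
    "cv_report_to_dict",
    "write_json",
]

MEASUREMENT_COLUMNS = ["condition_id", "e_in_uE_per_s", "c0", "time_h", "od730"]
ATTENUATION_COLUMNS = ["depth_cm", "conc_cell_per_ml", "rel_ppfd"]


def write_measurements_csv(series: Sequence[MeasurementSeries], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "condition_id": s.label,
                "e_in_uE_per_s": s.condition.e_in,
                "c0": s.condition.c0,
                "time_h": s.times,
                "od730": s.od,
            }
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_measurements_csv(
    path,
    geometry: CultureGeometry = DEFAULT_GEOMETRY,
    default_od0: float = 0.025,
) -> list[MeasurementSeries]:
    """Read a long-format measurement table back into series.

    The initial biomass of each condition is taken from its t = 0
    observation when present, otherwise from ``default_od0``.
    """
    df = pd.read_csv(path, comment="#")
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement CSV is missing columns: {sorted(missing)}")
    out: list[MeasurementSeries] = []
    for label, grp in df.groupby("condition_id", sort=False):
        grp = grp.sort_values("time_h")
        times = grp["time_h"].to_numpy(dtype=float)
        od = grp["od730"].to_numpy(dtype=float)
        od0 = float(od[0]) if times.size and times[0] == 0 else default_od0
        cond = CultureCondition(
            e_in=float(grp["e_in_uE_per_s"].iloc[0]),
            c0=float(grp["c0"].iloc[0]),
            n0=float(cells_from_od(od0, geometry)),
            geometry=geometry,
        )
        out.append(MeasurementSeries(condition=cond, times=times, od=od, label=str(label)))
    return out


def write_attenuation_csv(measurements: Sequence[AttenuationMeasurement], path) -> None:
    pd.DataFrame([asdict(m) for m in measurements])[ATTENUATION_COLUMNS].to_csv(path, index=False)


def read_attenuation_csv(path) -> list[AttenuationMeasurement]:
    df = pd.read_csv(path, comment="#")
    missing = set(ATTENUATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"attenuation CSV is missing columns: {sorted(missing)}")
    return [
        AttenuationMeasurement(
            depth_cm=float(r.depth_cm),
            conc_cell_per_ml=float(r.conc_cell_per_ml),
            rel_ppfd=float(r.rel_ppfd),
        )
        for r in df.itertuples()
    ]


def params_to_dict(params: ModelParams) -> dict:
    return {
        "mu_per_h": params.mu,
        "lambda_l_uE_per_h_per_cell": params.lambda_l,
        "gamma_cap_cell": params.gamma_cap,
        "xi_c": params.xi_c,
        "alpha_per_cell": params.alpha,
        "k_ext_ml_per_cm_per_cell": params.k_ext,
    }


def _json_safe(value):
    if isinstance(value, float) and math.isinf(value):
        return None
    if isinstance(value, np.ndarray):
        return value.tolist()
    return value


def fit_result_to_dict(result: FitResult) -> dict:
    return {
        "estimates": params_to_dict(result.estimates),
        "residual_norm": result.residual_norm,
        "n_observations": result.n_observations,
        "converged": result.converged,
        "fitted_windows": {k: _json_safe(v) for k, v in result.fitted_windows.items()},
        "diagnostics": {
            k: _json_safe(v) for k, v in result.diagnostics.items()
        },
    }


def cv_report_to_dict(report: CVReport) -> dict:
    return {
        "aggregate_rmse_od": report.aggregate_rmse,
        "folds": [
            {
                "label": f.label,
                "rmse_od": f.rmse,
                "n_points": int(f.times.size),
                "fitted": params_to_dict(f.fitted),
                "terminal_od_predicted": f.terminal_od_predicted,
            }
            for f in report.folds
        ],
    }


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)
        fh.write("\n")
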