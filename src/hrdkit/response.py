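"""Tumour-volume response metrics for PDX treatment experiments.

Volumes are computed from caliper diameters as V = a*b^2/2 (a the largest
diameter).  Per mouse, the percent volume change dVol_t = 100*(V_t-V0)/V0
is tracked over measured days; BestResponse is the minimum dVol for
t >= 14 d and BestAvgResponse the minimum over t >= 14 d of the running
mean of dVol from day 0 to t.  Per model, medians of the two metrics over
evaluable mice are classified, in order, as

    CR: BestResponse < -95 and BestAvgResponse < -40
    PR: BestResponse < -50 and BestAvgResponse < -20
    SD: BestResponse <  35 and BestAvgResponse <  30
    PD: otherwise

with all inequalities strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

CATEGORIES = ("CR", "PR", "SD", "PD")
MIN_EVAL_DAY = 14.0


class NotEvaluable(ValueError):
    """Mouse has no measurement at day >= 14."""


def tumour_volume(a: float, b: float) -> float:
    """V = a*b^2/2, ``a`` the largest and ``b`` the smallest diameter (mm)."""
    if b > a:
        raise ValueError(f"diameters swapped: largest a={a} < smallest b={b}")
    if b <= 0:
        raise ValueError("diameters must be positive")
    return a * b * b / 2.0


@dataclass
class VolumeSeries:
    mouse_id: str
    days: np.ndarray  # ascending, unique, days[0] == 0
    volumes: np.ndarray  # mm^3, > 0

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)

    @property
    def v0(self) -> float:
        return float(self.volumes[0])

    @property
    def delta_vol(self) -> np.ndarray:
        return 100.0 * (self.volumes - self.v0) / self.v0

    @property
    def rtv(self) -> np.ndarray:
        return self.volumes / self.v0


@dataclass
class MouseResponse:
    mouse_id: str
    best_response: float | None
    best_avg_response: float | None
    evaluable: bool


@dataclass
class ModelResponse:
    pdx_id: str
    median_best_response: float
    median_best_avg_response: float
    category: str
    n_mice: int
    n_excluded: int = 0


def delta_vol_series(measurements: pd.DataFrame, mouse_id: str | None = None) -> VolumeSeries:
    """Build a VolumeSeries from one mouse's measurement rows.

    ``measurements`` needs columns day plus either volume_mm3 or a_mm/b_mm.
    A day-0 measurement must be present; duplicate days are an error.
    """
    df = measurements.copy()
    if mouse_id is None:
        mouse_id = str(df["mouse"].iloc[0]) if "mouse" in df.columns else "?"
    if "volume_mm3" in df.columns and df["volume_mm3"].notna().all():
        vols = df["volume_mm3"].to_numpy(dtype=float)
    else:
        vols = np.array(
            [tumour_volume(float(r.a_mm), float(r.b_mm)) for r in df.itertuples(index=False)]
        )
    days = df["day"].to_numpy(dtype=float)
    order = np.argsort(days)
    days, vols = days[order], vols[order]
    if len(np.unique(days)) != len(days):
        raise ValueError(f"mouse {mouse_id}: duplicate measurement days")
    if days[0] != 0:
        raise ValueError(f"mouse {mouse_id}: missing day-0 measurement")
    if (vols <= 0).any():
        raise ValueError(f"mouse {mouse_id}: volumes must be positive")
    return VolumeSeries(mouse_id, days, vols)


def best_response(series: VolumeSeries) -> float:
    """Minimum dVol over measured timepoints at day >= 14."""
    mask = series.days >= MIN_EVAL_DAY
    if not mask.any():
        raise NotEvaluable(f"mouse {series.mouse_id}: no measurement at day >= 14")
    return float(series.delta_vol[mask].min())


def best_avg_response(series: VolumeSeries, include_t0: bool = True) -> float:
    """Minimum over t >= 14 d of the running mean of dVol from day 0 to t.

    The day-0 value (0 by definition) is included in the mean by default;
    ``include_t0=False`` drops it (sensitivity analysis).
    """
    dv = series.delta_vol
    mask = series.days >= MIN_EVAL_DAY
    if not mask.any():
        raise NotEvaluable(f"mouse {series.mouse_id}: no measurement at day >= 14")
    start = 0 if include_t0 else 1
    means = [
        float(np.mean(dv[start : i + 1]))
        for i in range(len(dv))
        if series.days[i] >= MIN_EVAL_DAY
    ]
    return min(means)


def classify_response(best: float, best_avg: float) -> str:
    """Ordered CR -> PR -> SD rules (strict inequalities); PD otherwise."""
    if best < -95 and best_avg < -40:
        return "CR"
    if best < -50 and best_avg < -20:
        return "PR"
    if best < 35 and best_avg < 30:
        return "SD"
    return "PD"


def mouse_response(series: VolumeSeries, include_t0: bool = True) -> MouseResponse:
    try:
        br = best_response(series)
        bar = best_avg_response(series, include_t0=include_t0)
    except NotEvaluable:
        return MouseResponse(series.mouse_id, None, None, evaluable=False)
    return MouseResponse(series.mouse_id, br, bar, evaluable=True)


def aggregate_model(pdx_id: str, responses: list[MouseResponse]) -> ModelResponse:
    """Median of best/best-average response over evaluable mice, then classify.

    Even mouse counts use the mean-of-middle-two median convention
    (numpy default).  Non-evaluable mice are excluded and counted.
    """
    evaluable = [r for r in responses if r.evaluable]
    if not evaluable:
        raise NotEvaluable(f"PDX {pdx_id}: no evaluable mice")
    med_best = float(np.median([r.best_response for r in evaluable]))
    med_avg = float(np.median([r.best_avg_response for r in evaluable]))
    return ModelResponse(
        pdx_id=pdx_id,
        median_best_response=med_best,
        median_best_avg_response=med_avg,
        category=classify_response(med_best, med_avg),
        n_mice=len(evaluable),
        n_excluded=len(responses) - len(evaluable),
    )


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Measurement TSV: pdx, mouse, day, a_mm, b_mm (or volume_mm3)."""
    return pd.read_csv(path, sep="\t")


def cohort_responses(
    measurements: pd.DataFrame, include_t0: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-mouse and per-model response tables for a measurement cohort."""
    mouse_rows = []
    model_rows = []
    for pdx, pdx_grp in measurements.groupby("pdx", sort=False):
        responses = []
        for mouse, grp in pdx_grp.groupby("mouse", sort=False):
            series = delta_vol_series(grp, mouse_id=str(mouse))
            resp = mouse_response(series, include_t0=include_t0)
            responses.append(resp)
            mouse_rows.append(
                (pdx, mouse, resp.best_response, resp.best_avg_response, resp.evaluable)
            )
        model = aggregate_model(str(pdx), responses)
        model_rows.append(
            (
                pdx,
                model.median_best_response,
                model.median_best_avg_response,
                model.category,
                model.n_mice,
                model.n_excluded,
            )
        )
    per_mouse = pd.DataFrame(
        mouse_rows, columns=["pdx", "mouse", "best_response", "best_avg_response", "evaluable"]
    )
    per_model = pd.DataFrame(
        model_rows,
        columns=[
            "pdx",
            "median_best_response",
            "median_best_avg_response",
            "category",
            "n_mice",
            "n_excluded",
        ],
    )
    return per_mouse, per_model
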