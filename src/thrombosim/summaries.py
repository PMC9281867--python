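"""Per-donor summary predictions extracted from simulated trajectories.

Each simulation is reduced to a panel of time-dependent summary statistics
covering depletion of the nine measured quantities (time to fall below a
threshold fraction of the initial level, and fraction consumed by the
horizon) and generation of the ten activated factors and complexes (peak
concentration and time of peak), plus the headline thrombin readouts: peak
free FIIa, time to peak, thrombin AUC, peak total thrombin activity
(FIIa + 1.2 mIIa) and TFPI consumption.  The membership of the depletion
and generation lists is configuration, not code.
"""

from __future__ import annotations

import math
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .simulate import SimulationError, Trajectory, simulate
from .units import panel_to_profile

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import CohortTable
    from .config import ModelConfig

__all__ = [
    "DEPLETION_FACTORS",
    "GENERATION_SPECIES",
    "column_name",
    "summarize",
    "cohort_summaries",
]

#: Measured quantities whose depletion is summarised (9 entries).
DEPLETION_FACTORS = ("FII", "FV", "FVII", "FVIII", "FIX", "FX", "TF", "TFPI", "AT")

#: Activated factors and complexes whose generation is summarised (10 entries).
GENERATION_SPECIES = (
    "FIIa",
    "mIIa",
    "FVIIa",
    "FIXa",
    "FXa",
    "FVIIIa",
    "FVa",
    "TF:VIIa",
    "IXa:VIIIa",
    "Xa:Va",
)


def column_name(species: str) -> str:
    """Species name made safe for CSV/DataFrame column use."""
    return species.replace(":", "_").replace("-", "_")


def _refined_peak(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Peak value and time with parabolic refinement around the grid maximum."""
    i = int(np.argmax(y))
    if y[i] <= 0:
        return 0.0, math.nan
    if i == 0 or i == len(y) - 1:
        return float(y[i]), float(t[i])
    # vertex of the parabola through the three points around the maximum
    t0, t1, t2 = t[i - 1], t[i], t[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (t0 - t1) * (t0 - t2) * (t1 - t2)
    a = (t2 * (y1 - y0) + t1 * (y0 - y2) + t0 * (y2 - y1)) / denom
    if a >= 0:  # flat or degenerate neighbourhood
        return float(y1), float(t1)
    b = (t2**2 * (y0 - y1) + t1**2 * (y2 - y0) + t0**2 * (y1 - y2)) / denom
    tv = -b / (2 * a)
    c = y1 - a * t1**2 - b * t1
    yv = a * tv**2 + b * tv + c
    if not (t0 <= tv <= t2):
        return float(y1), float(t1)
    return float(max(yv, y1)), float(tv)


def _first_crossing(t: np.ndarray, y: np.ndarray, level: float) -> float:
    """Linear-interpolated time of the first downward crossing of *level*."""
    below = y < level
    if not below.any():
        return math.nan
    i = int(np.argmax(below))
    if i == 0:
        return float(t[0])
    frac = (y[i - 1] - level) / (y[i - 1] - y[i])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def summarize(
    trajectory: Trajectory,
    theta: float = 0.10,
    depletion: Sequence[str] = DEPLETION_FACTORS,
    generation: Sequence[str] = GENERATION_SPECIES,
    meizothrombin_weight: float = 1.2,
) -> dict[str, float]:
    """Reduce one trajectory to its scalar summary panel.

    theta is the depletion threshold: a factor counts as depleted when its
    free concentration first falls below theta times its initial value.
    """
    if trajectory.time.size < 2:
        raise ValueError("trajectory too short to summarise")
    t = trajectory.time
    out: dict[str, float] = {}

    iia = trajectory["FIIa"]
    out["peak_FIIa"], out["time_to_peak_FIIa"] = _refined_peak(t, iia)
    out["thrombin_AUC"] = float(np.trapezoid(iia, t))
    total = trajectory.total_thrombin(meizothrombin_weight)
    out["peak_total_thrombin"], out["time_to_peak_total_thrombin"] = _refined_peak(t, total)

    for f in depletion:
        y = trajectory[f]
        init, final = float(y[0]), float(y[-1])
        col = column_name(f)
        if init <= 0:
            out[f"depletion_time_{col}"] = math.nan
            out[f"frac_consumed_{col}"] = 0.0
        else:
            out[f"depletion_time_{col}"] = _first_crossing(t, y, theta * init)
            out[f"frac_consumed_{col}"] = float(np.clip((init - final) / init, 0.0, 1.0))

    for s in generation:
        col = column_name(s)
        out[f"peak_{col}"], out[f"peak_time_{col}"] = _refined_peak(t, trajectory[s])

    tfpi = trajectory["TFPI"]
    out["TFPI_consumed"] = float(max(tfpi[0] - tfpi[-1], 0.0))
    return out


def cohort_summaries(cohort: "CohortTable", model: "ModelConfig") -> pd.DataFrame:
    """One summary panel per donor, indexed by donor_id.

    A failed integration is recorded in the ``error`` column for that donor
    without aborting the batch.
    """
    rows = {}
    for panel in cohort:
        try:
            traj = simulate(
                panel_to_profile(panel, model.reference),
                model.scheme,
                model.rates,
                model.sim,
            )
            row = summarize(traj, theta=model.theta)
            row["error"] = ""
        except SimulationError as exc:
            row = {"error": str(exc)}
        rows[panel.donor_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "donor_id"
    return df
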