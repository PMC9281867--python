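"""Key-driver identification by substitution between typical donors.

A "typical" donor of a cohort subset is the panel of arithmetic means of
the measured levels (averaged in assay units, as measured).  Two analyses
quantify which factors drive the case-control gap in thrombin generation:

* one-at-a-time (OAT) contributions — each factor of the typical case is
  individually replaced by the typical-control value and the change in peak
  thrombin and time-to-peak recorded;
* sequential adjustment — factors are replaced cumulatively in a given
  order (e.g. the largest-contribution order), tracking the summary panel
  after each step until, with all nine factors substituted, the typical
  control is recovered exactly.

Because the cascade is nonlinear, OAT contributions need not sum to the
total gap; they are read as directions and rankings, not as a decomposition.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Sequence

import pandas as pd

from .scheme import MEASURED_FACTORS
from .simulate import simulate
from .summaries import summarize
from .units import FactorPanel, panel_to_profile

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import CohortTable
    from .config import ModelConfig

__all__ = [
    "DEFAULT_MALE_ORDER",
    "DEFAULT_FEMALE_ORDER",
    "typical_profile",
    "oat_contributions",
    "rank_factors",
    "sequential_adjustment",
]

#: Default adjustment orders for typical male and female case donors.
DEFAULT_MALE_ORDER = ("FVIII", "TF", "TFPI", "FIX")
DEFAULT_FEMALE_ORDER = ("FII", "FIX", "FVIII")


def typical_profile(
    cohort: "CohortTable", group: str, sex: str | None = None
) -> FactorPanel:
    """Mean factor panel of a cohort subset (by group, optionally by sex)."""
    subset = cohort.subset(group=group, sex=sex)
    if len(subset) == 0:
        raise ValueError(f"no donors with group={group!r}, sex={sex!r}")
    levels = {
        f: float(subset.levels(f).mean()) for f in MEASURED_FACTORS
    }
    return FactorPanel(
        donor_id=f"typical_{group}" + (f"_{sex}" if sex else ""),
        group=group,
        sex=sex or "male",
        levels=levels,
    )


def _summarize_panel(panel: FactorPanel, model: "ModelConfig") -> dict[str, float]:
    traj = simulate(
        panel_to_profile(panel, model.reference), model.scheme, model.rates, model.sim
    )
    return summarize(traj, theta=model.theta)


def oat_contributions(
    case_typical: FactorPanel,
    control_typical: FactorPanel,
    model: "ModelConfig",
) -> pd.DataFrame:
    """One-at-a-time contribution of each factor to the case-control gap.

    For each measured factor, the typical case is re-simulated with that
    single factor set to the typical-control level; the contribution is the
    resulting change in peak thrombin and time-to-peak (absolute and as a
    percent of the unadjusted case values).
    """
    base = _summarize_panel(case_typical, model)
    peak0, t0 = base["peak_FIIa"], base["time_to_peak_FIIa"]
    rows = []
    for f in MEASURED_FACTORS:
        adj = _summarize_panel(
            case_typical.replace_levels(**{f: control_typical[f]}), model
        )
        d_peak = adj["peak_FIIa"] - peak0
        d_t = adj["time_to_peak_FIIa"] - t0
        rows.append(
            dict(
                factor=f,
                delta_peak_M=d_peak,
                delta_peak_pct=100.0 * d_peak / peak0 if peak0 else float("nan"),
                delta_time_to_peak_s=d_t,
                delta_time_to_peak_pct=100.0 * d_t / t0 if t0 else float("nan"),
            )
        )
    return pd.DataFrame(rows)


def rank_factors(contributions: pd.DataFrame) -> list[str]:
    """Automatic adjustment order: descending |delta peak|, ties by
    |delta time-to-peak| then factor name."""
    df = contributions.assign(
        _p=contributions["delta_peak_M"].abs(),
        _t=contributions["delta_time_to_peak_s"].abs(),
    )
    df = df.sort_values(["_p", "_t", "factor"], ascending=[False, False, True],
                        kind="mergesort")
    return list(df["factor"])


def sequential_adjustment(
    case_typical: FactorPanel,
    control_typical: FactorPanel,
    order: Sequence[str],
    model: "ModelConfig",
) -> list[tuple[FactorPanel, dict[str, float]]]:
    """Cumulatively replace factors of the typical case with control means.

    Step 0 is the unadjusted case; step k has the first k factors of
    ``order`` at their control values.  Returns (panel, summary) per step.
    """
    order = list(order)
    unknown = [f for f in order if f not in MEASURED_FACTORS]
    if unknown:
        raise ValueError(f"unknown factor(s) in order: {unknown}")
    if len(set(order)) != len(order):
        raise ValueError("duplicate factor in adjustment order")
    steps = []
    panel = case_typical
    steps.append((panel, _summarize_panel(panel, model)))
    for f in order:
        panel = panel.replace_levels(**{f: control_typical[f]})
        steps.append((panel, _summarize_panel(panel, model)))
    return steps
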