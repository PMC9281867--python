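"""Anticoagulant models: vitamin-K antagonism and direct reversible inhibitors.

Three drug classes are modelled.  A vitamin-K antagonist (warfarin) acts at
equilibrium by scaling the vitamin-K-dependent zymogens (FII, FVII/FVIIa,
FIX, FX) to a fraction of their measured level — no pharmacokinetics.  The
direct FXa inhibitor (rivaroxaban-like) and direct thrombin inhibitor
(dabigatran-like) are added to the reaction network as a new species D with
reversible 1:1 binding to the free target, target + D <-> target:D; dose,
on-rate and off-rate come from the parameter file and the drug itself is a
conserved lineage.  Optionally (off by default) the inhibitor also binds
the complex-bound target: prothrombinase-bound FXa, or meizothrombin for
the thrombin inhibitor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import numpy as np

from .scheme import (
    DonorConcentrationProfile,
    RateConstantSet,
    Reaction,
    ReactionScheme,
    SchemeError,
)
from .simulate import simulate, simulate_state
from .summaries import summarize
from .units import FactorPanel, panel_to_profile

if TYPE_CHECKING:  # pragma: no cover
    from .config import ModelConfig

__all__ = [
    "DrugSpec",
    "DrugEffect",
    "VITAMIN_K_FACTORS",
    "apply_vka",
    "extend_scheme_with_inhibitor",
    "drug_effect",
    "cohort_drug_effects",
]

VITAMIN_K_FACTORS = ("FII", "FVII", "FVIIa", "FIX", "FX")

DRUG_KINDS = ("vitamin_k_antagonist", "xa_inhibitor", "iia_inhibitor")

_TARGETS = {
    "xa_inhibitor": {"free": "FXa", "complexed": "Xa:Va", "lineage": {"X": 1, "V": 1}},
    "iia_inhibitor": {"free": "FIIa", "complexed": "mIIa", "lineage": {"II": 1}},
}


@dataclass(frozen=True)
class DrugSpec:
    """One anticoagulant: kind, dose/fraction and binding kinetics."""

    name: str
    kind: str
    dose: float = 0.0  # M, direct inhibitors
    fraction: float = 1.0  # VKA scaling of vitamin-K-dependent factors
    kon: float = 1.0e8  # M^-1 s^-1
    koff: float = 1.0e-2  # s^-1
    bind_complexed: bool = False

    def __post_init__(self) -> None:
        if self.kind not in DRUG_KINDS:
            raise SchemeError(f"unknown drug kind {self.kind!r}")
        if self.dose < 0:
            raise SchemeError("dose must be nonnegative")
        if not 0.0 < self.fraction <= 1.0:
            raise SchemeError("VKA fraction must lie in (0, 1]")
        if self.kon <= 0 or self.koff <= 0:
            raise SchemeError("binding rates must be positive")

    def with_dose(self, dose: float) -> "DrugSpec":
        return replace(self, dose=dose)


@dataclass(frozen=True)
class DrugEffect:
    """Per-donor effect of one drug on thrombin generation."""

    drug: str
    pct_peak_reduction: float
    pct_time_to_peak_change: float
    drugged_peak_M: float
    drugged_time_to_peak_s: float
    baseline_peak_M: float
    baseline_time_to_peak_s: float
    dose: float
    defined: bool = True


def apply_vka(
    profile: DonorConcentrationProfile, fraction: float
) -> DonorConcentrationProfile:
    """Scale the vitamin-K-dependent factors; everything else untouched."""
    if not 0.0 < fraction <= 1.0:
        raise SchemeError("VKA fraction must lie in (0, 1]")
    updates = {
        f: profile[f] * fraction
        for f in VITAMIN_K_FACTORS
        if f in profile.concentrations
    }
    return profile.replace(**updates)


def extend_scheme_with_inhibitor(
    scheme: ReactionScheme, rates: RateConstantSet, spec: DrugSpec
) -> tuple[ReactionScheme, RateConstantSet, dict[str, float]]:
    """Add a direct reversible inhibitor to the network.

    Returns the extended scheme and rates plus the extra initial
    concentrations (the drug at its dose).  The drug is tracked as its own
    conserved lineage, so the standard conservation audit covers it.
    """
    if spec.kind not in _TARGETS:
        raise SchemeError(f"{spec.kind!r} is not a direct inhibitor")
    target = _TARGETS[spec.kind]
    drug = spec.name
    if drug in scheme.index:
        raise SchemeError(f"species {drug!r} already present in scheme")
    kon_id, koff_id = f"k_{drug}_on", f"k_{drug}_off"
    new_species = [drug]
    new_lineages: dict[str, dict[str, float]] = {drug: {drug: 1}}
    new_reactions: list[Reaction] = []

    def bind(tgt: str) -> None:
        complex_name = f"{tgt}:{drug}"
        new_species.append(complex_name)
        new_lineages[complex_name] = {**scheme.lineages[tgt], drug: 1}
        new_reactions.append(
            Reaction(reactants=(tgt, drug), products=(complex_name,), k=kon_id, kind="binding")
        )
        new_reactions.append(
            Reaction(reactants=(complex_name,), products=(tgt, drug), k=koff_id, kind="dissociation")
        )

    bind(target["free"])
    if spec.bind_complexed:
        bind(target["complexed"])

    ext = scheme.with_additions(
        new_species, new_lineages, new_reactions, name=f"{scheme.name}+{drug}"
    )
    ext_rates = RateConstantSet(
        {**rates.values, kon_id: spec.kon, koff_id: spec.koff},
        {**rates.units, kon_id: "M^-1 s^-1", koff_id: "s^-1"},
    )
    return ext, ext_rates, {drug: spec.dose}


def drug_effect(
    panel: FactorPanel, spec: DrugSpec, model: "ModelConfig"
) -> DrugEffect:
    """Simulate a donor with and without one anticoagulant.

    Peak reduction and time-to-peak change are percentages of the undrugged
    values; a donor with zero undrugged peak thrombin is flagged undefined.
    """
    profile = panel_to_profile(panel, model.reference)
    base = summarize(
        simulate(profile, model.scheme, model.rates, model.sim), theta=model.theta
    )
    peak0, t0 = base["peak_FIIa"], base["time_to_peak_FIIa"]

    if spec.kind == "vitamin_k_antagonist":
        drugged_traj = simulate(
            apply_vka(profile, spec.fraction), model.scheme, model.rates, model.sim
        )
    else:
        ext, ext_rates, extra = extend_scheme_with_inhibitor(
            model.scheme, model.rates, spec
        )
        drugged_traj = simulate_state(
            {**profile.concentrations, **extra}, ext, ext_rates, model.sim
        )
    drugged = summarize(drugged_traj, theta=model.theta)
    peak_d, t_d = drugged["peak_FIIa"], drugged["time_to_peak_FIIa"]

    if peak0 <= 0 or not np.isfinite(t0) or t0 <= 0:
        return DrugEffect(
            drug=spec.name, pct_peak_reduction=np.nan, pct_time_to_peak_change=np.nan,
            drugged_peak_M=peak_d, drugged_time_to_peak_s=t_d,
            baseline_peak_M=peak0, baseline_time_to_peak_s=t0,
            dose=spec.dose if spec.kind != "vitamin_k_antagonist" else spec.fraction,
            defined=False,
        )
    return DrugEffect(
        drug=spec.name,
        pct_peak_reduction=100.0 * (peak0 - peak_d) / peak0,
        pct_time_to_peak_change=100.0 * (t_d - t0) / t0,
        drugged_peak_M=peak_d,
        drugged_time_to_peak_s=t_d,
        baseline_peak_M=peak0,
        baseline_time_to_peak_s=t0,
        dose=spec.dose if spec.kind != "vitamin_k_antagonist" else spec.fraction,
    )


def cohort_drug_effects(cohort, specs, model: "ModelConfig"):
    """Drug effects for every (donor, drug) pair as a tidy DataFrame."""
    import pandas as pd

    rows = []
    for panel in cohort:
        for spec in specs:
            eff = drug_effect(panel, spec, model)
            rows.append({"donor_id": panel.donor_id, "drug": spec.name, **eff.__dict__})
    return pd.DataFrame(rows)
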