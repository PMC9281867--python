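"""Assay-unit factor panels and their conversion to molar initial conditions.

Clotting-factor activities are reported as a percent of a reference plasma
(FII, FV, FVII, FVIII, FIX, FX, AT), TF as an activity in pM and TFPI as
U/mL.  Conversion to molar model inputs is linear through a reference
concentration table: ``level/100 * reference`` for the percent factors, pM
-> M for TF, and ``U/mL * reference`` for TFPI (1 U/mL being the reference
TFPI concentration).  Trace circulating FVIIa is set to a configurable
fraction of the donor's FVII.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .scheme import MEASURED_FACTORS, DonorConcentrationProfile, load_parameters

__all__ = [
    "FactorPanel",
    "ReferenceConcentrationTable",
    "panel_to_profile",
    "profile_to_panel",
    "PanelError",
]

PERCENT_FACTORS = ("FII", "FV", "FVII", "FVIII", "FIX", "FX", "AT")

GROUPS = ("case", "control")
SEXES = ("male", "female")
GENOTYPES = ("GG", "GA", "AA", "unknown")


class PanelError(ValueError):
    """Raised on an invalid factor panel or reference table."""


@dataclass
class FactorPanel:
    """One donor's measured coagulation-factor levels plus metadata.

    Percent-denominated levels are relative to the reference plasma; TF is
    an activity in pM, TFPI in U/mL.
    """

    donor_id: str
    group: str
    sex: str
    levels: dict[str, float]
    genotype_20210: str = "unknown"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise PanelError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in SEXES:
            raise PanelError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.genotype_20210 not in GENOTYPES:
            raise PanelError(f"unknown genotype {self.genotype_20210!r}")
        missing = [f for f in MEASURED_FACTORS if f not in self.levels]
        if missing:
            raise PanelError(f"panel {self.donor_id}: missing factor(s) {missing}")
        for f in MEASURED_FACTORS:
            v = self.levels[f]
            if not np.isfinite(v) or v < 0:
                raise PanelError(f"panel {self.donor_id}: invalid level {f}={v}")
        for f in PERCENT_FACTORS:
            if self.levels[f] >= 500:
                raise PanelError(
                    f"panel {self.donor_id}: {f}={self.levels[f]}% is implausible"
                )

    def __getitem__(self, factor: str) -> float:
        return self.levels[factor]

    def replace_levels(self, **updates: float) -> "FactorPanel":
        return FactorPanel(
            donor_id=self.donor_id,
            group=self.group,
            sex=self.sex,
            genotype_20210=self.genotype_20210,
            levels={**self.levels, **updates},
        )


@dataclass
class ReferenceConcentrationTable:
    """Molar concentration corresponding to 100 % (1 U/mL for TFPI)."""

    concentrations: dict[str, float]
    fviia_fraction: float = 0.01

    def __post_init__(self) -> None:
        needed = set(PERCENT_FACTORS) | {"TFPI"}
        missing = sorted(needed - set(self.concentrations))
        if missing:
            raise PanelError(f"reference table missing factor(s) {missing}")
        for f, c in self.concentrations.items():
            if not np.isfinite(c) or c <= 0:
                raise PanelError(f"reference concentration for {f} must be > 0, got {c}")
        if not 0.0 <= self.fviia_fraction < 1.0:
            raise PanelError("fviia_fraction must be in [0, 1)")

    def __getitem__(self, factor: str) -> float:
        return self.concentrations[factor]

    @classmethod
    def from_parameters(cls, path=None) -> "ReferenceConcentrationTable":
        raw = load_parameters(path)
        return cls(
            {k: float(v) for k, v in raw["reference_concentrations"].items()},
            fviia_fraction=float(raw.get("fviia_fraction", 0.01)),
        )


def panel_to_profile(
    panel: FactorPanel, ref: ReferenceConcentrationTable
) -> DonorConcentrationProfile:
    """Convert an assay-unit panel to molar initial conditions."""
    conc: dict[str, float] = {}
    for f in PERCENT_FACTORS:
        conc[f] = panel[f] / 100.0 * ref[f]
    conc["TF"] = panel["TF"] * 1e-12
    conc["TFPI"] = panel["TFPI"] * ref["TFPI"]
    conc["FVIIa"] = ref.fviia_fraction * conc["FVII"]
    return DonorConcentrationProfile(conc)


def profile_to_panel(
    profile: DonorConcentrationProfile,
    ref: ReferenceConcentrationTable,
    donor_id: str = "profile",
    group: str = "control",
    sex: str = "male",
) -> FactorPanel:
    """Exact inverse of :func:`panel_to_profile` on the measured subspace."""
    levels = {f: profile[f] / ref[f] * 100.0 for f in PERCENT_FACTORS}
    levels["TF"] = profile["TF"] / 1e-12
    levels["TFPI"] = profile["TFPI"] / ref["TFPI"]
    return FactorPanel(donor_id=donor_id, group=group, sex=sex, levels=levels)
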