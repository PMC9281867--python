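"""Bundled model configuration: scheme, rates, reference data, solver settings.

A :class:`ModelConfig` is the single object the pipeline stages consume.
It is built from the packaged parameter file (optionally overridden) plus
an optional YAML run-configuration controlling horizon, tolerances, the
depletion threshold, the stratification key and drug definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .pharmaco import DrugSpec
from .scheme import (
    RateConstantSet,
    ReactionScheme,
    build_default_scheme,
    load_parameters,
)
from .simulate import SimulationConfig
from .units import ReferenceConcentrationTable

__all__ = ["ModelConfig", "load_drug_specs"]


def load_drug_specs(params: dict) -> dict[str, DrugSpec]:
    """Build the drug registry from a parameter dictionary's ``drugs`` block."""
    specs = {}
    for name, entry in (params.get("drugs") or {}).items():
        specs[name] = DrugSpec(
            name=name,
            kind=str(entry["kind"]),
            dose=float(entry.get("dose", 0.0)),
            fraction=float(entry.get("fraction", 1.0)),
            kon=float(entry.get("kon", 1.0e8)),
            koff=float(entry.get("koff", 1.0e-2)),
            bind_complexed=bool(entry.get("bind_complexed", False)),
        )
    return specs


@dataclass
class ModelConfig:
    """Everything needed to simulate and summarise one donor."""

    scheme: ReactionScheme
    rates: RateConstantSet
    reference: ReferenceConcentrationTable
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    theta: float = 0.10
    stratification_key: str = "peak_FIIa"
    drugs: dict[str, DrugSpec] = field(default_factory=dict)

    @classmethod
    def default(
        cls,
        params_path: str | Path | None = None,
        config_path: str | Path | None = None,
    ) -> "ModelConfig":
        """Load from the (packaged) parameter file and optional run config."""
        scheme, rates = build_default_scheme(params_path)
        params = load_parameters(params_path)
        model = cls(
            scheme=scheme,
            rates=rates,
            reference=ReferenceConcentrationTable.from_parameters(params_path),
            drugs=load_drug_specs(params),
        )
        if config_path is not None:
            model = model.with_run_config(config_path)
        return model

    def with_run_config(self, config_path: str | Path) -> "ModelConfig":
        raw = yaml.safe_load(Path(config_path).read_text()) or {}
        sim = SimulationConfig(
            horizon_s=float(raw.get("horizon_s", self.sim.horizon_s)),
            grid_s=float(raw.get("grid_s", self.sim.grid_s)),
            rtol=float(raw.get("rtol", self.sim.rtol)),
            atol=float(raw.get("atol", self.sim.atol)),
            clip_tol=float(raw.get("clip_tol", self.sim.clip_tol)),
        )
        drugs = dict(self.drugs)
        drugs.update(load_drug_specs(raw))
        return replace(
            self,
            sim=sim,
            theta=float(raw.get("theta", self.theta)),
            stratification_key=str(raw.get("stratification_key", self.stratification_key)),
            drugs=drugs,
        )

    def with_sim(self, **kwargs) -> "ModelConfig":
        """Copy with some solver settings changed (e.g. tighter tolerances)."""
        return replace(self, sim=replace(self.sim, **kwargs))
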