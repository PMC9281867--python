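"""Seeded synthetic cohorts with case-control and sex structure.

The generator emulates the statistical shape of a premature-MI case-control
plasma study: ~162 cases / ~186 controls, ~86 % male, cases with elevated
TF, FVIII, FIX and FX and reduced TFPI, females with elevated FVIII (and,
among cases, FII and FIX), and a rare prothrombin-20210A variant raising
FII in carriers.  Per-factor levels are drawn independently from a
truncated-normal or lognormal family around a male-control baseline and
scaled by group/sex multipliers.  The multipliers are deliberately modest
synthetic effects expressing the reported directions, not estimates of any
cohort's true effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import CohortTable
from .scheme import MEASURED_FACTORS
from .units import FactorPanel

__all__ = ["FactorDistribution", "SyntheticCohortConfig", "default_config", "generate"]


@dataclass(frozen=True)
class FactorDistribution:
    """Baseline sampling distribution of one factor in male controls.

    mean/sd are in the factor's assay units (percent, pM or U/mL);
    family is ``normal`` (truncated at zero by redraw) or ``lognormal``
    (moment-matched to the requested mean and SD).
    """

    mean: float
    sd: float
    family: str = "normal"

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("factor mean must be positive")
        if self.sd < 0:
            raise ValueError("factor SD must be nonnegative")
        if self.family not in ("normal", "lognormal"):
            raise ValueError(f"unknown distribution family {self.family!r}")

    def sample(self, rng: np.random.Generator, n: int, multiplier: float) -> np.ndarray:
        m = self.mean * multiplier
        s = self.sd * multiplier
        if s == 0:
            return np.full(n, m)
        if self.family == "lognormal":
            sigma2 = np.log1p((s / m) ** 2)
            mu = np.log(m) - sigma2 / 2.0
            return rng.lognormal(mu, np.sqrt(sigma2), size=n)
        x = rng.normal(m, s, size=n)
        # truncate at zero by redraw so the mean is essentially unbiased
        for _ in range(100):
            bad = x <= 0
            if not bad.any():
                break
            x[bad] = rng.normal(m, s, size=int(bad.sum()))
        return np.clip(x, np.finfo(float).tiny, None)


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Full specification of a synthetic case-control cohort."""

    n_cases: int = 162
    n_controls: int = 186
    male_fraction_cases: float = 0.86
    male_fraction_controls: float = 0.87
    factors: dict[str, FactorDistribution] = field(default_factory=dict)
    case_multipliers: dict[str, float] = field(default_factory=dict)
    female_multipliers: dict[str, float] = field(default_factory=dict)
    female_case_multipliers: dict[str, float] = field(default_factory=dict)
    minor_allele_frequency: float = 0.02
    genotype_fii_multiplier: float = 1.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("group sizes must be positive")
        for frac in (self.male_fraction_cases, self.male_fraction_controls):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("male fraction must lie in [0, 1]")
        if not 0.0 <= self.minor_allele_frequency < 0.5:
            raise ValueError("minor-allele frequency must lie in [0, 0.5)")
        for name, mult in {
            **self.case_multipliers,
            **self.female_multipliers,
            **self.female_case_multipliers,
        }.items():
            if mult <= 0:
                raise ValueError(f"multiplier for {name} must be positive")
        missing = [f for f in MEASURED_FACTORS if f not in self.factors]
        if self.factors and missing:
            raise ValueError(f"factor distribution(s) missing: {missing}")

    def with_updates(self, **kwargs) -> "SyntheticCohortConfig":
        return replace(self, **kwargs)


def default_config() -> SyntheticCohortConfig:
    """Defaults matching the emulated study structure.

    Group sizes 162/186 with 86 %/87 % male (sex counts by floor, giving
    139/23 and 161/25 male/female); right-skewed TF and FVIII are
    lognormal, everything else truncated-normal; case effects up for TF,
    FVIII, FIX, FX and down for TFPI; female FVIII elevated in both groups,
    FII and FIX additionally elevated in female cases; 2 % minor-allele
    frequency (carriage just under 4 %) with a 1.25x FII effect.
    """
    return SyntheticCohortConfig(
        factors={
            "FII": FactorDistribution(100.0, 15.0),
            "FV": FactorDistribution(100.0, 20.0),
            "FVII": FactorDistribution(100.0, 25.0),
            "FVIII": FactorDistribution(100.0, 30.0, family="lognormal"),
            "FIX": FactorDistribution(100.0, 20.0),
            "FX": FactorDistribution(100.0, 20.0),
            "AT": FactorDistribution(100.0, 12.0),
            "TF": FactorDistribution(5.0, 2.0, family="lognormal"),
            "TFPI": FactorDistribution(1.0, 0.25),
        },
        case_multipliers={"TF": 1.25, "FVIII": 1.2, "FIX": 1.15, "FX": 1.1, "TFPI": 0.9},
        female_multipliers={"FVIII": 1.15},
        female_case_multipliers={"FII": 1.1, "FIX": 1.15},
    )


def _genotypes(rng: np.random.Generator, n: int, maf: float) -> list[str]:
    q = maf
    probs = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
    return list(rng.choice(["GG", "GA", "AA"], size=n, p=probs))


def generate(
    config: SyntheticCohortConfig | None = None, seed: int | None = None
) -> CohortTable:
    """Draw a reproducible synthetic cohort.

    The seed argument overrides ``config.seed``; identical (config, seed)
    yield bit-identical cohorts.
    """
    config = config or default_config()
    if not config.factors:
        config = replace(default_config(), **{
            k: getattr(config, k)
            for k in (
                "n_cases", "n_controls", "male_fraction_cases",
                "male_fraction_controls", "minor_allele_frequency",
                "genotype_fii_multiplier", "seed",
            )
        })
    rng = np.random.default_rng(config.seed if seed is None else seed)
    panels: list[FactorPanel] = []
    for group, n, male_frac, prefix in (
        ("case", config.n_cases, config.male_fraction_cases, "C"),
        ("control", config.n_controls, config.male_fraction_controls, "H"),
    ):
        n_male = int(n * male_frac)
        sexes = ["male"] * n_male + ["female"] * (n - n_male)
        genotypes = _genotypes(rng, n, config.minor_allele_frequency)
        draws: dict[str, np.ndarray] = {}
        for f in MEASURED_FACTORS:
            dist = config.factors[f]
            mult_case = config.case_multipliers.get(f, 1.0) if group == "case" else 1.0
            levels = dist.sample(rng, n, mult_case)
            fem = np.array([s == "female" for s in sexes])
            fmult = config.female_multipliers.get(f, 1.0)
            if group == "case":
                fmult *= config.female_case_multipliers.get(f, 1.0)
            if fmult != 1.0:
                levels[fem] *= fmult
            if f not in ("TF", "TFPI"):
                # panels cap percent levels below 500; the clip is a
                # negligible-mass tail event for the default spreads
                levels = np.minimum(levels, 499.0)
            draws[f] = levels
        carrier = np.array([g != "GG" for g in genotypes])
        draws["FII"] = draws["FII"] * np.where(
            carrier, config.genotype_fii_multiplier, 1.0
        )
        for i in range(n):
            panels.append(
                FactorPanel(
                    donor_id=f"{prefix}{i + 1:04d}",
                    group=group,
                    sex=sexes[i],
                    genotype_20210=genotypes[i],
                    levels={f: float(draws[f][i]) for f in MEASURED_FACTORS},
                )
            )
    return CohortTable(panels)
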