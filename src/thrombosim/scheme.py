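"""Coagulation reaction network: species, reactions, rate constants.

The tissue-factor (extrinsic) pathway is represented as a closed mass-action
reaction network over 34 species — zymogens (FII, FV, FVII, FVIII, FIX, FX),
their activated forms, the tenase (IXa:VIIIa) and prothrombinase (Xa:Va)
complexes, and the stoichiometric inhibitors TFPI and antithrombin.  The
network, its rate constants, the lineage bookkeeping used for conservation
audits and the reference plasma concentrations all ship in an editable YAML
parameter file; nothing kinetic is hard-coded.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Reaction",
    "ReactionScheme",
    "RateConstantSet",
    "DonorConcentrationProfile",
    "SchemeError",
    "build_default_scheme",
    "load_scheme",
    "default_parameter_path",
    "load_parameters",
    "derivative",
    "audit_conservation",
    "MEASURED_FACTORS",
    "LINEAGES",
]

#: The nine quantities measured per donor, in panel order.
MEASURED_FACTORS = ("FII", "FV", "FVII", "FVIII", "FIX", "FX", "AT", "TF", "TFPI")

#: Zymogen/inhibitor lineages tracked by the conservation audit.
LINEAGES = ("II", "V", "VII", "VIII", "IX", "X", "TF", "TFPI", "AT")

#: Species that may carry a non-zero initial concentration.
PROFILE_SPECIES = ("TF", "FII", "FV", "FVII", "FVIIa", "FVIII", "FIX", "FX", "TFPI", "AT")


class SchemeError(ValueError):
    """Raised when a parameter file or reaction scheme fails validation."""


@dataclass(frozen=True)
class Reaction:
    """A single mass-action reaction.

    ``reactants`` and ``products`` are species names with repetition
    expressing stoichiometry; ``kind`` is one of ``binding``,
    ``dissociation``, ``catalysis`` or ``inactivation``.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    k: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("binding", "dissociation", "catalysis", "inactivation"):
            raise SchemeError(f"unknown reaction kind {self.kind!r}")
        if not 1 <= len(self.reactants) <= 2:
            raise SchemeError("mass-action reactions take one or two reactants")


@dataclass
class RateConstantSet:
    """Rate-constant map ``k-id -> value`` with units.

    Bimolecular constants are in M^-1 s^-1, unimolecular in s^-1.
    """

    values: dict[str, float]
    units: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def __contains__(self, key: str) -> bool:
        return key in self.values

    def replace(self, **overrides: float) -> "RateConstantSet":
        """Return a copy with some constants overridden."""
        vals = dict(self.values)
        for key, val in overrides.items():
            if key not in vals:
                raise SchemeError(f"unknown rate constant {key!r}")
            vals[key] = float(val)
        return RateConstantSet(vals, dict(self.units))

    def validate(self) -> None:
        for key, val in self.values.items():
            if not np.isfinite(val) or val <= 0:
                raise SchemeError(f"rate constant {key} must be positive, got {val}")


class ReactionScheme:
    """An ordered list of mass-action reactions over a fixed species set."""

    def __init__(
        self,
        species: Sequence[str],
        reactions: Sequence[Reaction],
        lineages: Mapping[str, Mapping[str, float]],
        name: str = "custom",
    ) -> None:
        self.species = tuple(species)
        if len(set(self.species)) != len(self.species):
            raise SchemeError("species names must be unique")
        self.reactions = tuple(reactions)
        self.lineages = {s: dict(lineages.get(s, {})) for s in self.species}
        self.name = name
        self.index = {s: i for i, s in enumerate(self.species)}
        for rx in self.reactions:
            for s in rx.reactants + rx.products:
                if s not in self.index:
                    raise SchemeError(f"reaction references unknown species {s!r}")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def validate_rates(self, rates: RateConstantSet) -> None:
        """Check every reaction's rate-constant id resolves in *rates*."""
        missing = sorted({rx.k for rx in self.reactions} - set(rates.values))
        if missing:
            raise SchemeError(f"missing rate constant(s): {', '.join(missing)}")
        rates.validate()

    def stoichiometry(self, rates: RateConstantSet) -> tuple[np.ndarray, ...]:
        """Compile the network to dense arrays for fast evaluation.

        Returns ``(S, r1, r2, k)`` where ``S`` is the (n_species x
        n_reactions) net-stoichiometry matrix, ``r1``/``r2`` the reactant
        indices (``r2 = -1`` for unimolecular reactions) and ``k`` the
        rate-constant values in reaction order.
        """
        self.validate_rates(rates)
        n_rx = len(self.reactions)
        S = np.zeros((self.n_species, n_rx))
        r1 = np.full(n_rx, -1, dtype=np.int64)
        r2 = np.full(n_rx, -1, dtype=np.int64)
        k = np.zeros(n_rx)
        for j, rx in enumerate(self.reactions):
            for s in rx.reactants:
                S[self.index[s], j] -= 1.0
            for s in rx.products:
                S[self.index[s], j] += 1.0
            r1[j] = self.index[rx.reactants[0]]
            if len(rx.reactants) == 2:
                r2[j] = self.index[rx.reactants[1]]
            k[j] = rates[rx.k]
        return S, r1, r2, k

    def lineage_weights(self, lineage: str) -> np.ndarray:
        """Stoichiometric weight of *lineage* in each species."""
        if lineage not in LINEAGES and not any(
            lineage in comp for comp in self.lineages.values()
        ):
            raise SchemeError(f"unknown lineage {lineage!r}")
        return np.array([self.lineages[s].get(lineage, 0.0) for s in self.species])

    def with_additions(
        self,
        new_species: Sequence[str],
        new_lineages: Mapping[str, Mapping[str, float]],
        new_reactions: Sequence[Reaction],
        name: str | None = None,
    ) -> "ReactionScheme":
        """Return an extended copy (used by the anticoagulant models)."""
        species = self.species + tuple(new_species)
        lineages = {**self.lineages, **{s: dict(c) for s, c in new_lineages.items()}}
        return ReactionScheme(
            species,
            self.reactions + tuple(new_reactions),
            lineages,
            name=name or self.name,
        )


@dataclass
class DonorConcentrationProfile:
    """Initial molar concentrations for one donor.

    Only the ten input species (TF, the zymogens, trace FVIIa, TFPI, AT) may
    be non-zero; everything else starts at zero.
    """

    concentrations: dict[str, float]

    def __post_init__(self) -> None:
        for s, c in self.concentrations.items():
            if s not in PROFILE_SPECIES:
                raise SchemeError(f"{s!r} is not a donor-input species")
            if not np.isfinite(c):
                raise SchemeError(f"non-finite initial concentration for {s}")
            if c < 0:
                raise SchemeError(f"negative initial concentration for {s}: {c}")

    def __getitem__(self, species: str) -> float:
        return self.concentrations.get(species, 0.0)

    def replace(self, **updates: float) -> "DonorConcentrationProfile":
        return DonorConcentrationProfile({**self.concentrations, **updates})

    def initial_state(self, scheme: ReactionScheme) -> np.ndarray:
        y0 = np.zeros(scheme.n_species)
        for s, c in self.concentrations.items():
            y0[scheme.index[s]] = c
        return y0


# ---------------------------------------------------------------------------
# Parameter-file loading

def default_parameter_path() -> Path:
    """Path of the packaged default parameter file."""
    return Path(resources.files("thrombosim").joinpath("data/mass_action_scheme.yaml"))


def load_parameters(path: str | Path | None = None) -> dict:
    """Load and structurally validate a parameter file.

    Returns the raw parameter dictionary; raises :class:`SchemeError` naming
    the offending entry on malformed input.
    """
    p = Path(path) if path is not None else default_parameter_path()
    try:
        raw = yaml.safe_load(p.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - depends on file
        raise SchemeError(f"cannot parse parameter file {p}: {exc}") from exc
    for section in ("species", "reactions", "rates", "reference_concentrations"):
        if section not in raw:
            raise SchemeError(f"parameter file missing section {section!r}")
    raw["_path"] = str(p)
    raw["_sha256"] = hashlib.sha256(p.read_bytes()).hexdigest()
    return raw


def load_scheme(path: str | Path | None = None) -> tuple[ReactionScheme, RateConstantSet]:
    """Build a :class:`ReactionScheme` and :class:`RateConstantSet` from a file."""
    raw = load_parameters(path)
    species = [str(s) for s in raw["species"]]
    reactions = []
    for i, entry in enumerate(raw["reactions"]):
        try:
            reactions.append(
                Reaction(
                    reactants=tuple(entry["reactants"]),
                    products=tuple(entry["products"]),
                    k=str(entry["k"]),
                    kind=str(entry["kind"]),
                )
            )
        except (KeyError, TypeError) as exc:
            raise SchemeError(f"malformed reaction entry #{i}: {entry!r}") from exc
    rates = {}
    units = {}
    for kid, entry in raw["rates"].items():
        try:
            rates[str(kid)] = float(entry["value"])
            units[str(kid)] = str(entry.get("units", ""))
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemeError(f"malformed rate entry {kid!r}: {entry!r}") from exc
    scheme = ReactionScheme(
        species, reactions, raw.get("lineages", {}), name=str(raw.get("name", "custom"))
    )
    rateset = RateConstantSet(rates, units)
    scheme.validate_rates(rateset)
    return scheme, rateset


def build_default_scheme(
    path: str | Path | None = None,
) -> tuple[ReactionScheme, RateConstantSet]:
    """Load the default 34-species scheme and audit lineage conservation."""
    scheme, rates = load_scheme(path)
    audit_conservation(scheme)
    return scheme, rates


# ---------------------------------------------------------------------------
# Conservation audit and the reference (pure NumPy) derivative

def audit_conservation(scheme: ReactionScheme, lineages: Iterable[str] = LINEAGES) -> None:
    """Verify every reaction conserves every zymogen lineage.

    For each reaction the lineage-weighted stoichiometry of the reactant and
    product sides must balance; a mass-action network with this property
    conserves each lineage total exactly along any trajectory.
    """
    for lineage in lineages:
        w = scheme.lineage_weights(lineage)
        for rx in scheme.reactions:
            lhs = sum(w[scheme.index[s]] for s in rx.reactants)
            rhs = sum(w[scheme.index[s]] for s in rx.products)
            if abs(lhs - rhs) > 1e-12:
                raise SchemeError(
                    f"reaction {rx.reactants} -> {rx.products} does not conserve "
                    f"lineage {lineage} ({lhs} vs {rhs})"
                )


def derivative(
    state: np.ndarray | Mapping[str, float],
    scheme: ReactionScheme,
    rates: RateConstantSet,
) -> np.ndarray:
    """Mass-action time derivative (M/s) of every species.

    Pure-NumPy reference implementation; the integrator uses a compiled
    equivalent, cross-checked against this one in the test suite.
    """
    if isinstance(state, Mapping):
        y = np.zeros(scheme.n_species)
        for s, c in state.items():
            y[scheme.index[s]] = c
    else:
        y = np.asarray(state, dtype=float)
        if y.shape != (scheme.n_species,):
            raise SchemeError(
                f"state has shape {y.shape}, expected ({scheme.n_species},)"
            )
    S, r1, r2, k = scheme.stoichiometry(rates)
    flux = k * y[r1]
    bi = r2 >= 0
    flux[bi] *= y[r2[bi]]
    return S @ flux
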