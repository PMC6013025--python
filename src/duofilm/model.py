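"""Kinetic model: parameters, species, solutes and reaction networks.

Two lineages grow in a biofilm: a resistant type ``R`` (unaffected by the
antibiotic, optionally paying a growth-rate cost ``c`` and detoxifying its
neighbourhood at rate ``alpha`` per unit of new biomass) and a susceptible
type ``S`` whose growth is slowed by a bacteriostatic antibiotic through a
hyperbolic inhibition factor ``Ki_A/(A + Ki_A)``.

Four media define the metabolic relationship between the lineages:

``interference_competition``
    shared nutrient N, each lineage secretes a toxin inhibiting the other;
``exploitation_competition``
    shared nutrient N only;
``non_crossfeeding``
    private nutrients N_R / N_S, no chemical interaction;
``crossfeeding``
    private nutrients plus reciprocal consumption of each other's
    by-products E_R / E_S (mutualism).

All rates follow Monod kinetics.  Units: concentrations in g/L
(numerically identical to fg/um^3), rates in 1/h, diffusivities in um^2/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "ConfigurationError",
    "StateError",
    "ParameterSet",
    "SpeciesSpec",
    "SoluteSpec",
    "ReactionSpec",
    "MediumDefinition",
    "MEDIUM_NAMES",
    "build_medium",
    "monod_factor",
    "inhibition_factor",
    "reaction_rate_per_biomass",
    "specific_growth_rate",
    "solute_source_terms",
]

#: 7.2e-6 m^2/day expressed in um^2/h.
DIFFUSIVITY_UM2_PER_H = 7.2e-6 * 1e12 / 24.0  # = 3.0e5

MEDIUM_NAMES = (
    "interference_competition",
    "exploitation_competition",
    "non_crossfeeding",
    "crossfeeding",
)


class ConfigurationError(ValueError):
    """Raised for invalid model or simulation configuration."""


class StateError(RuntimeError):
    """Raised when a simulation state violates a structural precondition."""


@dataclass(frozen=True)
class ParameterSet:
    """Shared kinetic and transport parameters.

    Defaults are the standard simulation values: equal maximal growth
    rates for both lineages, half-saturation constants far below the bulk
    nutrient level (growth is nearly saturated at the biofilm front), and a
    single diffusivity for every solute.
    """

    mu_max: float = 1.0          # 1/h
    K_N: float = 3.5e-5          # g/L
    K_E: float = 3.5e-5          # g/L
    Y_N: float = 0.5             # g biomass / g nutrient
    Y_E: float = 0.5             # g biomass / g by-product
    Ki_T: float = 0.1            # g/L
    Ki_A: float = 0.1            # g/L
    N_bulk: float = 0.05         # g/L
    A_bulk: float = 0.0          # g/L
    D_N: float = DIFFUSIVITY_UM2_PER_H   # um^2/h
    D_E: float = DIFFUSIVITY_UM2_PER_H
    D_A: float = DIFFUSIVITY_UM2_PER_H
    D_T: float = DIFFUSIVITY_UM2_PER_H

    def __post_init__(self) -> None:
        for name in ("mu_max", "K_N", "K_E", "Y_N", "Y_E", "Ki_T", "Ki_A",
                     "N_bulk", "D_N", "D_E", "D_A", "D_T"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.A_bulk < 0:
            raise ConfigurationError("A_bulk must be non-negative")


@dataclass(frozen=True)
class SpeciesSpec:
    """Per-lineage identity and resistance phenotype.

    ``cost_c`` is an absolute reduction of ``mu_max`` in 1/h; with the
    default ``mu_max = 1/h`` a cost of 0.1 is equivalently a 10% cost.
    ``alpha_detox`` is the mass of antibiotic removed per unit of new R
    biomass (growth-coupled detoxification; no enzyme is released, and a
    non-growing cell does not detoxify).
    """

    label: str
    mu_max: float = 1.0
    cost_c: float = 0.0
    susceptible: bool = False
    alpha_detox: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in ("R", "S"):
            raise ConfigurationError("species label must be 'R' or 'S'")
        if not 0.0 <= self.cost_c < self.mu_max:
            raise ConfigurationError("cost must satisfy 0 <= c < mu_max")
        if self.alpha_detox < 0:
            raise ConfigurationError("alpha_detox must be non-negative")
        if self.label == "S" and self.alpha_detox != 0:
            raise ConfigurationError("only R detoxifies (alpha_detox = 0 for S)")

    @property
    def effective_mu_max(self) -> float:
        return self.mu_max - self.cost_c


@dataclass(frozen=True)
class SoluteSpec:
    """One diffusible solute: name, diffusivity and bulk (Dirichlet) value.

    By-products and toxins have no bulk supply; their bulk value is 0 and
    the well-mixed compartment above the boundary layer acts as a sink.
    """

    name: str
    diffusivity: float
    bulk_value: float

    def __post_init__(self) -> None:
        if self.diffusivity <= 0:
            raise ConfigurationError("diffusivity must be positive")
        if self.bulk_value < 0:
            raise ConfigurationError("bulk value must be non-negative")


@dataclass(frozen=True)
class ReactionSpec:
    """One growth process of one lineage.

    The per-biomass rate is ``max_rate * prod C/(C+K) * prod Ki/(C+Ki)``;
    the volumetric rate multiplies by the actor's biomass density X.
    ``stoichiometry`` maps each solute to its coefficient in g solute per
    g biomass formed (negative = consumed): ``-1/Y`` for the substrate,
    ``+1`` for a secreted toxin or by-product, ``-alpha`` for antibiotic
    removal on R growth.
    """

    name: str
    actor: str
    max_rate: float
    monod_terms: tuple[tuple[str, float], ...]
    inhibition_terms: tuple[tuple[str, float], ...] = ()
    stoichiometry: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class MediumDefinition:
    """Solutes plus reaction network for one metabolic-interaction regime."""

    name: str
    solutes: tuple[SoluteSpec, ...]
    reactions: tuple[ReactionSpec, ...]
    params: ParameterSet

    @property
    def solute_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.solutes)

    def solute(self, name: str) -> SoluteSpec:
        for s in self.solutes:
            if s.name == name:
                return s
        raise KeyError(name)

    def reactions_of(self, label: str) -> tuple[ReactionSpec, ...]:
        return tuple(r for r in self.reactions if r.actor == label)


def monod_factor(C, K):
    """Saturating substrate factor C/(C+K), in [0, 1).

    Accepts scalars or arrays; raises on negative concentrations.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentration must be non-negative")
    if K <= 0:
        raise ValueError("half-saturation constant must be positive")
    out = C / (C + K)
    return float(out) if out.ndim == 0 else out


def inhibition_factor(C, Ki):
    """Hyperbolic inhibition factor Ki/(C+Ki), in (0, 1]."""
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentration must be non-negative")
    if Ki <= 0:
        raise ValueError("inhibitory constant must be positive")
    out = Ki / (C + Ki)
    return float(out) if out.ndim == 0 else out


def build_medium(
    name: str,
    params: ParameterSet | None = None,
    cost_c: float = 0.0,
    alpha_detox: float = 0.0,
) -> MediumDefinition:
    """Construct the reaction network for one of the four media.

    R growth runs at ``mu_max - cost_c``; every S growth reaction carries
    the antibiotic inhibition factor; every R growth reaction removes
    ``alpha_detox`` g of antibiotic per g of new biomass.  The antibiotic
    solute is always present (its bulk value may be 0).
    """
    params = params or ParameterSet()
    if name not in MEDIUM_NAMES:
        raise ConfigurationError(
            f"unknown medium {name!r}; expected one of {MEDIUM_NAMES}")
    if cost_c >= params.mu_max or cost_c < 0:
        raise ConfigurationError("cost must satisfy 0 <= c < mu_max")
    if alpha_detox < 0:
        raise ConfigurationError("alpha_detox must be non-negative")

    mu_R = params.mu_max - cost_c
    mu_S = params.mu_max
    inv_YN = 1.0 / params.Y_N
    inv_YE = 1.0 / params.Y_E
    a = alpha_detox

    def solute(n: str, D: float, bulk: float) -> SoluteSpec:
        return SoluteSpec(name=n, diffusivity=D, bulk_value=bulk)

    s_inhib = (("A", params.Ki_A),)

    if name == "exploitation_competition":
        solutes = (
            solute("N", params.D_N, params.N_bulk),
            solute("A", params.D_A, params.A_bulk),
        )
        reactions = (
            ReactionSpec("R_growth", "R", mu_R,
                         monod_terms=(("N", params.K_N),),
                         stoichiometry={"N": -inv_YN, "A": -a}),
            ReactionSpec("S_growth", "S", mu_S,
                         monod_terms=(("N", params.K_N),),
                         inhibition_terms=s_inhib,
                         stoichiometry={"N": -inv_YN}),
        )
    elif name == "interference_competition":
        solutes = (
            solute("N", params.D_N, params.N_bulk),
            solute("A", params.D_A, params.A_bulk),
            solute("T_R", params.D_T, 0.0),
            solute("T_S", params.D_T, 0.0),
        )
        reactions = (
            ReactionSpec("R_growth_toxin", "R", mu_R,
                         monod_terms=(("N", params.K_N),),
                         inhibition_terms=(("T_S", params.Ki_T),),
                         stoichiometry={"N": -inv_YN, "T_R": 1.0, "A": -a}),
            ReactionSpec("S_growth_toxin", "S", mu_S,
                         monod_terms=(("N", params.K_N),),
                         inhibition_terms=s_inhib + (("T_R", params.Ki_T),),
                         stoichiometry={"N": -inv_YN, "T_S": 1.0}),
        )
    elif name == "non_crossfeeding":
        solutes = (
            solute("N_R", params.D_N, params.N_bulk),
            solute("N_S", params.D_N, params.N_bulk),
            solute("A", params.D_A, params.A_bulk),
        )
        reactions = (
            ReactionSpec("R_growth", "R", mu_R,
                         monod_terms=(("N_R", params.K_N),),
                         stoichiometry={"N_R": -inv_YN, "A": -a}),
            ReactionSpec("S_growth", "S", mu_S,
                         monod_terms=(("N_S", params.K_N),),
                         inhibition_terms=s_inhib,
                         stoichiometry={"N_S": -inv_YN}),
        )
    else:  # crossfeeding
        solutes = (
            solute("N_R", params.D_N, params.N_bulk),
            solute("N_S", params.D_N, params.N_bulk),
            solute("E_R", params.D_E, 0.0),
            solute("E_S", params.D_E, 0.0),
            solute("A", params.D_A, params.A_bulk),
        )
        reactions = (
            ReactionSpec("R_growth_on_N", "R", mu_R,
                         monod_terms=(("N_R", params.K_N),),
                         stoichiometry={"N_R": -inv_YN, "E_R": 1.0, "A": -a}),
            ReactionSpec("R_growth_on_ES", "R", mu_R,
                         monod_terms=(("E_S", params.K_E),),
                         stoichiometry={"E_S": -inv_YE, "E_R": 1.0, "A": -a}),
            ReactionSpec("S_growth_on_N", "S", mu_S,
                         monod_terms=(("N_S", params.K_N),),
                         inhibition_terms=s_inhib,
                         stoichiometry={"N_S": -inv_YN, "E_S": 1.0}),
            ReactionSpec("S_growth_on_ER", "S", mu_S,
                         monod_terms=(("E_R", params.K_E),),
                         inhibition_terms=s_inhib,
                         stoichiometry={"E_R": -inv_YE, "E_S": 1.0}),
        )
    return MediumDefinition(name=name, solutes=solutes, reactions=reactions,
                            params=params)


def reaction_rate_per_biomass(reaction: ReactionSpec,
                              local: Mapping[str, object]):
    """Per-unit-biomass rate of one reaction at local concentrations (1/h).

    Scalar or array concentrations; missing solutes raise :class:`StateError`.
    """
    rate = reaction.max_rate
    try:
        for name, K in reaction.monod_terms:
            rate = rate * monod_factor(local[name], K)
        for name, Ki in reaction.inhibition_terms:
            rate = rate * inhibition_factor(local[name], Ki)
    except KeyError as exc:
        raise StateError(
            f"reaction {reaction.name!r} requires solute {exc.args[0]!r} "
            "missing from the local environment") from exc
    return rate


def specific_growth_rate(species: SpeciesSpec, medium: MediumDefinition,
                         local: Mapping[str, object]):
    """Specific growth rate mu (1/h) of one lineage: sum over its reactions.

    In the cross-feeding medium the two growth routes (private nutrient and
    partner by-product) are additive.
    """
    total = 0.0
    for reaction in medium.reactions_of(species.label):
        total = total + reaction_rate_per_biomass(reaction, local)
    return total


def solute_source_terms(medium: MediumDefinition,
                        biomass: Mapping[str, object],
                        local: Mapping[str, object]) -> dict[str, object]:
    """Net volumetric production rate of every solute (g/L/h).

    ``biomass`` maps species label to biomass density X (g/L); each
    reaction contributes ``stoich * rate_per_biomass * X_actor``.
    """
    sources: dict[str, object] = {name: 0.0 for name in medium.solute_names}
    for reaction in medium.reactions:
        X = biomass.get(reaction.actor, 0.0)
        rate = reaction_rate_per_biomass(reaction, local)
        vol_rate = rate * X
        for name, coeff in reaction.stoichiometry.items():
            if coeff != 0.0:
                sources[name] = sources[name] + coeff * vol_rate
    return sources


def species_pair(params: ParameterSet | None = None, cost_c: float = 0.0,
                 alpha_detox: float = 0.0) -> tuple[SpeciesSpec, SpeciesSpec]:
    """The standard (R, S) pair for a given cost and detoxification level."""
    params = params or ParameterSet()
    R = SpeciesSpec(label="R", mu_max=params.mu_max, cost_c=cost_c,
                    susceptible=False, alpha_detox=alpha_detox)
    S = SpeciesSpec(label="S", mu_max=params.mu_max, susceptible=True)
    return R, S


def with_antibiotic(medium: MediumDefinition, A_bulk: float) -> MediumDefinition:
    """Copy of ``medium`` with the antibiotic bulk value replaced."""
    if A_bulk < 0:
        raise ConfigurationError("A_bulk must be non-negative")
    solutes = tuple(
        replace(s, bulk_value=A_bulk) if s.name == "A" else s
        for s in medium.solutes)
    return replace(medium, solutes=solutes,
                   params=replace(medium.params, A_bulk=A_bulk))
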