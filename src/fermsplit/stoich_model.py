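"""Stoichiometric core: compounds, glycolytic pathway modes, genotype gating.

The model covers the anaerobic mixed-acid fermentation network of an
*E. coli* strain lineage engineered for H2/ethanol co-production
(ΔldhA ΔfrdAB background, FHL derepressed, uptake hydrogenases deleted).
Glucose (or gluconate, or glycerol) is oxidized to pyruvate through one of
several glycolytic routes ("pathway modes"), each with a fixed per-mol
coefficient vector; pyruvate is then dissimilated by pyruvate-formate lyase
(PFL) to acetyl-CoA + formate, formate is split to H2 + CO2 by
formate-hydrogen lyase (FHL), and acetyl-CoA is drained to ethanol
(AdhE, 2 NAD(P)H) and/or acetate (Pta-AckA, +1 ATP).

All mode coefficients are exact rationals (`fractions.Fraction`) so the
carbon and electron closure identities hold to machine identity, not just
to a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Mapping, Optional

__all__ = [
    "Compound",
    "COMPOUNDS",
    "PathwayMode",
    "PATHWAY_MODES",
    "Genotype",
    "STRAIN_PRESETS",
    "ModelOptions",
    "ModelSpec",
    "DOWNSTREAM_REACTIONS",
    "FluxVector",
    "BalanceResiduals",
    "mode_coefficients",
    "build_model",
    "validate_flux",
    "InvalidModeError",
    "InfeasibleModelError",
    "FluxDomainError",
]


class InvalidModeError(ValueError):
    """Unknown pathway mode or mode/substrate pairing."""


class InfeasibleModelError(ValueError):
    """Genotype leaves no admissible glycolytic route for the substrate."""


class FluxDomainError(ValueError):
    """Flux vector violates its domain (negative component, bad simplex)."""


@dataclass(frozen=True)
class Compound:
    """A metabolite with elemental composition and optional heats of combustion.

    ``gamma`` is the degree of reduction: available electrons per mol,
    4*C + H - 2*O from the molecular formula (N-free compounds here).
    Heating values are kJ/mol; LHV excludes, HHV includes the condensation
    enthalpy of product water.
    """

    name: str
    c: int
    h: int
    o: int
    lhv: Optional[float] = None
    hhv: Optional[float] = None

    @property
    def carbons(self) -> int:
        return self.c

    @property
    def gamma(self) -> int:
        return 4 * self.c + self.h - 2 * self.o


COMPOUNDS: Mapping[str, Compound] = {
    cpd.name: cpd
    for cpd in (
        Compound("glucose", 6, 12, 6, lhv=2539.0, hhv=2803.0),
        Compound("gluconate", 6, 12, 7),
        Compound("glycerol", 3, 8, 3, lhv=1479.0, hhv=1655.0),
        Compound("pyruvate", 3, 4, 3),
        Compound("ethanol", 2, 6, 1, lhv=1235.0, hhv=1367.0),
        Compound("acetate", 2, 4, 2),
        Compound("formate", 1, 2, 2),
        Compound("h2", 0, 2, 0, lhv=241.8, hhv=285.8),
        Compound("co2", 1, 0, 2),
    )
}


@dataclass(frozen=True)
class PathwayMode:
    """Per-mol-substrate coefficients of one glycolytic route.

    Coefficients are mol per mol substrate routed through the mode:
    ``pyr`` pyruvate, ``nadh``/``nadph`` reduced cofactor, ``co2_gly``
    CO2 released upstream of pyruvate (oxidative PP / Gnd
    decarboxylations), ``atp`` net substrate-level ATP (PTS/kinase costs
    lumped in).
    """

    id: str
    substrate: str
    pyr: Fraction
    nadh: Fraction
    nadph: Fraction
    co2_gly: Fraction
    atp: Fraction

    @property
    def nadph_pool(self) -> Fraction:
        """Pooled NAD(P)H production (NADH + NADPH, one redox currency)."""
        return self.nadh + self.nadph

    def carbon_closure_gap(self) -> Fraction:
        sub = COMPOUNDS[self.substrate]
        return Fraction(sub.carbons) - (3 * self.pyr + self.co2_gly)

    def electron_closure_gap(self) -> Fraction:
        sub = COMPOUNDS[self.substrate]
        return Fraction(sub.gamma) - (10 * self.pyr + 2 * self.nadh + 2 * self.nadph)


F = Fraction

# Mode derivations (exact; each row closes carbon and electrons):
#   EMP             glucose -> 2 pyr + 2 NADH                       (textbook)
#   PP_SINGLE_PASS  3 G6P -> 3 CO2 + 6 NADPH + 2 F6P + GAP, the F6P
#                   continuing down EMP: per glucose 5/3 pyr, 5/3 NADH,
#                   2 NADPH, 1 CO2
#   PP_CYCLIC       F6P recycled to G6P; steady state needs 3 Zwf turns
#                   per net glucose: 1 pyr, 1 NADH, 6 NADPH, 3 CO2
#   ED              G6P -> 6PG (1 NADPH) -> KDPG -> pyr + GAP; GAP -> pyr
#   GNT_GND         gluconate -> 6PG (1 ATP) -> Gnd/non-ox PP as single pass
#   GNT_ED          gluconate -> 6PG -> Edd/Eda -> 2 pyr + 1 NADH
#   GLYCEROL        glycerol -> GAP (1 NADH) -> pyr (1 NADH)
PATHWAY_MODES: Mapping[str, PathwayMode] = {
    m.id: m
    for m in (
        PathwayMode("EMP", "glucose", F(2), F(2), F(0), F(0), F(2)),
        PathwayMode("PP_SINGLE_PASS", "glucose", F(5, 3), F(5, 3), F(2), F(1), F(5, 3)),
        PathwayMode("PP_CYCLIC", "glucose", F(1), F(1), F(6), F(3), F(1)),
        PathwayMode("ED", "glucose", F(2), F(1), F(1), F(0), F(1)),
        PathwayMode("GNT_GND", "gluconate", F(5, 3), F(5, 3), F(1), F(1), F(5, 3)),
        PathwayMode("GNT_ED", "gluconate", F(2), F(1), F(0), F(0), F(1)),
        PathwayMode("GLYCEROL", "glycerol", F(1), F(2), F(0), F(0), F(1)),
    )
}

#: Pathway modes that belong to the Entner-Doudoroff family (gated by edd-eda).
ED_FAMILY = frozenset({"ED", "GNT_ED"})
#: Modes whose oxidative-PP entry requires Gnd.
GND_FAMILY = frozenset({"PP_SINGLE_PASS", "PP_CYCLIC", "GNT_GND"})


def mode_coefficients(mode_id: str, substrate: str) -> PathwayMode:
    """Return the fixed coefficient record for ``mode_id`` on ``substrate``.

    Raises :class:`InvalidModeError` for an unknown mode or a
    mode/substrate mismatch (e.g. EMP on gluconate).
    """
    mode = PATHWAY_MODES.get(mode_id)
    if mode is None:
        raise InvalidModeError(f"unknown pathway mode {mode_id!r}")
    if mode.substrate != substrate:
        raise InvalidModeError(
            f"mode {mode_id!r} is defined for {mode.substrate!r}, not {substrate!r}"
        )
    return mode


# ---------------------------------------------------------------------------
# Downstream (post-pyruvate) reactions
# ---------------------------------------------------------------------------

#: name -> (electrons in, electrons out); every reaction conserves electrons.
DOWNSTREAM_REACTIONS: Mapping[str, tuple[int, int]] = {
    # pyr (10) -> AcCoA (8, as acetate skeleton) + formate (2)
    "PFL": (10, 8 + 2),
    # formate (2) -> H2 (2) + CO2 (0)
    "FHL": (2, 2 + 0),
    # AcCoA (8) + 2 NAD(P)H (4) -> ethanol (12)
    "ADH_ACCOA": (8 + 4, 12),
    # AcCoA (8) -> acetate (8), +1 ATP
    "PTA_ACKA": (8, 8),
    # pyruvate excreted unchanged
    "PYR_EXCRETION": (10, 10),
    # pyr (10) -> acetaldehyde + CO2; acetaldehyde + 1 NAD(P)H (2) -> ethanol (12)
    "PDC_ROUTE": (10 + 2, 12 + 0),
    # NAD(P)H (2) -> H2 (2)
    "NADH_H2": (2, 2),
}


@dataclass(frozen=True)
class Genotype:
    """Deletion flags for the gated genes plus informational overexpression.

    True means the locus is deleted. ldhA and frdAB are deleted in every
    shipped preset (the SH5 lineage); lactate and succinate are therefore
    not modeled at all. ``gnd`` deletion is supported only to express
    infeasible gluconate models; no shipped strain deletes it.
    """

    ldhA: bool = True
    frdAB: bool = True
    pta_ackA: bool = False
    pfkA: bool = False
    edd_eda: bool = False
    hycA: bool = True
    hyaAB_hybBC: bool = True
    gnd: bool = False
    overexpressed: tuple[str, ...] = ()


#: Strain presets of the study lineage. Overexpression flags are
#: informational only (they do not gate reactions); pfkA deletion does not
#: remove the EMP mode because PfkB compensates.
STRAIN_PRESETS: Mapping[str, Genotype] = {
    "SH5": Genotype(),
    "SH5_ZG": Genotype(overexpressed=("zwf", "gnd")),
    "SH8*": Genotype(pta_ackA=True, pfkA=True),
    "SH8*_Z": Genotype(pta_ackA=True, pfkA=True, overexpressed=("zwf",)),
    "SH8*_G": Genotype(pta_ackA=True, pfkA=True, overexpressed=("gnd",)),
    "SH8*_ZG": Genotype(pta_ackA=True, pfkA=True, overexpressed=("zwf", "gnd")),
    "SH9*": Genotype(pfkA=True),
    "SH9*_Z": Genotype(pfkA=True, overexpressed=("zwf",)),
    "SH9*_G": Genotype(pfkA=True, overexpressed=("gnd",)),
    "SH9*_ZG": Genotype(pfkA=True, overexpressed=("zwf", "gnd")),
    "SH10_ZG": Genotype(pfkA=True, edd_eda=True, overexpressed=("zwf", "gnd")),
}


@dataclass(frozen=True)
class ModelOptions:
    """Optional reactions and policies toggled per scenario.

    ``nadh_h2`` is off for every facultative-anaerobe preset and is only
    enabled for the strict-anaerobe ceiling scenario. ``formate_excretion``
    relaxes the default assumption that FHL splits all formate (hycA is
    deleted in the lineage, so FHL is derepressed).
    """

    pdc_route: bool = False
    nadh_h2: bool = False
    formate_excretion: bool = False


@dataclass(frozen=True)
class ModelSpec:
    """Admissible pathway modes and downstream reactions for one genotype."""

    substrate: str
    genotype: Genotype
    modes: tuple[PathwayMode, ...]
    reactions: frozenset[str]
    options: ModelOptions = field(default_factory=ModelOptions)

    @property
    def mode_ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.modes)

    def mode(self, mode_id: str) -> PathwayMode:
        for m in self.modes:
            if m.id == mode_id:
                return m
        raise InvalidModeError(f"mode {mode_id!r} not admissible in this model")


_SUBSTRATE_MODES = {
    "glucose": ("EMP", "PP_SINGLE_PASS", "PP_CYCLIC", "ED"),
    "gluconate": ("GNT_GND", "GNT_ED"),
    "glycerol": ("GLYCEROL",),
}


def build_model(
    genotype: Genotype,
    substrate: str = "glucose",
    options: ModelOptions | None = None,
) -> ModelSpec:
    """Assemble the admissible mode and reaction sets for a genotype.

    edd-eda deletion removes the ED-family modes; gnd deletion removes the
    oxidative-PP entries; pta-ackA deletion removes the acetate branch.
    pfkA deletion does *not* remove EMP (PfkB compensates). hyaAB/hybBC
    deletion documents that H2 is terminal (no uptake reaction exists
    either way).
    """
    if substrate not in _SUBSTRATE_MODES:
        raise InvalidModeError(f"unknown substrate {substrate!r}")
    options = options or ModelOptions()

    mode_ids = [m for m in _SUBSTRATE_MODES[substrate]]
    if genotype.edd_eda:
        mode_ids = [m for m in mode_ids if m not in ED_FAMILY]
    if genotype.gnd:
        mode_ids = [m for m in mode_ids if m not in GND_FAMILY]
    if not mode_ids:
        raise InfeasibleModelError(
            f"genotype leaves no glycolytic route for {substrate!r}"
        )

    reactions = {"PFL", "FHL", "ADH_ACCOA", "PYR_EXCRETION"}
    if not genotype.pta_ackA:
        reactions.add("PTA_ACKA")
    if options.pdc_route:
        reactions.add("PDC_ROUTE")
    if options.nadh_h2:
        reactions.add("NADH_H2")

    return ModelSpec(
        substrate=substrate,
        genotype=genotype,
        modes=tuple(PATHWAY_MODES[m] for m in mode_ids),
        reactions=frozenset(reactions),
        options=options,
    )


def strict_anaerobe_model() -> ModelSpec:
    """Clostridial-type ceiling model: EMP-only glycolysis with an
    NAD(P)H-driven H2-evolving reaction (ferredoxin/hydrogenase lumped).

    The 4 mol/mol H2 ceiling of strict anaerobes is an EMP fermentation
    argument; the cyclic-PP routing is deliberately excluded here.
    """
    genotype = Genotype()
    options = ModelOptions(nadh_h2=True)
    base = build_model(genotype, "glucose", options)
    return replace(base, modes=(PATHWAY_MODES["EMP"],))


# ---------------------------------------------------------------------------
# Flux vectors and conservation audits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluxVector:
    """Reaction-level fluxes per 1 mol substrate fed.

    ``fractions`` maps mode id -> mol substrate routed; ``slack`` is the
    substrate fraction not covered by the modeled routes (biomass,
    unmeasured byproducts). Downstream rates are mol per mol substrate.
    """

    fractions: Mapping[str, float]
    pfl: float = 0.0
    fhl: float = 0.0
    adh: float = 0.0
    ack: float = 0.0
    pyr_exc: float = 0.0
    pdc: float = 0.0
    nadh_h2: float = 0.0
    formate_exc: float = 0.0
    slack: float = 0.0

    def downstream(self) -> dict[str, float]:
        return {
            "pfl": self.pfl,
            "fhl": self.fhl,
            "adh": self.adh,
            "ack": self.ack,
            "pyr_exc": self.pyr_exc,
            "pdc": self.pdc,
            "nadh_h2": self.nadh_h2,
            "formate_exc": self.formate_exc,
        }


@dataclass(frozen=True)
class BalanceResiduals:
    """Conservation residuals of a flux vector (all mol per mol substrate).

    ``carbon`` and ``electron`` are the global closure gaps; ``nadph`` is
    the pooled NAD(P)H surplus (production minus consumption, >= 0 for a
    feasible vector); the node residuals are the internal metabolite
    balances. ``atp_net`` is informational (maintenance is not modeled).
    """

    carbon: float
    electron: float
    nadph: float
    atp_net: float
    pyr_node: float
    accoa_node: float
    formate_node: float

    def feasible(self, tol: float = 1e-9, closed_redox: bool = False) -> bool:
        ok = (
            abs(self.carbon) <= tol
            and abs(self.electron) <= tol
            and abs(self.pyr_node) <= tol
            and abs(self.accoa_node) <= tol
            and abs(self.formate_node) <= tol
        )
        if closed_redox:
            return ok and abs(self.nadph) <= tol
        return ok and self.nadph >= -tol


def validate_flux(flux: FluxVector, model: ModelSpec, tol: float = 1e-9) -> BalanceResiduals:
    """Audit a flux vector against the conservation laws of the model.

    Raises :class:`FluxDomainError` on negative components or on mode
    fractions outside the model; checks Σ fractions + slack = 1.
    """
    for mode_id in flux.fractions:
        model.mode(mode_id)  # raises if not admissible
    comps = dict(flux.fractions)
    comps.update(flux.downstream())
    comps["slack"] = flux.slack
    for name, v in comps.items():
        if v < -tol:
            raise FluxDomainError(f"negative flux component {name}={v}")
    total = sum(flux.fractions.values()) + flux.slack
    if abs(total - 1.0) > max(tol, 1e-9):
        raise FluxDomainError(f"mode fractions + slack must sum to 1, got {total}")

    pyr_pool = sum(float(model.mode(m).pyr) * f for m, f in flux.fractions.items())
    nadph_prod = sum(
        float(model.mode(m).nadph_pool) * f for m, f in flux.fractions.items()
    )
    co2_gly = sum(float(model.mode(m).co2_gly) * f for m, f in flux.fractions.items())
    atp_gly = sum(float(model.mode(m).atp) * f for m, f in flux.fractions.items())

    pyr_node = pyr_pool - (flux.pfl + flux.pdc + flux.pyr_exc)
    accoa_node = flux.pfl - (flux.adh + flux.ack)
    formate_node = flux.pfl - (flux.fhl + flux.formate_exc)
    nadph_surplus = nadph_prod - (2.0 * flux.adh + flux.pdc + flux.nadh_h2)

    # terminal products
    y_etoh = flux.adh + flux.pdc
    y_ace = flux.ack
    y_h2 = flux.fhl + flux.nadh_h2
    y_co2 = co2_gly + flux.fhl + flux.pdc
    y_pyr = flux.pyr_exc
    y_for = flux.formate_exc

    sub = COMPOUNDS[model.substrate]
    covered = 1.0 - flux.slack
    carbon = sub.carbons * covered - (
        3.0 * y_pyr + 2.0 * y_etoh + 2.0 * y_ace + y_co2 + y_for
    )
    electron = sub.gamma * covered - (
        10.0 * y_pyr
        + 12.0 * y_etoh
        + 8.0 * y_ace
        + 2.0 * y_h2
        + 2.0 * y_for
        + 2.0 * nadph_surplus
    )
    atp_net = atp_gly + flux.ack  # acetate kinase contributes 1 ATP per acetate

    return BalanceResiduals(
        carbon=carbon,
        electron=electron,
        nadph=nadph_surplus,
        atp_net=atp_net,
        pyr_node=pyr_node,
        accoa_node=accoa_node,
        formate_node=formate_node,
    )
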