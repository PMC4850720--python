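"""Data-consistency audits of fermentation yield measurements.

Three checks, all per mol substrate: carbon recovery (fraction of
substrate carbon found in measured products, CO2 and biomass), the signed
degree-of-reduction balance error ((γ_in − γ_out)/γ_in, electrons per
mol), and energy recovery (combustion energy of the fuel products H2 and
ethanol over that of the substrate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .stoich_model import COMPOUNDS

__all__ = [
    "YieldMeasurement",
    "BalanceReport",
    "carbon_recovery",
    "reduction_degree_error",
    "energy_recovery",
    "audit",
    "MissingDataError",
    "InconsistentDataError",
]

#: Degree of reduction of biomass carbon (electrons per C-mol), generic
#: CH1.8O0.5N0.2 composition. Used only when biomass carbon is reported.
BIOMASS_GAMMA_PER_C = 4.2


class MissingDataError(ValueError):
    """A required field (e.g. CO2 under the strict policy) is absent."""


class InconsistentDataError(ValueError):
    """Measurements contradict a conservation law (e.g. inferred CO2 < 0)."""


@dataclass(frozen=True)
class YieldMeasurement:
    """Molar product yields of one fermentation, mol per mol substrate.

    ``y_co2`` and ``biomass_c`` (mol carbon per mol substrate) may be None
    when not measured, which is the common case for serum-bottle data.
    """

    sample_id: str
    substrate: str
    y_h2: float = 0.0
    y_etoh: float = 0.0
    y_ace: float = 0.0
    y_pyr: float = 0.0
    y_co2: Optional[float] = None
    biomass_c: Optional[float] = None

    def __post_init__(self):
        if self.substrate not in COMPOUNDS:
            raise ValueError(f"unknown substrate {self.substrate!r}")
        for name in ("y_h2", "y_etoh", "y_ace", "y_pyr", "y_co2", "biomass_c"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{self.sample_id}: negative yield {name}={v}")


@dataclass(frozen=True)
class BalanceReport:
    sample_id: str
    carbon_recovery: float
    reduction_degree_error: float
    energy_recovery: float
    co2_source: str  # measured | inferred | absent


def _product_carbon(m: YieldMeasurement) -> float:
    return 3.0 * m.y_pyr + 2.0 * m.y_etoh + 2.0 * m.y_ace


def infer_co2(m: YieldMeasurement) -> float:
    """CO2 implied by carbon closure: substrate C − product C − biomass C."""
    sub = COMPOUNDS[m.substrate]
    co2 = sub.carbons - _product_carbon(m) - (m.biomass_c or 0.0)
    if co2 < -1e-9:
        raise InconsistentDataError(
            f"{m.sample_id}: inferred CO2 = {co2:.4f} < 0; products exceed substrate carbon"
        )
    return max(0.0, co2)


def carbon_recovery(m: YieldMeasurement, policy: str = "strict") -> float:
    """Fraction of substrate carbon recovered in products (+CO2, +biomass).

    ``strict`` requires a measured CO2; ``infer_co2`` closes the balance
    by construction (recovery 1.0 unless products already exceed substrate
    carbon); ``ignore_co2`` counts measured products and biomass only.
    """
    sub = COMPOUNDS[m.substrate]
    carbon = _product_carbon(m) + (m.biomass_c or 0.0)
    if policy == "strict":
        if m.y_co2 is None:
            raise MissingDataError(f"{m.sample_id}: CO2 required under strict policy")
        carbon += m.y_co2
    elif policy == "infer_co2":
        carbon += infer_co2(m)
    elif policy == "ignore_co2":
        pass
    else:
        raise ValueError(f"unknown CO2 policy {policy!r}")
    return carbon / sub.carbons


def reduction_degree_error(m: YieldMeasurement) -> float:
    """Signed electron-balance error (γ_in − γ_out)/γ_in.

    H2 contributes γ=2 and CO2 contributes 0, so the CO2 policy is
    irrelevant here. Biomass electrons are counted at 4.2 per carbon when
    biomass carbon is reported. A positive error means electrons are
    missing from the measured products (unmeasured biomass/byproducts).
    """
    sub = COMPOUNDS[m.substrate]
    gamma_out = (
        COMPOUNDS["h2"].gamma * m.y_h2
        + COMPOUNDS["ethanol"].gamma * m.y_etoh
        + COMPOUNDS["acetate"].gamma * m.y_ace
        + COMPOUNDS["pyruvate"].gamma * m.y_pyr
        + BIOMASS_GAMMA_PER_C * (m.biomass_c or 0.0)
    )
    return (sub.gamma - gamma_out) / sub.gamma


def energy_recovery(m: YieldMeasurement, convention: str = "LHV") -> float:
    """Combustion energy of fuel products (H2, ethanol) over substrate energy.

    Uses the pinned heating values on the compound table; LHV is the
    default (fuels context). Raises on a substrate without a heat value
    (e.g. gluconate).
    """
    attr = {"LHV": "lhv", "HHV": "hhv"}.get(convention)
    if attr is None:
        raise ValueError(f"unknown energy convention {convention!r}")
    sub = COMPOUNDS[m.substrate]
    heat_sub = getattr(sub, attr)
    if heat_sub is None:
        raise ValueError(f"no {convention} heat value for substrate {m.substrate!r}")
    heat = (
        getattr(COMPOUNDS["h2"], attr) * m.y_h2
        + getattr(COMPOUNDS["ethanol"], attr) * m.y_etoh
    )
    return heat / heat_sub


def audit(
    m: YieldMeasurement,
    co2_policy: str = "infer_co2",
    convention: str = "LHV",
) -> BalanceReport:
    """Full consistency report for one measurement.

    Under ``infer_co2`` a measured CO2 takes precedence over inference.
    """
    effective = co2_policy
    if co2_policy == "infer_co2" and m.y_co2 is not None:
        effective = "strict"
    co2_source = {
        "strict": "measured",
        "infer_co2": "inferred",
        "ignore_co2": "absent",
    }[effective]
    rec = carbon_recovery(m, policy=effective)
    try:
        er = energy_recovery(m, convention)
    except ValueError:
        er = float("nan")
    return BalanceReport(
        sample_id=m.sample_id,
        carbon_recovery=rec,
        reduction_degree_error=reduction_degree_error(m),
        energy_recovery=er,
        co2_source=co2_source,
    )
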