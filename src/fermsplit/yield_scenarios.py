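"""Closed-form yield scenarios and LP theoretical maxima.

``scenario_yields`` turns a glycolytic flux split into product yields by
linear bookkeeping: the pyruvate pool goes through PFL, formate is split
by FHL, and the acetyl-CoA pool is divided between ethanol (2 NAD(P)H
each) and acetate according to the routing policy. ``max_yield`` solves a
small linear program over the reaction-level flux space for the
theoretical maximum of H2, ethanol, or their minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from .stoich_model import (
    COMPOUNDS,
    FluxVector,
    ModelSpec,
    validate_flux,
)

__all__ = ["ScenarioResult", "OptimumResult", "scenario_yields", "max_yield"]

_TOL = 1e-9


@dataclass(frozen=True)
class ScenarioResult:
    """Product yields implied by a flux split under a routing policy."""

    y_h2: float
    y_etoh: float
    y_ace: float
    y_pyr: float
    y_co2: float
    nadph_surplus: float
    atp_net: float
    flux: FluxVector
    feasible: bool
    note: str = ""

    def yields(self) -> dict[str, float]:
        return {
            "y_h2": self.y_h2,
            "y_etoh": self.y_etoh,
            "y_ace": self.y_ace,
            "y_pyr": self.y_pyr,
            "y_co2": self.y_co2,
        }


@dataclass(frozen=True)
class OptimumResult:
    """LP optimum: objective value, argmax flux vector, active constraints."""

    objective: str
    value: Optional[float]
    flux: Optional[FluxVector]
    feasible: bool
    active_constraints: tuple[str, ...] = ()
    certificate: str = ""


def _pools(split: Mapping[str, float], model: ModelSpec):
    pyr = sum(float(model.mode(m).pyr) * f for m, f in split.items())
    nadph = sum(float(model.mode(m).nadph_pool) * f for m, f in split.items())
    co2 = sum(float(model.mode(m).co2_gly) * f for m, f in split.items())
    atp = sum(float(model.mode(m).atp) * f for m, f in split.items())
    return pyr, nadph, co2, atp


def scenario_yields(
    split: Mapping[str, float],
    model: ModelSpec,
    routing_policy: str = "redox_closed",
    downstream: Mapping[str, float] | None = None,
) -> ScenarioResult:
    """Compute product yields for a given mode split.

    Policies:

    ``redox_closed``
        Solve the ethanol/acetate ratio so pooled NAD(P)H production
        exactly equals consumption; flagged infeasible (not raised) when
        no solution exists in [0, acetyl-CoA], e.g. when the acetate
        branch is deleted but the split leaves surplus NAD(P)H.
    ``all_ethanol``
        All acetyl-CoA to ethanol; NAD(P)H surplus reported; infeasible on
        a redox deficit.
    ``fixed``
        Caller supplies the downstream rates; the vector is audited as-is.
    """
    for m, f in split.items():
        if f < -_TOL:
            raise ValueError(f"negative split fraction {m}={f}")
    total = sum(split.values())
    if total > 1.0 + 1e-9:
        raise ValueError(f"split fractions sum to {total} > 1")
    slack = max(0.0, 1.0 - total)

    if routing_policy == "fixed":
        if downstream is None:
            raise ValueError("routing_policy='fixed' requires downstream rates")
        flux = FluxVector(fractions=dict(split), slack=slack, **dict(downstream))
        res = validate_flux(flux, model)
        return _finish(flux, model, res.nadph, res.atp_net, res.feasible(), "fixed rates")

    pyr, nadph, co2_gly, atp = _pools(split, model)
    pfl = pyr  # PFL carries the whole pool; excretion only via 'fixed'
    accoa = pfl
    formate = pfl
    fhl = formate if "FHL" in model.reactions else 0.0
    formate_exc = formate - fhl

    note = ""
    feasible = True
    if routing_policy == "redox_closed":
        adh = nadph / 2.0
        if adh > accoa + _TOL:
            feasible, note = False, "NAD(P)H surplus cannot be consumed (adh > AcCoA)"
            adh = accoa
        ack = max(0.0, accoa - adh)
        if "PTA_ACKA" not in model.reactions and ack > _TOL:
            feasible, note = False, "acetate branch deleted but redox closure needs it"
            ack = 0.0
        surplus = nadph - 2.0 * adh
    elif routing_policy == "all_ethanol":
        adh = accoa
        ack = 0.0
        surplus = nadph - 2.0 * adh
        if surplus < -_TOL:
            feasible, note = False, "NAD(P)H deficit under all-ethanol routing"
    else:
        raise ValueError(f"unknown routing policy {routing_policy!r}")

    flux = FluxVector(
        fractions=dict(split),
        pfl=pfl,
        fhl=fhl,
        adh=adh,
        ack=ack,
        formate_exc=formate_exc,
        slack=slack,
    )
    return _finish(flux, model, surplus, atp + ack, feasible, note)


def _finish(flux, model, surplus, atp_net, feasible, note) -> ScenarioResult:
    co2_gly = sum(
        float(model.mode(m).co2_gly) * f for m, f in flux.fractions.items()
    )
    return ScenarioResult(
        y_h2=flux.fhl + flux.nadh_h2,
        y_etoh=flux.adh + flux.pdc,
        y_ace=flux.ack,
        y_pyr=flux.pyr_exc,
        y_co2=co2_gly + flux.fhl + flux.pdc,
        nadph_surplus=surplus,
        atp_net=atp_net,
        flux=flux,
        feasible=feasible,
        note=note,
    )


# ---------------------------------------------------------------------------
# Linear programming maxima
# ---------------------------------------------------------------------------

_DOWNSTREAM_ORDER = ("pfl", "fhl", "adh", "ack", "pyr_exc", "pdc", "nadh_h2", "formate_exc")


def _variable_names(model: ModelSpec) -> list[str]:
    return list(model.mode_ids) + list(_DOWNSTREAM_ORDER) + ["slack", "surplus"]


def _balance_matrix(model: ModelSpec, allow_surplus: bool):
    """Equality constraints A x = b over the reaction-level flux space."""
    names = _variable_names(model)
    idx = {n: i for i, n in enumerate(names)}
    n = len(names)
    rows, rhs, labels = [], [], []

    def row(coeffs: dict[str, float], b: float, label: str):
        r = np.zeros(n)
        for k, v in coeffs.items():
            r[idx[k]] = v
        rows.append(r)
        rhs.append(b)
        labels.append(label)

    row({**{m: 1.0 for m in model.mode_ids}, "slack": 1.0}, 1.0, "substrate")
    row(
        {
            **{m: float(model.mode(m).pyr) for m in model.mode_ids},
            "pfl": -1.0,
            "pdc": -1.0,
            "pyr_exc": -1.0,
        },
        0.0,
        "pyruvate",
    )
    row({"pfl": 1.0, "fhl": -1.0, "formate_exc": -1.0}, 0.0, "formate")
    row({"pfl": 1.0, "adh": -1.0, "ack": -1.0}, 0.0, "acetyl-CoA")
    row(
        {
            **{m: float(model.mode(m).nadph_pool) for m in model.mode_ids},
            "adh": -2.0,
            "pdc": -1.0,
            "nadh_h2": -1.0,
            "surplus": -1.0,
        },
        0.0,
        "NAD(P)H",
    )

    ub = np.full(n, np.inf)
    alias = {"pyr_exc": "PYR_EXCRETION", "pdc": "PDC_ROUTE", "adh": "ADH_ACCOA",
             "ack": "PTA_ACKA"}
    for var in _DOWNSTREAM_ORDER:
        if var == "formate_exc":
            if not model.options.formate_excretion:
                ub[idx[var]] = 0.0
            continue
        if alias.get(var, var.upper()) not in model.reactions:
            ub[idx[var]] = 0.0
    if not allow_surplus:
        ub[idx["surplus"]] = 0.0
    return names, idx, np.array(rows), np.array(rhs), labels, ub


_OBJECTIVES = {
    "h2": {"fhl": 1.0, "nadh_h2": 1.0},
    "ethanol": {"adh": 1.0, "pdc": 1.0},
}


def max_yield(
    model: ModelSpec,
    objective: str = "h2",
    extra_constraints: Sequence[str] = (),
    allow_surplus: bool = True,
) -> OptimumResult:
    """Maximize a product yield by LP over the reaction-level flux space.

    ``objective`` is ``h2``, ``ethanol`` or ``min_h2_ethanol``. Extra
    constraints: ``no_acetate`` (ack = 0), ``equal_h2_ethanol``,
    ``no_surplus`` (equivalent to allow_surplus=False). Ties in the argmax
    are broken toward the lexicographically smallest flux vector.
    """
    if "no_surplus" in extra_constraints:
        allow_surplus = False
    names, idx, A, b, labels, ub = _balance_matrix(model, allow_surplus)
    n = len(names)

    if "no_acetate" in extra_constraints:
        ub[idx["ack"]] = 0.0

    minmax = objective == "min_h2_ethanol"
    if minmax:
        # add variable t with t <= h2, t <= ethanol; maximize t
        n_t = n + 1
        A = np.hstack([A, np.zeros((A.shape[0], 1))])
        ub = np.append(ub, np.inf)
        A_ub, b_ub = [], []
        for prod in ("h2", "ethanol"):
            r = np.zeros(n_t)
            for k, v in _OBJECTIVES[prod].items():
                r[idx[k]] = -v
            r[-1] = 1.0
            A_ub.append(r)
            b_ub.append(0.0)
        c = np.zeros(n_t)
        c[-1] = -1.0
        A_ub, b_ub = np.array(A_ub), np.array(b_ub)
    else:
        if objective not in _OBJECTIVES:
            raise ValueError(f"unknown objective {objective!r}")
        c = np.zeros(n)
        for k, v in _OBJECTIVES[objective].items():
            c[idx[k]] = -v
        A_ub = b_ub = None

    if "equal_h2_ethanol" in extra_constraints:
        r = np.zeros(len(c))
        for k, v in _OBJECTIVES["h2"].items():
            r[idx[k]] += v
        for k, v in _OBJECTIVES["ethanol"].items():
            r[idx[k]] -= v
        A = np.vstack([A, r])
        b = np.append(b, 0.0)
        labels = labels + ["H2 = ethanol"]

    bounds = [(0.0, u if np.isfinite(u) else None) for u in ub]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A, b_eq=b, bounds=bounds, method="highs")
    if not res.success:
        # identify a violated balance as certificate (best effort)
        return OptimumResult(
            objective=objective,
            value=None,
            flux=None,
            feasible=False,
            certificate=f"LP infeasible: {res.message}",
        )
    value = -res.fun

    # lexicographic tie-break: fix the objective, then minimize variables in
    # name order one at a time
    A_fix = np.vstack([A, -c])
    b_fix = np.append(b, value)
    x = res.x
    for j in range(n):
        cj = np.zeros(len(c))
        cj[j] = 1.0
        r2 = linprog(cj, A_ub=A_ub, b_ub=b_ub, A_eq=A_fix, b_eq=b_fix,
                     bounds=bounds, method="highs")
        if not r2.success:
            break
        x = r2.x
        A_fix = np.vstack([A_fix, cj])
        b_fix = np.append(b_fix, r2.fun)

    fracs = {m: max(0.0, x[idx[m]]) for m in model.mode_ids}
    flux = FluxVector(
        fractions=fracs,
        slack=max(0.0, x[idx["slack"]]),
        **{v: max(0.0, x[idx[v]]) for v in _DOWNSTREAM_ORDER},
    )
    resid = validate_flux(flux, model, tol=1e-6)
    active = tuple(
        lbl for lbl, row_a, row_b in zip(labels, A, b)
        if abs(row_a[: len(x)] @ x - row_b) <= 1e-9
    )
    return OptimumResult(
        objective=objective,
        value=float(value),
        flux=flux,
        feasible=resid.feasible(tol=1e-6),
        active_constraints=active,
    )
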