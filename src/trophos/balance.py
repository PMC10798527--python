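"""Mass-balance solve of the Ecopath master equation.

For every living group i the budget

    B_i (P/B)_i EE_i + I_i + BA_i
        = sum_j B_j (C/B)_j D_ij + E_i + F_i

must hold: production used within the system (left) equals predation,
emigration, and fishery losses (right).  Each living group supplies
exactly one unknown — EE when biomass was measured, biomass when EE was
fixed a priori.  The equation is linear in the unknown biomasses once
the known-biomass predation terms are moved to the constant side, so the
mixed problem is one linear solve followed by direct EE evaluation.

The ``ba_convention`` switch controls whether biomass accumulation and
immigration are applied on the production side (``"as_printed"``, the
default) or as right-side losses (``"canonical"``); with the default
BA = I = 0 parameterization the two coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .foodweb import (
    EcopathModel,
    TrophosError,
    ValidationError,
    production_rate,
)

__all__ = [
    "BalanceError",
    "NonIdentifiableError",
    "InfeasibleError",
    "BalancedModel",
    "solve_ecopath",
    "rebalance_by_scaling",
]

_COND_LIMIT = 1e12


class BalanceError(TrophosError):
    pass


class NonIdentifiableError(BalanceError):
    """The linear system for the unknown biomasses is singular."""


class InfeasibleError(BalanceError):
    """A solved biomass came out negative."""


@dataclass
class BalancedModel:
    """An EcopathModel with all B and EE populated.

    ``predation`` holds Q[i, j] = B_j (C/B)_j D_ij (mt km^-2 yr^-1) over
    the full id index; ``imbalance_report`` lists (group_id, EE) for
    groups whose EE exceeds 1 — a diagnostic, not an error, to be fixed
    by rescaling inputs.
    """

    model: EcopathModel
    predation: pd.DataFrame
    imbalance_report: list[tuple[int, float]]

    @property
    def ee(self) -> dict[int, float]:
        return {g.id: g.ee for g in self.model.groups if g.ee is not None}

    def consumption_rate(self, j: int) -> float:
        """c_j = B_j (C/B)_j for a living consumer."""
        g = self.model.group(j)
        if g.cb is None or g.biomass is None:
            return 0.0
        return g.biomass * g.cb


def _loss_terms(model: EcopathModel, gid: int, ba_convention: str) -> tuple[float, float]:
    """(left-side additions, right-side constant) for group gid, excluding predation."""
    g = model.group(gid)
    f = model.catch.total_removal(gid)
    if ba_convention == "as_printed":
        return g.immigration + g.ba, g.emigration + f
    if ba_convention == "canonical":
        return g.immigration, g.emigration + f + g.ba
    raise ValueError(f"unknown ba_convention {ba_convention!r}")


def solve_ecopath(model: EcopathModel, ba_convention: str = "as_printed") -> BalancedModel:
    """Solve the master equation for the mixed unknowns.

    Unknown biomasses (groups with ``ee_fixed``) are obtained from one
    linear solve; EE is then evaluated directly for the fixed-biomass
    groups, and detritus EE is reported from the detritus budget
    (consumption of the pool over inflow to the pool) as a diagnostic.
    """
    model = model.copy()
    model.validate()
    living = model.living_ids
    consumers = model.consumer_ids

    unknown_b = []
    for gid in living:
        g = model.group(gid)
        if g.biomass is None:
            if g.ee is None:
                raise ValidationError(f"group {gid}: both B and EE unset")
            unknown_b.append(gid)
        elif g.ee_fixed and g.ee is None:
            raise ValidationError(f"group {gid}: ee_fixed but EE unset")

    D = model.diet.table  # prey x consumer over full id space
    idx_u = {gid: k for k, gid in enumerate(unknown_b)}
    n_u = len(unknown_b)

    if n_u:
        A = np.zeros((n_u, n_u))
        b = np.zeros(n_u)
        for gid in unknown_b:
            i = idx_u[gid]
            g = model.group(gid)
            left_add, right_const = _loss_terms(model, gid, ba_convention)
            # B_i * PB_i * EE_i  -  sum_{j unknown} B_j CB_j D_ij = const
            A[i, i] += g.pb * g.ee
            rhs = right_const - left_add
            for j in consumers:
                d_ij = D.loc[gid, j]
                if d_ij == 0:
                    continue
                cj = model.group(j)
                if j in idx_u:
                    A[i, idx_u[j]] -= cj.cb * d_ij
                else:
                    rhs += cj.biomass * cj.cb * d_ij
            b[i] = rhs
        cond = np.linalg.cond(A) if n_u else 0.0
        if not np.isfinite(cond) or cond > _COND_LIMIT:
            raise NonIdentifiableError(
                f"biomass system ill-conditioned (cond={cond:.3g}) "
                f"over groups {unknown_b}"
            )
        x = np.linalg.solve(A, b)
        neg = [(unknown_b[k], x[k]) for k in range(n_u) if x[k] < 0]
        if neg:
            raise InfeasibleError(
                "negative estimated biomass: "
                + ", ".join(f"group {g}={v:.4g}" for g, v in neg)
            )
        for gid, val in zip(unknown_b, x):
            g = model.group(gid)
            model.groups[model.ids.index(gid)] = replace(g, biomass=float(val))
        model._by_id = {g.id: g for g in model.groups}

    # predation matrix over the full index
    ids = model.ids
    Q = pd.DataFrame(0.0, index=ids, columns=ids)
    for j in consumers:
        cj = model.group(j)
        col = D[j]
        Q[j] = col.values * cj.biomass * cj.cb

    # EE for fixed-biomass living groups
    imbalance = []
    for gid in living:
        g = model.group(gid)
        prod = production_rate(g)
        left_add, right_const = _loss_terms(model, gid, ba_convention)
        losses = float(Q.loc[gid].sum()) + right_const - left_add
        if gid in idx_u:
            ee = g.ee  # fixed input
        else:
            ee = losses / prod if prod > 0 else 0.0
            model.groups[model.ids.index(gid)] = replace(g, ee=float(ee))
        if ee is not None and ee > 1:
            imbalance.append((gid, float(ee)))
    model._by_id = {g.id: g for g in model.groups}

    # detritus EE: consumption of the pool / inflow to the pool (diagnostic)
    for gid in model.detritus_ids:
        inflow = _detritus_inflow(model, Q, gid)
        consumed = float(Q.loc[gid].sum())
        g = model.group(gid)
        ee = consumed / inflow if inflow > 0 else 0.0
        model.groups[model.ids.index(gid)] = replace(g, ee=float(ee))
    model._by_id = {g.id: g for g in model.groups}

    return BalancedModel(model=model, predation=Q, imbalance_report=imbalance)


_POOL_NAMES = {
    "invertebrate_eggs": ("invertebrate egg",),
    "fish_eggs": ("fish egg",),
    "pelagic_detritus": ("pelagic detritus",),
    "fishery_offal": ("offal",),
    "benthic_detritus": ("benthic detritus",),
}


def detritus_destination_of(model: EcopathModel, gid: int) -> str | None:
    """Match a detritus group to its fate-table destination label by name."""
    name = model.group(gid).name.lower()
    for dest, keys in _POOL_NAMES.items():
        if any(k in name for k in keys):
            return dest
    return None


def _detritus_inflow(model: EcopathModel, Q: pd.DataFrame, gid: int) -> float:
    """Feces + unconsumed production + discards routed into pool gid."""
    dest = detritus_destination_of(model, gid)
    if dest is None or model.fates is None:
        return 0.0
    total = 0.0
    for lid in model.living_ids:
        g = model.group(lid)
        if not model.fates.has_group(lid):
            continue
        if g.category == "consumer" and g.cb and g.ae is not None:
            feces = g.biomass * g.cb * (1.0 - g.ae)
            total += feces * model.fates.routing(lid, "feces").get(dest, 0.0)
        prod = production_rate(g)
        ee = g.ee if g.ee is not None else 1.0
        unconsumed = max(prod * (1.0 - min(ee, 1.0)), 0.0)
        total += unconsumed * model.fates.routing(lid, "senescence").get(dest, 0.0)
    if dest == "fishery_offal":
        total += sum(model.catch.total_discards(i) for i in model.living_ids)
    return total


def rebalance_by_scaling(model: EcopathModel, scalers: dict[int, float]) -> EcopathModel:
    """Return a copy with biomasses multiplied by per-group scalers.

    Raises for non-positive scalers or scalers aimed at groups whose
    biomass is to be estimated (B unset).
    """
    out = model.copy()
    for gid, s in scalers.items():
        if s <= 0:
            raise ValueError(f"scaler for group {gid} must be positive")
        g = out.group(gid)
        if g.biomass is None:
            raise ValueError(f"group {gid} has no biomass to scale (B is estimated)")
        out.groups[out.ids.index(gid)] = replace(g, biomass=g.biomass * s)
    out._by_id = {g.id: g for g in out.groups}
    return out
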