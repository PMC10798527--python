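"""Trophic levels and pre-balance (PREBAL) diagnostics.

Trophic level is 1 for producers and detritus and solves the linear
system TL_j = 1 + sum_i D_ij TL_i for consumers (cycles are fine).
Fleets get 1 plus the catch-share-weighted mean TL of the groups they
remove (landings + discards).

The PREBAL report screens a parameterization before balancing: biomass
densities should span 5-7 orders of magnitude, log10 biomass should
decline gently with trophic level, P/B should never exceed C/B, and EE
should stay below 1 (homeotherms are expected P/B-low / C/B-high
exceptions and are flagged rather than failed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .foodweb import DietMatrix, EcopathModel, FleetCatch, FunctionalGroup, TrophosError

__all__ = ["PrebalReport", "trophic_levels", "prebal"]


class MetricsError(TrophosError):
    pass


def trophic_levels(
    diet: DietMatrix,
    catch: FleetCatch | None = None,
    *,
    producer_ids: Sequence[int] = (),
    detritus_ids: Sequence[int] = (),
    consumer_ids: Sequence[int] = (),
    fleet_ids: Sequence[int] = (),
) -> dict[int, float]:
    """Per-group trophic level from the diet matrix (and catch for fleets)."""
    base = {int(i): 1.0 for i in list(producer_ids) + list(detritus_ids)}
    consumers = [int(j) for j in consumer_ids]
    n = len(consumers)
    pos = {j: k for k, j in enumerate(consumers)}
    A = np.eye(n)
    b = np.ones(n)
    for j in consumers:
        col = diet.column(j)
        if float(col.sum()) == 0:
            raise MetricsError(f"consumer {j} has an all-zero diet column")
        for i, d in col.items():
            if d == 0:
                continue
            i = int(i)
            if i in pos:
                A[pos[j], pos[i]] -= d
            else:
                b[pos[j]] += d * base.get(i, 1.0)
    tl = dict(base)
    if n:
        sol = np.linalg.solve(A, b)
        for j, v in zip(consumers, sol):
            tl[j] = float(v)
    if catch is not None:
        for f in fleet_ids:
            f = int(f)
            weights = {}
            for gid in catch.landings.index:
                w = 0.0
                if f in catch.landings.columns:
                    w += float(catch.landings.loc[gid, f])
                if f in catch.discards.columns:
                    w += float(catch.discards.loc[gid, f])
                if w > 0:
                    weights[int(gid)] = w
            total = sum(weights.values())
            if total > 0:
                tl[f] = 1.0 + sum(w * tl.get(g, 1.0) for g, w in weights.items()) / total
            else:
                tl[f] = float("nan")
    return tl


def trophic_levels_model(model: EcopathModel) -> dict[int, float]:
    """Convenience wrapper taking index roles from an EcopathModel."""
    return trophic_levels(
        model.diet,
        model.catch,
        producer_ids=model.producer_ids,
        detritus_ids=model.detritus_ids,
        consumer_ids=model.consumer_ids,
        fleet_ids=model.fleet_ids,
    )


@dataclass
class PrebalReport:
    span_orders: int
    slope: float
    intercept: float
    slope_subset: list[int]
    pb_cb_violations: list[int]
    ee_violations: list[int]
    homeotherm_flags: list[int]

    def passes(self, span_range=(5, 7)) -> bool:
        return (
            span_range[0] <= self.span_orders <= span_range[1]
            and not self.pb_cb_violations
            and not self.ee_violations
        )


def prebal(
    model: EcopathModel | Sequence[FunctionalGroup],
    tls: dict[int, float],
    slope_subset: Sequence[int] | None = None,
) -> PrebalReport:
    """Pre-balance diagnostics over a group table.

    ``span_orders`` is floor(log10(max B / min B)) over all functional
    groups with positive biomass (detritus included).  The slope of
    log10(B) on TL is fitted by least squares over ``slope_subset``
    (default: all living groups with biomass; detritus excluded from the
    regression).
    """
    groups = list(model.groups) if isinstance(model, EcopathModel) else list(model)
    groups = [g for g in groups if g.category != "fleet"]
    with_b = [g for g in groups if g.biomass is not None and g.biomass > 0]
    if not with_b:
        raise MetricsError("no groups with positive biomass")
    bs = [g.biomass for g in with_b]
    span = int(math.floor(math.log10(max(bs) / min(bs))))

    if slope_subset is None:
        subset = [g.id for g in with_b if g.is_living]
    else:
        subset = [int(i) for i in slope_subset]
    pts = [
        (tls[g.id], math.log10(g.biomass))
        for g in with_b
        if g.id in set(subset) and g.id in tls
    ]
    if len(pts) < 3:
        raise MetricsError(f"slope subset has {len(pts)} points; need >= 3")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    slope, intercept = np.polyfit(x, y, 1)

    pb_cb = [
        g.id
        for g in groups
        if g.pb is not None and g.cb is not None and g.cb > 0 and g.pb > g.cb
    ]
    ee_viol = [g.id for g in groups if g.ee is not None and g.ee > 1]
    homeo = [g.id for g in groups if g.is_homeotherm]
    return PrebalReport(
        span_orders=span,
        slope=float(slope),
        intercept=float(intercept),
        slope_subset=subset,
        pb_cb_violations=pb_cb,
        ee_violations=ee_viol,
        homeotherm_flags=homeo,
    )
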