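"""Donor-normalized energy-flow network built from a balanced model.

The balanced consumption matrix is transposed into flow fractions: entry
A[j, i] is the fraction of group i's total production that flows to
destination j.  Over living consumers only this is

    A_ji = D_ij c_j / sum_j (D_ij c_j),      c_j = B_j (C/B)_j,

the donor-normalized share of what is actually consumed.  The expanded
network rescales consumer entries by EE_i (the consumed-plus-fished
share of production) and closes every living column to exactly 1 by
routing fishery removals to landings/offal, emigration to export, and
the unconsumed remainder (1 - EE_i) to egg and detritus pools per the
group's senescence fate row.

The network also carries the intake-side bioenergetic split used by the
time-dynamic model: of each consumer's intake, P/Q becomes production,
(1 - AE) is feces routed per the feces fate row, and (AE - P/Q) is
excreted to the ammonium pool, so the intake budget closes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .balance import BalancedModel, detritus_destination_of
from .foodweb import ConfigurationError, DetritusFateTable, production_rate, pq_ratio

__all__ = ["TrophicNetwork", "transpose_consumers", "expand_fates", "POOL_LABELS"]

# pseudo-pool row labels (used when the model has no matching detritus group)
POOL_LABELS = ("nh4", "no3", "export", "landings")


@dataclass
class TrophicNetwork:
    """Flow-fraction matrix plus the intake split needed for dynamics.

    ``A``: DataFrame, rows = destinations (group ids plus pool labels),
    columns = sources (living group ids and detritus group ids); each
    living column sums to 1.  ``consumption_rates``: c_j per consumer.
    ``intake_split``: per consumer j -> (pq, ae, feces routing dict).
    """

    A: pd.DataFrame
    consumption_rates: dict[int, float]
    intake_split: dict[int, tuple[float, float, dict[str, float]]]
    pool_rows: dict[str, object] = field(default_factory=dict)
    balanced: BalancedModel | None = None

    def column(self, i) -> pd.Series:
        return self.A[i]

    def flow(self, src, dst) -> float:
        return float(self.A.loc[dst, src])

    def to_edgelist(self) -> pd.DataFrame:
        rows = []
        for src in self.A.columns:
            col = self.A[src]
            for dst, f in col.items():
                if f != 0.0:
                    rows.append((src, dst, float(f)))
        return pd.DataFrame(rows, columns=["from_id", "to_id", "fraction"])


def transpose_consumers(bm: BalancedModel) -> pd.DataFrame:
    """Consumer-only flow fractions A[j, i] = D_ij c_j / sum_j D_ij c_j.

    Columns of prey with zero total consumption are left all-zero.
    """
    model = bm.model
    living = model.living_ids
    consumers = model.consumer_ids
    A = pd.DataFrame(0.0, index=consumers, columns=living)
    for i in living:
        flows = {j: bm.predation.loc[i, j] for j in consumers}
        total = sum(flows.values())
        if total > 0:
            for j, q in flows.items():
                A.loc[j, i] = q / total
    return A


def _dest_row(model, dest: str):
    """Map a fate destination to a detritus group id or a pool label."""
    for gid in model.detritus_ids:
        if detritus_destination_of(model, gid) == dest:
            return gid
    return dest if dest in ("nh4", "export") else dest


def expand_fates(bm: BalancedModel, fates: DetritusFateTable | None = None) -> TrophicNetwork:
    """Expand the consumer transpose with detritus, egg, offal, nutrient,
    landings, and export pools so every living column sums to 1."""
    model = bm.model
    if fates is None:
        fates = model.fates
    if fates is None:
        raise ConfigurationError("no detritus fate table supplied")
    living = model.living_ids
    consumers = model.consumer_ids
    detritus = model.detritus_ids

    dest_rows = {d: _dest_row(model, d) for d in
                 ("invertebrate_eggs", "fish_eggs", "pelagic_detritus",
                  "fishery_offal", "benthic_detritus", "nh4", "export")}
    offal_row = dest_rows["fishery_offal"]

    index = list(dict.fromkeys(
        living + detritus + [dest_rows[d] for d in dest_rows] + list(POOL_LABELS)
    ))
    A = pd.DataFrame(0.0, index=index, columns=living + detritus)

    for i in living:
        g = model.group(i)
        prod = production_rate(g)
        if prod <= 0:
            continue
        if not fates.has_group(i):
            raise ConfigurationError(f"no fate rows for living group {i} ({g.name})")
        for j in consumers:
            q = bm.predation.loc[i, j]
            if q:
                A.loc[j, i] += q / prod
        A.loc["landings", i] += model.catch.total_landings(i) / prod
        A.loc[offal_row, i] += model.catch.total_discards(i) / prod
        A.loc["export", i] += (g.emigration + g.ba) / prod
        used = float(A[i].sum())
        senescence = max(1.0 - used, 0.0)
        if senescence > 0:
            routing = fates.routing(i, "senescence")
            for dest, frac in routing.items():
                if frac:
                    A.loc[dest_rows.get(dest, dest), i] += senescence * frac

    # detritus columns: consumed share split among consumers, remainder exported
    for d in detritus:
        consumed = {j: bm.predation.loc[d, j] for j in consumers}
        total_consumed = sum(consumed.values())
        gd = model.group(d)
        ee_d = gd.ee if gd.ee is not None else None
        denom = total_consumed / ee_d if (ee_d and total_consumed > 0) else total_consumed
        if denom and denom > 0:
            for j, q in consumed.items():
                if q:
                    A.loc[j, d] = q / denom
            A.loc["export", d] = max(1.0 - total_consumed / denom, 0.0)

    # intake-side split for the dynamic model
    intake_split: dict[int, tuple[float, float, dict[str, float]]] = {}
    for j in consumers:
        g = model.group(j)
        ae = g.ae if g.ae is not None else 0.8
        pq = pq_ratio(g)
        if pq > ae:
            raise ConfigurationError(
                f"group {j} ({g.name}): P/Q={pq:.3f} exceeds AE={ae:.3f}; "
                "the intake budget cannot close"
            )
        feces_routing = fates.routing(j, "feces") if fates.has_group(j) else {}
        intake_split[j] = (pq, ae, feces_routing)

    c = {j: bm.consumption_rate(j) for j in consumers}
    return TrophicNetwork(
        A=A,
        consumption_rates=c,
        intake_split=intake_split,
        pool_rows=dest_rows,
        balanced=bm,
    )
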