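"""Synthetic inputs with the statistical structure the pipeline assumes.

Food webs are built flow-first: consumption flows are drawn so that
every living group's ecotrophic efficiency lands in a target range by
construction, and the diet matrix is derived from the flows afterwards.
(Diet-first construction frequently yields EE > 1 — exactly the kind of
imbalance real parameterizations exhibit — so building flows first is
what guarantees a balanceable web.)  Upwelling series are seasonal
sinusoids with noise; trawl surveys are zero-inflated lognormal
catches; diet sources are Dirichlet-perturbed observations with sample
sizes, unidentified material, and broad prey labels.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diet import DietSource
from .foodweb import (
    DetritusFateTable,
    DietMatrix,
    EcopathModel,
    FleetCatch,
    FunctionalGroup,
)
from .physics import UpwellingSeries

__all__ = ["SyntheticSpec", "make_toy_web", "make_upwelling", "make_survey",
           "make_diet_sources"]


@dataclass(frozen=True)
class SyntheticSpec:
    # food web
    n_groups: int = 8                # living groups (incl. producers)
    n_producers: int = 2
    n_fleets: int = 1
    trophic_depth: int = 3
    ee_range: tuple[float, float] = (0.2, 0.9)
    biomass_log10_range: tuple[float, float] = (-3.0, 2.0)
    detritivory: bool = True
    seed: int = 0
    # upwelling
    upwelling_mean: float = 0.5      # m^2 s^-1
    upwelling_amplitude: float = 1.0
    upwelling_noise_sd: float = 0.2
    upwelling_years: int = 1
    # survey
    zero_probability: float = 0.5
    log_mu: float = 0.0
    log_sigma: float = 1.0
    n_hauls: int = 100
    # diet
    n_sources: int = 3
    sample_size_range: tuple[int, int] = (10, 100)

    def __post_init__(self) -> None:
        lo, hi = self.ee_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("target EE range must be a sub-interval of (0, 1)")
        if self.n_groups < 3:
            raise ValueError("need at least 3 living groups")
        if self.n_producers >= self.n_groups:
            raise ValueError("need at least one consumer")


def make_toy_web(spec: SyntheticSpec) -> EcopathModel:
    """A balanceable web: EE of every living group lands in the target
    range when solved, because flows are drawn first and the residual of
    each group's usable production is topped up as emigration (plankton
    and low trophic levels) or fishery catch (upper trophic levels)."""
    rng = np.random.default_rng(spec.seed)
    n_live = spec.n_groups
    n_prod = spec.n_producers
    n_cons = n_live - n_prod
    depth = max(1, min(spec.trophic_depth, n_cons))

    live_ids = list(range(1, n_live + 1))
    det_ids = [n_live + 1, n_live + 2]  # pelagic, benthic detritus
    fleet_ids = list(range(n_live + 3, n_live + 3 + spec.n_fleets))
    all_ids = live_ids + det_ids + fleet_ids

    lo, hi = spec.biomass_log10_range
    B = 10.0 ** rng.uniform(lo, hi, n_live)
    layer = np.zeros(n_live, dtype=int)  # 0 = producer
    layer[n_prod:] = 1 + (np.arange(n_cons) * depth) // max(n_cons, 1)
    layer[n_prod:] = np.clip(layer[n_prod:], 1, depth)

    pb = np.empty(n_live)
    pb[:n_prod] = rng.uniform(150.0, 250.0, n_prod)
    for k in range(n_prod, n_live):
        pb[k] = 10.0 ** rng.uniform(1.8 - 0.8 * layer[k], 2.4 - 0.8 * layer[k])
    pq = rng.uniform(0.15, 0.30, n_live)
    cb = np.where(np.arange(n_live) < n_prod, 0.0, pb / pq)

    u = rng.uniform(*spec.ee_range, size=n_live)  # target EE
    P = B * pb
    avail = u * P  # usable production

    # scale each consumer layer so its demand fits in 90% of what is below
    for ell in range(1, depth + 1):
        members = np.nonzero(layer == ell)[0]
        if not len(members):
            continue
        below = np.nonzero(layer < ell)[0]
        pool = 0.9 * avail[below].sum()
        demand = (B[members] * cb[members]).sum()
        if demand > pool and demand > 0:
            B[members] *= pool / demand
            P = B * pb
            avail = u * P

    det_B = rng.uniform(5.0, 20.0, 2)
    det_avail = det_B * 10.0 if spec.detritivory else np.zeros(2)

    # the first layer-1 consumer is an obligate benthic detritivore
    # (infauna-like); its demand is sized to fit the benthic supply
    detritivore = None
    if spec.detritivory:
        l1 = [k for k in range(n_prod, n_live) if layer[k] == 1]
        if l1:
            detritivore = l1[0]
            demand = B[detritivore] * cb[detritivore]
            cap = 0.85 * det_avail[1]
            if demand > cap:
                B[detritivore] *= cap / demand
                P[detritivore] = B[detritivore] * pb[detritivore]
                avail[detritivore] = u[detritivore] * P[detritivore]

    remaining = np.concatenate([avail.copy(), det_avail.copy()])
    q = np.zeros((n_live + 2, n_live))  # flows prey x consumer
    for j in range(n_prod, n_live):
        demand = B[j] * cb[j]
        if j == detritivore:
            idx = [n_live + 1]
        else:
            allowed = list(np.nonzero(layer < layer[j])[0])
            det_ok = spec.detritivory and layer[j] == 1
            idx = allowed + ([n_live, n_live + 1] if det_ok else [])
        rem = remaining[idx]
        pref = rng.uniform(0.2, 1.0, len(idx))
        w = rem * pref
        if w.sum() <= 0:
            continue
        # cap each draw at 95% of what remains so later consumers in the
        # same layer always find something to eat
        draw = np.minimum(demand * w / w.sum(), 0.95 * rem)
        for ii, dk in zip(idx, draw):
            q[ii, j] += dk
            remaining[ii] -= dk
        realized = float(draw.sum())
        if realized < demand * (1 - 1e-12) and realized > 0:
            # prey ran short: shrink this consumer's rates (keeping P/Q) so
            # its demand matches what it actually obtained, then refresh its
            # own usable production for the layers above
            cb[j] = realized / B[j]
            pb[j] = pq[j] * cb[j]
            P[j] = B[j] * pb[j]
            avail[j] = u[j] * P[j]
            remaining[j] = avail[j]

    consumed = q[:n_live].sum(axis=1)
    topup = np.maximum(avail - consumed, 0.0)
    emigration = np.zeros(n_live)
    landings = pd.DataFrame(0.0, index=all_ids, columns=fleet_ids)
    discards = pd.DataFrame(0.0, index=all_ids, columns=fleet_ids)
    fishable = layer >= max(1, depth // 2 + 1)
    for k in range(n_live):
        if spec.n_fleets and fishable[k]:
            shares = rng.dirichlet(np.ones(spec.n_fleets))
            disc_frac = rng.uniform(0.0, 0.2)
            gid = live_ids[k]
            landings.loc[gid] = topup[k] * shares * (1 - disc_frac)
            discards.loc[gid] = topup[k] * shares * disc_frac
        else:
            emigration[k] = topup[k]

    diet = pd.DataFrame(0.0, index=all_ids, columns=all_ids)
    for j in range(n_prod, n_live):
        total = q[:, j].sum()
        if total > 0:
            for i in range(n_live):
                diet.loc[live_ids[i], live_ids[j]] = q[i, j] / total
            diet.loc[det_ids[0], live_ids[j]] = q[n_live, j] / total
            diet.loc[det_ids[1], live_ids[j]] = q[n_live + 1, j] / total

    groups = []
    for k, gid in enumerate(live_ids):
        cat = "producer" if k < n_prod else "consumer"
        groups.append(FunctionalGroup(
            id=gid, name=f"{'producer' if k < n_prod else 'consumer'} {gid}",
            category=cat, biomass=float(B[k]), pb=float(pb[k]),
            cb=None if cat == "producer" else float(cb[k]),
            ae=None if cat == "producer" else 0.8,
            ee=None, emigration=float(emigration[k]),
            retention=1.0 if (k == detritivore or layer[k] > 1) else 0.0,
        ))
    groups.append(FunctionalGroup(id=det_ids[0], name="pelagic detritus",
                                  category="detritus", biomass=float(det_B[0]),
                                  pb=0.0, cb=0.0, retention=0.0))
    groups.append(FunctionalGroup(id=det_ids[1], name="benthic detritus",
                                  category="detritus", biomass=float(det_B[1]),
                                  pb=0.0, cb=0.0, retention=1.0))
    for fid in fleet_ids:
        groups.append(FunctionalGroup(id=fid, name=f"fleet {fid}", category="fleet"))

    fate_rows = []
    for gid in live_ids:
        split = rng.uniform(0.2, 0.8)
        fate_rows += [
            (gid, "feces", "pelagic_detritus", round(split, 6)),
            (gid, "feces", "benthic_detritus", round(1 - split, 6)),
            (gid, "senescence", "pelagic_detritus", round(split, 6)),
            (gid, "senescence", "benthic_detritus", round(1 - split, 6)),
            (gid, "excretion", "nh4", 1.0),
        ]
    fates = DetritusFateTable(pd.DataFrame(
        fate_rows, columns=["group_id", "flow_class", "destination", "fraction"]
    ))

    model = EcopathModel(
        groups=groups,
        diet=DietMatrix(diet),
        catch=FleetCatch(landings, discards),
        fates=fates,
        subregion_id="synthetic",
    )
    model.validate()
    return model


def make_upwelling(spec: SyntheticSpec) -> UpwellingSeries:
    """Seasonal upwelling forcing: summer-peaked sinusoid plus noise.

    The annual mean equals ``upwelling_mean`` up to noise; winter values
    go negative (downwelling) when the amplitude exceeds the mean.
    """
    rng = np.random.default_rng(spec.seed + 1)
    days = spec.upwelling_years * 365
    doy = np.arange(days) % 365
    # peak near day 200 (late July)
    signal = spec.upwelling_mean + spec.upwelling_amplitude * np.cos(
        2 * np.pi * (doy - 200) / 365.0
    )
    noise = rng.normal(0.0, spec.upwelling_noise_sd, days)
    dates = pd.date_range("2001-01-01", periods=days, freq="D")
    return UpwellingSeries(dates, signal + noise)


def make_survey(spec: SyntheticSpec) -> tuple[pd.DataFrame, float]:
    """Zero-inflated lognormal haul table and its true mean density.

    Hauls are zero with probability ``zero_probability``, otherwise
    lognormal(log_mu, log_sigma); the true mean is
    (1 - p) exp(mu + sigma^2/2).
    """
    rng = np.random.default_rng(spec.seed + 2)
    zero = rng.random(spec.n_hauls) < spec.zero_probability
    vals = np.where(
        zero, 0.0, rng.lognormal(spec.log_mu, spec.log_sigma, spec.n_hauls)
    )
    truth = (1 - spec.zero_probability) * float(
        np.exp(spec.log_mu + spec.log_sigma ** 2 / 2)
    )
    df = pd.DataFrame({
        "station_id": np.arange(spec.n_hauls),
        "subregion": 1,
        "survey": "synthetic",
        "species": "synthetic species",
        "value": vals,
        "value_kind": "volumetric",
    })
    return df, truth


def make_diet_sources(
    spec: SyntheticSpec, prey_labels: list[str] | None = None
) -> tuple[list[DietSource], dict[str, float]]:
    """Dirichlet-true diet observed by several noisy sources.

    Each source perturbs the true diet (concentration grows with its
    sample size), carries an 'unidentified' mass, and relabels one prey
    as a broad label ('broadprey') so standardization and
    disaggregation are exercised.  Returns (sources, true diet).
    """
    rng = np.random.default_rng(spec.seed + 3)
    labels = prey_labels or ["prey A", "prey B", "prey C", "prey D"]
    truth = rng.dirichlet(np.ones(len(labels)) * 2.0)
    true_diet = dict(zip(labels, truth.tolist()))
    sources = []
    for k in range(spec.n_sources):
        n = int(rng.integers(*spec.sample_size_range))
        obs = rng.dirichlet(truth * n * 2.0)
        prey = {lab: float(v * 100.0) for lab, v in zip(labels, obs)}
        prey["unidentified"] = float(rng.uniform(0, 30))
        sources.append(DietSource(predator="synthetic predator", n=n, prey=prey))
    return sources, true_diet
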