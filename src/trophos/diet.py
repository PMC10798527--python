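"""Diet-matrix compilation and fisheries-landings reallocation.

Diet columns are built from heterogeneous stomach-content and
frequency-of-occurrence sources: unidentified material is dropped and
the rest renormalized; multiple sources for one predator are averaged
weighted by sample size; predator species are combined into functional
groups weighted by their biomass share; prey labels broader than the
model's groups are split across member groups in proportion to biomass,
restricted to members actually observed in that predator's diet.

Landings reported on coarse latitude zones are redistributed to model
latitude bins by interval overlap, spread across the shelf by
occurrence proportions, mapped from gear categories to fleets, and
augmented with discards via per-fleet-per-group rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .foodweb import TrophosError

__all__ = [
    "DietSource",
    "standardize_diet",
    "merge_sources",
    "species_to_group",
    "disaggregate_broad_prey",
    "rescale_prey",
    "legacy_average",
    "LandingsZoneTable",
    "latitude_overlap",
    "reallocate_landings",
]

UNIDENTIFIED_LABELS = {"unidentified", "unid", "unknown"}


class DietError(TrophosError):
    pass


@dataclass
class DietSource:
    """One predator's diet observations from a single study.

    ``prey``: label -> summed amount (prey weight, or %FO for sources
    on a frequency-of-occurrence basis — treated identically after
    normalization).  ``n`` is the number of predator individuals.
    """

    predator: str
    n: int
    prey: dict[str, float]
    basis: str = "weight"  # or "frequency-of-occurrence"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DietError("sample size must be >= 1")
        if any(v < 0 for v in self.prey.values()):
            raise DietError("negative prey amounts")


def _is_unidentified(label: str) -> bool:
    return label.strip().lower() in UNIDENTIFIED_LABELS


def standardize_diet(src: DietSource) -> dict[str, float]:
    """Drop unidentified material and renormalize to proportions."""
    identified = {k: v for k, v in src.prey.items() if not _is_unidentified(k) and v > 0}
    total = sum(identified.values())
    if total <= 0:
        raise DietError(f"{src.predator}: no identified prey")
    return {k: v / total for k, v in identified.items()}


def merge_sources(sources: list[DietSource]) -> dict[str, float]:
    """Sample-size-weighted mean of per-source diet proportions."""
    if not sources:
        raise DietError("no sources")
    diets = [standardize_diet(s) for s in sources]
    weights = np.array([s.n for s in sources], dtype=float)
    weights /= weights.sum()
    out: dict[str, float] = {}
    for w, d in zip(weights, diets):
        for k, v in d.items():
            out[k] = out.get(k, 0.0) + w * v
    return out


def species_to_group(
    diets: dict[str, dict[str, float]], biomass_shares: dict[str, float]
) -> dict[str, float]:
    """Biomass-share-weighted combination of member-species diets."""
    total = sum(biomass_shares.values())
    if total <= 0:
        raise DietError("biomass shares must sum to a positive value")
    out: dict[str, float] = {}
    for sp, d in diets.items():
        w = biomass_shares.get(sp, 0.0) / total
        for k, v in d.items():
            out[k] = out.get(k, 0.0) + w * v
    s = sum(out.values())
    return {k: v / s for k, v in out.items()} if s > 0 else out


def disaggregate_broad_prey(
    diet: dict[str, float],
    broad_map: dict[str, list[str]],
    prey_biomass: dict[str, float],
    observed_prey: set[str] | None = None,
) -> tuple[dict[str, float], list[str]]:
    """Split broad prey labels across member groups in proportion to
    biomass, restricted to members observed in this predator's diet.

    A broad label none of whose members were observed is split across
    all members by biomass, with a warning.
    """
    observed = observed_prey if observed_prey is not None else set(diet)
    out: dict[str, float] = {}
    warnings: list[str] = []
    for label, share in diet.items():
        if label not in broad_map:
            out[label] = out.get(label, 0.0) + share
            continue
        members = broad_map[label]
        usable = [m for m in members if m in observed]
        if not usable:
            warnings.append(
                f"broad prey {label!r}: no member observed; allocating by biomass"
            )
            usable = list(members)
        w = np.array([max(prey_biomass.get(m, 0.0), 0.0) for m in usable])
        if w.sum() <= 0:
            w = np.ones(len(usable))
        w = w / w.sum()
        for m, frac in zip(usable, w):
            out[m] = out.get(m, 0.0) + share * float(frac)
    return out, warnings


def rescale_prey(diet: dict[str, float], prey: str, new_value: float) -> dict[str, float]:
    """Pin one prey's proportion; renormalize the rest proportionally."""
    if prey not in diet:
        raise DietError(f"prey {prey!r} not in diet")
    if not (0 <= new_value < 1):
        raise DietError("new proportion must lie in [0, 1)")
    rest = {k: v for k, v in diet.items() if k != prey}
    rest_total = sum(rest.values())
    if rest_total <= 0:
        raise DietError("cannot rescale: no other prey to absorb the change")
    scale = (1.0 - new_value) / rest_total
    out = {k: v * scale for k, v in rest.items()}
    out[prey] = new_value
    return out


def legacy_average(new_diet: dict[str, float], legacy_diet: dict[str, float]) -> dict[str, float]:
    """Unweighted mean of a new diet column and a legacy one, renormalized."""
    keys = set(new_diet) | set(legacy_diet)
    out = {k: 0.5 * (new_diet.get(k, 0.0) + legacy_diet.get(k, 0.0)) for k in keys}
    s = sum(out.values())
    if s <= 0:
        raise DietError("both diets empty")
    return {k: v / s for k, v in out.items()}


# ---------------------------------------------------------------------------
# Fisheries landings reallocation
# ---------------------------------------------------------------------------

@dataclass
class LandingsZoneTable:
    """Landings on coarse source latitude zones.

    ``table`` columns: lat_min, lat_max, group_id, gear, landed_mt.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"lat_min", "lat_max", "group_id", "gear", "landed_mt"}
        missing = req - set(self.table.columns)
        if missing:
            raise DietError(f"landings table missing columns: {sorted(missing)}")
        if (self.table["lat_min"] >= self.table["lat_max"]).any():
            raise DietError("lat_min must be < lat_max")
        if (self.table["landed_mt"] < 0).any():
            raise DietError("negative landings")


def latitude_overlap(zone: tuple[float, float], bin_: tuple[float, float]) -> float:
    """Fraction of the source zone overlapping a model latitude bin."""
    lo = max(zone[0], bin_[0])
    hi = min(zone[1], bin_[1])
    if hi <= lo:
        return 0.0
    return (hi - lo) / (zone[1] - zone[0])


def reallocate_landings(
    z: LandingsZoneTable,
    lat_bins: dict[str, tuple[float, float]],
    cross_shelf: dict[int, dict[str, float]],
    gear_map: dict[str, str],
    discard_rates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Redistribute zone landings to (subregion, fleet) cells.

    ``lat_bins``: model bin name -> (lat_min, lat_max).
    ``cross_shelf``: group_id -> {shelf zone name: proportion} (sums to
    1; subregion key = f"{lat_bin}:{shelf_zone}").
    ``gear_map``: gear category -> fleet name (unmapped gear raises).
    ``discard_rates``: optional per (group_id, fleet) discard-to-landings
    ratio (long format: group_id, fleet, rate).

    Returns long format: subregion, group_id, fleet, landed_mt,
    discard_mt.  Total landed weight is conserved whenever the latitude
    bins jointly cover each source zone.
    """
    unmapped = sorted(set(z.table["gear"]) - set(gear_map))
    if unmapped:
        raise DietError(f"unmapped gear categories: {unmapped}")
    rates = {}
    if discard_rates is not None:
        for r in discard_rates.itertuples():
            rates[(int(r.group_id), str(r.fleet))] = float(r.rate)

    rows = []
    for rec in z.table.itertuples():
        fleet = gear_map[rec.gear]
        shelf = cross_shelf.get(int(rec.group_id))
        if shelf is None:
            shelf = {"inner": 1.0}
        shelf_total = sum(shelf.values())
        for bname, bounds in lat_bins.items():
            ov = latitude_overlap((rec.lat_min, rec.lat_max), bounds)
            if ov == 0.0:
                continue
            for zone, prop in shelf.items():
                landed = rec.landed_mt * ov * prop / shelf_total
                if landed == 0.0:
                    continue
                rows.append({
                    "subregion": f"{bname}:{zone}",
                    "group_id": int(rec.group_id),
                    "fleet": fleet,
                    "landed_mt": landed,
                    "discard_mt": landed * rates.get((int(rec.group_id), fleet), 0.0),
                })
    out = pd.DataFrame(
        rows, columns=["subregion", "group_id", "fleet", "landed_mt", "discard_mt"]
    )
    if out.empty:
        return out
    return (
        out.groupby(["subregion", "group_id", "fleet"], as_index=False)[
            ["landed_mt", "discard_mt"]
        ].sum()
    )
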