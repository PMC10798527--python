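"""Core domain types for mass-balance food-web models.

A model is a table of functional groups (producers, consumers, detritus
pools, and fishing fleets) together with a diet matrix, fishery landings
and discards, and a detritus-fate table routing feces, senescence, and
excretion flows among egg, detritus, offal, nutrient, and export pools.

All tables share one 1-based group-id index space; fleets are stored as
groups with ``category="fleet"`` so that trophic-level and network code
can treat them uniformly.

Units: biomass is wet-weight areal density (mt km^-2); P/B and C/B are
biomass-specific rates (yr^-1); landings and discards are mt km^-2 yr^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrophosError",
    "LoadError",
    "ValidationError",
    "UnsetParameterError",
    "UndefinedRatioError",
    "ConfigurationError",
    "CATEGORIES",
    "FLOW_CLASSES",
    "FATE_DESTINATIONS",
    "FunctionalGroup",
    "DietMatrix",
    "FleetCatch",
    "DetritusFateTable",
    "EcopathModel",
    "read_model",
    "write_model",
    "production_rate",
    "pq_ratio",
    "load_table1",
    "table1_groups",
]

DIET_READ_TOL = 1e-6
FATE_TOL = 1e-9

CATEGORIES = ("producer", "consumer", "detritus", "fleet")
FLOW_CLASSES = ("feces", "senescence", "excretion")
FATE_DESTINATIONS = (
    "invertebrate_eggs",
    "fish_eggs",
    "pelagic_detritus",
    "fishery_offal",
    "benthic_detritus",
    "nh4",
    "export",
)


class TrophosError(Exception):
    """Base class for all package errors."""


class LoadError(TrophosError):
    """A table file is missing, malformed, or has a bad header."""


class ValidationError(TrophosError):
    """A loaded table violates a model invariant."""


class UnsetParameterError(TrophosError):
    """An operation needs a parameter that is unset for this group."""


class UndefinedRatioError(TrophosError):
    """P/Q requested for a group with zero consumption rate."""


class ConfigurationError(TrophosError):
    """Required configuration (e.g. a fate row) is missing."""


@dataclass(frozen=True)
class FunctionalGroup:
    """One model compartment: a producer, consumer, detritus pool, or fleet.

    Exactly one of ``biomass`` / ``ee`` may be unset for a living group;
    ``ee_fixed`` marks groups whose EE was an input and whose biomass is
    to be estimated by the mass-balance solve.
    """

    id: int
    name: str
    category: str
    biomass: float | None = None       # mt km^-2 wet weight
    pb: float | None = None            # production/biomass, yr^-1
    cb: float | None = None            # consumption/biomass, yr^-1
    ae: float | None = None            # assimilation efficiency, fraction
    ee: float | None = None            # ecotrophic efficiency, fraction
    ee_fixed: bool = False
    ba: float = 0.0                    # biomass accumulation, mt km^-2 yr^-1
    immigration: float = 0.0
    emigration: float = 0.0
    is_homeotherm: bool = False
    retention: float = 0.0             # 0 = advected freely, 1 = resists

    @property
    def is_living(self) -> bool:
        return self.category in ("producer", "consumer")

    def validate(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"group {self.id} ({self.name}): unknown category {self.category!r}"
            )
        if self.biomass is not None and self.biomass < 0:
            raise ValidationError(f"group {self.id}: negative biomass")
        if self.pb is not None and self.pb < 0:
            raise ValidationError(f"group {self.id}: negative P/B")
        if self.cb is not None and self.cb < 0:
            raise ValidationError(f"group {self.id}: negative C/B")
        if self.category == "consumer" and self.cb is not None and self.cb == 0:
            raise ValidationError(
                f"group {self.id}: consumer with C/B = 0 (only producers/detritus may)"
            )
        if self.ae is not None and not (0.0 <= self.ae <= 1.0):
            raise ValidationError(f"group {self.id}: AE outside [0, 1]")
        if self.ee is not None and self.ee < 0:
            raise ValidationError(f"group {self.id}: negative EE")
        if not (0.0 <= self.retention <= 1.0):
            raise ValidationError(f"group {self.id}: retention outside [0, 1]")
        if self.is_living and self.biomass is None and self.ee is None:
            raise ValidationError(
                f"group {self.id}: living group with both biomass and EE unset"
            )


def production_rate(g: FunctionalGroup) -> float:
    """Total production B x (P/B), mt km^-2 yr^-1."""
    if g.biomass is None:
        raise UnsetParameterError(f"group {g.id} ({g.name}): biomass unset")
    if g.pb is None:
        raise UnsetParameterError(f"group {g.id} ({g.name}): P/B unset")
    return g.biomass * g.pb


def pq_ratio(g: FunctionalGroup) -> float:
    """Production efficiency P/Q = (P/B) / (C/B)."""
    if g.cb is None or g.cb == 0:
        raise UndefinedRatioError(f"group {g.id} ({g.name}): C/B is zero or unset")
    if g.pb is None:
        raise UnsetParameterError(f"group {g.id} ({g.name}): P/B unset")
    return g.pb / g.cb


class DietMatrix:
    """Prey-fraction matrix D[i, j]: share of prey i in consumer j's diet.

    Stored as a square DataFrame over the full group-id index; producer,
    detritus, and fleet columns are all-zero.  Consumer columns sum to 1
    (renormalized on construction from a 1e-6 read tolerance).
    """

    def __init__(self, table: pd.DataFrame, consumer_ids: Sequence[int] | None = None):
        table = table.astype(float)
        if list(table.index) != list(table.columns):
            raise ValidationError("diet matrix must be square with matching id labels")
        if (table.values < -FATE_TOL).any() or (table.values > 1 + DIET_READ_TOL).any():
            raise ValidationError("diet fractions must lie in [0, 1]")
        self.table = table.clip(lower=0.0)
        if consumer_ids is not None:
            self._check_and_normalize(consumer_ids)

    def _check_and_normalize(self, consumer_ids: Sequence[int]) -> None:
        bad = []
        for j in consumer_ids:
            s = float(self.table[j].sum())
            if abs(s - 1.0) > DIET_READ_TOL:
                bad.append((j, s))
            elif s > 0:
                self.table[j] = self.table[j] / s
        if bad:
            detail = ", ".join(f"consumer {j} sums to {s:.6g}" for j, s in bad)
            raise ValidationError(f"diet columns must sum to 1: {detail}")

    @property
    def ids(self) -> list[int]:
        return list(self.table.index)

    def column(self, j: int) -> pd.Series:
        return self.table[j]

    def fraction(self, prey: int, consumer: int) -> float:
        return float(self.table.loc[prey, consumer])

    def to_array(self, ids: Sequence[int]) -> np.ndarray:
        return self.table.loc[list(ids), list(ids)].to_numpy()


class FleetCatch:
    """Landings and discards per (group, fleet), mt km^-2 yr^-1."""

    def __init__(self, landings: pd.DataFrame, discards: pd.DataFrame):
        landings = landings.astype(float)
        discards = discards.reindex(
            index=landings.index, columns=landings.columns, fill_value=0.0
        ).astype(float)
        for nm, df in (("landings", landings), ("discards", discards)):
            if (df.values < 0).any():
                raise ValidationError(f"{nm} must be nonnegative")
        self.landings = landings
        self.discards = discards

    @classmethod
    def empty(cls, group_ids: Sequence[int], fleet_ids: Sequence[int]) -> "FleetCatch":
        z = pd.DataFrame(0.0, index=list(group_ids), columns=list(fleet_ids))
        return cls(z, z.copy())

    def total_removal(self, group_id: int) -> float:
        """F_i = sum over fleets of landings + discards."""
        f = 0.0
        if group_id in self.landings.index:
            f += float(self.landings.loc[group_id].sum())
        if group_id in self.discards.index:
            f += float(self.discards.loc[group_id].sum())
        return f

    def total_landings(self, group_id: int) -> float:
        if group_id in self.landings.index:
            return float(self.landings.loc[group_id].sum())
        return 0.0

    def total_discards(self, group_id: int) -> float:
        if group_id in self.discards.index:
            return float(self.discards.loc[group_id].sum())
        return 0.0


class DetritusFateTable:
    """Routing of feces, senescence, and excretion flows to pools.

    Long-format rows (group_id, flow_class, destination, fraction); each
    (group, flow_class) row of fractions sums to 1.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"group_id", "flow_class", "destination", "fraction"}
        missing = required - set(table.columns)
        if missing:
            raise LoadError(f"fate table missing columns: {sorted(missing)}")
        bad_class = set(table["flow_class"]) - set(FLOW_CLASSES)
        if bad_class:
            raise ValidationError(f"unknown fate flow classes: {sorted(bad_class)}")
        bad_dest = set(table["destination"]) - set(FATE_DESTINATIONS)
        if bad_dest:
            raise ValidationError(f"unknown fate destinations: {sorted(bad_dest)}")
        frac = table["fraction"].astype(float)
        if (frac < -FATE_TOL).any() or (frac > 1 + 1e-6).any():
            raise ValidationError("fate fractions must lie in [0, 1]")
        sums = table.groupby(["group_id", "flow_class"])["fraction"].sum()
        off = sums[(sums - 1.0).abs() > 1e-6]
        if len(off):
            raise ValidationError(
                "fate rows must sum to 1: "
                + ", ".join(f"{g}/{c}={s:.6g}" for (g, c), s in off.items())
            )
        self.table = table.reset_index(drop=True)

    def routing(self, group_id: int, flow_class: str) -> dict[str, float]:
        """Destination -> fraction for one group and flow class.

        Raises ConfigurationError when no row exists for the group.
        """
        sub = self.table[
            (self.table["group_id"] == group_id)
            & (self.table["flow_class"] == flow_class)
        ]
        if sub.empty:
            raise ConfigurationError(
                f"no {flow_class} fate row for group {group_id}"
            )
        out = dict.fromkeys(FATE_DESTINATIONS, 0.0)
        for _, r in sub.iterrows():
            out[r["destination"]] += float(r["fraction"])
        total = sum(out.values())
        return {k: v / total for k, v in out.items()}

    def has_group(self, group_id: int) -> bool:
        return bool((self.table["group_id"] == group_id).any())

    @classmethod
    def uniform(
        cls,
        group_ids: Sequence[int],
        feces_to: str = "benthic_detritus",
        senescence_to: str = "benthic_detritus",
    ) -> "DetritusFateTable":
        """Simple default: all feces/senescence to one pool, excretion to NH4."""
        rows = []
        for g in group_ids:
            rows.append((g, "feces", feces_to, 1.0))
            rows.append((g, "senescence", senescence_to, 1.0))
            rows.append((g, "excretion", "nh4", 1.0))
        return cls(
            pd.DataFrame(rows, columns=["group_id", "flow_class", "destination", "fraction"])
        )


@dataclass
class EcopathModel:
    """A full model parameterization: groups + diet + catch + fates."""

    groups: list[FunctionalGroup]
    diet: DietMatrix
    catch: FleetCatch
    fates: DetritusFateTable | None = None
    subregion_id: str | None = None

    def __post_init__(self) -> None:
        ids = [g.id for g in self.groups]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise LoadError(f"duplicate group ids: {dup}")
        self._by_id = {g.id: g for g in self.groups}

    # -- index helpers -------------------------------------------------
    @property
    def ids(self) -> list[int]:
        return [g.id for g in self.groups]

    def group(self, gid: int) -> FunctionalGroup:
        return self._by_id[gid]

    def ids_of(self, *categories: str) -> list[int]:
        return [g.id for g in self.groups if g.category in categories]

    @property
    def living_ids(self) -> list[int]:
        return self.ids_of("producer", "consumer")

    @property
    def consumer_ids(self) -> list[int]:
        return self.ids_of("consumer")

    @property
    def producer_ids(self) -> list[int]:
        return self.ids_of("producer")

    @property
    def detritus_ids(self) -> list[int]:
        return self.ids_of("detritus")

    @property
    def fleet_ids(self) -> list[int]:
        return self.ids_of("fleet")

    def validate(self) -> None:
        for g in self.groups:
            g.validate()
        ids = set(self.ids)
        if set(self.diet.ids) - ids:
            raise ValidationError("diet matrix has ids not in the group table")
        self.diet._check_and_normalize(self.consumer_ids)
        for j in self.consumer_ids:
            g = self.group(j)
            if g.cb is not None and g.cb > 0 and float(self.diet.column(j).sum()) == 0:
                raise ValidationError(
                    f"consumer {j} ({g.name}) has C/B > 0 but an all-zero diet column"
                )
        for j in self.producer_ids + self.detritus_ids:
            if j in self.diet.table.columns and float(self.diet.column(j).sum()) > FATE_TOL:
                raise ValidationError(f"non-consumer {j} has a nonzero diet column")

    def copy(self) -> "EcopathModel":
        return EcopathModel(
            groups=[replace(g) for g in self.groups],
            diet=DietMatrix(self.diet.table.copy()),
            catch=FleetCatch(self.catch.landings.copy(), self.catch.discards.copy()),
            fates=self.fates,
            subregion_id=self.subregion_id,
        )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

GROUP_COLUMNS = [
    "id", "name", "category", "biomass", "pb", "cb", "ae", "ee", "ee_fixed",
    "ba", "immigration", "emigration", "is_homeotherm", "retention",
]

_BOOL = {"true": True, "false": False, "1": True, "0": False, "": False}


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def _as_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, float) and math.isnan(v):
        return False
    return _BOOL.get(str(v).strip().lower(), False)


def _groups_from_frame(df: pd.DataFrame) -> list[FunctionalGroup]:
    missing = [c for c in GROUP_COLUMNS if c not in df.columns]
    if missing:
        raise LoadError(f"groups table missing columns: {missing}")
    groups = []
    for _, r in df.iterrows():
        groups.append(
            FunctionalGroup(
                id=int(r["id"]),
                name=str(r["name"]),
                category=str(r["category"]),
                biomass=_opt_float(r["biomass"]),
                pb=_opt_float(r["pb"]),
                cb=_opt_float(r["cb"]),
                ae=_opt_float(r["ae"]),
                ee=_opt_float(r["ee"]),
                ee_fixed=_as_bool(r["ee_fixed"]),
                ba=_opt_float(r["ba"]) or 0.0,
                immigration=_opt_float(r["immigration"]) or 0.0,
                emigration=_opt_float(r["emigration"]) or 0.0,
                is_homeotherm=_as_bool(r["is_homeotherm"]),
                retention=_opt_float(r["retention"]) or 0.0,
            )
        )
    return groups


def read_model(path: str | Path | Mapping[str, Path]) -> EcopathModel:
    """Read a model from a directory of CSV tables.

    Expects ``groups.csv`` and ``diet.csv``; ``landings.csv``,
    ``discards.csv``, and ``fates.csv`` are optional (absent catch tables
    mean an unfished system).  The returned model is validated.
    """
    if isinstance(path, Mapping):
        files = dict(path)
    else:
        d = Path(path)
        files = {
            name: d / f"{name}.csv"
            for name in ("groups", "diet", "landings", "discards", "fates")
        }
    gpath = Path(files["groups"])
    if not gpath.exists():
        raise LoadError(f"missing groups table: {gpath}")
    groups = _groups_from_frame(pd.read_csv(gpath))
    ids = [g.id for g in groups]

    dpath = Path(files["diet"])
    if not dpath.exists():
        raise LoadError(f"missing diet table: {dpath}")
    dt = pd.read_csv(dpath, index_col=0)
    dt.index = dt.index.astype(int)
    dt.columns = dt.columns.astype(int)
    dt = dt.reindex(index=ids, columns=ids, fill_value=0.0).fillna(0.0)
    diet = DietMatrix(dt)

    fleet_ids = [g.id for g in groups if g.category == "fleet"]
    lpath, xpath = files.get("landings"), files.get("discards")

    def _catch_frame(p) -> pd.DataFrame:
        if p is None or not Path(p).exists():
            return pd.DataFrame(0.0, index=ids, columns=fleet_ids)
        df = pd.read_csv(p, index_col=0)
        df.index = df.index.astype(int)
        df.columns = df.columns.astype(int)
        return df.reindex(index=ids, fill_value=0.0).fillna(0.0)

    catch = FleetCatch(_catch_frame(lpath), _catch_frame(xpath))

    fates = None
    fpath = files.get("fates")
    if fpath is not None and Path(fpath).exists():
        fates = DetritusFateTable(pd.read_csv(fpath))

    model = EcopathModel(groups=groups, diet=diet, catch=catch, fates=fates)
    model.validate()
    return model


def write_model(model: EcopathModel, outdir: str | Path) -> None:
    """Write the model back to CSV tables (inverse of read_model)."""
    d = Path(outdir)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for g in model.groups:
        rows.append(
            {
                "id": g.id, "name": g.name, "category": g.category,
                "biomass": g.biomass, "pb": g.pb, "cb": g.cb, "ae": g.ae,
                "ee": g.ee, "ee_fixed": g.ee_fixed, "ba": g.ba,
                "immigration": g.immigration, "emigration": g.emigration,
                "is_homeotherm": g.is_homeotherm, "retention": g.retention,
            }
        )
    pd.DataFrame(rows, columns=GROUP_COLUMNS).to_csv(d / "groups.csv", index=False)
    model.diet.table.to_csv(d / "diet.csv", float_format="%.17g")
    model.catch.landings.to_csv(d / "landings.csv", float_format="%.17g")
    model.catch.discards.to_csv(d / "discards.csv", float_format="%.17g")
    if model.fates is not None:
        model.fates.table.to_csv(d / "fates.csv", index=False)


# ---------------------------------------------------------------------------
# Packaged reference parameter table (aggregated NCC shelf model)
# ---------------------------------------------------------------------------

def load_table1() -> pd.DataFrame:
    """The packaged 90-group + 9-fleet parameter table.

    Columns follow the groups.csv schema plus a ``tl`` column with the
    published trophic-level estimates.
    """
    with resources.files("trophos.data").joinpath("table1.csv").open("rb") as fh:
        return pd.read_csv(fh)


def table1_groups() -> list[FunctionalGroup]:
    """The packaged parameter table as FunctionalGroup records."""
    return _groups_from_frame(load_table1())
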