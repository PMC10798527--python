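"""Five-box cross-shelf physical scaffold and upwelling-driven transport.

The shelf is split into an inner zone (box I, vertically integrated), a
middle zone (surface box II over sub-surface box III), and an outer zone
(surface box IV over sub-surface box V); the surface/sub-surface break
is the annual-mean mixed layer depth (15 m).  A daily coastal upwelling
transport index (CUTI, m^2 s^-1 per meter of coastline) forces a closed
advective circuit: positive CUTI drives deep onshore flow
ocean -> V -> III -> I with compensating surface offshore flow
I -> II -> IV -> ocean; negative CUTI reverses every arrow.  Volume
continuity holds exactly at every box.

Nutrients enter only by advection across the oceanic boundary at the
monthly climatological boundary concentration.  Non-nutrient tracers
have reflective ocean boundaries: inflowing water carries the receiving
box's own concentration (no net import, no dilution), while offshore
outflow exports tracer mass.  Per-group retention scales a tracer's
susceptibility to advection (0 = fully advected, 1 = fully resists).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np
import pandas as pd

from .foodweb import TrophosError, ValidationError

__all__ = [
    "BOXES",
    "ShelfGeometry",
    "UpwellingSeries",
    "NutrientClimatology",
    "advection_fluxes",
    "boundary_input",
    "transport_step",
    "sinking_step",
]

BOXES = ("I", "II", "III", "IV", "V")
_BOX_IDX = {b: k for k, b in enumerate(BOXES)}

# upwelling circuit; negative CUTI traverses it in reverse
_UPWELLING_PATH = [("ocean", "V"), ("V", "III"), ("III", "I"),
                   ("I", "II"), ("II", "IV"), ("IV", "ocean")]

M3S_TO_KM3D = 86400.0 / 1e9  # m^3 s^-1 -> km^3 d^-1
KM3_TO_M3 = 1e9


@dataclass(frozen=True)
class ShelfGeometry:
    """Box areas/volumes and the alongshore length scaling CUTI.

    Defaults describe a bathymetrically defined shelf (inner 1-100 m,
    middle 101-200 m, outer 201-1280 m) with an assumed alongshore
    length and zone widths; real applications should supply surveyed
    areas via configuration.
    """

    alongshore_km: float = 830.0
    mld_m: float = 15.0
    # surface areas, km^2
    area_km2: dict[str, float] = field(default_factory=lambda: {
        "I": 830.0 * 15.0, "II": 830.0 * 10.0, "III": 830.0 * 10.0,
        "IV": 830.0 * 30.0, "V": 830.0 * 30.0,
    })
    # mean tracer-column thickness, m
    depth_m: dict[str, float] = field(default_factory=lambda: {
        "I": 50.0, "II": 15.0, "III": 135.0, "IV": 15.0, "V": 625.0,
    })

    def __post_init__(self) -> None:
        for b in BOXES:
            if self.area_km2[b] <= 0 or self.depth_m[b] <= 0:
                raise ValidationError(f"box {b}: nonpositive area or depth")
        if abs(self.depth_m["II"] - self.mld_m) > 1e-9 or abs(
            self.depth_m["IV"] - self.mld_m
        ) > 1e-9:
            raise ValidationError("surface boxes II/IV must have MLD thickness")

    def volume_km3(self, box: str) -> float:
        return self.area_km2[box] * self.depth_m[box] / 1000.0

    @property
    def volumes_km3(self) -> np.ndarray:
        return np.array([self.volume_km3(b) for b in BOXES])

    @property
    def volumes_m3(self) -> np.ndarray:
        return self.volumes_km3 * KM3_TO_M3


@dataclass
class UpwellingSeries:
    """Daily upwelling-transport forcing (CUTI-style, m^2 s^-1)."""

    dates: pd.DatetimeIndex
    cuti: np.ndarray

    def __post_init__(self) -> None:
        self.cuti = np.asarray(self.cuti, dtype=float)
        if len(self.dates) != len(self.cuti):
            raise ValidationError("dates and cuti must have equal length")
        if len(self.dates) > 1:
            deltas = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
            if not (deltas == 1).all():
                raise ValidationError("upwelling series must be daily")
        if not np.isfinite(self.cuti).all():
            raise ValidationError("upwelling series contains non-finite values")

    def __len__(self) -> int:
        return len(self.cuti)

    @classmethod
    def read_csv(cls, path) -> "UpwellingSeries":
        df = pd.read_csv(path, parse_dates=["date"])
        return cls(pd.DatetimeIndex(df["date"]), df["cuti"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"date": self.dates, "cuti": self.cuti}).to_csv(path, index=False)

    def day_of_year_mean(self) -> np.ndarray:
        """365-entry day-of-year climatology (Feb 29 folded into day 59)."""
        doy = np.minimum(self.dates.dayofyear.to_numpy(), 365) - 1
        out = np.zeros(365)
        counts = np.zeros(365)
        np.add.at(out, doy, self.cuti)
        np.add.at(counts, doy, 1)
        counts[counts == 0] = 1
        return out / counts


@dataclass
class NutrientClimatology:
    """Monthly boundary NO3/NH4 concentrations (mmol N m^-3)."""

    table: pd.DataFrame  # columns: month, no3_surface, no3_deep, nh4_surface, nh4_deep

    def __post_init__(self) -> None:
        req = {"month", "no3_surface", "no3_deep", "nh4_surface", "nh4_deep"}
        if not req <= set(self.table.columns):
            raise ValidationError(f"climatology needs columns {sorted(req)}")
        if sorted(self.table["month"]) != list(range(1, 13)):
            raise ValidationError("climatology must cover months 1-12")
        if (self.table[list(req - {"month"})].values < 0).any():
            raise ValidationError("negative boundary concentration")
        self.table = self.table.set_index("month", drop=False)

    def month_values(self, month: int) -> dict[str, float]:
        r = self.table.loc[((month - 1) % 12) + 1]
        return {k: float(r[k]) for k in
                ("no3_surface", "no3_deep", "nh4_surface", "nh4_deep")}

    @classmethod
    def read_csv(cls, path) -> "NutrientClimatology":
        return cls(pd.read_csv(path))

    @classmethod
    def constant(cls, no3_deep=25.0, nh4_deep=1.0, no3_surface=5.0,
                 nh4_surface=0.5) -> "NutrientClimatology":
        return cls(pd.DataFrame({
            "month": range(1, 13),
            "no3_surface": no3_surface, "no3_deep": no3_deep,
            "nh4_surface": nh4_surface, "nh4_deep": nh4_deep,
        }))


def advection_fluxes(cuti_value: float, geom: ShelfGeometry) -> dict[tuple[str, str], float]:
    """Daily volume flux (km^3 d^-1) through each interface on the circuit.

    Returns directed edges with nonnegative magnitudes; negative CUTI
    mirrors positive CUTI with every arrow reversed.  Continuity
    (inflow = outflow per box) holds by construction.
    """
    q = abs(cuti_value) * geom.alongshore_km * 1000.0 * M3S_TO_KM3D
    if q == 0.0:
        return {}
    path = _UPWELLING_PATH if cuti_value > 0 else [(b, a) for a, b in reversed(_UPWELLING_PATH)]
    return {edge: q for edge in path}


def boundary_input(
    date, clim: NutrientClimatology, fluxes: dict[tuple[str, str], float]
) -> dict[str, dict[str, float]]:
    """Nutrient mass inflow (mmol N d^-1) per boundary box.

    Deep onshore inflow (ocean -> V) carries deep-boundary
    concentrations; downwelling surface inflow (ocean -> IV) carries
    surface-boundary concentrations.  The climatology is periodic in
    month of year.
    """
    month = date.month if hasattr(date, "month") else int(date)
    vals = clim.month_values(month)
    out: dict[str, dict[str, float]] = {}
    for (a, b), q in fluxes.items():
        if a != "ocean" or q == 0:
            continue
        layer = "deep" if b == "V" else "surface"
        out[b] = {
            "no3": vals[f"no3_{layer}"] * q * KM3_TO_M3,
            "nh4": vals[f"nh4_{layer}"] * q * KM3_TO_M3,
        }
    return out


def transport_step(
    conc: np.ndarray,
    fluxes: dict[tuple[str, str], float],
    retention: np.ndarray,
    geom: ShelfGeometry,
    *,
    nutrient_mask: np.ndarray,
    boundary_conc: dict[str, np.ndarray] | None = None,
    dt: float = 1.0,
    open_boundary: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Advect tracer concentrations for one step (upwind scheme).

    ``conc``: (5, n_tracers) mmol N m^-3 in box order I..V.
    ``retention``: per-tracer fraction resisting advection.
    ``nutrient_mask``: True for tracers with open (climatological)
    boundaries; others are reflective on inflow.
    ``boundary_conc``: per boundary box ("IV"/"V"), inflow concentration
    for each tracer (used only where nutrient_mask).

    Returns (new_conc, exported_mass) where exported_mass (mmol per
    tracer) is what left through the offshore boundary.
    """
    conc = np.asarray(conc, dtype=float)
    n = conc.shape[1]
    mass = conc * geom.volumes_m3[:, None]
    dmass = np.zeros_like(mass)
    export = np.zeros(n)
    mobility = (1.0 - np.asarray(retention, dtype=float))
    if np.any(conc < -1e-12):
        raise ValidationError("negative concentration entering transport step")

    for (a, b), q in fluxes.items():
        qm3 = q * KM3_TO_M3 * dt
        if a == "ocean":
            bi = _BOX_IDX[b]
            inflow = np.zeros(n)
            if open_boundary:
                if boundary_conc is not None and b in boundary_conc:
                    inflow = np.where(nutrient_mask, boundary_conc[b], conc[bi])
                else:
                    inflow = np.where(nutrient_mask, 0.0, conc[bi])
            # reflective: non-nutrient inflow carries the box's own water
            dmass[bi] += qm3 * inflow * mobility
        elif b == "ocean":
            ai = _BOX_IDX[a]
            out = qm3 * conc[ai] * mobility
            if open_boundary:
                dmass[ai] -= out
                export += out
        else:
            ai, bi = _BOX_IDX[a], _BOX_IDX[b]
            move = qm3 * conc[ai] * mobility
            dmass[ai] -= move
            dmass[bi] += move

    new_mass = mass + dmass
    # guard tiny negatives from the explicit scheme
    np.clip(new_mass, 0.0, None, out=new_mass)
    return new_mass / geom.volumes_m3[:, None], export


def sinking_step(
    conc: np.ndarray,
    tracer_idx: int,
    rate_per_day: float,
    geom: ShelfGeometry,
    dt: float = 1.0,
) -> np.ndarray:
    """Move a sinking tracer from surface boxes II/IV to III/V below."""
    conc = conc.copy()
    vol = geom.volumes_m3
    for top, bottom in (("II", "III"), ("IV", "V")):
        ti, bi = _BOX_IDX[top], _BOX_IDX[bottom]
        m = rate_per_day * dt * conc[ti, tracer_idx] * vol[ti]
        conc[ti, tracer_idx] -= m / vol[ti]
        conc[bi, tracer_idx] += m / vol[bi]
    return conc
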