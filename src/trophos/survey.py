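"""Survey-to-biomass estimators and unit conversions.

Trawl catches mix many zeros with highly skewed positive values, so the
mean areal biomass of a group is estimated with the delta-lognormal
(Pennington) minimum-variance unbiased estimator: with m positive
values out of n, and ybar, s^2 the mean and variance of the logs of the
positives,

    mean = (m/n) exp(ybar) G_m(s^2 / 2),

where G_m is the Bessel-type power series

    G_m(t) = 1 + (m-1)/m t
           + sum_{j>=2} (m-1)^(2j-1) t^j / (m^j (m+1)(m+3)...(m+2j-3) j!).

Acoustic-trawl and mid-water data use the plain arithmetic mean.  The
rest of the module converts counts and volumetric densities into areal
wet-weight densities (mt km^-2), applies catchability and gelatinous
water-content scalers, averages across overlapping surveys, and sums
species into functional groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .foodweb import TrophosError

__all__ = [
    "delta_lognormal_mean",
    "pennington_g",
    "arithmetic_mean_density",
    "counts_to_biomass",
    "volumetric_to_areal",
    "subregional_biomass",
    "gelatinous_scaling",
    "seasonal_annual_mean",
    "vgpm_to_phyto_biomass",
    "phyto_size_partition",
    "apportion",
]


class SurveyError(TrophosError):
    pass


def pennington_g(m: int, t: float, rel_tol: float = 1e-12) -> float:
    """The G_m series; terms are added until they fall below rel_tol."""
    if m < 2:
        return 1.0
    total = 1.0 + (m - 1) / m * t
    denom_prod = 1.0  # (m+1)(m+3)...(m+2j-3)
    term_pow = float(m - 1)  # (m-1)^(2j-1)
    factorial = 1.0
    t_pow = float(t)  # t^(j-1) entering iteration j
    for j in range(2, 200):
        denom_prod *= m + 2 * j - 3
        term_pow *= (m - 1) ** 2
        factorial *= j
        t_pow *= t
        term = term_pow * t_pow / (m ** j * denom_prod * factorial)
        total += term
        if abs(term) < rel_tol * abs(total):
            break
    return total


def delta_lognormal_mean(values) -> float:
    """Pennington's MVU estimator of the mean of zero-inflated lognormal data."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise SurveyError("empty sample")
    if (x < 0).any():
        raise SurveyError("negative values in a density sample")
    n = x.size
    pos = x[x > 0]
    m = pos.size
    if m == 0:
        return 0.0
    if m == 1:
        return float(pos[0] / n)
    logs = np.log(pos)
    ybar = float(logs.mean())
    s2 = float(logs.var(ddof=1))
    return (m / n) * math.exp(ybar) * pennington_g(m, s2 / 2.0)


def arithmetic_mean_density(values) -> float:
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise SurveyError("empty sample")
    if (x < 0).any():
        raise SurveyError("negative values in a density sample")
    return float(x.mean())


_ESTIMATORS = {"delta": delta_lognormal_mean, "arithmetic": arithmetic_mean_density}


def counts_to_biomass(count: float, mean_length: float, lw: tuple[float, float]) -> float:
    """count x a L^b with a species length-weight relationship."""
    a, b = lw
    if a <= 0 or b <= 0:
        raise SurveyError("length-weight coefficients must be positive")
    if count == 0:
        return 0.0
    return count * a * mean_length ** b


def volumetric_to_areal(density_mt_km3: float, depth_range_m: float) -> float:
    """Vertical integration: mt km^-3 x (occupied depth in km) -> mt km^-2."""
    return density_mt_km3 * depth_range_m / 1000.0


def gelatinous_scaling(biomass: float, wc_gel: float = 0.96, wc_ref: float = 0.80) -> float:
    """Scale gelatinous wet weight to the water content of reference prey.

    factor = (1 - wc_gel) / (1 - wc_ref): one unit of gelatinous biomass
    counts as the dry-equivalent fraction of the reference group.
    """
    if not (0 <= wc_gel < 1 and 0 <= wc_ref < 1):
        raise SurveyError("water contents must lie in [0, 1)")
    return biomass * (1.0 - wc_gel) / (1.0 - wc_ref)


def seasonal_annual_mean(observations) -> float:
    """Annual mean from sparse (day-of-year, value) points by periodic
    linear interpolation over a 365-day year."""
    obs = sorted((float(d) % 365.0, float(v)) for d, v in observations)
    if not obs:
        raise SurveyError("no observations")
    if len(obs) == 1:
        return obs[0][1]
    days = np.array([d for d, _ in obs])
    vals = np.array([v for _, v in obs])
    # wrap the first point past year end for periodic interpolation
    days_ext = np.concatenate([days, [days[0] + 365.0]])
    vals_ext = np.concatenate([vals, [vals[0]]])
    grid = np.arange(365.0)
    shifted = (grid - days[0]) % 365.0 + days[0]
    return float(np.interp(shifted, days_ext, vals_ext).mean())


def vgpm_to_phyto_biomass(
    production_mt_km2_yr: float, pb_per_yr: float
) -> float:
    """Areal biomass from annual production divided by the production rate."""
    if pb_per_yr <= 0:
        raise SurveyError("P/B must be positive")
    return production_mt_km2_yr / pb_per_yr


def phyto_size_partition(chl_mg_m3: float) -> float:
    """Fraction of total phytoplankton in the small (<=10 um) size class.

    Empirical power law 0.30821 x Chl^-0.82351, clamped to [0, 1] (the
    raw relation exceeds 1 at very low chlorophyll).
    """
    if chl_mg_m3 <= 0:
        raise SurveyError("chlorophyll concentration must be positive")
    return min(1.0, 0.30821 * chl_mg_m3 ** -0.82351)


def apportion(total: float, proportions: dict) -> dict:
    """Split an aggregate biomass by fixed relative proportions."""
    s = sum(proportions.values())
    if s <= 0:
        raise SurveyError("proportions must sum to a positive value")
    return {k: total * v / s for k, v in proportions.items()}


@dataclass
class ConversionTables:
    """Per-species processing parameters.

    ``table`` columns: species, group_id, estimator ("delta" or
    "arithmetic"), depth_m (assumed vertical occupation), catchability,
    lw_a, lw_b (length-weight, optional).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"species", "group_id", "estimator", "depth_m", "catchability"}
        missing = req - set(self.table.columns)
        if missing:
            raise SurveyError(f"conversion table missing columns: {sorted(missing)}")
        if (self.table["depth_m"] <= 0).any() or (self.table["catchability"] <= 0).any():
            raise SurveyError("depths and catchability scalers must be positive")
        self.table = self.table.set_index("species", drop=False)

    def for_species(self, sp: str):
        if sp not in self.table.index:
            return None
        return self.table.loc[sp]


def subregional_biomass(
    records: pd.DataFrame, conv: ConversionTables
) -> tuple[pd.DataFrame, list[str]]:
    """Per-group, per-subregion areal biomass densities (mt km^-2).

    ``records`` columns: station_id, subregion, survey, species, value,
    value_kind in {"volumetric", "areal", "count_length"}, and for
    count_length additionally mean_length and sample_volume_km3.

    Pipeline per species and subregion: estimator over stations within
    each survey -> vertical integration of volumetric densities ->
    catchability scaler -> average across overlapping surveys -> sum
    species into functional groups.  Species without a conversion row
    are skipped and returned as warnings.
    """
    req = {"station_id", "subregion", "survey", "species", "value", "value_kind"}
    missing = req - set(records.columns)
    if missing:
        raise SurveyError(f"survey table missing columns: {sorted(missing)}")
    if (records["value"] < 0).any():
        raise SurveyError("negative survey values")

    warnings: list[str] = []
    contributions = []  # (group_id, subregion, species, survey-mean density)
    for (species, subregion, survey), sub in records.groupby(
        ["species", "subregion", "survey"]
    ):
        c = conv.for_species(species)
        if c is None:
            msg = f"species {species!r} mapped to no functional group"
            if msg not in warnings:
                warnings.append(msg)
            continue
        kinds = set(sub["value_kind"])
        if len(kinds) > 1:
            raise SurveyError(
                f"mixed value kinds for {species} in subregion {subregion}"
            )
        kind = kinds.pop()
        if kind == "count_length":
            if "mean_length" not in sub.columns or "sample_volume_km3" not in sub.columns:
                raise SurveyError("count_length records need mean_length and sample_volume_km3")
            vals = np.array([
                counts_to_biomass(r.value, r.mean_length, (c["lw_a"], c["lw_b"]))
                / r.sample_volume_km3
                for r in sub.itertuples()
            ])
            kind = "volumetric"
        else:
            vals = sub["value"].to_numpy(dtype=float)
        est = _ESTIMATORS[str(c["estimator"])]
        density = est(vals)
        if kind == "volumetric":
            density = volumetric_to_areal(density, float(c["depth_m"]))
        density *= float(c["catchability"])
        contributions.append(
            {"group_id": int(c["group_id"]), "subregion": subregion,
             "species": species, "density": density}
        )

    if not contributions:
        return pd.DataFrame(columns=["group_id", "subregion", "biomass"]), warnings
    df = pd.DataFrame(contributions)
    # average across surveys (rows repeated per survey), then sum species
    per_species = df.groupby(["group_id", "subregion", "species"])["density"].mean()
    out = (
        per_species.groupby(["group_id", "subregion"]).sum()
        .rename("biomass").reset_index()
    )
    return out, warnings
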