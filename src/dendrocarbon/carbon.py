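"""Allometric biomass, carbon stocks and lifetime-quartile statistics.

Aboveground biomass (AGB, kg) is estimated from stem diameter D (cm), wood
density rho (g cm^-3) and a site-level environmental stress factor E with
the pantropical height-free allometry

    AGB = exp(-1.803 - 0.976 E + 0.976 ln rho + 2.673 ln D - 0.0339 ln^2 D)

E grows with temperature seasonality and water deficit; it enters as a pure
scaling exp(-0.976 E) and is a config input here. AGB is converted to
carbon with a species-level carbon fraction (default 0.471, a published
tropical-angiosperm mean; the allometry source prints no fraction of its
own). Annual carbon accumulation is the first difference of the carbon
stock, with the first year's accumulation equal to the first year's stock
(zero origin).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .series import DiameterTrajectory

__all__ = [
    "CarbonTrajectory",
    "QuartileSummary",
    "agb_chave",
    "diameter_from_agb",
    "carbon_trajectory",
    "quartile_shares",
    "cumulative_curve",
    "cohort_summary",
    "DEFAULT_CARBON_FRACTION",
]

logger = logging.getLogger(__name__)

DEFAULT_CARBON_FRACTION = 0.471

# allometry coefficients: intercept, E, ln(rho), ln(D), ln^2(D)
_A0 = -1.803
_AE = -0.976
_ARHO = 0.976
_AD = 2.673
_AD2 = -0.0339


@dataclass(frozen=True)
class CarbonTrajectory:
    """Per-year AGB, carbon stock and annual carbon accumulation (kg)."""

    tree_id: str
    years: np.ndarray
    agb_kg: np.ndarray
    carbon_kg: np.ndarray
    annual_c_kg: np.ndarray

    @property
    def age(self) -> int:
        return int(self.carbon_kg.size)

    @property
    def final_carbon_kg(self) -> float:
        return float(self.carbon_kg[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tree_id": self.tree_id,
                "year": self.years,
                "agb_kg": self.agb_kg,
                "carbon_kg": self.carbon_kg,
                "annual_c_kg": self.annual_c_kg,
            }
        )


@dataclass(frozen=True)
class QuartileSummary:
    """Percent of lifetime carbon accumulated in each quarter of lifetime."""

    tree_id: str
    shares_percent: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.shares_percent, dtype=float)
        if s.size != 4:
            raise ValueError("expected exactly 4 quartile shares")
        if abs(s.sum() - 100.0) > 1e-6:
            raise ValueError(f"quartile shares sum to {s.sum()}, not 100")
        object.__setattr__(self, "shares_percent", s)


def agb_chave(d_cm, rho: float, e: float):
    """Pantropical height-free AGB (kg) from diameter, density and stress.

    Strictly increasing in D over the biological range, increasing in rho
    (doubling rho multiplies AGB by exactly 2**0.976) and decreasing in E.
    Scalar in, scalar out; arrays are evaluated elementwise.
    """
    d = np.asarray(d_cm, dtype=float)
    if rho <= 0:
        raise ValueError("wood density must be positive")
    if np.any(d <= 0):
        raise ValueError("diameter must be positive (log-linear model)")
    ln_d = np.log(d)
    agb = np.exp(_A0 + _AE * e + _ARHO * math.log(rho) + _AD * ln_d + _AD2 * ln_d**2)
    return float(agb) if np.isscalar(d_cm) else agb


def diameter_from_agb(agb_kg, rho: float, e: float):
    """Invert the allometry for D (cm): the quadratic in ln D solved on the
    increasing branch. Used by the synthetic generator to realize growth
    archetypes specified in carbon space."""
    agb = np.asarray(agb_kg, dtype=float)
    if np.any(agb <= 0):
        raise ValueError("AGB must be positive")
    c0 = _A0 + _AE * e + _ARHO * math.log(rho)
    # -AD2 ln^2 D ... solve AD2' x^2 - AD x + (y - c0) = 0 with AD2' = -_AD2 > 0
    g = -_AD2
    y = np.log(agb)
    disc = _AD**2 - 4.0 * g * (y - c0)
    if np.any(disc <= 0):
        raise ValueError("AGB beyond the invertible (biological) range")
    x = (_AD - np.sqrt(disc)) / (2.0 * g)
    d = np.exp(x)
    return float(d) if np.isscalar(agb_kg) else d


def carbon_trajectory(
    traj: DiameterTrajectory,
    rho: float,
    e: float,
    carbon_fraction: float = DEFAULT_CARBON_FRACTION,
) -> CarbonTrajectory:
    """Carbon stock and annual accumulation along a diameter trajectory.

    Years with diameter 0 (a trajectory starting at the pith before any
    measurable ring) map to AGB 0 by the limit convention.
    """
    if not 0 < carbon_fraction < 1:
        raise ValueError("carbon_fraction must lie in (0, 1)")
    d = traj.diameter_cm
    agb = np.zeros_like(d)
    pos = d > 0
    if pos.any():
        agb[pos] = agb_chave(d[pos], rho, e)
    carbon = carbon_fraction * agb
    annual = np.diff(carbon, prepend=0.0)
    return CarbonTrajectory(
        tree_id=traj.tree_id,
        years=traj.years,
        agb_kg=agb,
        carbon_kg=carbon,
        annual_c_kg=annual,
    )


def quartile_boundaries(t: int) -> list[tuple[int, int]]:
    """Half-open index ranges [lo, hi) of the four lifetime quarters.

    Boundaries fall at ceil(T/4), ceil(T/2), ceil(3T/4): when T is not a
    multiple of 4 the extra years go to the earliest eligible quarter, so
    every year belongs to exactly one quarter.
    """
    cuts = [0] + [math.ceil(t * k / 4) for k in (1, 2, 3)] + [t]
    return [(cuts[i], cuts[i + 1]) for i in range(4)]


def quartile_shares(traj: CarbonTrajectory) -> QuartileSummary:
    """Percent of lifetime carbon accumulated in each quarter of lifetime."""
    t = traj.age
    if t < 4:
        raise ValueError(f"tree {traj.tree_id}: lifetime {t} < 4 years")
    total = traj.final_carbon_kg
    if total <= 0:
        raise ValueError(f"tree {traj.tree_id}: zero final carbon stock")
    sums = np.array(
        [traj.annual_c_kg[lo:hi].sum() for lo, hi in quartile_boundaries(t)]
    )
    return QuartileSummary(tree_id=traj.tree_id, shares_percent=100.0 * sums / total)


def cumulative_curve(traj: CarbonTrajectory) -> np.ndarray:
    """Running sum of annual accumulation; equals the carbon stock by the
    telescoping identity."""
    return np.cumsum(traj.annual_c_kg)


def cohort_summary(results: Sequence) -> dict[str, pd.DataFrame]:
    """Species-level summary tables of a processed cohort.

    ``results`` is a sequence of objects exposing ``record`` (TreeRecord),
    ``diameter`` (DiameterTrajectory), ``carbon`` (CarbonTrajectory) and
    ``quartiles`` (QuartileSummary) — the pipeline's per-tree results.

    Returns three frames mirroring the classic cohort tables:

    - ``age_diameter_stock``: per species mean/min/max of age, final
      diameter and final carbon stock;
    - ``annual_rates``: per species mean/min/max/SD of annual carbon
      accumulation and annual diameter growth, pooling all tree-years;
    - ``quartile_shares``: per species and lifetime quarter the mean/min/max
      percent of lifetime carbon.
    """
    if not results:
        raise ValueError("cohort_summary needs a non-empty result set")
    by_species: dict[str, list] = {}
    for res in results:
        by_species.setdefault(res.record.species, []).append(res)

    rows1, rows2, rows3 = [], [], []
    for species in sorted(by_species):
        group = by_species[species]
        if not group:
            logger.warning("species %s has no trees; omitted from summary", species)
            continue
        ages = np.array([r.carbon.age for r in group], dtype=float)
        diams = np.array([r.diameter.final_diameter_cm for r in group])
        stocks = np.array([r.carbon.final_carbon_kg for r in group])
        rows1.append(
            {
                "species": species,
                "n_trees": len(group),
                "age_mean": ages.mean(),
                "age_min": ages.min(),
                "age_max": ages.max(),
                "diameter_mean_cm": diams.mean(),
                "diameter_min_cm": diams.min(),
                "diameter_max_cm": diams.max(),
                "carbon_mean_kg": stocks.mean(),
                "carbon_min_kg": stocks.min(),
                "carbon_max_kg": stocks.max(),
            }
        )
        annual_c = np.concatenate([r.carbon.annual_c_kg for r in group])
        annual_d = np.concatenate([r.diameter.annual_increment_cm for r in group])
        rows2.append(
            {
                "species": species,
                "annual_c_mean_kg": annual_c.mean(),
                "annual_c_min_kg": annual_c.min(),
                "annual_c_max_kg": annual_c.max(),
                "annual_c_sd_kg": annual_c.std(ddof=1),
                "annual_d_mean_cm": annual_d.mean(),
                "annual_d_min_cm": annual_d.min(),
                "annual_d_max_cm": annual_d.max(),
                "annual_d_sd_cm": annual_d.std(ddof=1) if annual_d.size > 1 else 0.0,
            }
        )
        shares = np.vstack([r.quartiles.shares_percent for r in group])
        for q in range(4):
            rows3.append(
                {
                    "species": species,
                    "quartile": q + 1,
                    "share_mean_pct": shares[:, q].mean(),
                    "share_min_pct": shares[:, q].min(),
                    "share_max_pct": shares[:, q].max(),
                }
            )
    return {
        "age_diameter_stock": pd.DataFrame(rows1),
        "annual_rates": pd.DataFrame(rows2),
        "quartile_shares": pd.DataFrame(rows3),
    }
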