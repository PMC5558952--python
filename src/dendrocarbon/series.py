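"""Mean tree-ring series, cross-dating coherence, diameter reconstruction.

Several radii measured on the same stem disc are averaged into one mean
tree-ring series per tree. Wedge (locally absent) rings, encoded as width 0,
are excluded from that year's mean rather than averaged in as zero growth:
the ring exists on the stem even where a given radius misses it. Diameter
trajectories follow by cumulating mean ring widths (two radii per diameter,
mm to cm), with no pith-offset or bark correction, so the reconstruction is
an under-bark, hence conservative, diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ringio import RingSeries

__all__ = [
    "DiameterTrajectory",
    "mean_tree_series",
    "crossdate_check",
    "reconstruct_diameter",
    "moving_average",
]


@dataclass(frozen=True)
class DiameterTrajectory:
    """Per-year stem diameter (cm) and annual diameter increment of one tree."""

    tree_id: str
    years: np.ndarray
    diameter_cm: np.ndarray
    annual_increment_cm: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.diameter_cm, dtype=float)
        if np.any(np.diff(d) < -1e-12):
            raise ValueError("diameter trajectory must be non-decreasing")

    @property
    def age(self) -> int:
        return int(self.diameter_cm.size)

    @property
    def final_diameter_cm(self) -> float:
        return float(self.diameter_cm[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tree_id": self.tree_id,
                "year": self.years,
                "diameter_cm": self.diameter_cm,
                "increment_cm": self.annual_increment_cm,
            }
        )


def mean_tree_series(radii: list[RingSeries]) -> RingSeries:
    """Arithmetic per-year mean across radii, excluding wedge rings.

    Radii must already be aligned at the outermost ring (equal ``last_year``)
    and cross-dated to equal ring counts. Zero-width cells (wedge rings) are
    left out of the year's mean; a year that is zero on every radius is a
    truly missing ring and keeps width 0.
    """
    if len(radii) < 2:
        raise ValueError(
            "mean_tree_series needs at least 2 radii; a single radius is not "
            "a mean series"
        )
    lengths = {r.n_years for r in radii}
    if len(lengths) > 1:
        raise ValueError(
            f"radii of unequal ring counts {sorted(lengths)}: cross-date and "
            "align the radii before averaging"
        )
    last_years = {r.last_year for r in radii}
    if len(last_years) > 1:
        raise ValueError(
            f"radii disagree on last_year {sorted(last_years)}: align at the "
            "outermost ring first"
        )
    mat = np.vstack([r.widths for r in radii])
    present = mat > 0
    counts = present.sum(axis=0)
    sums = np.where(present, mat, 0.0).sum(axis=0)
    mean = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    first = radii[0]
    return RingSeries(
        tree_id=first.tree_id,
        radius_id="mean",
        species=first.species,
        widths=mean,
        last_year=first.last_year,
    )


def crossdate_check(
    radii: list[RingSeries],
    threshold: float = 0.3,
    min_rings: int = 10,
) -> pd.DataFrame:
    """Pairwise coherence of radii after alignment at the outermost ring.

    For each pair the Pearson correlation of first-differenced log-widths is
    computed; years where either radius has a wedge ring (width 0, log
    undefined) are skipped pairwise. Pairs below ``threshold`` are flagged.
    No realignment is attempted: cross-dating itself is assumed done.

    Returns a frame with columns radius_a, radius_b, n_used, correlation,
    flag (one of "", "low_correlation", "too_short").
    """
    rows = []
    diffs = []
    for r in radii:
        w = r.widths
        valid = (w[:-1] > 0) & (w[1:] > 0)
        d = np.full(w.size - 1, np.nan)
        d[valid] = np.log(w[1:][valid]) - np.log(w[:-1][valid])
        diffs.append(d)
    for i in range(len(radii)):
        for j in range(i + 1, len(radii)):
            a, b = radii[i], radii[j]
            if a.n_years < min_rings or b.n_years < min_rings:
                rows.append((a.radius_id, b.radius_id, 0, np.nan, "too_short"))
                continue
            da, db = diffs[i], diffs[j]
            n = min(da.size, db.size)
            da, db = da[-n:], db[-n:]  # align at the outermost ring
            ok = np.isfinite(da) & np.isfinite(db)
            if ok.sum() < min_rings - 1 or np.std(da[ok]) == 0 or np.std(db[ok]) == 0:
                rows.append((a.radius_id, b.radius_id, int(ok.sum()), np.nan, "too_short"))
                continue
            r_ab = float(np.corrcoef(da[ok], db[ok])[0, 1])
            flag = "" if r_ab >= threshold else "low_correlation"
            rows.append((a.radius_id, b.radius_id, int(ok.sum()), r_ab, flag))
    return pd.DataFrame(
        rows, columns=["radius_a", "radius_b", "n_used", "correlation", "flag"]
    )


def reconstruct_diameter(mean_series: RingSeries) -> DiameterTrajectory:
    """Diameter trajectory from cumulative mean ring widths.

    ``diameter_cm[t] = 2 * sum(width_mm[1..t]) / 10`` — two radii per
    diameter, mm to cm. The annual increment telescopes back to the final
    diameter exactly.
    """
    widths = mean_series.widths
    increments = 2.0 * widths / 10.0
    return DiameterTrajectory(
        tree_id=mean_series.tree_id,
        years=mean_series.years,
        diameter_cm=np.cumsum(increments),
        annual_increment_cm=increments,
    )


def moving_average(series, window_years: int) -> np.ndarray:
    """Centred moving average with a shrinking window at the edges.

    The window must be odd; near the boundaries the mean is taken over the
    available years only, so no years are dropped and no padding is invented.
    """
    if window_years < 1:
        raise ValueError("window must be >= 1")
    if window_years % 2 == 0:
        raise ValueError("window must be odd for a centred moving average")
    x = np.asarray(getattr(series, "widths", series), dtype=float)
    if window_years == 1:
        return x.copy()
    h = window_years // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
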