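"""Ring-width I/O: Tucson/RWL decadal files and long-form tables.

The Tucson (RWL) dialect written here uses 8-character series ids, a
right-justified decade start year, and up to ten integer width fields per
line. Widths are stored in units of 0.01 mm with the ``999`` stop marker,
or in units of 0.001 mm with the ``-9999`` stop marker. A width of exactly
0 encodes a locally absent (wedge / discontinuous) ring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RingSeries",
    "TreeRecord",
    "RwlFormatError",
    "read_rwl",
    "write_rwl",
    "read_series_table",
    "write_series_table",
    "read_species_params",
    "WOOD_DENSITY_DEFAULTS",
]

#: Species-level wood densities (oven-dry mass over green volume, g cm^-3).
WOOD_DENSITY_DEFAULTS = {
    "C_odorata": 0.38,
    "H_courbaril": 0.77,
    "G_glabra": 0.72,
}

TABLE_COLUMNS = ["tree_id", "species", "radius_id", "year", "width_mm"]


class RwlFormatError(ValueError):
    """Raised when a Tucson/RWL file violates the decadal layout."""


@dataclass(frozen=True)
class RingSeries:
    """Annual ring widths of one radius, pith (innermost) to bark.

    ``last_year`` anchors the outermost ring to a calendar year (the felling
    year); series without a known felling date use cambial indices, i.e.
    ``last_year = len(widths)`` so years run 1..n.
    """

    tree_id: str
    radius_id: str
    widths: np.ndarray
    last_year: int
    species: str = ""
    resolution_mm: float = 0.01

    def __post_init__(self) -> None:
        w = np.asarray(self.widths, dtype=float)
        if w.ndim != 1 or w.size < 1:
            raise ValueError("widths must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(w)):
            raise ValueError("widths must be finite")
        if np.any(w < 0):
            raise ValueError("widths must be non-negative")
        if self.resolution_mm <= 0:
            raise ValueError("resolution_mm must be positive")
        w.flags.writeable = False
        object.__setattr__(self, "widths", w)
        object.__setattr__(self, "last_year", int(self.last_year))

    @property
    def n_years(self) -> int:
        """Cambial age in years (one ring per year)."""
        return int(self.widths.size)

    @property
    def first_year(self) -> int:
        return self.last_year - self.n_years + 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    @property
    def series_id(self) -> str:
        return f"{self.tree_id}_{self.radius_id}" if self.radius_id else self.tree_id

    def with_widths(self, widths: np.ndarray) -> "RingSeries":
        return replace(self, widths=np.asarray(widths, dtype=float))


@dataclass
class TreeRecord:
    """One tree: species parameters plus all measured radii."""

    tree_id: str
    species: str
    radii: list
    wood_density: float = 0.0
    stress_E: float = 0.0
    carbon_fraction: float = 0.471

    def __post_init__(self) -> None:
        if not self.radii:
            raise ValueError(f"tree {self.tree_id}: needs at least one radius")
        if not self.wood_density:
            try:
                self.wood_density = WOOD_DENSITY_DEFAULTS[self.species]
            except KeyError:
                raise ValueError(
                    f"tree {self.tree_id}: no wood density for species "
                    f"{self.species!r} and no default known"
                ) from None
        if self.wood_density <= 0:
            raise ValueError("wood_density must be positive")
        if not 0 < self.carbon_fraction < 1:
            raise ValueError("carbon_fraction must lie in (0, 1)")
        for r in self.radii:
            if r.tree_id != self.tree_id:
                raise ValueError(
                    f"radius {r.series_id} does not belong to tree {self.tree_id}"
                )
        last_years = {r.last_year for r in self.radii}
        if len(last_years) > 1:
            raise ValueError(
                f"tree {self.tree_id}: radii disagree on last_year {sorted(last_years)}; "
                "align radii at the outermost ring first"
            )

    @property
    def n_radii(self) -> int:
        return len(self.radii)


# ---------------------------------------------------------------------------
# Tucson / RWL decadal format
# ---------------------------------------------------------------------------

_STOP_001 = 999       # stop marker, 0.01 mm dialect
_STOP_0001 = -9999    # stop marker, 0.001 mm dialect
_MAX_FIELD = 99999    # widest value a 6-char field can carry with a separator


def _split_series_id(series_id: str) -> tuple[str, str]:
    if "_" in series_id:
        tree, _, radius = series_id.rpartition("_")
        return tree, radius
    return series_id, ""


def read_rwl(path) -> list[RingSeries]:
    """Parse a Tucson decadal ring-width file.

    Both stop-marker dialects are accepted: ``999`` (values in 0.01 mm) and
    ``-9999`` (values in 0.001 mm). Returns one :class:`RingSeries` per
    series id, widths in mm, calendar years reconstructed from the decade
    labels.
    """
    path = Path(path)
    out: list[RingSeries] = []
    cur_id: str | None = None
    cur_values: list[int] = []
    cur_first: int | None = None
    expect_year: int | None = None

    def finish(resolution: float) -> None:
        nonlocal cur_id, cur_values, cur_first, expect_year
        # divide (correctly rounded) rather than multiply by the inexact
        # binary 0.01, so decimal widths round-trip bit-exactly
        widths = np.array(cur_values, dtype=float) / round(1.0 / resolution)
        if widths.size == 0:
            raise RwlFormatError(f"series {cur_id}: stop marker with no data")
        tree, radius = _split_series_id(cur_id)
        out.append(
            RingSeries(
                tree_id=tree,
                radius_id=radius,
                widths=widths,
                last_year=cur_first + widths.size - 1,
                resolution_mm=resolution,
            )
        )
        cur_id, cur_values, cur_first, expect_year = None, [], None, None

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            # fixed layout: id cols 1-8, decade year cols 9-12, values beyond
            sid = raw[:8].strip()
            value_tokens = raw[12:].split()
            if not sid or not value_tokens:
                raise RwlFormatError(f"line {lineno}: expected id, year and values")
            try:
                year = int(raw[8:12])
            except ValueError:
                raise RwlFormatError(
                    f"line {lineno}: unreadable decade year {raw[8:12]!r}"
                )
            if sid != cur_id:
                if cur_id is not None:
                    raise RwlFormatError(
                        f"line {lineno}: series {cur_id} not terminated before {sid}"
                    )
                cur_id, cur_first, expect_year = sid, year, year
            if year != expect_year:
                raise RwlFormatError(
                    f"line {lineno}: decade year {year} does not follow "
                    f"expected {expect_year} for series {sid}"
                )
            finished = False
            for tok in value_tokens:
                try:
                    value = int(tok)
                except ValueError:
                    raise RwlFormatError(f"line {lineno}: unreadable value {tok!r}")
                if value == _STOP_0001:
                    finish(0.001)
                    finished = True
                    break
                if value == _STOP_001:
                    finish(0.01)
                    finished = True
                    break
                if value < 0:
                    raise ValueError(
                        f"line {lineno}: negative width {value} "
                        "(only the stop marker may be negative)"
                    )
                cur_values.append(value)
            if not finished:
                expect_year = (year // 10) * 10 + 10
                if len(cur_values) != expect_year - cur_first:
                    raise RwlFormatError(
                        f"line {lineno}: series {sid} has {len(value_tokens)} values "
                        f"but the decade line spans years {year}..{expect_year - 1}"
                    )
    if cur_id is not None:
        raise RwlFormatError(f"series {cur_id}: file ended before stop marker")
    return out


def write_rwl(series: Iterable[RingSeries], path) -> None:
    """Write series in the Tucson decadal layout, re-readable by read_rwl.

    The 0.01 mm / ``999`` dialect is used unless a width would itself encode
    to the stop marker, in which case that series switches to the 0.001 mm /
    ``-9999`` dialect so data and marker can never collide.
    """
    path = Path(path)
    lines: list[str] = []
    for s in series:
        resolution, stop = 0.01, _STOP_001
        values = np.rint(s.widths * 100).astype(int)
        if not np.allclose(values / 100.0, s.widths, atol=1e-9):
            raise ValueError(
                f"series {s.series_id}: widths not representable at 0.01 mm; "
                "round them or change resolution"
            )
        if np.any(values == _STOP_001):
            resolution, stop = 0.001, _STOP_0001
            values = np.rint(s.widths * 1000).astype(int)
        if np.any(values > _MAX_FIELD):
            raise ValueError(
                f"series {s.series_id}: width overflows the fixed-width field "
                f"at resolution {resolution} mm"
            )
        sid = s.series_id
        if len(sid) > 8:
            raise ValueError(f"series id {sid!r} exceeds 8 characters")
        if any(c.isspace() for c in sid):
            raise ValueError(f"series id {sid!r} contains whitespace")
        fields = [str(v) for v in values] + [str(stop)]
        year = s.first_year
        pos = 0
        while pos < len(fields):
            decade_end = (year // 10) * 10 + 9
            take = min(decade_end - year + 1, len(fields) - pos)
            row = fields[pos : pos + take]
            lines.append(f"{sid:<8}{year:>4}" + "".join(f"{v:>6}" for v in row))
            pos += take
            year += take
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Long-form delimited table
# ---------------------------------------------------------------------------

def read_series_table(path) -> list[RingSeries]:
    """Read a long-form CSV (tree_id, species, radius_id, year, width_mm).

    Rows may arrive in any order; within each radius the years must be
    contiguous and unique.
    """
    df = pd.read_csv(path, dtype={"tree_id": str, "radius_id": str, "species": str})
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"series table missing columns: {missing}")
    out: list[RingSeries] = []
    for (tree, radius), grp in df.groupby(["tree_id", "radius_id"], sort=True):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy(dtype=int)
        dup = years[:-1][np.diff(years) == 0]
        if dup.size:
            raise ValueError(
                f"radius {tree}_{radius}: duplicate years {sorted(set(dup.tolist()))}"
            )
        full = np.arange(years[0], years[-1] + 1)
        if years.size != full.size:
            gaps = sorted(set(full.tolist()) - set(years.tolist()))
            raise ValueError(f"radius {tree}_{radius}: missing years {gaps}")
        species = grp["species"].iloc[0]
        out.append(
            RingSeries(
                tree_id=str(tree),
                radius_id=str(radius),
                species="" if pd.isna(species) else str(species),
                widths=grp["width_mm"].to_numpy(dtype=float),
                last_year=int(years[-1]),
            )
        )
    return out


def write_series_table(series: Iterable[RingSeries], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "tree_id": s.tree_id,
                "species": s.species,
                "radius_id": s.radius_id,
                "year": s.years,
                "width_mm": s.widths,
            }
        )
        for s in series
    ]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=TABLE_COLUMNS)
    )
    df.to_csv(path, index=False)


def read_species_params(path) -> dict[str, dict[str, float]]:
    """Read a species parameter table (species, wood_density, carbon_fraction)."""
    df = pd.read_csv(path)
    if "species" not in df.columns or "wood_density" not in df.columns:
        raise ValueError("species table needs columns species, wood_density")
    params: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        entry = {"wood_density": float(row["wood_density"])}
        if "carbon_fraction" in df.columns and not pd.isna(row.get("carbon_fraction")):
            entry["carbon_fraction"] = float(row["carbon_fraction"])
        params[str(row["species"])] = entry
    return params
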