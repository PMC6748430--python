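"""Geographic domain types and distance providers.

A planning region consists of census output areas (OAs), each represented
by its population-weighted centroid and resident population, and candidate
testing sites (GP surgeries and pharmacies). Distances between locations
are held in a :class:`DistanceTable`; three providers are offered:

* ``euclidean`` — straight-line metres on planar coordinates,
* ``great_circle`` — haversine metres on lon/lat WGS84 coordinates,
* ``precomputed`` — a long-format table of directed street-network legs,
  the route a real deployment would take (e.g. OSRM walking distances
  exported to CSV).

Distances are stored as *directed* pairs even when generated from a
symmetric provider, because street-network walking legs need not be
symmetric (one-way systems, turn restrictions).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SiteKind",
    "CrsMode",
    "OutputArea",
    "CandidateSite",
    "Region",
    "DistanceTable",
    "Scenario",
    "load_region",
    "write_region",
    "compute_distances",
    "EARTH_RADIUS_M",
]

#: Mean Earth radius (IUGG), metres; used by the great-circle provider.
EARTH_RADIUS_M = 6_371_008.8


class SiteKind(str, enum.Enum):
    """Kind of candidate testing site."""

    GP_SURGERY = "gp_surgery"
    PHARMACY = "pharmacy"


class CrsMode(str, enum.Enum):
    """Coordinate convention declared per region."""

    PLANAR_METRES = "planar_metres"
    LONLAT_WGS84 = "lonlat_wgs84"


@dataclass(frozen=True)
class OutputArea:
    """A demand point: census output area centroid with its population."""

    id: str
    centroid: tuple[float, float]
    population: int

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ValueError(f"OA {self.id!r}: population must be >= 0")
        if not all(math.isfinite(c) for c in self.centroid):
            raise ValueError(f"OA {self.id!r}: centroid must be finite")


@dataclass(frozen=True)
class CandidateSite:
    """A potential machine host: GP surgery or pharmacy."""

    id: str
    location: tuple[float, float]
    kind: SiteKind

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.location):
            raise ValueError(f"site {self.id!r}: location must be finite")


@dataclass
class Region:
    """A named study region: output areas plus candidate sites.

    Invariants: at least one OA; at least one GP surgery (base travel is
    anchored to the nearest GP, so a region without GPs is undefined);
    ids unique within OAs and within sites.
    """

    name: str
    crs_mode: CrsMode
    oas: list[OutputArea]
    sites: list[CandidateSite]

    def __post_init__(self) -> None:
        self.crs_mode = CrsMode(self.crs_mode)
        if not self.oas:
            raise ValueError("region must contain at least one output area")
        for label, ids in (
            ("OA", [o.id for o in self.oas]),
            ("site", [s.id for s in self.sites]),
        ):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValueError(f"duplicate {label} id {i!r}")
                seen.add(i)
        if not any(s.kind is SiteKind.GP_SURGERY for s in self.sites):
            raise ValueError(
                "no GP surgery in region: base travel is undefined"
            )

    def gp_surgeries(self) -> list[CandidateSite]:
        return [s for s in self.sites if s.kind is SiteKind.GP_SURGERY]

    def pharmacies(self) -> list[CandidateSite]:
        return [s for s in self.sites if s.kind is SiteKind.PHARMACY]

    def sites_of_kinds(self, kinds: Iterable[SiteKind]) -> list[CandidateSite]:
        kinds = set(SiteKind(k) for k in kinds)
        return [s for s in self.sites if s.kind in kinds]

    def site(self, site_id: str) -> CandidateSite:
        for s in self.sites:
            if s.id == site_id:
                return s
        raise KeyError(site_id)

    def oa(self, oa_id: str) -> OutputArea:
        for o in self.oas:
            if o.id == oa_id:
                return o
        raise KeyError(oa_id)

    @property
    def total_population(self) -> int:
        return sum(o.population for o in self.oas)


class DistanceTable:
    """Directed distances in metres between identified locations.

    Entries map ``(origin_id, destination_id) -> metres``. Symmetry is not
    assumed; providers that are symmetric simply store both directions.
    """

    def __init__(self, entries: Mapping[tuple[str, str], float]):
        self._d = dict(entries)
        for (a, b), v in self._d.items():
            if v < 0:
                raise ValueError(f"negative distance {v} for ({a!r}, {b!r})")

    def __call__(self, origin: str, destination: str) -> float:
        if origin == destination:
            return 0.0
        try:
            return self._d[(origin, destination)]
        except KeyError:
            raise KeyError(
                f"no distance for pair ({origin!r}, {destination!r})"
            ) from None

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair[0] == pair[1] or pair in self._d

    def __len__(self) -> int:
        return len(self._d)

    def items(self):
        return self._d.items()


@dataclass(frozen=True)
class Scenario:
    """One planning configuration.

    Parameters
    ----------
    T:
        Maximum allowed travel burden per patient, metres. ``T = 1`` with
        GP-only candidates is the conventional base case of one machine at
        every nearest GP (1 m rather than 0 absorbs router rounding noise).
    candidate_kinds:
        Which site kinds may host machines.
    demand_rate:
        Expected tests per person per week.
    capacity:
        Tests one machine can process per week (default 175).
    """

    T: float
    candidate_kinds: frozenset[SiteKind]
    demand_rate: float
    capacity: float = 175.0
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "candidate_kinds",
            frozenset(SiteKind(k) for k in self.candidate_kinds),
        )
        if not self.candidate_kinds:
            raise ValueError("candidate_kinds must be non-empty")
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if self.demand_rate <= 0:
            raise ValueError("demand_rate must be > 0")
        if self.capacity <= 0:
            raise ValueError("capacity must be > 0")


# ---------------------------------------------------------------------------
# I/O

_OA_COLS = ["oa_id", "x", "y", "population"]
_SITE_COLS = ["site_id", "x", "y", "kind"]


def load_region(
    oa_path: str | Path,
    sites_path: str | Path,
    crs_mode: CrsMode | str = CrsMode.PLANAR_METRES,
    name: str = "region",
) -> Region:
    """Read a region from the two CSV schemas.

    OA file: ``oa_id,x,y,population``; sites file: ``site_id,x,y,kind``
    with ``kind`` in {gp_surgery, pharmacy}. ``x,y`` are lon,lat when
    ``crs_mode`` is ``lonlat_wgs84``.
    """
    crs_mode = CrsMode(crs_mode)
    oa_df = pd.read_csv(oa_path)
    site_df = pd.read_csv(sites_path)
    for path, df, cols in (
        (oa_path, oa_df, _OA_COLS),
        (sites_path, site_df, _SITE_COLS),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")

    oas = []
    for row in oa_df.itertuples(index=True):
        try:
            oas.append(
                OutputArea(
                    id=str(row.oa_id),
                    centroid=(float(row.x), float(row.y)),
                    population=int(row.population),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"{oa_path}: malformed row {row.Index + 2}: {exc}"
            ) from exc
    sites = []
    for row in site_df.itertuples(index=True):
        try:
            sites.append(
                CandidateSite(
                    id=str(row.site_id),
                    location=(float(row.x), float(row.y)),
                    kind=SiteKind(str(row.kind)),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"{sites_path}: malformed row {row.Index + 2}: {exc}"
            ) from exc
    return Region(name=name, crs_mode=crs_mode, oas=oas, sites=sites)


def write_region(
    region: Region, oa_path: str | Path, sites_path: str | Path
) -> None:
    """Write a region back to the CSV schemas read by :func:`load_region`."""
    pd.DataFrame(
        [
            {"oa_id": o.id, "x": o.centroid[0], "y": o.centroid[1],
             "population": o.population}
            for o in region.oas
        ]
    ).to_csv(oa_path, index=False)
    pd.DataFrame(
        [
            {"site_id": s.id, "x": s.location[0], "y": s.location[1],
             "kind": s.kind.value}
            for s in region.sites
        ]
    ).to_csv(sites_path, index=False)


# ---------------------------------------------------------------------------
# Distance providers


def _haversine_m(a: tuple[float, float], b: tuple[float, float]) -> float:
    lon1, lat1, lon2, lat2 = map(math.radians, (*a, *b))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = (
        math.sin(dlat / 2) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    )
    return 2 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(h)))


def _required_pairs(region: Region) -> list[tuple[str, str]]:
    """All directed pairs the burden formula can touch.

    The extended trip home -> nearest GP -> site -> home needs every
    OA->site leg in both directions plus every site->site leg.
    """
    oa_ids = [o.id for o in region.oas]
    site_ids = [s.id for s in region.sites]
    pairs: list[tuple[str, str]] = []
    for i in oa_ids:
        for j in site_ids:
            pairs.append((i, j))
            pairs.append((j, i))
    for j in site_ids:
        for k in site_ids:
            if j != k:
                pairs.append((j, k))
    return pairs


def compute_distances(
    region: Region,
    provider: str = "euclidean",
    matrix_path: str | Path | None = None,
) -> DistanceTable:
    """Build the complete distance table a burden matrix needs.

    Providers: ``euclidean`` (planar metres), ``great_circle`` (lon/lat
    WGS84), ``precomputed`` (long-format CSV ``from_id,to_id,metres``
    covering every required directed pair).
    """
    coords: dict[str, tuple[float, float]] = {
        o.id: o.centroid for o in region.oas
    }
    coords.update({s.id: s.location for s in region.sites})
    pairs = _required_pairs(region)

    if provider == "euclidean":
        if region.crs_mode is not CrsMode.PLANAR_METRES:
            raise ValueError(
                "euclidean provider requires crs_mode=planar_metres"
            )
        entries = {
            (a, b): math.dist(coords[a], coords[b]) for a, b in pairs
        }
    elif provider == "great_circle":
        if region.crs_mode is not CrsMode.LONLAT_WGS84:
            raise ValueError(
                "great_circle provider requires crs_mode=lonlat_wgs84"
            )
        entries = {
            (a, b): _haversine_m(coords[a], coords[b]) for a, b in pairs
        }
    elif provider == "precomputed":
        if matrix_path is None:
            raise ValueError("precomputed provider requires matrix_path")
        df = pd.read_csv(matrix_path)
        missing_cols = [
            c for c in ("from_id", "to_id", "metres") if c not in df.columns
        ]
        if missing_cols:
            raise ValueError(f"{matrix_path}: missing columns {missing_cols}")
        table = {
            (str(r.from_id), str(r.to_id)): float(r.metres)
            for r in df.itertuples(index=False)
        }
        entries = {}
        for a, b in pairs:
            if a == b:
                continue
            if (a, b) not in table:
                raise ValueError(
                    f"precomputed table missing pair ({a!r}, {b!r})"
                )
            entries[(a, b)] = table[(a, b)]
    else:
        raise ValueError(f"unknown distance provider {provider!r}")

    return DistanceTable(entries)
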