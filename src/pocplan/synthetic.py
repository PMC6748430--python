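"""Seeded synthetic region generators and the scenario grid.

Two geographic archetypes are emulated so the full pipeline runs with no
external data:

* **urban** — OA centroids and sites uniform over a small square
  (default 7 km side), matching the high site density of a compact city.
* **rural** — OA centroids drawn from a mixture of Gaussian "village"
  clusters over a large square (default 60 km side), with candidate
  sites placed near cluster centres, so between-village distances are
  long and a pharmacy-only network leaves remote OAs beyond short
  travel limits.

OA populations are lognormal, centred near 300 persons — the typical
magnitude of a UK census output area — and rounded to integers (floor 1).
All draws flow from a single integer seed; regions are bitwise
reproducible.

``scenario_grid`` builds the standard 20-scenario experiment per region:
candidates GP-only / pharmacy-only / both crossed with travel-burden
limits T in {1, 500, 1000, 2000} m and low/high demand, where T = 1 m
(the every-patient-at-their-nearest-GP base case) is run GP-only since a
pharmacy referral always incurs some extra travel. The low/high weekly
demand-rate defaults (0.00025 / 0.005 tests per person) are package
conventions chosen to span low- and high-utilisation regimes; real
studies should substitute locally estimated rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .region import CandidateSite, OutputArea, Region, Scenario, SiteKind

__all__ = [
    "ArchetypeSpec",
    "generate_region",
    "scenario_grid",
    "DEMAND_LOW",
    "DEMAND_HIGH",
]

#: Default weekly testing demand rates, tests/person/week (conventions).
DEMAND_LOW = 0.00025
DEMAND_HIGH = 0.005


@dataclass(frozen=True)
class ArchetypeSpec:
    """Parameters of a synthetic region draw."""

    archetype: str  # "urban" | "rural"
    n_oas: int = 50
    n_gp: int = 8
    n_pharmacies: int = 5
    side_km: float | None = None  # default 7 urban / 60 rural
    n_clusters: int = 6
    population_log_mean: float = math.log(300.0)
    population_log_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype not in ("urban", "rural"):
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if min(self.n_oas, self.n_gp) < 1 or self.n_pharmacies < 0:
            raise ValueError("need >= 1 OA and >= 1 GP surgery")
        side = self.side
        if side <= 0:
            raise ValueError("side_km must be > 0")

    @property
    def side(self) -> float:
        if self.side_km is not None:
            return self.side_km
        return 7.0 if self.archetype == "urban" else 60.0


def _populations(rng: np.random.Generator, spec: ArchetypeSpec) -> np.ndarray:
    pops = rng.lognormal(
        spec.population_log_mean, spec.population_log_sd, spec.n_oas
    )
    return np.maximum(1, np.rint(pops)).astype(int)


def generate_region(spec: ArchetypeSpec) -> Region:
    """Draw a region for the archetype; planar metres, reproducible."""
    rng = np.random.default_rng(spec.seed)
    side_m = spec.side * 1000.0

    if spec.archetype == "urban":
        oa_xy = rng.uniform(0.0, side_m, size=(spec.n_oas, 2))
        site_xy = rng.uniform(
            0.0, side_m, size=(spec.n_gp + spec.n_pharmacies, 2)
        )
    else:
        # villages: Gaussian clusters; sd ~ side/40 keeps each compact
        centres = rng.uniform(
            0.15 * side_m, 0.85 * side_m, size=(spec.n_clusters, 2)
        )
        sd = side_m / 40.0
        oa_cluster = rng.integers(0, spec.n_clusters, size=spec.n_oas)
        oa_xy = centres[oa_cluster] + rng.normal(
            0.0, sd, size=(spec.n_oas, 2)
        )
        n_sites = spec.n_gp + spec.n_pharmacies
        site_cluster = rng.integers(0, spec.n_clusters, size=n_sites)
        site_xy = centres[site_cluster] + rng.normal(
            0.0, sd / 2.0, size=(n_sites, 2)
        )
    oa_xy = np.clip(oa_xy, 0.0, side_m)
    site_xy = np.clip(site_xy, 0.0, side_m)

    pops = _populations(rng, spec)
    oas = [
        OutputArea(f"OA{k:04d}", (float(x), float(y)), int(p))
        for k, ((x, y), p) in enumerate(zip(oa_xy, pops))
    ]
    sites = []
    for k in range(spec.n_gp):
        x, y = site_xy[k]
        sites.append(
            CandidateSite(f"GP{k:03d}", (float(x), float(y)),
                          SiteKind.GP_SURGERY)
        )
    for k in range(spec.n_pharmacies):
        x, y = site_xy[spec.n_gp + k]
        sites.append(
            CandidateSite(f"PH{k:03d}", (float(x), float(y)),
                          SiteKind.PHARMACY)
        )
    return Region(
        name=f"{spec.archetype}-seed{spec.seed}",
        crs_mode="planar_metres",
        oas=oas,
        sites=sites,
    )


_GP = frozenset({SiteKind.GP_SURGERY})
_PH = frozenset({SiteKind.PHARMACY})
_BOTH = frozenset({SiteKind.GP_SURGERY, SiteKind.PHARMACY})


def scenario_grid(
    demand_low: float = DEMAND_LOW,
    demand_high: float = DEMAND_HIGH,
    capacity: float = 175.0,
) -> list[Scenario]:
    """The 20-scenario experiment grid for one region.

    GP-only x T in {1, 500, 1000, 2000} x {low, high} (8 scenarios),
    pharmacy-only and both x T in {500, 1000, 2000} x {low, high}
    (6 + 6); T = 1 is restricted to GP-only.
    """
    if demand_low <= 0 or demand_high <= 0:
        raise ValueError("demand rates must be > 0")
    grid: list[Scenario] = []
    plans: list[tuple[str, frozenset, list[float]]] = [
        ("gp", _GP, [1.0, 500.0, 1000.0, 2000.0]),
        ("pharmacy", _PH, [500.0, 1000.0, 2000.0]),
        ("both", _BOTH, [500.0, 1000.0, 2000.0]),
    ]
    for name, kinds, t_levels in plans:
        for T in t_levels:
            for dname, rate in (("low", demand_low), ("high", demand_high)):
                grid.append(
                    Scenario(
                        T=T,
                        candidate_kinds=kinds,
                        demand_rate=rate,
                        capacity=capacity,
                        label=f"{name}-T{int(T)}-{dname}",
                    )
                )
    return grid
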