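"""Solution metrics, results tables and map-ready GeoJSON export.

The four reported metrics per scenario:

* ``Mach`` — total number of testing machines placed.
* ``ATB``  — average travel burden per patient, metres: the
  population-weighted mean of assigned burdens, exempt patients
  included at their forced burden.
* ``MU``   — highest capacity utilisation across opened sites, percent:
  ``100 x assigned weekly demand / (machines x per-machine capacity)``.
* ``PS``   — percentage of patients served within the travel limit T.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .burden import BurdenMatrix, burden_matrix
from .optimize import Solution, T_TOLERANCE_M
from .region import CrsMode, Region, Scenario, SiteKind

__all__ = ["Metrics", "compute_metrics", "results_table", "export_geojson"]


@dataclass(frozen=True)
class Metrics:
    Mach: int
    ATB: float
    MU: float
    PS: float


def compute_metrics(
    solution: Solution,
    region: Region,
    scenario: Scenario,
    bm: BurdenMatrix | None = None,
    weighted: bool = True,
) -> Metrics:
    """Metrics of an optimal solution.

    ``weighted=False`` switches ATB to an unweighted mean over OAs
    (diagnostic variant; the population-weighted patient mean is the
    reported default).
    """
    if solution.status != "optimal":
        raise ValueError("metrics require an optimal solution")
    if bm is None:
        from .region import compute_distances

        provider = (
            "euclidean"
            if region.crs_mode is CrsMode.PLANAR_METRES
            else "great_circle"
        )
        bm = burden_matrix(
            region, compute_distances(region, provider),
            scenario.candidate_kinds,
        )

    pop = {o.id: o.population for o in region.oas}
    total_pop = sum(pop.values())
    served_pop = 0
    wb = 0.0
    plain = 0.0
    load: dict[str, float] = {}
    for i, j in solution.assignment.items():
        b = bm.burden[(i, j)]
        wb += pop[i] * b
        plain += b
        if b <= scenario.T + T_TOLERANCE_M:
            served_pop += pop[i]
        load[j] = load.get(j, 0.0) + pop[i] * scenario.demand_rate

    atb = (
        wb / total_pop if weighted else plain / len(solution.assignment)
    ) if total_pop else 0.0
    mu = 0.0
    for j, d in load.items():
        m = solution.machines.get(j, 0)
        if m > 0:
            mu = max(mu, 100.0 * d / (m * scenario.capacity))
    ps = 100.0 * served_pop / total_pop if total_pop else 100.0
    return Metrics(
        Mach=solution.total_machines, ATB=atb, MU=mu, PS=ps
    )


_CAND_ORDER = {"gp": 0, "pharmacy": 1, "both": 2}


def _candidate_label(scenario: Scenario) -> str:
    kinds = scenario.candidate_kinds
    if kinds == {SiteKind.GP_SURGERY, SiteKind.PHARMACY}:
        return "both"
    if kinds == {SiteKind.GP_SURGERY}:
        return "gp"
    return "pharmacy"


def _demand_label(scenario: Scenario, rows) -> str:
    rates = sorted({s.demand_rate for s, _ in rows})
    if len(rates) <= 1:
        return "low"
    return "low" if scenario.demand_rate == rates[0] else "high"


def results_table(rows: list[tuple[Scenario, Metrics]]) -> pd.DataFrame:
    """Wide results table: one row per (candidate set, T), low/high demand
    side by side, sorted by candidate set then T."""
    cols = [
        "candidates", "T", "PS",
        "Mach_low", "ATB_low", "MU_low",
        "Mach_high", "ATB_high", "MU_high",
    ]
    if not rows:
        return pd.DataFrame(columns=cols)
    records: dict[tuple[str, float], dict] = {}
    for scenario, m in rows:
        cand = _candidate_label(scenario)
        d = _demand_label(scenario, rows)
        rec = records.setdefault(
            (cand, scenario.T),
            {"candidates": cand, "T": scenario.T, "PS": m.PS},
        )
        rec[f"Mach_{d}"] = m.Mach
        rec[f"ATB_{d}"] = m.ATB
        rec[f"MU_{d}"] = m.MU
        rec["PS"] = m.PS
    df = pd.DataFrame(
        [records[k] for k in sorted(
            records, key=lambda k: (_CAND_ORDER[k[0]], k[1])
        )]
    )
    return df.reindex(columns=cols)


def export_geojson(
    solution: Solution,
    region: Region,
    bm: BurdenMatrix | None = None,
    path: str | Path | None = None,
) -> dict:
    """RFC 7946 FeatureCollection of the assignment.

    Every site becomes a point feature with ``kind``, ``machines`` and
    ``open``; every OA centroid a point feature with ``assigned_site``,
    ``burden_m``, ``exempt`` and the shared ``group`` key (the assigned
    site id) so renderers can colour assignments alike. Coordinates are
    emitted as stored: lon,lat order for WGS84 regions, planar metres
    otherwise.
    """
    features = []
    for s in region.sites:
        machines = solution.machines.get(s.id, 0)
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [s.location[0], s.location[1]],
                },
                "properties": {
                    "feature": "site",
                    "site_id": s.id,
                    "kind": s.kind.value,
                    "machines": machines,
                    "open": machines > 0,
                    "group": s.id if machines > 0 else None,
                },
            }
        )
    for o in region.oas:
        j = solution.assignment.get(o.id)
        b = None
        if bm is not None and j is not None:
            b = bm.burden.get((o.id, j))
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [o.centroid[0], o.centroid[1]],
                },
                "properties": {
                    "feature": "output_area",
                    "oa_id": o.id,
                    "population": o.population,
                    "assigned_site": j,
                    "burden_m": b,
                    "exempt": o.id in solution.exempt,
                    "group": j,
                },
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=2))
    return doc
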