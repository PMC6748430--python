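"""Travel-burden geometry.

Patients always see their GP first: the *base travel* is the return trip
home -> nearest GP surgery -> home, approximated from the OA centroid.
If the test happens at another facility j the trip becomes
home -> nearest GP -> j -> home (*extended travel*), and the *travel
burden* is the difference:

    burden(i, j) = d(i->g) + d(g->j) + d(j->i) - 2 d(i->g)

where g is OA i's nearest GP surgery. The burden of the nearest GP itself
is identically zero. Burdens are not clipped: on a non-metric precomputed
network a leg combination can come out negative, and the difference
definition is kept faithfully (a warning is logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .region import (
    CandidateSite,
    DistanceTable,
    OutputArea,
    Region,
    SiteKind,
)

__all__ = ["BurdenMatrix", "nearest_gp", "travel_burden", "burden_matrix"]

logger = logging.getLogger(__name__)


@dataclass
class BurdenMatrix:
    """Per-(OA, candidate site) extra travel, with the nearest-GP anchor.

    ``burden`` maps ``(oa_id, site_id)`` to metres for every candidate
    site; ``nearest_gp`` and ``base_travel`` are always computed over GP
    surgeries regardless of the candidate set.
    """

    nearest_gp: dict[str, str]
    base_travel: dict[str, float]
    burden: dict[tuple[str, str], float]
    candidate_sites: list[str]

    def candidates_for(self, oa_id: str) -> dict[str, float]:
        return {
            j: self.burden[(oa_id, j)]
            for j in self.candidate_sites
            if (oa_id, j) in self.burden
        }

    def to_frame(self):
        """Long-format dump `oa_id,site_id,burden_m` (debug aid)."""
        import pandas as pd

        return pd.DataFrame(
            [
                {"oa_id": i, "site_id": j, "burden_m": v}
                for (i, j), v in sorted(self.burden.items())
            ]
        )


def nearest_gp(oa: OutputArea, region: Region, D: DistanceTable) -> str:
    """Id of the GP surgery minimising d(oa -> site).

    Pharmacies are never eligible; ties broken by lexicographically
    smallest site id so reruns are deterministic.
    """
    gps = region.gp_surgeries()
    if not gps:
        raise ValueError("region has no GP surgery")
    return min(gps, key=lambda s: (D(oa.id, s.id), s.id)).id


def travel_burden(
    oa: OutputArea,
    site: CandidateSite,
    D: DistanceTable,
    gp_id: str,
) -> float:
    """Extended minus base travel, metres, for testing OA ``oa`` at ``site``."""
    home_gp = D(oa.id, gp_id)
    extended = home_gp + D(gp_id, site.id) + D(site.id, oa.id)
    return extended - 2.0 * home_gp


def burden_matrix(
    region: Region,
    D: DistanceTable,
    candidate_kinds: Iterable[SiteKind] = (
        SiteKind.GP_SURGERY,
        SiteKind.PHARMACY,
    ),
) -> BurdenMatrix:
    """Burdens for every OA x every site of the candidate kinds."""
    candidates = region.sites_of_kinds(candidate_kinds)
    if not candidates:
        raise ValueError("no candidate sites of the requested kinds")

    near: dict[str, str] = {}
    base: dict[str, float] = {}
    burden: dict[tuple[str, str], float] = {}
    n_negative = 0
    for oa in region.oas:
        g = nearest_gp(oa, region, D)
        near[oa.id] = g
        base[oa.id] = 2.0 * D(oa.id, g)
        for site in candidates:
            b = travel_burden(oa, site, D, g)
            if b < 0:
                n_negative += 1
            burden[(oa.id, site.id)] = b
    if n_negative:
        logger.warning(
            "burden matrix contains %d negative entries "
            "(non-metric distance table); values preserved",
            n_negative,
        )
    return BurdenMatrix(
        nearest_gp=near,
        base_travel=base,
        burden=burden,
        candidate_sites=[s.id for s in candidates],
    )
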