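"""Brute-force reference solver and the LINE3 worked micro-fixture.

The brute-force solver enumerates every feasible whole-OA assignment and
pairs each with its minimal machine vector; it is the independent check
the MILP optimizer is tested against on micro-instances, never a
production path.

LINE3 is a 1-D region small enough to work every quantity by hand:

    position (m):   0        1000       2000
    OAs:            A(100)   B(100)     C(100)
    sites:          GP1      PH1        GP2

Nearest GPs: A->GP1, C->GP2, B is equidistant and takes GP1 by the
smallest-id tie rule. Burdens (extended minus base trip):

    A: GP1 0, GP2 4000, PH1 2000
    B: GP1 0, GP2 2000, PH1 0
    C: GP1 4000, GP2 0, PH1 2000
"""

from __future__ import annotations

import itertools
import math

from .optimize import Instance, Solution, T_TOLERANCE_M
from .region import CandidateSite, OutputArea, Region, Scenario, SiteKind

__all__ = ["line3_region", "line3_scenario", "brute_force_solve"]

MAX_ORACLE_OAS = 8
MAX_ORACLE_SITES = 5


def line3_region() -> Region:
    """The three-OA, three-site collinear fixture (planar metres)."""
    return Region(
        name="LINE3",
        crs_mode="planar_metres",
        oas=[
            OutputArea("A", (0.0, 0.0), 100),
            OutputArea("B", (1000.0, 0.0), 100),
            OutputArea("C", (2000.0, 0.0), 100),
        ],
        sites=[
            CandidateSite("GP1", (0.0, 0.0), SiteKind.GP_SURGERY),
            CandidateSite("GP2", (2000.0, 0.0), SiteKind.GP_SURGERY),
            CandidateSite("PH1", (1000.0, 0.0), SiteKind.PHARMACY),
        ],
    )


def line3_scenario(
    T: float,
    candidate_kinds=(SiteKind.GP_SURGERY, SiteKind.PHARMACY),
    demand_rate: float = 0.005,
    capacity: float = 175.0,
) -> Scenario:
    return Scenario(
        T=T,
        candidate_kinds=frozenset(candidate_kinds),
        demand_rate=demand_rate,
        capacity=capacity,
        label="LINE3",
    )


def brute_force_solve(
    inst: Instance, max_machines_per_site: int = 3
) -> Solution:
    """Exhaustive lexicographic optimum on a micro-instance.

    Enumerates every feasible whole-OA assignment (respecting the burden
    limit for non-exempt OAs and the forced assignments of exempt ones);
    for each, the minimal feasible machine vector is
    ceil(assigned demand / capacity) per open site, since extra machines
    only worsen the lexicographic objective. Assignments needing more
    than ``max_machines_per_site`` anywhere are rejected. Optimal within
    the enumeration bounds; raises if the instance exceeds them.
    """
    oa_ids = sorted(inst.demand)
    site_ids = sorted(inst.candidate_sites)
    if len(oa_ids) > MAX_ORACLE_OAS or len(site_ids) > MAX_ORACLE_SITES:
        raise ValueError(
            f"instance too large for enumeration "
            f"({len(oa_ids)} OAs, {len(site_ids)} sites)"
        )
    if max_machines_per_site > 3:
        raise ValueError("max_machines_per_site capped at 3")

    choices = [inst.eligible_sites(i) for i in oa_ids]
    if any(not c for c in choices):
        raise ValueError("an OA has no eligible site")

    best: tuple[int, float] | None = None
    best_assignment: dict[str, str] | None = None
    for combo in itertools.product(*choices):
        load: dict[str, float] = {}
        served: set[str] = set()
        for i, j in zip(oa_ids, combo):
            load[j] = load.get(j, 0.0) + inst.demand[i]
            served.add(j)
        machines = {
            j: max(1, math.ceil(load[j] / inst.capacity - 1e-9))
            for j in served
        }
        if any(m > max_machines_per_site for m in machines.values()):
            continue
        total = sum(machines.values())
        wb = sum(
            inst.population[i] * inst.burden.burden[(i, j)]
            for i, j in zip(oa_ids, combo)
        )
        key = (total, wb)
        if best is None or key < best:
            best = key
            best_assignment = dict(zip(oa_ids, combo))

    if best is None or best_assignment is None:
        return Solution({}, {}, set(inst.forced_assignments), 0,
                        math.inf, status="infeasible")
    load = {}
    for i, j in best_assignment.items():
        load[j] = load.get(j, 0.0) + inst.demand[i]
    machines = {
        j: max(1, math.ceil(d / inst.capacity - 1e-9))
        for j, d in load.items()
    }
    return Solution(
        machines=machines,
        assignment=best_assignment,
        exempt=set(inst.forced_assignments),
        total_machines=best[0],
        weighted_burden=best[1],
        status="optimal",
    )
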