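"""Two-stage lexicographic capacitated location-allocation solver.

The planning question is solved as two sequential exact integer programs
(lexicographic order):

* **Stage 1** — minimise the total number of testing machines subject to:
  every OA assigned as a block to exactly one candidate site; the
  assignment's travel burden within the limit T (non-exempt OAs); site
  capacity ``machines x per-machine capacity`` covering assigned weekly
  demand; machine counts unbounded non-negative integers.
* **Stage 2** — with total machines capped at the stage-1 optimum M*,
  minimise the population-weighted total travel burden
  ``sum_i pop_i * burden(i, assignment(i))``.

OAs whose *minimum* achievable burden over the candidate set exceeds T
cannot be served within the limit at all (this arises in pharmacy-only
scenarios); rather than declare the model infeasible they are *exempted*:
force-assigned to their minimum-burden candidate, with their demand still
consuming capacity and their burden still counted in the stage-2
objective. When GP surgeries are among the candidates the exempt set is
empty, since the nearest GP always has burden 0.

Both stages are solved exactly with HiGHS branch-and-cut via
:func:`scipy.optimize.milp`.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix

from .burden import BurdenMatrix, burden_matrix
from .region import DistanceTable, Region, Scenario, SiteKind

__all__ = [
    "Instance",
    "Solution",
    "preprocess_exemptions",
    "build_instance",
    "solve_stage1",
    "solve_stage2",
    "solve",
    "verify_solution",
    "T_TOLERANCE_M",
]

logger = logging.getLogger(__name__)

#: Feasibility tolerance on the travel-burden limit, metres.
T_TOLERANCE_M = 1e-6


@dataclass
class Instance:
    """A fully preprocessed optimisation problem.

    ``demand`` is expected tests/week per OA (population x demand rate);
    ``forced_assignments`` pins each exempt OA to its minimum-burden
    candidate. Every non-exempt OA must have at least one candidate with
    burden <= T.
    """

    burden: BurdenMatrix
    demand: dict[str, float]
    population: dict[str, int]
    T: float
    capacity: float
    candidate_sites: list[str]
    forced_assignments: dict[str, str] = field(default_factory=dict)

    @property
    def oa_ids(self) -> list[str]:
        return list(self.demand)

    def eligible_sites(self, oa_id: str) -> list[str]:
        """Sites OA ``oa_id`` may be assigned to in the optimisation."""
        if oa_id in self.forced_assignments:
            return [self.forced_assignments[oa_id]]
        row = self.burden.candidates_for(oa_id)
        return sorted(
            j for j, b in row.items() if b <= self.T + T_TOLERANCE_M
        )

    def validate(self) -> None:
        for i, d in self.demand.items():
            if d < 0:
                raise ValueError(f"OA {i!r}: negative demand")
        cand = set(self.candidate_sites)
        for i, j in self.forced_assignments.items():
            if j not in cand:
                raise ValueError(
                    f"forced assignment of {i!r} targets non-candidate {j!r}"
                )
        for i in self.demand:
            if not self.eligible_sites(i):
                raise ValueError(
                    f"OA {i!r} has no candidate within T and is not exempt"
                )


@dataclass
class Solution:
    """A machine placement plus whole-OA assignment, with objectives."""

    machines: dict[str, int]
    assignment: dict[str, str]
    exempt: set[str]
    total_machines: int
    weighted_burden: float
    status: str = "optimal"

    def to_dict(self, scenario: Scenario | None = None,
                burden: BurdenMatrix | None = None) -> dict:
        doc: dict = {
            "total_machines": self.total_machines,
            "weighted_burden": self.weighted_burden,
            "status": self.status,
            "machines": [
                {"site_id": j, "count": c}
                for j, c in sorted(self.machines.items())
            ],
            "assignment": [
                {
                    "oa_id": i,
                    "site_id": j,
                    "burden_m": (
                        burden.burden[(i, j)] if burden is not None else None
                    ),
                    "exempt": i in self.exempt,
                }
                for i, j in sorted(self.assignment.items())
            ],
        }
        if scenario is not None:
            doc["scenario"] = {
                "label": scenario.label,
                "T": scenario.T,
                "candidate_kinds": sorted(
                    k.value for k in scenario.candidate_kinds
                ),
                "demand_rate": scenario.demand_rate,
                "capacity": scenario.capacity,
            }
        return doc

    def to_json(self, path: str | Path, **kwargs) -> None:
        Path(path).write_text(json.dumps(self.to_dict(**kwargs), indent=2))


def preprocess_exemptions(
    burden: BurdenMatrix,
    candidates: list[str],
    T: float,
) -> tuple[set[str], dict[str, str]]:
    """Exempt every OA whose minimum candidate burden exceeds T.

    Each exempt OA is force-assigned to its minimum-burden candidate
    (ties broken by smallest site id). With GP surgeries among the
    candidates the exempt set is always empty.
    """
    if not candidates:
        raise ValueError("candidate set must be non-empty")
    exempt: set[str] = set()
    forced: dict[str, str] = {}
    for oa_id in burden.nearest_gp:
        row = {
            j: burden.burden[(oa_id, j)]
            for j in candidates
            if (oa_id, j) in burden.burden
        }
        best = min(row.values())
        if best > T + T_TOLERANCE_M:
            exempt.add(oa_id)
            forced[oa_id] = min(
                (j for j, b in row.items() if b == best), key=str
            )
    return exempt, forced


def build_instance(
    region: Region,
    bm: BurdenMatrix,
    scenario: Scenario,
) -> Instance:
    """Assemble demand, exemptions and candidate lists for one scenario."""
    exempt, forced = preprocess_exemptions(
        bm, bm.candidate_sites, scenario.T
    )
    inst = Instance(
        burden=bm,
        demand={
            o.id: o.population * scenario.demand_rate for o in region.oas
        },
        population={o.id: o.population for o in region.oas},
        T=scenario.T,
        capacity=scenario.capacity,
        candidate_sites=list(bm.candidate_sites),
        forced_assignments=forced,
    )
    inst.validate()
    return inst


# ---------------------------------------------------------------------------
# MILP assembly


def _solve_milp(inst: Instance, machine_cap: int | None):
    """Shared MILP core; ``machine_cap=None`` -> stage 1, else stage 2.

    Variables: one binary x_(i,j) per eligible (OA, site) pair, then one
    integer y_j per candidate site. Fixed variable ordering (sorted ids)
    keeps HiGHS runs reproducible.
    """
    oa_ids = sorted(inst.demand)
    site_ids = sorted(inst.candidate_sites)
    pairs = [
        (i, j) for i in oa_ids for j in sorted(inst.eligible_sites(i))
    ]
    n_x = len(pairs)
    n_y = len(site_ids)
    n = n_x + n_y
    pair_idx = {p: k for k, p in enumerate(pairs)}
    site_idx = {j: n_x + k for k, j in enumerate(site_ids)}

    total_demand = sum(inst.demand.values())
    y_max = max(1, math.ceil(total_demand / inst.capacity - 1e-9))

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    lb_c: list[float] = []
    ub_c: list[float] = []
    r = 0

    # each OA assigned to exactly one eligible site
    for i in oa_ids:
        for j in inst.eligible_sites(i):
            rows.append(r)
            cols.append(pair_idx[(i, j)])
            vals.append(1.0)
        lb_c.append(1.0)
        ub_c.append(1.0)
        r += 1

    # capacity: sum_i demand_i x_ij - capacity * y_j <= 0
    by_site: dict[str, list[tuple[str, str]]] = {j: [] for j in site_ids}
    for (i, j) in pairs:
        by_site[j].append((i, j))
    for j in site_ids:
        for p in by_site[j]:
            rows.append(r)
            cols.append(pair_idx[p])
            vals.append(inst.demand[p[0]])
        rows.append(r)
        cols.append(site_idx[j])
        vals.append(-inst.capacity)
        lb_c.append(-np.inf)
        ub_c.append(0.0)
        r += 1

    # link: x_ij <= y_j (a site with any assignee needs >= 1 machine,
    # even if its assigned demand is zero)
    for p in pairs:
        rows.append(r)
        cols.append(pair_idx[p])
        vals.append(1.0)
        rows.append(r)
        cols.append(site_idx[p[1]])
        vals.append(-1.0)
        lb_c.append(-np.inf)
        ub_c.append(0.0)
        r += 1

    if machine_cap is not None:
        for j in site_ids:
            rows.append(r)
            cols.append(site_idx[j])
            vals.append(1.0)
        lb_c.append(-np.inf)
        ub_c.append(float(machine_cap))
        r += 1

    A = csr_matrix((vals, (rows, cols)), shape=(r, n))
    constraints = LinearConstraint(A, lb_c, ub_c)

    c = np.zeros(n)
    if machine_cap is None:
        c[n_x:] = 1.0
    else:
        for p, k in pair_idx.items():
            c[k] = inst.population[p[0]] * inst.burden.burden[p]

    lb = np.zeros(n)
    ub = np.ones(n)
    ub[n_x:] = y_max
    # forced (exempt) OAs have a single eligible site; pin the variable
    for i, j in inst.forced_assignments.items():
        lb[pair_idx[(i, j)]] = 1.0

    res = milp(
        c=c,
        constraints=constraints,
        integrality=np.ones(n),
        bounds=Bounds(lb, ub),
    )
    if res.status != 0:
        return None, res
    x = res.x
    assignment: dict[str, str] = {}
    for (i, j), k in pair_idx.items():
        if x[k] > 0.5:
            assignment[i] = j
    return assignment, res


def _machines_from_assignment(
    inst: Instance, assignment: dict[str, str]
) -> dict[str, int]:
    """Minimal machine counts serving an assignment.

    ceil(assigned demand / capacity), at least one machine wherever any
    OA is assigned. Deriving counts from the assignment (rather than
    reading solver y-values) makes the reported placement deterministic
    across backends.
    """
    load: dict[str, float] = {}
    served: dict[str, int] = {}
    for i, j in assignment.items():
        load[j] = load.get(j, 0.0) + inst.demand[i]
        served[j] = served.get(j, 0) + 1
    machines = {}
    for j, d in load.items():
        machines[j] = max(1, math.ceil(d / inst.capacity - 1e-9))
    return machines


def _weighted_burden(inst: Instance, assignment: dict[str, str]) -> float:
    return sum(
        inst.population[i] * inst.burden.burden[(i, j)]
        for i, j in assignment.items()
    )


def solve_stage1(inst: Instance) -> tuple[int, Solution]:
    """Minimum total machine count, with a witness solution."""
    inst.validate()
    assignment, res = _solve_milp(inst, machine_cap=None)
    if assignment is None:
        return 0, Solution({}, {}, set(inst.forced_assignments), 0,
                           math.inf, status="infeasible")
    machines = _machines_from_assignment(inst, assignment)
    total = sum(machines.values())
    witness = Solution(
        machines=machines,
        assignment=assignment,
        exempt=set(inst.forced_assignments),
        total_machines=total,
        weighted_burden=_weighted_burden(inst, assignment),
        status="optimal",
    )
    return total, witness


def solve_stage2(inst: Instance, m_star: int) -> Solution:
    """Minimum population-weighted burden among solutions with <= M* machines."""
    inst.validate()
    assignment, res = _solve_milp(inst, machine_cap=m_star)
    if assignment is None:
        return Solution({}, {}, set(inst.forced_assignments), 0,
                        math.inf, status="infeasible")
    machines = _machines_from_assignment(inst, assignment)
    return Solution(
        machines=machines,
        assignment=assignment,
        exempt=set(inst.forced_assignments),
        total_machines=sum(machines.values()),
        weighted_burden=_weighted_burden(inst, assignment),
        status="optimal",
    )


def solve(
    region: Region,
    D: DistanceTable,
    scenario: Scenario,
) -> Solution:
    """Full pipeline: burden matrix, exemptions, stage 1 then stage 2."""
    if (
        scenario.T < 500
        and SiteKind.GP_SURGERY not in scenario.candidate_kinds
    ):
        logger.warning(
            "T=%g m without GP candidates: very tight limits are the "
            "GP-only base-case convention; expect many exemptions",
            scenario.T,
        )
    bm = burden_matrix(region, D, scenario.candidate_kinds)
    inst = build_instance(region, bm, scenario)
    m_star, witness = solve_stage1(inst)
    if witness.status != "optimal":
        return witness
    return solve_stage2(inst, m_star)


def verify_solution(inst: Instance, sol: Solution) -> list[str]:
    """Independent feasibility check; returns a list of violations.

    Deliberately re-derives every invariant from the instance rather than
    trusting solver bookkeeping: single assignment per OA, open-site
    machines, burden limit on non-exempt OAs, site capacity, machine
    total, objective consistency.
    """
    problems: list[str] = []
    if set(sol.assignment) != set(inst.demand):
        problems.append("assignment does not cover exactly the OA set")
    load: dict[str, float] = {}
    for i, j in sol.assignment.items():
        if j not in inst.candidate_sites:
            problems.append(f"OA {i} assigned to non-candidate {j}")
            continue
        if sol.machines.get(j, 0) < 1:
            problems.append(f"OA {i} assigned to machineless site {j}")
        b = inst.burden.burden.get((i, j))
        if b is None:
            problems.append(f"no burden entry for ({i}, {j})")
            continue
        if i not in sol.exempt and b > inst.T + T_TOLERANCE_M:
            problems.append(
                f"OA {i} burden {b} exceeds T={inst.T} (not exempt)"
            )
        if i in sol.exempt and inst.forced_assignments.get(i) != j:
            problems.append(f"exempt OA {i} not at its forced site")
        load[j] = load.get(j, 0.0) + inst.demand[i]
    for j, d in load.items():
        cap = sol.machines.get(j, 0) * inst.capacity
        if d > cap + 1e-9:
            problems.append(f"site {j} load {d} exceeds capacity {cap}")
    if sol.total_machines != sum(sol.machines.values()):
        problems.append("total_machines inconsistent with machine counts")
    wb = sum(
        inst.population[i] * inst.burden.burden[(i, j)]
        for i, j in sol.assignment.items()
        if (i, j) in inst.burden.burden
    )
    if not math.isclose(wb, sol.weighted_burden, rel_tol=1e-9, abs_tol=1e-6):
        problems.append(
            f"weighted_burden {sol.weighted_burden} != recomputed {wb}"
        )
    return problems
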