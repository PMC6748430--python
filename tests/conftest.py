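import pytest

import pocplan as p


@pytest.fixture(scope="session")
def line3():
    """LINE3 region with its euclidean distance table."""
    region = p.line3_region()
    D = p.compute_distances(region, "euclidean")
    return region, D


def make_micro_instance(rng, force_candidates=None):
    """Random micro-instance within the brute-force enumeration bounds.

    Capacity is drawn relative to total demand so that no assignment ever
    needs more than three machines at one site, yet the capacity
    constraint binds in a fair share of draws.
    """
    import numpy as np

    n_oas = int(rng.integers(2, 7))
    n_gp = int(rng.integers(1, 4))
    n_ph = int(rng.integers(0, 4 - n_gp + 1))
    oas = [
        p.OutputArea(
            f"O{k}",
            (float(rng.uniform(0, 3000)), float(rng.uniform(0, 3000))),
            int(rng.integers(1, 400)),
        )
        for k in range(n_oas)
    ]
    sites = [
        p.CandidateSite(
            f"G{k}",
            (float(rng.uniform(0, 3000)), float(rng.uniform(0, 3000))),
            p.SiteKind.GP_SURGERY,
        )
        for k in range(n_gp)
    ] + [
        p.CandidateSite(
            f"P{k}",
            (float(rng.uniform(0, 3000)), float(rng.uniform(0, 3000))),
            p.SiteKind.PHARMACY,
        )
        for k in range(n_ph)
    ]
    region = p.Region("micro", "planar_metres", oas, sites)
    D = p.compute_distances(region, "euclidean")

    options = [frozenset({p.SiteKind.GP_SURGERY})]
    if n_ph:
        options += [
            frozenset({p.SiteKind.PHARMACY}),
            frozenset({p.SiteKind.GP_SURGERY, p.SiteKind.PHARMACY}),
        ]
    kinds = (
        force_candidates
        if force_candidates is not None
        else options[int(rng.integers(0, len(options)))]
    )
    T = float(rng.choice([0.0, 250.0, 500.0, 1000.0, 2000.0]))
    rate = float(rng.uniform(0.001, 0.05))
    total_demand = sum(o.population for o in oas) * rate
    capacity = total_demand / float(rng.uniform(0.5, 3.0))
    scenario = p.Scenario(
        T=T, candidate_kinds=kinds, demand_rate=rate, capacity=capacity
    )
    bm = p.burden_matrix(region, D, kinds)
    return region, D, scenario, p.build_instance(region, bm, scenario)
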