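"""Shared fixtures and the quadrature likelihood oracle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from multinbda import (
    AssociationNetwork,
    DiffusionData,
    IndividualCovariates,
    ModelSpec,
    NetworkStack,
    acquisition_rate,
    tie_matrix,
)


@pytest.fixture
def tiny_stack():
    """Five individuals, two species, two hand-written layers."""
    ids = ["A", "B", "C", "D", "E"]
    intra = np.array(
        [
            [0.0, 0.5, 0.2, 0.0, 0.0],
            [0.5, 0.0, 0.4, 0.0, 0.0],
            [0.2, 0.4, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0, 0.6],
            [0.0, 0.0, 0.0, 0.6, 0.0],
        ]
    )
    inter = np.array(
        [
            [0.0, 0.0, 0.0, 0.3, 0.1],
            [0.0, 0.0, 0.0, 0.0, 0.2],
            [0.0, 0.0, 0.0, 0.5, 0.0],
            [0.3, 0.0, 0.5, 0.0, 0.0],
            [0.1, 0.2, 0.0, 0.0, 0.0],
        ]
    )
    return NetworkStack(
        layers=[AssociationNetwork(ids, intra), AssociationNetwork(ids, inter)],
        layer_names=["intra", "inter"],
    )


@pytest.fixture
def tiny_cov(tiny_stack):
    return IndividualCovariates(
        pd.DataFrame(
            {
                "id": tiny_stack.node_ids,
                "species": ["blue", "blue", "blue", "great", "great"],
                "site": ["s1"] * 5,
                "n_obs": [120, 90, 150, 60, 200],
            }
        )
    )


def loglik_by_quadrature(diff, stack, cov, spec, params) -> float:
    """Adaptive-quadrature oracle for the diffusion log-likelihood.

    Integrates the pointwise hazard of every individual numerically and adds
    the event log-hazards with the informed state taken strictly before each
    arrival; independent of the closed-form piecewise evaluation.
    """
    node_ids = stack.node_ids
    p = dict(params)
    if spec.use_ties:
        p["tie_mask"] = tie_matrix(diff, node_ids)
    ev_times = sorted(diff.arrivals.values())

    def informed_before(t):
        return {k for k, v in diff.arrivals.items() if v < t} | set(diff.seeded)

    ll = 0.0
    for ind in node_ids:
        if ind in diff.seeded:
            continue
        tau = min(diff.arrivals.get(ind, diff.t_end), diff.t_end)
        pts = [t for t in ev_times if t < tau]
        integral, _ = quad(
            lambda u: acquisition_rate(
                ind, u, informed_before(u), stack, cov, spec, p
            ),
            0.0,
            tau,
            points=pts,
            limit=400,
            epsabs=1e-11,
            epsrel=1e-11,
        )
        ll -= integral
        if ind in diff.arrivals:
            t_i = diff.arrivals[ind]
            ll += np.log(
                acquisition_rate(
                    ind, t_i, informed_before(t_i), stack, cov, spec, p
                )
            )
    return ll


def random_instance(rng, n_max=5, baseline="constant"):
    """Random small diffusion problem for oracle cross-checks."""
    n = int(rng.integers(3, n_max + 1))
    ids = [f"N{k}" for k in range(n)]
    layers = []
    for _ in range(2):
        w = np.triu(rng.random((n, n)) * (rng.random((n, n)) < 0.7), k=1)
        w = w + w.T
        layers.append(AssociationNetwork(ids, w))
    stack = NetworkStack(layers=layers, layer_names=["intra", "inter"])
    cov = IndividualCovariates(
        pd.DataFrame(
            {
                "id": ids,
                "species": rng.choice(["blue", "great"], size=n),
                "site": "s1",
                "n_obs": rng.integers(10, 300, size=n),
            }
        )
    )
    t_end = 1000.0
    n_arr = int(rng.integers(1, n))
    who = rng.choice(n, size=n_arr, replace=False)
    times = np.sort(rng.uniform(1.0, t_end, size=n_arr))
    diff = DiffusionData(
        "rand",
        "s1",
        t_end,
        {ids[w]: float(t) for w, t in zip(who, times)},
        tie_window=float(rng.choice([0.0, 150.0, 600.0])),
    )
    ilv_mode = str(rng.choice(["none", "additive", "multiplicative"]))
    spec = ModelSpec(
        baseline=baseline,
        ilv_mode=ilv_mode,
        layer_constraint="free",
        ilv_names=("species", "n_obs") if ilv_mode != "none" else (),
        use_ties=bool(rng.integers(0, 2)),
    )
    n_beta = len(cov.design_columns(spec.ilv_names)) if spec.ilv_names else 0
    params = {
        "lambda0": float(rng.uniform(1e-4, 5e-3)),
        "s": {"intra": float(rng.uniform(0, 3)), "inter": float(rng.uniform(0, 3))},
        "beta": rng.normal(0, 0.4, size=n_beta),
    }
    if baseline == "weibull":
        params["kappa"] = float(rng.uniform(0.7, 1.6))
    return diff, stack, cov, spec, params
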