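"""Shared fixtures and the brute-force LP oracle.

The oracle enumerates every basic feasible solution (vertex) of the
bounded flux polytope {v : S v = 0, lb <= v <= ub} by fixing n - rank(S)
fluxes at a bound and solving the remaining square system.  It is
exponential in the reaction count and therefore only usable on toy
networks, which is exactly what makes it independent of the LP engine
it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from bfgem.fba import MediumSpec, apply_medium
from bfgem.model import MetabolicModel, Metabolite, Reaction, stoichiometric_matrix
from bfgem.synth import ToySpec, toy_branch, toy_chain, toy_fermenter, toy_medium, toy_parallel


def enumerate_vertices(model: MetabolicModel) -> np.ndarray:
    """All vertices of the flux polytope, rows = flux vectors.

    Requires finite bounds on every reaction.
    """
    S = stoichiometric_matrix(model).toarray()
    lb = np.array([r.lower_bound for r in model.reactions.values()])
    ub = np.array([r.upper_bound for r in model.reactions.values()])
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
        raise ValueError("oracle needs finite bounds")
    m, n = S.shape
    rank = np.linalg.matrix_rank(S)
    vertices = []
    for free in itertools.combinations(range(n), n - rank):
        basic = [j for j in range(n) if j not in free]
        B = S[:, basic]
        if np.linalg.matrix_rank(B) < rank:
            continue
        for choice in itertools.product(*[(lb[j], ub[j]) for j in free]):
            rhs = -S[:, list(free)] @ np.array(choice) if free else np.zeros(m)
            sol, *_ = np.linalg.lstsq(B, rhs, rcond=None)
            v = np.zeros(n)
            v[list(free)] = choice
            v[basic] = sol
            if np.max(np.abs(S @ v)) > 1e-8:
                continue
            if np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9):
                vertices.append(np.clip(v, lb, ub))
    if not vertices:
        raise ValueError("polytope has no vertices (infeasible?)")
    return np.unique(np.round(np.array(vertices), 10), axis=0)


def oracle_optimum(model: MetabolicModel, objective: str, direction: str = "max") -> float:
    """LP optimum by exhaustive vertex enumeration."""
    j = list(model.reactions).index(objective)
    values = enumerate_vertices(model)[:, j]
    return float(values.max() if direction == "max" else values.min())


# -- micro-models ---------------------------------------------------------

build_parallel_toy = toy_parallel
build_branch_toy = toy_branch


# -- fixtures --------------------------------------------------------------

@pytest.fixture(scope="session")
def toy_spec() -> ToySpec:
    return ToySpec()


@pytest.fixture(scope="session")
def toy(toy_spec) -> MetabolicModel:
    return toy_fermenter(toy_spec)


@pytest.fixture(scope="session")
def toy_on_glucose(toy, toy_spec) -> MetabolicModel:
    return apply_medium(toy, toy_medium(toy_spec))


@pytest.fixture()
def chain() -> MetabolicModel:
    return toy_chain()
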