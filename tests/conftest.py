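"""Shared oracles for the test suite.

The expensive correctness checks in this suite compare the h-transform
machinery against routes that do not share code with it: exact enumeration
of all paths of a small chain, rejection sampling from the unconditioned
chain, and closed-form birth–death absorption probabilities.
"""

from __future__ import annotations

import numpy as np
import pytest

from selbridge import ModelSpec, build_transition_matrix


def enumerate_paths(P: np.ndarray, i0: int, T: int):
    """All positive-probability paths of length ``T`` from ``i0``.

    Returns a list of ``(path_tuple, probability)`` pairs; probabilities sum
    to one.  Exponential in ``T`` — use only on tiny chains.
    """
    paths = [((i0,), 1.0)]
    for _ in range(T):
        nxt = []
        for path, prob in paths:
            i = path[-1]
            for j in np.flatnonzero(P[i]):
                nxt.append((path + (int(j),), prob * P[i, j]))
        paths = nxt
    return paths


def bridge_law_by_enumeration(P: np.ndarray, i0: int, k: int, T: int) -> dict:
    """Exact law of the ``T``-step bridge from ``i0`` to ``k`` by renormalization."""
    paths = enumerate_paths(P, i0, T)
    hits = {path: prob for path, prob in paths if path[-1] == k}
    total = sum(hits.values())
    if total <= 0:
        raise ValueError("bridge infeasible")
    return {path: prob / total for path, prob in hits.items()}


@pytest.fixture(scope="session")
def moran6_s2():
    return build_transition_matrix(ModelSpec("moran", 6, 2.0))


@pytest.fixture(scope="session")
def moran4_neutral():
    return build_transition_matrix(ModelSpec("moran", 4, 1.0))
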