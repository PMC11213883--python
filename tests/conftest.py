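"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the library's own algorithms: likelihoods are
computed by exhaustive summation over internal-node state assignments,
parsimony scores by enumeration over labelings, and HPD intervals by a plain
window scan.  They are only feasible on tiny inputs, which is the point.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from lexiphylo.covarion import (ClockModel, CovarionParams,
                                TransitionMatrixCache,
                                stationary_distribution)
from lexiphylo.simulate import simulate_yule_tree
from lexiphylo.trees import TimeTree

_PARTIAL = {0: [1.0, 0, 1, 0], 1: [0, 1.0, 0, 1], -1: [1.0, 1, 1, 1]}


def enum_column_prob(tree: TimeTree, clock: ClockModel, params: CovarionParams,
                     column: dict[str, int], rate_multiplier: float = 1.0
                     ) -> float:
    """Column probability by brute-force sum over internal state assignments."""
    cache = TransitionMatrixCache(params)
    pi = stationary_distribution(params)
    nodes = tree.postorder()
    internals = [n for n in nodes if not n.is_leaf]
    P = {n.index: cache.probabilities((n.parent.age - n.age) * clock.mean_rate
                                      * n.rate * rate_multiplier)
         for n in nodes if n.parent is not None}
    total = 0.0
    for assign in itertools.product(range(4), repeat=len(internals)):
        st = {n.index: s for n, s in zip(internals, assign)}
        p = pi[st[tree.root.index]]
        for n in nodes:
            if n.parent is None:
                continue
            if n.is_leaf:
                p *= sum(P[n.index][st[n.parent.index], k]
                         * _PARTIAL[column[n.label]][k] for k in range(4))
            else:
                p *= P[n.index][st[n.parent.index], st[n.index]]
        total += p
    return total


def enum_joint_internal(tree: TimeTree, clock: ClockModel,
                        params: CovarionParams, column: dict[str, int]
                        ) -> tuple[dict[tuple[int, ...], float], list]:
    """Exact conditional joint over internal-node states given a column."""
    cache = TransitionMatrixCache(params)
    pi = stationary_distribution(params)
    nodes = tree.postorder()
    internals = [n for n in nodes if not n.is_leaf]
    P = {n.index: cache.probabilities((n.parent.age - n.age)
                                      * clock.mean_rate * n.rate)
         for n in nodes if n.parent is not None}
    probs: dict[tuple[int, ...], float] = {}
    for assign in itertools.product(range(4), repeat=len(internals)):
        st = {n.index: s for n, s in zip(internals, assign)}
        p = pi[st[tree.root.index]]
        for n in nodes:
            if n.parent is None:
                continue
            if n.is_leaf:
                p *= sum(P[n.index][st[n.parent.index], k]
                         * _PARTIAL[column[n.label]][k] for k in range(4))
            else:
                p *= P[n.index][st[n.parent.index], st[n.index]]
        probs[assign] = p
    z = sum(probs.values())
    return {k: v / z for k, v in probs.items()}, internals


def brute_force_parsimony(tree: TimeTree, trait: dict[str, str],
                          root_state: str, states=("background", "negrito")
                          ) -> int:
    """Minimum change count over all internal labelings with a fixed root."""
    internals = [n for n in tree.postorder() if not n.is_leaf]
    best = math.inf
    for assign in itertools.product(states, repeat=len(internals)):
        st = {n.index: s for n, s in zip(internals, assign)}
        if st[tree.root.index] != root_state:
            continue
        for tip in tree.tips:
            st[tip.index] = trait[tip.label]
        changes = sum(1 for n in tree.postorder()
                      if n.parent is not None
                      and st[n.index] != st[n.parent.index])
        best = min(best, changes)
    return int(best)


def hpd_window_scan(samples, mass: float) -> tuple[float, float]:
    """Reference HPD: scan every window of ceil(mass*N) sorted samples."""
    x = sorted(float(v) for v in samples)
    n = len(x)
    k = max(math.ceil(mass * n), 1)
    best = None
    for i in range(n - k + 1):
        lo, hi = x[i], x[i + k - 1]
        if best is None or hi - lo < best[1] - best[0]:
            best = (lo, hi)
    return best


def random_params(rng: np.random.Generator) -> CovarionParams:
    f1 = float(rng.uniform(0.02, 0.5))
    return CovarionParams(alpha=float(rng.uniform(0.05, 1.0)),
                          s=float(rng.uniform(0.05, 3.0)),
                          f_absent=1.0 - f1, f_present=f1)


def random_tree(n_taxa: int, rng: np.random.Generator,
                root_age: float = 5000.0) -> TimeTree:
    return simulate_yule_tree(n_taxa, 1.0 / root_age, root_age, rng)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture
def cherry_tree() -> TimeTree:
    return TimeTree.from_newick("(A:1000,B:1000);")


@pytest.fixture
def four_taxon_tree() -> TimeTree:
    return TimeTree.from_newick("((A:1000,B:1000):1500,(C:2000,D:2000):500);")
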