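"""Probabilistic reconstruction of lexical innovations on a clade's stem.

A cognate set counts as an *innovation* for a focal clade when it is
reconstructed as observed-absent (covarion states 0 or 2) at the clade's
origin node (the parent of the MRCA) and observed-present (states 1 or 3) at
the MRCA itself — i.e. the gain happened on the stem branch.  At every
sampled generation of the posterior one joint ancestral-state draw is made
per cognate; the innovation posterior probability is the fraction of draws
in which the indicator fires.

Joint draws are exact: tip-to-root partials (inside probabilities) followed
by root-to-tip stochastic traceback, sampling each node conditional on its
parent's sampled state.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .cognate_data import CognateMatrix, MISSING
from .covarion import ClockModel, CovarionParams, stationary_distribution
from .likelihood import LikelihoodEngine
from .mcmc import PosteriorSample
from .trees import Node, TimeTree

__all__ = [
    "InnovationTable", "joint_state_sample", "sample_node_states",
    "innovation_posterior", "list_innovations",
]

_OBSERVED_ABSENT = (0, 2)
_OBSERVED_PRESENT = (1, 3)


@dataclass
class InnovationTable:
    """Per-cognate innovation posterior probabilities for one focal clade."""

    probabilities: pd.Series          # index: cognate id
    clade: frozenset[str]
    n_samples: int
    monophyly_fraction: float
    n_skipped_root: int = 0           # samples where the MRCA was the root

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("sample count must be positive")
        p = self.probabilities
        if ((p < 0) | (p > 1)).any():
            raise ValueError("innovation probabilities must lie in [0, 1]")


def sample_node_states(tree: TimeTree, clock: ClockModel, params: CovarionParams,
                       columns: np.ndarray, rng: np.random.Generator,
                       rate_multipliers: Optional[np.ndarray] = None,
                       ) -> np.ndarray:
    """One exact joint draw of covarion states at every node, per column.

    ``columns``: (n_columns, n_tips) in {0, 1, MISSING}, tip order matching
    ``tree.tips``.  ``rate_multipliers`` optionally scales branch distances
    per column (partition bins).  Returns (n_nodes, n_columns) states 0..3.
    """
    columns = np.atleast_2d(columns)
    ncol = columns.shape[0]
    engine = LikelihoodEngine(tree, clock, params)
    nodes = tree.postorder()
    tips = tree.tips
    mult = np.ones(ncol) if rate_multipliers is None else np.asarray(rate_multipliers)

    # inside (partial) vectors, one pruning pass per distinct multiplier
    partials = np.empty((len(nodes), ncol, 4))
    pmats = {}
    for m in np.unique(mult):
        pmats[m] = engine._transition_matrices(float(m))
    tip_lookup = np.stack([np.array([1.0, 0, 1, 0]), np.array([0, 1.0, 0, 1]),
                           np.ones(4)])
    state_idx = np.where(columns == MISSING, 2, columns)
    for t, tip in enumerate(tips):
        partials[tip.index] = tip_lookup[state_idx[:, t]]
    for node in nodes:
        if node.is_leaf:
            continue
        acc = np.ones((ncol, 4))
        for child in node.children:
            lifted = np.empty((ncol, 4))
            for m in np.unique(mult):
                sel = mult == m
                lifted[sel] = partials[child.index][sel] @ pmats[m][child.index].T
            acc *= lifted
        mx = acc.max(axis=1)
        mx = np.where(mx > 0, mx, 1.0)
        partials[node.index] = acc / mx[:, None]

    # root-to-tip stochastic traceback
    pi = stationary_distribution(params)
    states = np.empty((len(nodes), ncol), dtype=np.int8)
    root = tree.root
    w = partials[root.index] * pi
    states[root.index] = _categorical_rows(w, rng)
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_states = states[node.parent.index]
        w = np.empty((ncol, 4))
        for m in np.unique(mult):
            sel = mult == m
            P = pmats[m][node.index]
            w[sel] = P[parent_states[sel]] * partials[node.index][sel]
        states[node.index] = _categorical_rows(w, rng)
    return states


def _categorical_rows(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    totals = weights.sum(axis=1, keepdims=True)
    bad = totals[:, 0] <= 0
    if bad.any():
        # impossible column under this tree: fall back to uniform (the
        # corresponding likelihood is zero and the caller will have rejected)
        weights = weights.copy()
        weights[bad] = 1.0
        totals = weights.sum(axis=1, keepdims=True)
    cum = np.cumsum(weights / totals, axis=1)
    u = rng.random((weights.shape[0], 1))
    return (u > cum).sum(axis=1).astype(np.int8)


def joint_state_sample(tree: TimeTree, clock: ClockModel, params: CovarionParams,
                       column: Mapping[str, int], origin: Node, mrca: Node,
                       rng: np.random.Generator) -> tuple[int, int]:
    """One draw of (state at origin, state at MRCA) given a single column."""
    if mrca.parent is None:
        raise ValueError("the MRCA is the root: no origin node exists")
    if origin is not mrca.parent:
        raise ValueError("origin must be the parent of the MRCA")
    tips = tree.tips
    col = np.array([[column[t.label] for t in tips]], dtype=np.int8)
    states = sample_node_states(tree, clock, params, col, rng)
    return int(states[origin.index, 0]), int(states[mrca.index, 0])


def innovation_posterior(posterior: PosteriorSample, matrix: CognateMatrix,
                         clade: Iterable[str], rng: np.random.Generator,
                         scheme=None) -> InnovationTable:
    """Innovation posterior probabilities for every cognate set.

    For each sampled (tree, parameters) the MRCA of ``clade`` is located
    (regardless of monophyly; the monophyly fraction is reported alongside)
    and one joint state draw made per cognate.  Samples in which the MRCA is
    the root are skipped with a warning and counted.
    """
    clade = frozenset(clade)
    if not clade:
        raise ValueError("empty focal clade")
    taxa = set(matrix.doculects)
    if not clade < taxa:
        raise ValueError("focal clade must be a proper subset of the doculects")

    cog_ids = [c.id for c in matrix.cognate_sets]
    hits = np.zeros(matrix.n_cognates)
    used = 0
    skipped = 0
    mono = 0
    for k in range(len(posterior)):
        tree = posterior.trees[k]
        row = posterior.params.iloc[k]
        mrca = tree.mrca(clade)
        if frozenset(t.label for t in tree.tips
                     if _under(t, mrca)) == clade:
            mono += 1
        if mrca.parent is None:
            skipped += 1
            continue
        clock = ClockModel(mean_rate=float(row["clock_mean"]),
                           stdev=float(row.get("clock_stdev", 0.0)))
        params = CovarionParams(alpha=float(row["alpha"]),
                                s=float(row["switch_rate"]),
                                f_absent=_freq(matrix)[0],
                                f_present=_freq(matrix)[1])
        tip_rows = [matrix.doculects.index(t.label) for t in tree.tips]
        block = matrix.cells[tip_rows, :].T  # (ncols, ntips)
        mults = _column_multipliers(matrix, scheme, row)
        states = sample_node_states(tree, clock, params, block, rng, mults)
        origin_states = states[mrca.parent.index]
        mrca_states = states[mrca.index]
        hits += ((origin_states % 2 == 0) & (mrca_states % 2 == 1))
        used += 1
    if skipped:
        warnings.warn(f"{skipped} samples skipped: clade MRCA was the root",
                      stacklevel=2)
    if used == 0:
        raise ValueError("no usable posterior samples (MRCA always the root)")
    return InnovationTable(
        probabilities=pd.Series(hits / used, index=cog_ids),
        clade=clade, n_samples=used,
        monophyly_fraction=mono / len(posterior),
        n_skipped_root=skipped)


def _under(node: Node, ancestor: Node) -> bool:
    while node is not None:
        if node is ancestor:
            return True
        node = node.parent
    return False


def _freq(matrix: CognateMatrix) -> tuple[float, float]:
    return matrix.empirical_state_frequencies()


def _column_multipliers(matrix: CognateMatrix, scheme, row) -> Optional[np.ndarray]:
    if scheme is None:
        return None
    mults = np.ones(matrix.n_cognates)
    for j, c in enumerate(matrix.cognate_sets):
        lab = scheme.bin_of(c.meaning)
        mults[j] = float(row[f"rate_{lab}"])
    return mults


def list_innovations(table: InnovationTable, threshold: float = 0.5) -> pd.Series:
    """Cognates with innovation pp strictly above ``threshold``, sorted by
    descending probability, ties broken lexicographically by cognate id."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    p = table.probabilities
    hits = p[p > threshold]
    order = sorted(hits.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.Series({k: v for k, v in order}, dtype=float)
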