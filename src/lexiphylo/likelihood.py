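"""Ascertainment-corrected covarion likelihood on a clocked time tree.

The raw likelihood of a single cognate column is computed by Felsenstein
pruning over the 4 covarion states, with tip partials

    absent  -> (1, 0, 1, 0)      present -> (0, 1, 0, 1)
    missing -> (1, 1, 1, 1)

and root weights equal to the stationary distribution.  Because cognate
sets that are absent in every doculect are never recorded, each column's
likelihood is conditioned on observability: the log probability of the
all-absent pattern is computed *per meaning* (using that meaning's coverage
pattern, since uncovered doculects are missing rather than absent) and

    corrected = raw - log(1 - exp(log P(all absent)))

is subtracted column-wise.  Partition bins enter only as relative rate
multipliers on branch distances.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .cognate_data import CognateMatrix, MISSING, PartitionScheme
from .covarion import ClockModel, CovarionParams, TransitionMatrixCache
from .trees import TimeTree

__all__ = [
    "tip_partial", "character_loglik", "all_absent_logprob",
    "corrected_meaning_loglik", "total_loglik", "LikelihoodEngine",
    "MatrixLayout", "layout_loglik",
]

_PARTIALS = {
    0: np.array([1.0, 0.0, 1.0, 0.0]),    # absent
    1: np.array([0.0, 1.0, 0.0, 1.0]),    # present
    MISSING: np.array([1.0, 1.0, 1.0, 1.0]),
}


def tip_partial(state: int) -> np.ndarray:
    try:
        return _PARTIALS[int(state)].copy()
    except KeyError:
        raise ValueError(f"invalid tip state {state!r}") from None


def _log1mexp(a: float) -> float:
    """log(1 - exp(a)) for a < 0, stable near both ends."""
    if a >= 0:
        raise ValueError("log(1-exp(a)) requires a < 0")
    if a > -math.log(2.0):
        return math.log(-math.expm1(a))
    return math.log1p(-math.exp(a))


class LikelihoodEngine:
    """Pruning over a fixed tree/clock/parameter state, vectorized over columns.

    Branch distance for a node's branch is
    ``duration * clock.mean_rate * node.rate * bin_multiplier``.
    """

    def __init__(self, tree: TimeTree, clock: ClockModel, params: CovarionParams):
        self.tree = tree
        self.clock = clock
        self.params = params
        self.cache = TransitionMatrixCache(params)
        self.pi = self.cache.pi
        self._pmats: dict[float, np.ndarray] = {}

    def _transition_matrices(self, rate_multiplier: float = 1.0) -> np.ndarray:
        """(n_nodes, 4, 4) transition matrices keyed by postorder node index."""
        key = float(rate_multiplier)
        if key not in self._pmats:
            nodes = self.tree.postorder()
            dist = np.zeros(len(nodes))
            for node in nodes:
                if node.parent is not None:
                    dist[node.index] = ((node.parent.age - node.age)
                                        * self.clock.mean_rate * node.rate
                                        * rate_multiplier)
            self._pmats[key] = self.cache.probabilities(dist)
        return self._pmats[key]

    def column_logliks(self, columns: np.ndarray,
                       rate_multiplier: float = 1.0) -> np.ndarray:
        """Log-likelihoods of many columns at once.

        ``columns`` has shape (n_columns, n_tips) with entries in
        {0, 1, MISSING}; tip order matches ``self.tree.tips`` order.
        """
        columns = np.atleast_2d(np.asarray(columns))
        ncol = columns.shape[0]
        P = self._transition_matrices(rate_multiplier)
        nodes = self.tree.postorder()
        tips = self.tree.tips
        if columns.shape[1] != len(tips):
            raise ValueError(
                f"column length {columns.shape[1]} != {len(tips)} tips")
        partials = np.empty((len(nodes), ncol, 4))
        scaler = np.zeros(ncol)
        tip_lookup = np.stack([_PARTIALS[0], _PARTIALS[1], _PARTIALS[MISSING]])
        state_idx = np.where(columns == MISSING, 2, columns)
        for t, tip in enumerate(tips):
            partials[tip.index] = tip_lookup[state_idx[:, t]]
        for node in nodes:
            if node.is_leaf:
                continue
            acc = np.ones((ncol, 4))
            for child in node.children:
                acc *= partials[child.index] @ P[child.index].T
            mx = acc.max(axis=1)
            mx = np.where(mx > 0, mx, 1.0)
            acc /= mx[:, None]
            scaler += np.log(mx)
            partials[node.index] = acc
        root_lik = partials[self.tree.root.index] @ self.pi
        with np.errstate(divide="ignore"):
            return np.log(root_lik) + scaler


def _column_array(tree: TimeTree, column: Mapping[str, int]) -> np.ndarray:
    tips = tree.tips
    missing_taxa = [t.label for t in tips if t.label not in column]
    if missing_taxa:
        raise KeyError(f"column lacks states for tips {missing_taxa}")
    return np.array([[column[t.label] for t in tips]], dtype=np.int8)


def character_loglik(tree: TimeTree, clock: ClockModel, params: CovarionParams,
                     column: Mapping[str, int],
                     rate_multiplier: float = 1.0) -> float:
    """Raw (uncorrected) log-likelihood of a single cognate column.

    ``column`` maps tip label -> state in {0, 1, MISSING}.
    """
    engine = LikelihoodEngine(tree, clock, params)
    return float(engine.column_logliks(_column_array(tree, column),
                                       rate_multiplier)[0])


def all_absent_logprob(tree: TimeTree, clock: ClockModel, params: CovarionParams,
                       coverage: Mapping[str, bool],
                       rate_multiplier: float = 1.0) -> float:
    """Log probability of the all-absent pattern given a coverage pattern.

    Covered doculects are absent; uncovered doculects are missing (and thus
    marginalized out).
    """
    if not any(coverage.get(t.label, False) for t in tree.tips):
        raise ValueError("ascertainment correction undefined: no covered doculects")
    column = {t.label: (0 if coverage.get(t.label, False) else MISSING)
              for t in tree.tips}
    return character_loglik(tree, clock, params, column, rate_multiplier)


def corrected_meaning_loglik(tree: TimeTree, clock: ClockModel,
                             params: CovarionParams,
                             columns: Iterable[Mapping[str, int]],
                             coverage: Mapping[str, bool],
                             rate_multiplier: float = 1.0) -> float:
    """Sum of per-column log-likelihoods conditioned on observability."""
    columns = list(columns)
    if not columns:
        return 0.0
    log_absent = all_absent_logprob(tree, clock, params, coverage, rate_multiplier)
    if log_absent > -1e-12:
        raise FloatingPointError(
            "all-absent probability numerically 1; correction degenerate")
    correction = _log1mexp(log_absent)
    total = 0.0
    for column in columns:
        total += character_loglik(tree, clock, params, column, rate_multiplier)
        total -= correction
    return total


class MatrixLayout:
    """Precomputed column layout of a (matrix, partition scheme) pair.

    Holds everything about the data that does not change along an MCMC run:
    the stacked state-index block (real columns followed by one synthetic
    all-absent column per meaning for the ascertainment correction), each
    row's partition bin, and the meaning spans.  Building it once and reusing
    it makes the per-generation likelihood a single pruning pass.
    """

    def __init__(self, matrix: CognateMatrix,
                 scheme: Optional[PartitionScheme] = None):
        self.matrix = matrix
        self.scheme = scheme
        self.doculects = list(matrix.doculects)
        self.bin_labels = scheme.labels if scheme is not None else ["all"]
        bin_index = {lab: k for k, lab in enumerate(self.bin_labels)}

        n_cols = matrix.n_cognates
        meanings = matrix.meanings
        rows = np.empty((n_cols + len(meanings), matrix.n_doculects),
                        dtype=np.int8)
        row_bin = np.zeros(n_cols + len(meanings), dtype=np.intp)
        self.meaning_spans: list[tuple[str, np.ndarray, int]] = []
        for mi, meaning in enumerate(meanings):
            cols = np.asarray(matrix.columns_for_meaning(meaning))
            covered = matrix.cells[:, cols[0]] != MISSING
            if not covered.any():
                raise ValueError(f"meaning {meaning!r} has no covered doculects")
            b = bin_index[scheme.bin_of(meaning)] if scheme is not None else 0
            rows[cols] = matrix.cells[:, cols].T
            row_bin[cols] = b
            absent_row = n_cols + mi
            rows[absent_row] = np.where(covered, 0, MISSING)
            row_bin[absent_row] = b
            self.meaning_spans.append((meaning, cols, absent_row))
        # map states {-1,0,1} -> partial-vector index {2,0,1}
        self.state_idx = np.where(rows == MISSING, 2, rows).astype(np.intp)
        self.row_bin = row_bin
        self.n_cols = n_cols
        self.cognate_ids = [c.id for c in matrix.cognate_sets]

    def multipliers(self, partition_rates: Optional[Mapping[str, float]]
                    ) -> np.ndarray:
        if self.scheme is None:
            return np.ones(1)
        if partition_rates is None:
            raise ValueError("partition scheme given but no bin multipliers")
        out = np.empty(len(self.bin_labels))
        for k, lab in enumerate(self.bin_labels):
            if lab not in partition_rates:
                raise ValueError(f"no rate multiplier configured for bin {lab!r}")
            if partition_rates[lab] <= 0:
                raise ValueError(f"non-positive multiplier for bin {lab!r}")
            out[k] = partition_rates[lab]
        return out


_TIP_LOOKUP = np.stack([_PARTIALS[0], _PARTIALS[1], _PARTIALS[MISSING]])


@lru_cache(maxsize=32)
def _cached_transitions(params: CovarionParams) -> TransitionMatrixCache:
    # CovarionParams is frozen/hashable; the eigendecomposition only changes
    # when a covarion-parameter move is accepted
    return TransitionMatrixCache(params)


def layout_loglik(tree: TimeTree, clock: ClockModel, params: CovarionParams,
                  layout: MatrixLayout,
                  partition_rates: Optional[Mapping[str, float]] = None,
                  ) -> tuple[float, np.ndarray]:
    """Corrected total log-likelihood and per-cognate vector via a layout."""
    mult = layout.multipliers(partition_rates)
    cache = _cached_transitions(params)
    nodes = tree.postorder()
    dist = np.zeros((len(nodes), mult.size))
    for node in nodes:
        if node.parent is not None:
            dist[node.index] = ((node.parent.age - node.age)
                                * clock.mean_rate * node.rate * mult)
    P = cache.probabilities(dist)  # (n_nodes, n_bins, 4, 4)

    doc_pos = {d: i for i, d in enumerate(layout.doculects)}
    state_idx = layout.state_idx
    row_bin = layout.row_bin
    n_rows = state_idx.shape[0]
    partials = np.empty((len(nodes), n_rows, 4))
    scaler = np.zeros(n_rows)
    n_internal_seen = 0
    for node in nodes:
        if node.is_leaf:
            try:
                d = doc_pos[node.label]
            except KeyError:
                raise KeyError(f"tree tip {node.label!r} not in matrix") from None
            partials[node.index] = _TIP_LOOKUP[state_idx[:, d]]
            continue
        children = node.children
        acc = np.einsum("nij,nj->ni", P[children[0].index][row_bin],
                        partials[children[0].index])
        for child in children[1:]:
            acc *= np.einsum("nij,nj->ni", P[child.index][row_bin],
                             partials[child.index])
        n_internal_seen += 1
        if n_internal_seen % 8 == 0:  # occasional rescale against underflow
            mx = acc.max(axis=1)
            mx = np.where(mx > 0, mx, 1.0)
            acc /= mx[:, None]
            scaler += np.log(mx)
        partials[node.index] = acc
    root_lik = partials[tree.root.index] @ cache.pi
    with np.errstate(divide="ignore"):
        logliks = np.log(root_lik) + scaler

    per_cognate = np.empty(layout.n_cols)
    for meaning, cols, absent_row in layout.meaning_spans:
        log_absent = float(logliks[absent_row])
        if log_absent > -1e-12:
            raise FloatingPointError(
                f"meaning {meaning!r}: all-absent probability numerically 1")
        per_cognate[cols] = logliks[cols] - _log1mexp(log_absent)
    return float(per_cognate.sum()), per_cognate


def total_loglik(tree: TimeTree, clock: ClockModel, params: CovarionParams,
                 matrix: CognateMatrix, scheme: Optional[PartitionScheme] = None,
                 partition_rates: Optional[Mapping[str, float]] = None,
                 ) -> tuple[float, pd.Series]:
    """Corrected log-likelihood of the whole matrix, plus per-cognate values.

    Branch distances for the columns of each meaning are scaled by the rate
    multiplier of the meaning's partition bin (all 1.0 when no scheme is
    given).  The returned Series (indexed by cognate id) sums to the total.
    """
    layout = MatrixLayout(matrix, scheme)
    total, per_cognate = layout_loglik(tree, clock, params, layout,
                                       partition_rates)
    return total, pd.Series(per_cognate, index=layout.cognate_ids)
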