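"""Synthetic cognate data with known ground truth.

Emulates the structure of an ABVD-style basic-vocabulary dataset: meanings
holding a long-tailed number of cognate sets, rare "present" states, and
meaning-level missingness.  Columns evolve under the binary covarion process
on a Yule time tree and are conditioned on observability (all-absent columns
are redrawn), mirroring how unobservable cognate sets never enter a real
dataset.  Lexical innovations can be injected on the stem of a designated
clade, and lateral borrowing between designated lineage pairs copies
donor-lineage cognates into a recipient lineage.

The ground-truth history (per-column covarion states at every node) is kept
alongside the matrix so oracle tests can replay the data exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cognate_data import CognateMatrix, CognateSet, MISSING
from .covarion import ClockModel, CovarionParams, TransitionMatrixCache, \
    stationary_distribution
from .trees import Node, TimeTree

__all__ = [
    "SimulationConfig", "SimulatedData", "simulate_yule_tree",
    "simulate_cognate_matrix", "inject_innovation", "inject_borrowing",
    "simulate_dataset", "BorrowingEvent",
]


@dataclass(frozen=True)
class BorrowingEvent:
    """A discrete borrowing event at ``time`` years BP.

    Every cognate carried by the donor lineage at the event time is copied
    into the recipient lineage (and inherited by its descendants) with
    probability ``copy_probability``.
    """

    donor: str
    recipient: str
    time: float
    copy_probability: float


@dataclass
class SimulationConfig:
    """Study-scale defaults for the generated data.

    Defaults mirror a 202-doculect, 185-meaning basic-vocabulary dataset:
    root age 5200 years BP with a pure-birth topology, a clock near
    4.5e-5 expected changes per cognate per year (exp(-10)), covarion
    equilibrium present-frequency 0.008, and a truncated-geometric number of
    cognate sets per meaning with mean ~41 (7565/185).  Tests typically scale
    ``n_taxa`` / ``n_meanings`` down explicitly.
    """

    n_taxa: int = 202
    root_age: float = 5200.0
    birth_rate: float = math.log(101.0) / 5200.0  # E[tips]=2e^{lam*T} ~ 202
    clock_mean: float = math.exp(-10.0)
    clock_stdev: float = 0.3
    covarion: CovarionParams = field(default_factory=lambda: CovarionParams(
        alpha=0.3, s=0.5, f_absent=0.992, f_present=0.008))
    n_meanings: int = 185
    mean_cognates_per_meaning: float = 41.0
    missing_probability: float = 0.1
    borrowing_events: tuple[BorrowingEvent, ...] = ()
    innovation_clades: tuple[tuple[frozenset[str], str], ...] = ()
    negrito_tips: frozenset[str] = frozenset()
    transition_rate_multiplier: float = 1.0
    seed: int = 0


@dataclass
class SimulatedData:
    tree: TimeTree
    clock: ClockModel
    matrix: CognateMatrix
    # history[node_index, column] = covarion state 0..3 at that node
    history: np.ndarray
    borrowing_log: list[tuple[str, str, str]]  # (recipient tip, cognate, donor)
    innovations: list[tuple[str, frozenset[str]]]  # (cognate id, clade)


# ------------------------------------------------------------------ Yule tree

def simulate_yule_tree(n_taxa: int, birth_rate: float, root_age: float,
                       rng: np.random.Generator) -> TimeTree:
    """Pure-birth tree on ``n_taxa`` tips, rescaled to the given root age.

    Forward simulation from two root lineages: exponential waiting times with
    total rate k*birth_rate while k lineages are extant, splitting a uniformly
    chosen lineage at each event.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if birth_rate <= 0 or root_age <= 0:
        raise ValueError("birth rate and root age must be positive")
    root = Node(age=0.0)  # ages assigned as forward times first, flipped later
    active = [root.add_child(Node()), root.add_child(Node())]
    split_times = {id(root): 0.0}
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        k = int(rng.integers(len(active)))
        node = active.pop(k)
        split_times[id(node)] = t
        active.append(node.add_child(Node()))
        active.append(node.add_child(Node()))
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))
    for i, tip in enumerate(active):
        tip.label = f"t{i + 1}"
    # convert forward split times to ages BP, rescaled so root age matches
    scale = root_age / t_end

    def assign(node: Node) -> None:
        if node.is_leaf:
            node.age = 0.0
        else:
            node.age = (t_end - split_times[id(node)]) * scale
            for c in node.children:
                assign(c)

    assign(root)
    tree = TimeTree(root)
    tree.validate()
    return tree


def draw_branch_rates(tree: TimeTree, clock: ClockModel,
                      rng: np.random.Generator) -> None:
    """Assign lognormal unit-mean rate multipliers to every branch in place."""
    sd = clock.stdev
    for node in tree.postorder():
        if node.parent is None:
            node.rate = 1.0
        elif sd > 0:
            node.rate = float(rng.lognormal(-0.5 * sd * sd, sd))
        else:
            node.rate = 1.0


# ------------------------------------------------------- character simulation

def _simulate_states(tree: TimeTree, clock: ClockModel, params: CovarionParams,
                     n_columns: int, rng: np.random.Generator) -> np.ndarray:
    """(n_nodes, n_columns) covarion states simulated down the tree."""
    cache = TransitionMatrixCache(params)
    pi = stationary_distribution(params)
    nodes = tree.postorder()
    states = np.empty((len(nodes), n_columns), dtype=np.int8)
    root = tree.root
    states[root.index] = rng.choice(4, size=n_columns, p=pi)
    for node in tree.preorder():
        if node.parent is None:
            continue
        dist = (node.parent.age - node.age) * clock.mean_rate * node.rate
        P = cache.probabilities(dist)
        cum = np.cumsum(P, axis=1)
        u = rng.random(n_columns)
        parent_states = states[node.parent.index]
        states[node.index] = (u[:, None] > cum[parent_states]).sum(axis=1)
    return states


def simulate_cognate_matrix(tree: TimeTree, clock: ClockModel,
                            config: SimulationConfig,
                            rng: np.random.Generator,
                            ) -> tuple[CognateMatrix, np.ndarray]:
    """Evolve a full matrix; returns (matrix, per-node state history).

    Each meaning draws its coverage pattern (meaning-level missingness) and a
    truncated-geometric number of cognate sets; columns are redrawn until not
    all-absent among covered doculects (ascertainment conditioning).
    """
    tips = tree.tips
    tip_order = [t.label for t in tips]
    p_geom = 1.0 / config.mean_cognates_per_meaning
    meaning_sizes = rng.geometric(p_geom, size=config.n_meanings)  # support >= 1

    columns: list[np.ndarray] = []
    node_states: list[np.ndarray] = []
    cognate_sets: list[CognateSet] = []
    for m in range(config.n_meanings):
        meaning = f"m{m + 1:03d}"
        covered = rng.random(len(tips)) >= config.missing_probability
        if not covered.any():
            covered[int(rng.integers(len(tips)))] = True
        need = int(meaning_sizes[m])
        got = 0
        attempts = 0
        while got < need:
            batch = max(32, 2 * (need - got))
            attempts += batch
            if attempts > 1_000_000 * need:
                raise RuntimeError(
                    "ascertainment rejection did not terminate; "
                    "parameters are degenerate (observable columns too rare)")
            states = _simulate_states(tree, clock, config.covarion, batch, rng)
            observed = np.array([states[t.index] % 2 for t in tips])  # (ntips, batch)
            keep = (observed[covered] == 1).any(axis=0)
            for j in np.where(keep)[0]:
                if got >= need:
                    break
                col = np.where(covered, observed[:, j], MISSING).astype(np.int8)
                columns.append(col)
                node_states.append(states[:, j])
                cognate_sets.append(CognateSet(
                    id=f"{meaning}_{got + 1}", meaning=meaning))
                got += 1
    cells = np.array(columns, dtype=np.int8).T  # (ntips, ncols)
    history = np.array(node_states, dtype=np.int8).T  # (n_nodes, ncols)
    matrix = CognateMatrix(doculects=tip_order, cognate_sets=cognate_sets,
                           cells=cells)
    matrix.validate()
    return matrix, history


# ----------------------------------------------------------------- injections

def inject_innovation(matrix: CognateMatrix, history: np.ndarray,
                      tree: TimeTree, clade: frozenset[str],
                      cognate_label: str) -> tuple[CognateMatrix, np.ndarray]:
    """Add a column born on the stem branch of ``clade``.

    The column is present (slow category) in every clade tip, absent
    elsewhere; the recorded history places the gain on the stem: the clade
    MRCA and all its descendants carry state 1, everything else state 0.
    """
    mrca = tree.mrca(clade)
    if mrca is tree.root:
        raise ValueError("clade spans all tips: stem (origin) branch does not exist")
    in_clade = np.zeros(len(tree.postorder()), dtype=bool)

    def mark(node: Node) -> None:
        in_clade[node.index] = True
        for c in node.children:
            mark(c)

    mark(mrca)
    col = np.array([1 if in_clade[t.index] else 0 for t in tree.tips],
                   dtype=np.int8)
    meaning = f"inj_{cognate_label}"
    new_sets = list(matrix.cognate_sets) + [
        CognateSet(id=f"{meaning}_1", meaning=meaning)]
    new_cells = np.hstack([matrix.cells, col[:, None]])
    hist_col = np.where(in_clade, 1, 0).astype(np.int8)
    new_history = np.hstack([history, hist_col[:, None]])
    out = CognateMatrix(doculects=list(matrix.doculects), cognate_sets=new_sets,
                        cells=new_cells)
    out.validate()
    return out, new_history


def _lineage_at(tree: TimeTree, tip_label: str, time: float) -> Node:
    """The node at the bottom of the branch spanning ``time`` on the path
    from the root to ``tip_label``."""
    node = tree.tip(tip_label)
    while node.parent is not None and node.parent.age <= time:
        node = node.parent
    if node.parent is None:
        raise ValueError(
            f"lineage of {tip_label!r} does not exist at {time} BP "
            "(older than the root)")
    return node


def inject_borrowing(matrix: CognateMatrix, tree: TimeTree,
                     history: np.ndarray, events: Sequence[BorrowingEvent],
                     rng: np.random.Generator,
                     ) -> tuple[CognateMatrix, list[tuple[str, str, str]]]:
    """Copy donor-lineage cognates into recipient lineages.

    For each event, a cognate counts as carried by the donor lineage when the
    ground-truth covarion state at the donor-side node of the branch spanning
    the event time is observed-present.  Copied cognates become present in
    every recipient-descendant tip that is coded for the cognate's meaning.
    Returns the modified matrix and a log of (recipient tip, cognate, donor).
    """
    cells = matrix.cells.copy()
    log: list[tuple[str, str, str]] = []
    tips = tree.tips
    tip_pos = {t.label: i for i, t in enumerate(tips)}
    doc_pos = {d: i for i, d in enumerate(matrix.doculects)}
    for ev in events:
        if not (0.0 < ev.copy_probability <= 1.0):
            if ev.copy_probability == 0.0:
                continue
            raise ValueError("copy probability must be in [0, 1]")
        donor_node = _lineage_at(tree, ev.donor, ev.time)
        recip_node = _lineage_at(tree, ev.recipient, ev.time)
        recip_tips = [t.label for t in tips
                      if _descends_from(t, recip_node)]
        carried = history[donor_node.index] % 2 == 1
        for j in np.where(carried)[0]:
            if rng.random() >= ev.copy_probability:
                continue
            cid = matrix.cognate_sets[j].id
            for lab in recip_tips:
                i = doc_pos[lab]
                if cells[i, j] != MISSING:
                    cells[i, j] = 1
                    log.append((lab, cid, ev.donor))
    out = CognateMatrix(doculects=list(matrix.doculects),
                        cognate_sets=list(matrix.cognate_sets), cells=cells)
    return out, log


def _descends_from(node: Node, ancestor: Node) -> bool:
    while node is not None:
        if node is ancestor:
            return True
        node = node.parent
    return False


# ------------------------------------------------------------------ top level

def simulate_dataset(config: SimulationConfig) -> SimulatedData:
    """Full generator: tree + rates + matrix + injections, seeded."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_yule_tree(config.n_taxa, config.birth_rate,
                              config.root_age, rng)
    clock = ClockModel(mean_rate=config.clock_mean, stdev=config.clock_stdev)
    draw_branch_rates(tree, clock, rng)
    if config.negrito_tips and config.transition_rate_multiplier != 1.0:
        _scale_transition_branches(tree, config.negrito_tips,
                                   config.transition_rate_multiplier)
    matrix, history = simulate_cognate_matrix(tree, clock, config, rng)
    innovations = []
    for clade, label in config.innovation_clades:
        matrix, history = inject_innovation(matrix, history, tree, clade, label)
        innovations.append((f"inj_{label}_1", clade))
    borrowing_log: list[tuple[str, str, str]] = []
    if config.borrowing_events:
        matrix, borrowing_log = inject_borrowing(
            matrix, tree, history, config.borrowing_events, rng)
    return SimulatedData(tree=tree, clock=clock, matrix=matrix,
                         history=history, borrowing_log=borrowing_log,
                         innovations=innovations)


def _scale_transition_branches(tree: TimeTree, negrito: frozenset[str],
                               multiplier: float) -> None:
    """Multiply the rate of branches where the lineage switches into the
    negrito tip set (parent subtree contains non-negrito tips, child subtree
    only negrito tips)."""
    leafsets = tree.clade_leafsets()
    for node in tree.postorder():
        if node.parent is None:
            continue
        below = leafsets[node.index]
        parent_below = leafsets[node.parent.index]
        if below <= negrito and not (parent_below <= negrito):
            node.rate *= multiplier
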