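"""Posterior tree summarization: consensus, MCC tree, clade supports, census.

All summaries work on collections of :class:`~lexiphylo.trees.TimeTree`.
Clades are identified by their descendant tip-label sets, so summaries are
invariant to node rotation and tree-file ordering.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Optional, Sequence

import math

import numpy as np
import pandas as pd

from .trees import Node, TimeTree

__all__ = [
    "clade_posterior", "clade_frequencies", "majority_consensus", "mcc_tree",
    "group_topology_census",
]


def _tree_clades(tree: TimeTree) -> dict[frozenset[str], float]:
    """Map clade leafset -> node age, for every node of the tree."""
    leafsets = tree.clade_leafsets()
    return {leafsets[n.index]: n.age for n in tree.postorder()}


def clade_frequencies(trees: Sequence[TimeTree]) -> dict[frozenset[str], float]:
    """Fraction of trees containing each clade (tips included, always 1.0)."""
    if not trees:
        raise ValueError("empty tree collection")
    counts: Counter = Counter()
    for t in trees:
        for clade in _tree_clades(t):
            counts[clade] += 1
    n = len(trees)
    return {clade: c / n for clade, c in counts.items()}


def clade_posterior(trees: Sequence[TimeTree], taxon_set: Iterable[str]) -> float:
    """Posterior probability (sample frequency) that ``taxon_set`` is a clade."""
    want = frozenset(taxon_set)
    if not trees:
        raise ValueError("empty tree collection")
    all_taxa = frozenset(trees[0].taxa)
    unknown = want - all_taxa
    if unknown:
        raise KeyError(f"unknown taxa: {sorted(unknown)}")
    hits = 0
    for t in trees:
        leafsets = set(t.clade_leafsets().values())
        if want in leafsets:
            hits += 1
    return hits / len(trees)


def _clade_age_samples(trees: Sequence[TimeTree]) -> dict[frozenset[str], list[float]]:
    ages: dict[frozenset[str], list[float]] = {}
    for t in trees:
        for clade, age in _tree_clades(t).items():
            ages.setdefault(clade, []).append(age)
    return ages


def majority_consensus(trees: Sequence[TimeTree],
                       threshold: float = 0.5) -> TimeTree:
    """Majority-rule consensus: exactly the clades with frequency strictly
    above ``threshold`` (>= 0.5, which guarantees mutual compatibility).

    Node ages are the median age of each clade over the trees containing it;
    supports are stored on ``node.support``.  Non-binary (polytomous) nodes
    can result and are legitimate for a consensus topology.
    """
    if not trees:
        raise ValueError("empty tree collection")
    if threshold < 0.5:
        raise ValueError("threshold must be >= 0.5 for a majority-rule consensus")
    freqs = clade_frequencies(trees)
    ages = _clade_age_samples(trees)
    taxa = frozenset(trees[0].taxa)
    keep = {clade: f for clade, f in freqs.items()
            if f > threshold or len(clade) == 1 or clade == taxa}
    # build by nesting: parents are the smallest kept superset of each clade
    order = sorted(keep, key=len, reverse=True)
    nodes: dict[frozenset[str], Node] = {}
    for clade in order:
        node = Node(label=next(iter(clade)) if len(clade) == 1 else None)
        node.age = float(np.median(ages[clade]))
        node.support = keep[clade]
        nodes[clade] = node
    for clade in sorted(keep, key=len):
        if clade == taxa:
            continue
        parent = min((c for c in keep if clade < c), key=len)
        nodes[parent].add_child(nodes[clade])
    # guard against age inversions from independent medians
    def clamp(node: Node) -> None:
        for c in node.children:
            if not c.is_leaf and c.age >= node.age:
                c.age = math.nextafter(node.age, 0.0)
            clamp(c)
    clamp(nodes[taxa])
    return TimeTree(nodes[taxa])


def mcc_tree(trees: Sequence[TimeTree]) -> TimeTree:
    """Maximum clade credibility tree from the sample.

    The sampled tree maximizing the product of its clades' posterior
    frequencies (ties broken by first occurrence); node ages are re-annotated
    with the median age of each clade over the trees containing it, and
    supports with the clade frequency.
    """
    if not trees:
        raise ValueError("empty tree collection")
    freqs = clade_frequencies(trees)
    best_idx, best_score = 0, -math.inf
    for k, t in enumerate(trees):
        score = 0.0
        for clade in _tree_clades(t):
            if len(clade) > 1:
                score += math.log(freqs[clade])
        if score > best_score:
            best_idx, best_score = k, score
    winner = trees[best_idx].copy()
    ages = _clade_age_samples(trees)
    leafsets = winner.clade_leafsets()
    for node in winner.postorder():
        clade = leafsets[node.index]
        node.support = freqs[clade]
        if not node.is_leaf:
            node.age = float(np.median(ages[clade]))
    for node in winner.preorder():
        for c in node.children:
            if not c.is_leaf and c.age >= node.age:
                c.age = math.nextafter(node.age, 0.0)
    return winner


# ------------------------------------------------------------------- census

def _induced_topology(node: Node, label_of: Mapping[str, str]) -> Optional[str]:
    """Canonical label-sorted newick of the tree restricted to labelled tips."""
    if node.is_leaf:
        return label_of.get(node.label)
    parts = [p for p in (_induced_topology(c, label_of) for c in node.children)
             if p is not None]
    if not parts:
        return None
    if len(parts) == 1:
        return parts[0]
    return "(" + ",".join(sorted(parts)) + ")"


def group_topology_census(trees: Sequence[TimeTree],
                          groups: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Census of the induced topologies over named (disjoint) taxon groups.

    For every tree in which each group is monophyletic, the groups are
    collapsed to single tips and the induced topology recorded in canonical
    form.  Trees where any group is non-monophyletic fall into a separate
    ``"(incompatible)"`` bin.  Returns a frame with columns
    (rank, topology, frequency, cumulative) sorted by descending frequency;
    the incompatible bin, when non-empty, is listed last without a rank.
    """
    if not trees:
        raise ValueError("empty tree collection")
    named = {name: frozenset(tx) for name, tx in groups.items()}
    flat: dict[str, str] = {}
    for name, tx in named.items():
        for lab in tx:
            if lab in flat:
                raise ValueError(f"taxon {lab!r} appears in groups "
                                 f"{flat[lab]!r} and {name!r} (must be disjoint)")
            flat[lab] = name
    counts: Counter = Counter()
    incompatible = 0
    for t in trees:
        leafsets = set(t.clade_leafsets().values())
        if not all(tx in leafsets or len(tx) == 1 for tx in named.values()):
            incompatible += 1
            continue
        # collapse: first tip of each group carries the group label
        label_of: dict[str, str] = {}
        seen_groups: set[str] = set()
        for tip in t.tips:
            g = flat.get(tip.label)
            if g is not None and g not in seen_groups:
                label_of[tip.label] = g
                seen_groups.add(g)
        counts[_induced_topology(t.root, label_of)] += 1

    n = len(trees)
    rows = []
    cum = 0.0
    for rank, (topo, c) in enumerate(
            sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])), start=1):
        cum += c / n
        rows.append({"rank": rank, "topology": topo, "frequency": c / n,
                     "cumulative": cum})
    if incompatible:
        rows.append({"rank": pd.NA, "topology": "(incompatible)",
                     "frequency": incompatible / n, "cumulative": 1.0})
    return pd.DataFrame(rows, columns=["rank", "topology", "frequency", "cumulative"])
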