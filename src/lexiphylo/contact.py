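"""Language-switching analysis: parsimony ASR, transition dating, branch rates.

A binary population trait (background vs. 'negrito') is reconstructed on the
tree by maximum parsimony with the root fixed to the background state —
language switching is known to be directional, so reversals are not part of
the model.  Branches whose parent is background and whose child is negrito
are *transition* branches; their bracketing node ages give the (min, max)
dates of each switching event.  Per-category weighted mean branch rates
(weights = branch time durations) are compared across a posterior sample to
ask whether transitions show elevated rates of lexical change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mcmc import PosteriorSample
from .trees import TimeTree

__all__ = [
    "BACKGROUND", "NEGRITO", "fitch_asr", "transition_report",
    "branch_categories", "weighted_mean_rates", "read_trait_table",
]

BACKGROUND = "background"
NEGRITO = "negrito"
_STATES = (BACKGROUND, NEGRITO)


def read_trait_table(path: str) -> dict[str, str]:
    """Tab-separated (doculect, trait) table; trait in {background, negrito}
    or {no, yes} / {0, 1} shorthand for the negrito flag."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError("trait table needs two columns: doculect, trait")
    out: dict[str, str] = {}
    yes = {"negrito", "yes", "1", "true"}
    no = {"background", "no", "0", "false"}
    for doc, val in zip(frame.iloc[:, 0], frame.iloc[:, 1]):
        v = str(val).strip().lower()
        if v in yes:
            out[doc] = NEGRITO
        elif v in no:
            out[doc] = BACKGROUND
        else:
            raise ValueError(f"unknown trait value {val!r} for {doc!r}")
    return out


def fitch_asr(tree: TimeTree, trait: Mapping[str, str],
              root_state: str = BACKGROUND,
              ambiguity: str = "parent") -> tuple[dict[int, str], int]:
    """Minimum-change ancestral reconstruction with a fixed root state.

    Unit-cost Sankoff dynamic program (exact under the root constraint),
    resolved top-down.  ``ambiguity`` controls tie-breaking at nodes where
    both states are equally parsimonious: "parent" keeps the parent's state
    (delays changes tipward, yielding the latest consistent switching dates);
    "earliest" prefers the derived state (earliest consistent switch).

    Returns (node index -> state, minimal number of changes).
    """
    if root_state not in _STATES:
        raise ValueError(f"unknown root state {root_state!r}")
    if ambiguity not in ("parent", "earliest"):
        raise ValueError(f"unknown ambiguity rule {ambiguity!r}")
    tips = tree.tips
    missing = [t.label for t in tips if t.label not in trait]
    if missing:
        raise KeyError(f"tips without trait assignment: {missing}")

    n = len(tree.postorder())
    INF = 10 ** 9
    cost = np.zeros((n, 2), dtype=np.int64)
    for node in tree.postorder():
        if node.is_leaf:
            s = _STATES.index(trait[node.label])
            cost[node.index] = [INF, INF]
            cost[node.index, s] = 0
        else:
            for s in (0, 1):
                total = 0
                for c in node.children:
                    total += min(cost[c.index, t] + (s != t) for t in (0, 1))
                cost[node.index, s] = total

    root_idx = tree.root.index
    s_root = _STATES.index(root_state)
    changes = int(cost[root_idx, s_root])
    if changes >= INF:
        raise ValueError("root state incompatible with the tip data")

    assignment: dict[int, str] = {root_idx: root_state}
    for node in tree.preorder():
        if node.parent is None:
            continue
        p = _STATES.index(assignment[node.parent.index])
        options = [(cost[node.index, t] + (p != t), t) for t in (0, 1)]
        best = min(o[0] for o in options)
        tied = [t for c, t in options if c == best]
        if len(tied) == 1:
            choice = tied[0]
        elif ambiguity == "parent":
            choice = p if p in tied else tied[0]
        else:  # earliest: prefer the non-parent (derived) state
            non_parent = [t for t in tied if t != p]
            choice = non_parent[0] if non_parent else p
        assignment[node.index] = _STATES[choice]
    return assignment, changes


@dataclass(frozen=True)
class Transition:
    """One inferred switching event on a branch of the tree."""

    descendants: tuple[str, ...]
    min_age: float     # age of the child node bookending the branch
    max_age: float     # age of the parent node

    def __post_init__(self) -> None:
        if self.min_age > self.max_age:
            raise ValueError("transition min age exceeds max age")


def transition_report(tree: TimeTree,
                      asr: Mapping[int, str]) -> list[Transition]:
    """One entry per branch with a background parent and a negrito child."""
    leafsets = tree.clade_leafsets()
    out: list[Transition] = []
    for node in tree.postorder():
        if node.parent is None:
            continue
        if asr[node.parent.index] == BACKGROUND and asr[node.index] == NEGRITO:
            out.append(Transition(
                descendants=tuple(sorted(leafsets[node.index])),
                min_age=node.age, max_age=node.parent.age))
    out.sort(key=lambda t: (-t.max_age, t.descendants))
    return out


def branch_categories(tree: TimeTree,
                      asr: Mapping[int, str]) -> dict[int, str]:
    """Label each branch (keyed by child-node index) as background,
    transition, or within_negrito.  A negrito-to-background reversal is not
    expected under the root-constrained model; it is flagged with a warning
    and counted as background."""
    out: dict[int, str] = {}
    for node in tree.postorder():
        if node.parent is None:
            continue
        parent_s = asr[node.parent.index]
        child_s = asr[node.index]
        if parent_s == BACKGROUND and child_s == NEGRITO:
            out[node.index] = "transition"
        elif parent_s == NEGRITO and child_s == NEGRITO:
            out[node.index] = "within_negrito"
        elif parent_s == NEGRITO and child_s == BACKGROUND:
            warnings.warn("negrito-to-background reversal in reconstruction; "
                          "counted as background", stacklevel=2)
            out[node.index] = "background"
        else:
            out[node.index] = "background"
    return out


def weighted_mean_rates(posterior: PosteriorSample | Sequence[TimeTree],
                        trait: Mapping[str, str],
                        ambiguity: str = "parent") -> pd.DataFrame:
    """Posterior distributions of per-category duration-weighted mean rates.

    For each sampled tree the trait is reconstructed by parsimony on that
    tree, branches are labelled, and each category's mean branch rate is
    computed with branch time-durations as weights.  Returns a frame with
    one row per tree and columns (background, transition, within_negrito);
    a category empty in some tree yields NaN there.  The attribute
    ``frame.attrs["p_transition_gt_background"]`` holds the posterior
    probability that the transition-category mean exceeds the background
    mean (over trees where both are defined), and ``attrs["n_missing"]``
    counts per category how many trees contributed no value.
    """
    trees = posterior.trees if isinstance(posterior, PosteriorSample) else list(posterior)
    if not trees:
        raise ValueError("empty posterior")
    rows = []
    for tree in trees:
        asr, _ = fitch_asr(tree, trait, ambiguity=ambiguity)
        cats = branch_categories(tree, asr)
        sums = {c: 0.0 for c in ("background", "transition", "within_negrito")}
        wts = {c: 0.0 for c in sums}
        for node in tree.postorder():
            if node.parent is None:
                continue
            dur = node.parent.age - node.age
            cat = cats[node.index]
            sums[cat] += dur * node.rate
            wts[cat] += dur
        rows.append({c: (sums[c] / wts[c] if wts[c] > 0 else np.nan)
                     for c in sums})
    frame = pd.DataFrame(rows)
    both = frame.dropna(subset=["transition", "background"])
    frame.attrs["p_transition_gt_background"] = (
        float((both["transition"] > both["background"]).mean())
        if len(both) else np.nan)
    frame.attrs["n_missing"] = {c: int(frame[c].isna().sum()) for c in frame.columns}
    return frame
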