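"""Metropolis–Hastings sampling of (tree, clock, covarion, partition rates).

The sampler targets the posterior of a clocked covarion analysis: a
root-conditioned Yule tree prior with a normal root-age calibration,
lognormal hyperpriors on the birth rate and clock mean, a gamma prior on the
relaxed-clock standard deviation, unit-mean lognormal branch-rate
multipliers, and the ascertainment-corrected covarion likelihood.  Monophyly
constraints are enforced by rejection: topology proposals that break a
constraint are discarded.

The move kernel is conventional for time trees: node-age scalers and uniform
resamplings, a root scaler, narrow exchange, a (no-crossing) subtree slide,
Wilson–Balding, and scalers / random walks for the scalar parameters.  With
a fixed seed the sample stream is fully deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cognate_data import CognateMatrix, PartitionScheme
from .covarion import ClockModel, CovarionParams, PriorConfig, log_prior, \
    _gamma_logpdf as _gamma_lp, _lognormal_logpdf as _ln_logpdf
from .likelihood import MatrixLayout, layout_loglik
from .trees import Node, TimeTree

__all__ = [
    "ChainConfig", "MonophylyConstraint", "PosteriorSample", "ConstraintError",
    "IncompatibleRunsError", "run_chain", "combine_runs", "ess",
    "build_initial_tree",
]

MOVE_NAMES = [
    "node_age_uniform", "node_age_scaler", "root_scaler", "narrow_exchange",
    "subtree_slide", "wilson_balding", "clock_mean_scaler", "clock_stdev_scaler",
    "clock_stdev_rescale", "branch_rate_walk", "birth_rate_scaler",
    "alpha_walk", "switch_scaler", "partition_rate_exchange",
    # independence proposals from the priors: the Hastings term cancels the
    # prior ratio, so acceptance reduces to the likelihood ratio; they give
    # bold global jumps and make prior-only sampling essentially iid
    "clock_mean_prior_draw", "switch_prior_draw", "alpha_prior_draw",
    "clock_stdev_prior_draw", "birth_rate_prior_draw",
    # likelihood-invariant ridge move between the clock mean and the
    # branch-rate multipliers
    "clock_rate_exchange",
]


class ConstraintError(ValueError):
    """Unsatisfiable or violated monophyly constraints."""


class IncompatibleRunsError(ValueError):
    """Runs with different data/model signatures cannot be combined."""


@dataclass(frozen=True)
class MonophylyConstraint:
    """``must_be_clade``: the taxa must form a clade in every sampled tree;
    ``must_exclude``: they must never form one."""

    taxa: frozenset[str]
    polarity: str = "must_be_clade"

    def __post_init__(self) -> None:
        if self.polarity not in ("must_be_clade", "must_exclude"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if not self.taxa:
            raise ValueError("constraint taxon set is empty")

    def satisfied(self, tree: TimeTree) -> bool:
        is_clade = tree.is_clade(self.taxa)
        return is_clade if self.polarity == "must_be_clade" else not is_clade


@dataclass
class ChainConfig:
    """Desk-scale defaults: 200k generations sampled every 200."""

    generations: int = 200_000
    sample_every: int = 200
    seed: int = 0
    move_weights: Optional[dict[str, float]] = None
    burnin_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not (self.generations >= self.sample_every >= 1):
            raise ValueError("need generations >= sample_every >= 1")
        if self.move_weights is not None:
            unknown = set(self.move_weights) - set(MOVE_NAMES)
            if unknown:
                raise ValueError(f"unknown moves: {sorted(unknown)}")
            if any(w < 0 for w in self.move_weights.values()) or \
                    not any(w > 0 for w in self.move_weights.values()):
                raise ValueError("move weights must be >= 0 with at least one > 0")


@dataclass
class PosteriorSample:
    """Aligned posterior draws: trees, parameters, log-likelihoods."""

    generations: list[int]
    trees: list[TimeTree]
    params: pd.DataFrame
    loglik: np.ndarray
    per_cognate: Optional[pd.DataFrame]
    signature: tuple
    acceptance: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.generations)
        if not (len(self.trees) == len(self.params) == len(self.loglik) == n):
            raise ValueError("posterior components have unequal lengths")
        if any(b <= a for a, b in zip(self.generations, self.generations[1:])):
            raise ValueError("generation indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.generations)

    def write_trace(self, path: str) -> None:
        frame = self.params.copy()
        frame.insert(0, "generation", self.generations)
        frame["likelihood"] = self.loglik
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def write_per_cognate_trace(self, path: str) -> None:
        if self.per_cognate is None:
            raise ValueError("per-cognate likelihoods were not logged")
        frame = self.per_cognate.copy()
        frame.insert(0, "generation", self.generations)
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ----------------------------------------------------------------- state

class _State:
    __slots__ = ("tree", "clock", "params", "birth_rate", "partition_rates")

    def __init__(self, tree: TimeTree, clock: ClockModel, params: CovarionParams,
                 birth_rate: float, partition_rates: dict[str, float]):
        self.tree = tree
        self.clock = clock
        self.params = params
        self.birth_rate = birth_rate
        self.partition_rates = partition_rates

    def copy(self) -> "_State":
        return _State(self.tree.copy(),
                      ClockModel(self.clock.mean_rate, self.clock.stdev),
                      self.params, self.birth_rate,
                      dict(self.partition_rates))


# ------------------------------------------------------------- initial tree

def build_initial_tree(taxa: Sequence[str],
                       constraints: Sequence[MonophylyConstraint],
                       root_age: float, rng: np.random.Generator,
                       max_tries: int = 200) -> TimeTree:
    """Random resolution honoring all constraints (fixed-seed reproducible)."""
    clade_sets = [c.taxa for c in constraints if c.polarity == "must_be_clade"]
    taxa = list(taxa)
    taxon_set = set(taxa)
    for cs in clade_sets:
        if not cs < taxon_set:
            raise ConstraintError(
                f"constraint taxa {sorted(cs)} not a proper subset of the tips")
    for a in clade_sets:
        for b in clade_sets:
            if a is not b and a & b and not (a <= b or b <= a):
                raise ConstraintError(
                    "overlapping (non-nested) monophyly constraints")

    def build_group(members: list, parent_age: float) -> Node:
        # members: taxon labels and/or already-built subtree Nodes
        units: list[Node] = []
        for m in members:
            units.append(m if isinstance(m, Node) else Node(label=m))
        rng.shuffle(units)
        while len(units) > 1:
            a = units.pop()
            b = units.pop()
            join = Node()
            join.add_child(a)
            join.add_child(b)
            units.append(join)
        top = units[0]
        _assign_ages(top, parent_age, rng)
        return top

    def _assign_ages(node: Node, parent_age: float, rng: np.random.Generator) -> None:
        if node.is_leaf:
            node.age = 0.0
            return
        node.age = parent_age * rng.uniform(0.55, 0.95)
        for c in node.children:
            _assign_ages(c, node.age, rng)

    for _ in range(max_tries):
        # nest constraint groups smallest-first, members replaced by subtrees
        built: list[tuple[frozenset, Node]] = []
        for cs in sorted(clade_sets, key=len):
            members: list = []
            covered: set[str] = set()
            for other_set, other_node in built:
                if other_set <= cs and not other_set & covered:
                    members.append(other_node)
                    covered |= other_set
            members.extend(lab for lab in cs - covered)
            node = build_group(members, root_age)
            built = [(s, n) for s, n in built if not s <= cs]
            built.append((frozenset(cs), node))
        top_members: list = [n for _, n in built]
        claimed = set().union(*(s for s, _ in built)) if built else set()
        top_members.extend(lab for lab in taxa if lab not in claimed)
        if len(top_members) < 2:
            raise ConstraintError("constraints leave fewer than two root children")
        grouped = build_group(top_members, root_age)
        # build_group returns a single subtree whose root we re-age to root_age
        grouped.age = root_age
        for c in grouped.children:
            _reclamp(c, root_age, rng)
        tree = TimeTree(grouped)
        tree.validate()
        if all(c.satisfied(tree) for c in constraints):
            return tree
    raise ConstraintError("could not satisfy constraints by random resolution")


def _reclamp(node: Node, parent_age: float, rng: np.random.Generator) -> None:
    if node.is_leaf:
        return
    if node.age >= parent_age:
        node.age = parent_age * rng.uniform(0.55, 0.95)
    for c in node.children:
        _reclamp(c, node.age, rng)


# ----------------------------------------------------------------- proposals

def _scale_factor(rng: np.random.Generator, tuning: float) -> float:
    return math.exp(tuning * (rng.random() - 0.5))


def _propose(state: _State, move: str, rng: np.random.Generator,
             scheme: Optional[PartitionScheme],
             bin_weights: Optional[dict[str, float]],
             priors: PriorConfig) -> Optional[float]:
    """Mutate ``state`` in place; return log Hastings ratio or None to reject."""
    tree = state.tree
    internal = [n for n in tree.internal_nodes if n.parent is not None]

    if move == "node_age_uniform":
        if not internal:
            return None
        node = internal[int(rng.integers(len(internal)))]
        lo = max(c.age for c in node.children)
        hi = node.parent.age
        node.age = rng.uniform(lo, hi)
        return 0.0

    if move == "node_age_scaler":
        if not internal:
            return None
        node = internal[int(rng.integers(len(internal)))]
        m = _scale_factor(rng, 0.5)
        new_age = node.age * m
        if new_age <= max(c.age for c in node.children) or new_age >= node.parent.age:
            return None
        node.age = new_age
        return math.log(m)

    if move == "root_scaler":
        m = _scale_factor(rng, 0.1)
        new_age = tree.root.age * m
        if new_age <= max(c.age for c in tree.root.children):
            return None
        tree.root.age = new_age
        return math.log(m)

    if move == "narrow_exchange":
        if not internal:
            return None
        p = internal[int(rng.integers(len(internal)))]
        g = p.parent
        u = g.children[0] if g.children[1] is p else g.children[1]
        c = p.children[int(rng.integers(2))]
        if u.age >= p.age:
            return None
        g.children[g.children.index(u)] = c
        c.parent = g
        p.children[p.children.index(c)] = u
        u.parent = p
        tree.invalidate()
        return 0.0

    if move == "subtree_slide":
        # no-crossing variant: gaussian step on an internal node age within
        # its current bracket (topology untouched, tip ages untouched)
        if not internal:
            return None
        node = internal[int(rng.integers(len(internal)))]
        lo = max(c.age for c in node.children)
        hi = node.parent.age
        new_age = node.age + rng.normal(0.0, 0.2 * (hi - lo))
        if new_age <= lo or new_age >= hi:
            return None
        node.age = new_age
        return 0.0

    if move == "wilson_balding":
        movable = [n for n in tree.postorder()
                   if n.parent is not None and n.parent.parent is not None]
        if not movable:
            return None
        i = movable[int(rng.integers(len(movable)))]
        p = i.parent
        g = p.parent
        s = p.children[0] if p.children[1] is i else p.children[1]
        candidates = [n for n in tree.postorder() if n.parent is not None]
        j = candidates[int(rng.integers(len(candidates)))]
        if j is i or j is p or _is_descendant(j, i):
            return None
        pj = j.parent
        if pj is p:
            pj = g  # after detaching p, s hangs from g; branch (s, g)
            if j is not s:
                return None
        if pj.age <= i.age:
            return None
        window_old = g.age - max(i.age, s.age)
        # detach p
        g.children[g.children.index(p)] = s
        s.parent = g
        # attach on branch (j, pj)
        lo = max(i.age, j.age)
        hi = pj.age
        window_new = hi - lo
        if window_new <= 0:
            return None
        p.children[p.children.index(s)] = j
        pj.children[pj.children.index(j)] = p
        p.parent = pj
        j.parent = p
        p.age = rng.uniform(lo, hi)
        tree.invalidate()
        return math.log(window_new / window_old)

    if move == "clock_mean_scaler":
        m = _scale_factor(rng, 3.0)
        state.clock.mean_rate *= m
        return math.log(m)

    if move == "clock_stdev_scaler":
        if state.clock.stdev == 0:
            return None
        m = _scale_factor(rng, 0.7)
        state.clock.stdev *= m
        return math.log(m)

    if move == "clock_stdev_rescale":
        # non-centered stdev move: scale stdev and map every branch rate
        # through its standardized residual, avoiding the funnel between
        # stdev and the rates.  Deterministic bijection; the Hastings term
        # carries the scaler and the rate-transform Jacobian.
        sd = state.clock.stdev
        if sd == 0:
            return None
        m = _scale_factor(rng, 0.7)
        new_sd = sd * m
        branches = [n for n in tree.postorder() if n.parent is not None]
        log_jac = math.log(m)  # the stdev scaler itself
        for node in branches:
            z = (math.log(node.rate) + 0.5 * sd * sd) / sd
            new_rate = math.exp(-0.5 * new_sd * new_sd + new_sd * z)
            log_jac += math.log(new_rate / node.rate) + math.log(m)
            node.rate = new_rate
        state.clock.stdev = new_sd
        return log_jac

    if move == "branch_rate_walk":
        if state.clock.stdev == 0:
            return None
        branches = [n for n in tree.postorder() if n.parent is not None]
        node = branches[int(rng.integers(len(branches)))]
        m = _scale_factor(rng, 0.8)
        node.rate *= m
        return math.log(m)

    if move == "birth_rate_scaler":
        m = _scale_factor(rng, 3.0)
        state.birth_rate *= m
        return math.log(m)

    if move == "alpha_walk":
        delta = 0.15 * (rng.random() - 0.5) * 2.0
        new_alpha = state.params.alpha + delta
        # reflect into (0, 1]
        if new_alpha > 1.0:
            new_alpha = 2.0 - new_alpha
        if new_alpha <= 0.0:
            return None
        state.params = replace(state.params, alpha=new_alpha)
        return 0.0

    if move == "switch_scaler":
        m = _scale_factor(rng, 0.8)
        state.params = replace(state.params, s=state.params.s * m)
        return math.log(m)

    if move == "clock_mean_prior_draw":
        meanlog, sdlog = priors.clock_mean_prior
        new = float(rng.lognormal(meanlog, sdlog))
        hr = _ln_logpdf(state.clock.mean_rate, meanlog, sdlog) \
            - _ln_logpdf(new, meanlog, sdlog)
        state.clock.mean_rate = new
        return hr

    if move == "switch_prior_draw":
        meanlog, sdlog = priors.switch_rate_prior
        new = float(rng.lognormal(meanlog, sdlog))
        hr = _ln_logpdf(state.params.s, meanlog, sdlog) \
            - _ln_logpdf(new, meanlog, sdlog)
        state.params = replace(state.params, s=new)
        return hr

    if move == "alpha_prior_draw":
        new = 1.0 - float(rng.random())  # uniform on (0, 1]
        state.params = replace(state.params, alpha=new)
        return 0.0

    if move == "clock_stdev_prior_draw":
        sd = state.clock.stdev
        if sd == 0:
            return None
        shape, second = priors.clock_stdev_prior
        scale = 1.0 / second if priors.gamma_is_shape_rate else second
        new_sd = float(rng.gamma(shape, scale))
        if new_sd <= 0:
            return None
        hr = _gamma_lp(sd, shape, scale) - _gamma_lp(new_sd, shape, scale)
        for node in tree.postorder():
            if node.parent is None:
                continue
            z = (math.log(node.rate) + 0.5 * sd * sd) / sd
            new_rate = math.exp(-0.5 * new_sd * new_sd + new_sd * z)
            hr += math.log(new_rate / node.rate) + math.log(new_sd / sd)
            node.rate = new_rate
        state.clock.stdev = new_sd
        return hr

    if move == "birth_rate_prior_draw":
        # draw a birth rate from its prior and quantile-map every interior
        # node age through the conditioned-Yule age distribution, so the
        # (birth rate, node ages) pair jumps along the prior's ridge
        meanlog, sdlog = priors.birth_rate_prior
        lam = state.birth_rate
        new_lam = float(rng.lognormal(meanlog, sdlog))
        T = tree.root.age
        denom_old = -math.expm1(-lam * T)
        denom_new = -math.expm1(-new_lam * T)
        hr = _ln_logpdf(lam, meanlog, sdlog) - _ln_logpdf(new_lam, meanlog, sdlog)
        for node in internal:
            a = node.age
            u = -math.expm1(-lam * a) / denom_old
            u = min(max(u, 1e-15), 1.0 - 1e-15)
            a_new = -math.log1p(-u * denom_new) / new_lam
            # Jacobian da'/da = f_old(a) / f_new(a')
            hr += (math.log(lam) - lam * a - math.log(denom_old)) \
                - (math.log(new_lam) - new_lam * a_new - math.log(denom_new))
            node.age = a_new
        state.birth_rate = new_lam
        return hr

    if move == "clock_rate_exchange":
        # multiply the clock mean by m and divide every branch rate by m:
        # branch distances (and the likelihood) are unchanged, so the move
        # walks the rate ridge at prior-density cost only
        if state.clock.stdev == 0:
            return None
        m = _scale_factor(rng, 1.0)
        state.clock.mean_rate *= m
        branches = [n for n in tree.postorder() if n.parent is not None]
        for node in branches:
            node.rate /= m
        return math.log(m) - len(branches) * math.log(m)

    if move == "partition_rate_exchange":
        if scheme is None or len(state.partition_rates) < 2 or bin_weights is None:
            return None
        labels = sorted(state.partition_rates)
        a, b = rng.choice(len(labels), size=2, replace=False)
        la, lb = labels[int(a)], labels[int(b)]
        u = rng.uniform(0.0, 0.2)
        ra = state.partition_rates[la] + u / bin_weights[la]
        rb = state.partition_rates[lb] - u / bin_weights[lb]
        if ra <= 0 or rb <= 0:
            return None
        state.partition_rates[la] = ra
        state.partition_rates[lb] = rb
        return 0.0

    raise ValueError(f"unknown move {move!r}")


def _is_descendant(node: Node, ancestor: Node) -> bool:
    while node is not None:
        if node is ancestor:
            return True
        node = node.parent
    return False


_TOPOLOGY_MOVES = {"narrow_exchange", "wilson_balding"}


# --------------------------------------------------------------------- chain

def run_chain(matrix: Optional[CognateMatrix] = None,
              scheme: Optional[PartitionScheme] = None,
              priors: Optional[PriorConfig] = None,
              constraints: Sequence[MonophylyConstraint] = (),
              config: Optional[ChainConfig] = None,
              prior_only: bool = False,
              taxa: Optional[Sequence[str]] = None,
              initial_params: Optional[CovarionParams] = None,
              initial_clock: Optional[ClockModel] = None,
              relaxed_clock: bool = True,
              log_per_cognate: bool = True) -> PosteriorSample:
    """Sample the posterior (or, with ``prior_only``, the joint prior).

    Either ``matrix`` (whose doculects become the tips) or ``taxa`` must be
    given.  Identical config and seed produce an identical sample stream.
    """
    priors = priors or PriorConfig()
    config = config or ChainConfig()
    rng = np.random.default_rng(config.seed)

    if matrix is None and taxa is None:
        raise ValueError("need a cognate matrix or an explicit taxon list")
    tip_labels = list(taxa) if taxa is not None else list(matrix.doculects)
    if matrix is None and not prior_only:
        raise ValueError("cannot evaluate a likelihood without data")

    for c in constraints:
        unknown = c.taxa - set(tip_labels)
        if unknown:
            raise ConstraintError(f"constraint names unknown taxa {sorted(unknown)}")

    tree = build_initial_tree(tip_labels, constraints,
                              priors.root_age_prior[0], rng)
    clock = initial_clock or ClockModel(
        mean_rate=math.exp(priors.clock_mean_prior[0]),
        stdev=0.25 if relaxed_clock else 0.0)
    params = initial_params or CovarionParams(
        alpha=0.5, s=math.exp(priors.switch_rate_prior[0]))
    if matrix is not None and initial_params is None:
        f0, f1 = matrix.empirical_state_frequencies()
        if f1 > 0:
            params = replace(params, f_absent=f0, f_present=f1)
    birth_rate = math.exp(priors.birth_rate_prior[0])

    bin_weights: Optional[dict[str, float]] = None
    partition_rates: dict[str, float] = {}
    if scheme is not None and matrix is not None:
        sizes = matrix.meaning_sizes()
        bin_weights = {lab: float(sum(sizes[m] for m in members))
                       for lab, members in scheme.bins.items()}
        partition_rates = {lab: 1.0 for lab in scheme.bins}

    state = _State(tree, clock, params, birth_rate, partition_rates)

    weights = {name: 1.0 for name in MOVE_NAMES}
    if config.move_weights is not None:
        weights.update(config.move_weights)
    names = [n for n in MOVE_NAMES if weights[n] > 0]
    probs = np.array([weights[n] for n in names])
    probs = probs / probs.sum()

    layout = None
    if matrix is not None and not prior_only:
        layout = MatrixLayout(matrix, scheme)

    def evaluate(st: _State):
        lp = log_prior(st.tree, st.clock, st.params, priors, st.birth_rate)
        if layout is None:
            return lp, 0.0, None
        ll, per_cog = layout_loglik(st.tree, st.clock, st.params, layout,
                                    st.partition_rates or None)
        return lp, ll, per_cog

    cur_prior, cur_lik, cur_per_cog = evaluate(state)
    if not math.isfinite(cur_prior + cur_lik):
        raise RuntimeError("initial state has zero posterior density")

    accepted = {n: 0 for n in names}
    proposed = {n: 0 for n in names}
    gens: list[int] = []
    trees_out: list[TimeTree] = []
    rows: list[dict[str, float]] = []
    lls: list[float] = []
    per_cog_rows: list[np.ndarray] = []
    per_cog_index = None

    def record(gen: int) -> None:
        gens.append(gen)
        trees_out.append(state.tree.copy())
        row = {
            "posterior": cur_prior + cur_lik,
            "prior": cur_prior,
            "birth_rate": state.birth_rate,
            "clock_mean": state.clock.mean_rate,
            "clock_stdev": state.clock.stdev,
            "alpha": state.params.alpha,
            "switch_rate": state.params.s,
            "root_age": state.tree.root.age,
        }
        for lab, r in sorted(state.partition_rates.items()):
            row[f"rate_{lab}"] = r
        rows.append(row)
        lls.append(cur_lik)
        if cur_per_cog is not None and log_per_cognate:
            per_cog_rows.append(cur_per_cog.copy())

    if layout is not None:
        per_cog_index = list(layout.cognate_ids)

    for gen in range(1, config.generations + 1):
        move = names[int(rng.choice(len(names), p=probs))]
        proposed[move] += 1
        cand = state.copy()
        log_hastings = _propose(cand, move, rng, scheme, bin_weights, priors)
        ok = log_hastings is not None
        if ok and move in _TOPOLOGY_MOVES and constraints:
            ok = all(c.satisfied(cand.tree) for c in constraints)
        if ok:
            try:
                new_prior, new_lik, new_per_cog = evaluate(cand)
            except (FloatingPointError, ValueError):
                ok = False
        if ok:
            log_ratio = (new_prior + new_lik) - (cur_prior + cur_lik) + log_hastings
            if math.isfinite(log_ratio) and math.log(rng.random()) < log_ratio:
                state = cand
                cur_prior, cur_lik, cur_per_cog = new_prior, new_lik, new_per_cog
                accepted[move] += 1
        if gen % config.sample_every == 0:
            record(gen)

    params_frame = pd.DataFrame(rows)
    per_cog_frame = None
    if per_cog_rows and per_cog_index is not None:
        per_cog_frame = pd.DataFrame(per_cog_rows, columns=per_cog_index)
    signature = (tuple(sorted(tip_labels)),
                 tuple(c.id for c in matrix.cognate_sets) if matrix is not None else None,
                 repr(priors), prior_only)
    return PosteriorSample(
        generations=gens, trees=trees_out, params=params_frame,
        loglik=np.array(lls), per_cognate=per_cog_frame, signature=signature,
        acceptance={n: (proposed[n], accepted[n]) for n in names})


# --------------------------------------------------------------- diagnostics

def ess(trace: Sequence[float]) -> float:
    """Effective sample size by Geyer's initial-positive-sequence truncation.

    A constant trace has no information and returns 0 (with a warning).
    """
    x = np.asarray(trace, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples for an ESS estimate")
    x = x - x.mean()
    var = float(np.mean(x * x))
    if var == 0:
        warnings.warn("constant trace: ESS defined as 0", stacklevel=2)
        return 0.0
    # autocovariance via FFT
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[:n].real / n
    rho = acov / acov[0]
    tau = 0.0
    for k in range(0, n - 1, 2):
        gamma = rho[k] + (rho[k + 1] if k + 1 < n else 0.0)
        if gamma <= 0:
            break
        tau += gamma
    iact = max(2.0 * tau - 1.0, 1.0)
    return float(min(n / iact, n))


def combine_runs(runs: Sequence[PosteriorSample],
                 burnin_fraction: float = 0.1) -> PosteriorSample:
    """Concatenate runs after dropping ceil(burnin * N) samples from each."""
    if not runs:
        raise ValueError("no runs to combine")
    if not (0.0 <= burnin_fraction <= 1.0):
        raise ValueError("burn-in fraction must be in [0, 1]")
    sig = runs[0].signature
    for r in runs[1:]:
        if r.signature != sig:
            raise IncompatibleRunsError("runs have different data/model signatures")
    gens: list[int] = []
    trees: list[TimeTree] = []
    frames = []
    lls = []
    per_cogs = []
    offset = 0
    for r in runs:
        drop = math.ceil(burnin_fraction * len(r))
        keep = range(drop, len(r))
        if not keep:
            continue
        for k in keep:
            gens.append(offset + r.generations[k])
            trees.append(r.trees[k])
        offset = gens[-1] if gens else offset
        frames.append(r.params.iloc[list(keep)])
        lls.append(r.loglik[list(keep)])
        if r.per_cognate is not None:
            per_cogs.append(r.per_cognate.iloc[list(keep)])
    if not gens:
        raise ValueError("burn-in removed every sample")
    params = pd.concat(frames, ignore_index=True)
    per_cog = pd.concat(per_cogs, ignore_index=True) if per_cogs else None
    return PosteriorSample(generations=gens, trees=trees, params=params,
                           loglik=np.concatenate(lls), per_cognate=per_cog,
                           signature=sig)
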