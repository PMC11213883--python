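"""Pruning likelihood and ascertainment correction against enumeration."""

import itertools
import math

import numpy as np
import pytest

from lexiphylo.cognate_data import MISSING
from lexiphylo.covarion import ClockModel, CovarionParams
from lexiphylo.likelihood import (all_absent_logprob, character_loglik,
                                  corrected_meaning_loglik, total_loglik)
from lexiphylo.cognate_data import CognateMatrix, CognateSet, \
    partition_by_meaning_size
from lexiphylo.trees import TimeTree

from conftest import enum_column_prob, random_params, random_tree

CLOCK = ClockModel(mean_rate=4.5e-5, stdev=0.0)


class TestCharacterLoglik:
    def test_zero_duration_cherry_gives_stationary_mass(self):
        tree = TimeTree.from_newick("(A:0.0,B:0.0);")
        p = CovarionParams(f_absent=0.8, f_present=0.2)
        ll = character_loglik(tree, CLOCK, p, {"A": 1, "B": 1})
        assert ll == pytest.approx(math.log(0.2), abs=1e-9)
        ll0 = character_loglik(tree, CLOCK, p, {"A": 0, "B": 0})
        assert ll0 == pytest.approx(math.log(0.8), abs=1e-9)

    def test_all_missing_column_has_probability_one(self, rng):
        tree = random_tree(5, rng)
        p = random_params(rng)
        col = {t.label: MISSING for t in tree.tips}
        assert character_loglik(tree, CLOCK, p, col) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n_taxa", [2, 3, 4, 5])
    def test_pruning_equals_enumeration(self, n_taxa, rng):
        for _ in range(4):
            tree = random_tree(n_taxa, rng)
            p = random_params(rng)
            for _ in range(4):
                col = {t.label: int(rng.integers(0, 2)) for t in tree.tips}
                ll = character_loglik(tree, CLOCK, p, col)
                oracle = math.log(enum_column_prob(tree, CLOCK, p, col))
                assert ll == pytest.approx(oracle, abs=1e-10)

    def test_missing_tip_label_is_an_alignment_error(self, rng):
        tree = random_tree(3, rng)
        with pytest.raises(KeyError):
            character_loglik(tree, CLOCK, random_params(rng), {"nope": 1})

    def test_invariant_under_tip_order_permutation(self, rng):
        # the same data presented through relabelled tips gives the same
        # likelihood when the tree is relabelled consistently
        tree = random_tree(4, rng)
        p = random_params(rng)
        col = {t.label: int(rng.integers(0, 2)) for t in tree.tips}
        ll = character_loglik(tree, CLOCK, p, col)
        swapped = tree.copy()
        a, b = swapped.tips[0], swapped.tips[1]
        a.label, b.label = b.label, a.label
        col_swapped = dict(col)
        col_swapped[a.label], col_swapped[b.label] = \
            col[b.label], col[a.label]
        # undo the data swap so the (tree, data) pairing is unchanged
        assert character_loglik(swapped, CLOCK, p, col_swapped) == \
            pytest.approx(ll, abs=1e-12)


class TestAllAbsent:
    def test_zero_duration_two_taxa(self):
        tree = TimeTree.from_newick("(A:0.0,B:0.0);")
        p = CovarionParams(f_absent=0.9, f_present=0.1)
        lp = all_absent_logprob(tree, CLOCK, p, {"A": True, "B": True})
        assert lp == pytest.approx(math.log(0.9), abs=1e-9)

    def test_single_covered_tip_is_stationary_mass(self, rng):
        tree = random_tree(4, rng)
        p = random_params(rng)
        cov = {t.label: False for t in tree.tips}
        cov[tree.tips[0].label] = True
        lp = all_absent_logprob(tree, CLOCK, p, cov)
        assert lp == pytest.approx(math.log(p.f_absent), abs=1e-9)

    def test_uncovered_tips_are_marginalized(self, rng):
        # adding an uncovered outgroup marginalizes out: because the process
        # is stationary, ((A,B):x,C) with C uncovered equals the bare (A,B)
        # cherry with the same subtree ages
        p = random_params(rng)
        cherry = TimeTree.from_newick("(A:1000,B:1000);")
        extended = TimeTree.from_newick("((A:1000,B:1000):500,C:1500);")
        lp_cherry = all_absent_logprob(cherry, CLOCK, p,
                                       {"A": True, "B": True})
        lp_ext = all_absent_logprob(extended, CLOCK, p,
                                    {"A": True, "B": True, "C": False})
        assert lp_ext == pytest.approx(lp_cherry, abs=1e-10)

    def test_no_covered_doculects_is_an_error(self, rng):
        tree = random_tree(3, rng)
        with pytest.raises(ValueError):
            all_absent_logprob(tree, CLOCK, random_params(rng),
                               {t.label: False for t in tree.tips})


class TestCorrectedLikelihood:
    @pytest.mark.parametrize("n_taxa", [2, 3, 4])
    def test_observable_patterns_sum_to_one(self, n_taxa, rng):
        tree = random_tree(n_taxa, rng)
        p = random_params(rng)
        labels = [t.label for t in tree.tips]
        for covered_count in range(1, n_taxa + 1):
            cov = {lab: i < covered_count for i, lab in enumerate(labels)}
            total = 0.0
            for pattern in itertools.product([0, 1], repeat=covered_count):
                if not any(pattern):
                    continue  # the unobservable all-absent pattern
                col = {lab: (pattern[i] if i < covered_count else MISSING)
                       for i, lab in enumerate(labels)}
                ll = corrected_meaning_loglik(tree, CLOCK, p, [col], cov)
                total += math.exp(ll)
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_empty_meaning_contributes_zero(self, rng):
        tree = random_tree(3, rng)
        cov = {t.label: True for t in tree.tips}
        assert corrected_meaning_loglik(tree, CLOCK, random_params(rng),
                                        [], cov) == 0.0

    def test_duplicated_column_adds_its_own_contribution(self, rng):
        tree = random_tree(4, rng)
        p = random_params(rng)
        cov = {t.label: True for t in tree.tips}
        col = {t.label: int(rng.integers(0, 2)) for t in tree.tips}
        if not any(col.values()):
            col[tree.tips[0].label] = 1
        one = corrected_meaning_loglik(tree, CLOCK, p, [col], cov)
        two = corrected_meaning_loglik(tree, CLOCK, p, [col, col], cov)
        assert two == pytest.approx(2 * one, abs=1e-9)


def _matrix_on(tree, columns, meanings):
    labels = [t.label for t in tree.tips]
    cognate_sets = [CognateSet(f"{m}_{j}", m, False)
                    for j, m in enumerate(meanings)]
    cells = np.array([[col[lab] for col in columns] for lab in labels],
                     dtype=np.int8)
    return CognateMatrix(doculects=labels, cognate_sets=cognate_sets,
                         cells=cells)


class TestTotalLoglik:
    def _setup(self, rng, n_taxa=5, n_cols=12):
        tree = random_tree(n_taxa, rng)
        p = random_params(rng)
        meanings = [f"m{1 + j % 3}" for j in range(n_cols)]
        meanings.sort()
        cols = []
        for _ in range(n_cols):
            col = {t.label: int(rng.integers(0, 2)) for t in tree.tips}
            if not any(col.values()):
                col[tree.tips[0].label] = 1
            cols.append(col)
        matrix = _matrix_on(tree, cols, meanings)
        return tree, p, matrix

    def test_unit_multipliers_match_unpartitioned_sum(self, rng):
        tree, p, matrix = self._setup(rng)
        scheme = partition_by_meaning_size(matrix, 2)
        plain, _ = total_loglik(tree, CLOCK, p, matrix)
        rates = {lab: 1.0 for lab in scheme.bins}
        partitioned, _ = total_loglik(tree, CLOCK, p, matrix, scheme, rates)
        assert partitioned == pytest.approx(plain, abs=1e-9)

    def test_per_cognate_vector_sums_to_total(self, rng):
        tree, p, matrix = self._setup(rng)
        total, per_cog = total_loglik(tree, CLOCK, p, matrix)
        assert per_cog.sum() == pytest.approx(total, abs=1e-9)
        assert list(per_cog.index) == [c.id for c in matrix.cognate_sets]

    def test_doubling_a_bin_multiplier_equals_doubling_durations(self, rng):
        tree, p, matrix = self._setup(rng)
        scheme = partition_by_meaning_size(matrix, 2)
        lab = scheme.labels[0]
        rates = {k: (2.0 if k == lab else 1.0) for k in scheme.bins}
        with_mult, per_a = total_loglik(tree, CLOCK, p, matrix, scheme, rates)

        doubled_clock = ClockModel(CLOCK.mean_rate * 2.0, 0.0)
        target_meanings = scheme.bins[lab]
        expected = 0.0
        for meaning in matrix.meanings:
            cols = matrix.columns_for_meaning(meaning)
            cov = {d: bool(matrix.cells[i, cols[0]] != MISSING)
                   for i, d in enumerate(matrix.doculects)}
            colmaps = [{d: int(matrix.cells[i, j])
                        for i, d in enumerate(matrix.doculects)} for j in cols]
            clock = doubled_clock if meaning in target_meanings else CLOCK
            expected += corrected_meaning_loglik(tree, clock, p, colmaps, cov)
        assert with_mult == pytest.approx(expected, abs=1e-9)

    def test_missing_bin_rate_is_a_configuration_error(self, rng):
        tree, p, matrix = self._setup(rng)
        scheme = partition_by_meaning_size(matrix, 2)
        with pytest.raises(ValueError):
            total_loglik(tree, CLOCK, p, matrix, scheme, {})
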