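"""Stochastic character mapping: history validity, event rates, samplers."""

import math

import numpy as np
import pytest

from conftest import random_states, random_tree
from traitrates.mk import (
    fit_mk_rate,
    forward_branch_path,
    mean_scm_changes,
    sample_branch_path_rejection,
    sample_branch_path_uniformization,
    sample_stochastic_map,
    scm_counts,
)
from traitrates.parsimony import fitch_score
from traitrates.traits import TraitVariable
from traitrates.tree import PhylogeneticTree, TreeSample


def history_is_consistent(tree, states, history):
    """Branch paths must connect the sampled endpoint states in order."""
    nodes = list(tree.preorder())
    pos = {id(n): i for i, n in enumerate(nodes)}
    for node in nodes:
        if node is tree.root:
            continue
        a = history.node_states[pos[id(node.parent)]]
        b = history.node_states[pos[id(node)]]
        events = history.events[pos[id(node)]]
        state = a
        prev = 0.0
        for p, frm, to in events:
            if not (prev <= p <= node.length) or frm != state or to == frm:
                return False
            prev, state = p, to
        if state != b:
            return False
        if node.is_tip and b != states[node.label]:
            return False
    return True


class TestHistories:
    def test_constant_tips_near_zero_rate_give_no_events(self, rng):
        tree = PhylogeneticTree.from_newick("((A:1,B:1):1,C:2);")
        states = {"A": 1, "B": 1, "C": 1}
        history = sample_stochastic_map(tree, states, 1e-9, 2, rng)
        assert history.n_changes == 0

    @pytest.mark.parametrize("method", ["rejection", "uniformization"])
    def test_histories_valid_and_bounded_below_by_parsimony(self, rng, method):
        """Every sampled history is consistent and has >= the Fitch count."""
        for _ in range(40):
            tree = random_tree(rng, int(rng.integers(4, 9)))
            k = int(rng.integers(2, 5))
            states = random_states(rng, tree, k)
            fit = fit_mk_rate(tree, states)
            floor = fitch_score(tree, states)
            for _ in range(5):
                h = sample_stochastic_map(
                    tree, states, fit.rate, fit.k, rng, method=method
                )
                assert history_is_consistent(tree, states, h)
                assert h.n_changes >= floor

    def test_same_seed_reproduces_history(self):
        tree = PhylogeneticTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        states = {"A": 1, "B": 2, "C": 1, "D": 2}
        h1 = sample_stochastic_map(
            tree, states, 0.7, 2, np.random.default_rng(42)
        )
        h2 = sample_stochastic_map(
            tree, states, 0.7, 2, np.random.default_rng(42)
        )
        assert h1.node_states == h2.node_states
        assert h1.events == h2.events

    def test_rng_is_mandatory(self):
        tree = PhylogeneticTree.from_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="seeded"):
            sample_stochastic_map(tree, {"A": 1, "B": 1}, 0.5, 2, None)


class TestBranchPaths:
    def test_forward_mean_event_count(self, rng):
        """Unconditioned event count has mean (k-1) r t."""
        k, r, t, n = 3, 0.8, 1.5, 3000
        counts = np.array(
            [len(forward_branch_path(0, t, r, k, rng)[0]) for _ in range(n)]
        )
        expected = (k - 1) * r * t
        se = counts.std(ddof=1) / math.sqrt(n)
        assert abs(counts.mean() - expected) < 3 * se

    def test_rejection_and_uniformization_agree_in_mean(self, rng):
        """The two endpoint-conditioned samplers match in expected counts."""
        k, r, t, n = 3, 0.9, 1.2, 3000
        for a, b in [(0, 0), (0, 1)]:
            rej = np.array([
                len(sample_branch_path_rejection(a, b, t, r, k, rng))
                for _ in range(n)
            ])
            uni = np.array([
                len(sample_branch_path_uniformization(a, b, t, r, k, rng))
                for _ in range(n)
            ])
            se = math.sqrt(rej.var(ddof=1) / n + uni.var(ddof=1) / n)
            assert abs(rej.mean() - uni.mean()) < 3 * se

    def test_uniformization_paths_connect_endpoints(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 6))
            a, b = int(rng.integers(k)), int(rng.integers(k))
            t = float(rng.uniform(0.01, 3.0))
            events = sample_branch_path_uniformization(a, b, t, 0.8, k, rng)
            state = a
            prev = 0.0
            for p, frm, to in events:
                assert prev <= p <= t and frm == state and to != frm
                prev, state = p, to
            assert state == b

    def test_zero_length_branch(self, rng):
        assert sample_branch_path_uniformization(1, 1, 0.0, 2.0, 3, rng) == []
        with pytest.raises(ValueError):
            sample_branch_path_uniformization(0, 1, 0.0, 2.0, 3, rng)


class TestTraitLevel:
    def _variable(self, states, cats):
        return TraitVariable(
            id="v1", description="", n_categories=cats, trait_class="eco",
            states=states,
        )

    def test_constant_trait_counts_zero(self):
        tree = PhylogeneticTree.from_newick("((A:1,B:1):1,C:2);")
        sample = TreeSample(trees=[tree])
        v = self._variable({"A": 1, "B": 1, "C": 1}, cats=3)
        assert mean_scm_changes(sample, v, n_maps=5, seed=0) == 0.0

    def test_scm_mean_at_least_parsimony_mean(self, rng):
        """The per-history parsimony floor survives averaging."""
        tree = random_tree(rng, 12, polytomy_prob=0.0)
        states = {t: int(rng.integers(1, 4)) for t in tree.tip_labels}
        states[tree.tip_labels[0]] = 1
        states[tree.tip_labels[1]] = 2
        sample = TreeSample(trees=[tree])
        v = self._variable(states, cats=3)
        scm = mean_scm_changes(sample, v, n_maps=10, seed=3)
        assert scm >= fitch_score(tree, states)

    def test_seeded_substreams_are_reproducible(self, rng):
        tree = random_tree(rng, 8)
        states = {t: int(rng.integers(1, 3)) for t in tree.tip_labels}
        states[tree.tip_labels[0]] = 1
        states[tree.tip_labels[1]] = 2
        sample = TreeSample(trees=[tree])
        v = self._variable(states, cats=2)
        c1, _ = scm_counts(sample, v, n_maps=6, seed=7, stream=(0, 3))
        c2, _ = scm_counts(sample, v, n_maps=6, seed=7, stream=(0, 3))
        c3, _ = scm_counts(sample, v, n_maps=6, seed=8, stream=(0, 3))
        assert np.array_equal(c1, c2)
        assert not np.array_equal(c1, c3)

    def test_missing_data_pruned_before_mapping(self, rng):
        tree = PhylogeneticTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        sample = TreeSample(trees=[tree])
        v = self._variable({"A": 1, "B": 2, "C": None, "D": 2}, cats=2)
        counts, fits = scm_counts(sample, v, n_maps=5, seed=0)
        assert counts.shape == (1, 5)
        assert all(c >= 1 for c in counts.ravel())  # A vs B,D needs a change
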