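"""Maximum-parsimony change counts for discrete characters.

The parsimony score of a character on a tree is the minimum number of
state changes, over all assignments of states to internal nodes, needed
to produce the observed tip states — the classical proxy for how often a
trait has changed during the history the tree describes.  Scoring is
unordered (unit cost between any two distinct states) and is computed by
a Sankoff-style post-order dynamic programme that handles polytomies
natively, so no arbitrary resolution of multifurcations is needed and the
score is deterministic.  Branch lengths play no role.

Missing data are handled by pruning: a society without a code for the
trait is removed from the tree before scoring (with path lengths of the
remaining taxa preserved), never treated as a free wildcard state.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping

import numpy as np

from .traits import TraitVariable, UnanalysableTrait, trait_coverage
from .tree import PhylogeneticTree, TreeSample

__all__ = [
    "fitch_score",
    "brute_force_parsimony",
    "parsimony_scores",
    "mean_parsimony_changes",
]

_INF = 10**9  # effectively infinite integer cost


def fitch_score(tree: PhylogeneticTree, states: Mapping[str, int]) -> int:
    """Minimum number of unordered state changes explaining the tip states.

    Parameters
    ----------
    tree:
        Tree whose every tip must have a (non-missing) entry in ``states``.
    states:
        Mapping tip label -> state code.  Codes are nominal; any hashable,
        sortable values work.

    Returns
    -------
    int
        The parsimony score.  For ``s`` distinct observed states on
        ``n`` tips it satisfies ``s - 1 <= score <= n - 1``; it is 0 for a
        constant character and invariant under rerooting and relabelling.
    """
    tips = tree.tip_labels
    if len(tips) < 2:
        raise UnanalysableTrait("parsimony needs at least two tips")
    missing = [t for t in tips if t not in states]
    if missing:
        raise ValueError(f"tips without states (prune first): {missing[:5]}")
    codes = sorted({states[t] for t in tips})
    k = len(codes)
    if k == 1:
        return 0
    index = {c: i for i, c in enumerate(codes)}

    cost: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            c = np.full(k, _INF, dtype=np.int64)
            c[index[states[node.label]]] = 0
        else:
            c = np.zeros(k, dtype=np.int64)
            for child in node.children:
                child_cost = cost.pop(id(child))
                # unit-cost Sankoff: stay free, any change costs 1
                c += np.minimum(child_cost, child_cost.min() + 1)
        cost[id(node)] = c
    return int(cost[id(tree.root)].min())


def brute_force_parsimony(
    tree: PhylogeneticTree, states: Mapping[str, int]
) -> int:
    """Exhaustive-enumeration parsimony score (test oracle).

    Minimises the number of state-mismatched edges over every assignment
    of observed states to internal nodes.  Only feasible for tiny
    instances; guarded to <= 8 internal nodes and <= 5 states.
    """
    tips = tree.tip_labels
    codes = sorted({states[t] for t in tips})
    k = len(codes)
    index = {c: i for i, c in enumerate(codes)}
    internals = [n for n in tree.postorder() if not n.is_tip]
    if len(internals) > 8 or k > 5:
        raise ValueError("instance too large for exhaustive parsimony")
    internal_pos = {id(n): i for i, n in enumerate(internals)}

    edges = []  # (child slot, parent slot); slots: ('tip', state) or ('int', i)
    for node in tree.postorder():
        if node is tree.root:
            continue
        child_slot = (
            ("tip", index[states[node.label]])
            if node.is_tip
            else ("int", internal_pos[id(node)])
        )
        edges.append((child_slot, ("int", internal_pos[id(node.parent)])))

    best = math.inf
    for assignment in itertools.product(range(k), repeat=len(internals)):
        changes = 0
        for (ckind, cval), (_, pidx) in edges:
            cstate = cval if ckind == "tip" else assignment[cval]
            if cstate != assignment[pidx]:
                changes += 1
        best = min(best, changes)
    return int(best)


def parsimony_scores(sample: TreeSample, v: TraitVariable) -> np.ndarray:
    """Per-tree parsimony scores for one trait over a tree sample.

    Each tree is pruned to the societies coded for the trait before
    scoring.  Raises :class:`UnanalysableTrait` when fewer than two
    societies are coded.
    """
    coded, n, _ = trait_coverage(v)
    if n < 2:
        raise UnanalysableTrait(
            f"variable {v.id}: only {n} coded societies"
        )
    extra = coded - sample.taxa
    if extra:
        raise ValueError(
            f"variable {v.id}: coded societies not in tree sample: {sorted(extra)[:5]}"
        )
    tip_states = v.coded_states()
    scores = np.empty(len(sample), dtype=float)
    for i, tree in enumerate(sample):
        pruned = tree.prune_to_taxa(coded)
        scores[i] = fitch_score(pruned, tip_states)
    return scores


def mean_parsimony_changes(sample: TreeSample, v: TraitVariable) -> float:
    """Mean parsimony score over the tree sample for one trait.

    Averaging over a posterior sample of trees integrates out phylogenetic
    uncertainty; the result is the "mean parsimony changes" statistic that
    feeds the cross-family rate comparison.
    """
    return float(parsimony_scores(sample, v).mean())
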