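"""Independent test oracles, kept deliberately naive.

Every function here recomputes a quantity by a route different from the
implementation under test: exhaustive enumeration for the Mk likelihood,
dendropy's phylogenetic distance matrix for tip path lengths, explicit
normal equations for OLS residuals, and the inverse-correlation-matrix
formula for partial correlation.
"""

import itertools
import math

import numpy as np

from traitrates.mk import transition_matrix


def enum_log_likelihood(tree, states, r, k):
    """Mk tip-data log-likelihood by summing over all internal states."""
    codes = sorted(set(states.values()))
    assert k >= len(codes)
    index = {c: i for i, c in enumerate(codes)}
    internals = [n for n in tree.postorder() if not n.is_tip]
    pos = {id(n): i for i, n in enumerate(internals)}
    P = {id(n): transition_matrix(r, k, n.length)
         for n in tree.postorder() if n is not tree.root}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        prob = 1.0 / k  # uniform root prior
        for node in tree.postorder():
            if node is tree.root:
                continue
            child = index[states[node.label]] if node.is_tip else assign[pos[id(node)]]
            parent = assign[pos[id(node.parent)]]
            prob *= P[id(node)][parent, child]
        total += prob
    return math.log(total) if total > 0 else -math.inf


def tip_distances(tree):
    """All pairwise tip path lengths, via dendropy (independent of prune)."""
    dtree = tree._to_dendropy()
    pdm = dtree.phylogenetic_distance_matrix()
    out = {}
    for t1, t2 in itertools.combinations(pdm.taxon_iter(), 2):
        key = frozenset((t1.label, t2.label))
        out[key] = pdm.patristic_distance(t1, t2)
    return out


def normal_equation_residuals(y, X):
    """OLS residuals via the explicit (X'X)^-1 X'y solution."""
    y = np.asarray(y, float)
    D = np.column_stack([np.ones(len(y)), np.asarray(X, float)])
    beta = np.linalg.inv(D.T @ D) @ D.T @ y
    return y - D @ beta


def inverse_corr_partial(x, y, Z):
    """Partial correlation from the inverse of the full correlation matrix."""
    M = np.column_stack([x, y, Z])
    P = np.linalg.inv(np.corrcoef(M, rowvar=False))
    return -P[0, 1] / math.sqrt(P[0, 0] * P[1, 1])
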