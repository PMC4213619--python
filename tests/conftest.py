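import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from traitrates.tree import Node, PhylogeneticTree

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_tree(rng, n_tips, polytomy_prob=0.3, min_len=0.05, max_len=2.0):
    """Random rooted tree built by repeated merges; optional polytomies."""
    nodes = [
        Node(length=float(rng.uniform(min_len, max_len)), label=f"t{i + 1}")
        for i in range(n_tips)
    ]
    while len(nodes) > 1:
        width = 2
        if len(nodes) >= 3 and rng.random() < polytomy_prob:
            width = 3
        idx = rng.choice(len(nodes), size=width, replace=False)
        parent = Node(length=float(rng.uniform(min_len, max_len)))
        for i in sorted(idx, reverse=True):
            parent.add_child(nodes.pop(i))
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return PhylogeneticTree(root)


def random_states(rng, tree, k):
    """Random tip states in 0..k-1, resampled until at least 2 are observed."""
    tips = tree.tip_labels
    while True:
        states = {t: int(rng.integers(k)) for t in tips}
        if len(set(states.values())) >= 2 or k == 1:
            return states
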