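"""Symmetric Mk model: likelihood, ML rate fitting, stochastic character maps.

The Mk model is the k-state continuous-time Markov chain with one
instantaneous rate ``r`` for every ordered pair of distinct states
(generator off-diagonals ``r``, diagonals ``-(k-1) r``).  Its transition
probabilities have the closed form

    P_same(t) = 1/k + (k-1)/k * exp(-k r t)
    P_diff(t) = 1/k -     1/k * exp(-k r t)

and its stationary distribution is uniform, which is also used as the
root prior — making the likelihood invariant under root placement.

Stochastic character mapping (SCM) is the two-step change-count
estimator: first fit ``r`` by maximum likelihood (Felsenstein pruning +
bounded 1-D search on log r), then draw complete character histories —
states along every branch — conditional on the tip data and the fitted
rate, and read the number of changes off each sampled history.  Unlike
parsimony, SCM counts changes in proportion to how likely they are under
the fitted process, so its counts are always at least the parsimony
minimum and typically exceed it.

Endpoint-conditioned branch paths are drawn by forward-simulation
rejection with a capped number of attempts, falling back to an exact
uniformization sampler.  For the symmetric Mk chain, uniformization at
rate ``k r`` makes the auxiliary jump chain *uniform over all k states*
(R = I + Q/(k r) has every entry 1/k), so conditioning on the endpoint
costs nothing: the number of auxiliary jumps is a Poisson(k r t) variable
reweighted by the endpoint constraint and the intermediate states are
i.i.d. uniform.  Self-transitions of the auxiliary chain are virtual and
are never counted as changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .traits import TraitVariable, UnanalysableTrait, trait_coverage
from .tree import Node, PhylogeneticTree, TreeSample

__all__ = [
    "RATE_MIN",
    "RATE_MAX",
    "MkFit",
    "CharacterHistory",
    "transition_matrix",
    "mk_log_likelihood",
    "fit_mk_rate",
    "sample_stochastic_map",
    "forward_branch_path",
    "sample_branch_path_rejection",
    "sample_branch_path_uniformization",
    "scm_counts",
    "mean_scm_changes",
]

#: Bounds for the ML rate search, per unit branch length.
RATE_MIN = 1e-8
RATE_MAX = 1e3


@dataclass(frozen=True)
class MkFit:
    """Result of a maximum-likelihood Mk rate fit.

    ``status`` is ``"ok"`` for an interior optimum and ``"boundary"``
    when the optimum sits at a search bound — notably for constant
    characters, whose likelihood is monotone decreasing in the rate.
    """

    k: int
    rate: float
    log_likelihood: float
    status: str

    @property
    def converged(self) -> bool:
        return self.status in ("ok", "boundary")


@dataclass
class CharacterHistory:
    """One sampled character history on a tree.

    ``node_states`` maps preorder node index -> state code; ``events``
    maps the preorder index of a branch's child node to the ordered list
    of ``(position, from_state, to_state)`` changes along that branch,
    positions measured from the parent end in branch-length units.
    """

    node_states: dict[int, int]
    events: dict[int, list[tuple[float, int, int]]]

    @property
    def n_changes(self) -> int:
        return sum(len(ev) for ev in self.events.values())


def transition_matrix(r: float, k: int, t: float) -> np.ndarray:
    """Closed-form k x k transition probability matrix of symmetric Mk."""
    if r < 0 or t < 0:
        raise ValueError("rate and branch length must be non-negative")
    if k < 2:
        raise ValueError("Mk model needs at least two states")
    decay = math.exp(-k * r * t)
    p_diff = (1.0 - decay) / k
    P = np.full((k, k), p_diff)
    np.fill_diagonal(P, 1.0 / k + (k - 1) / k * decay)
    return P


def _index_states(
    states: Mapping[str, int], tips: Sequence[str], k: int | None
) -> tuple[dict[str, int], list[int], int]:
    """Map observed codes to 0..s-1 (model states beyond s are unobserved)."""
    missing = [t for t in tips if t not in states]
    if missing:
        raise ValueError(f"tips without states (prune first): {missing[:5]}")
    codes = sorted({states[t] for t in tips})
    if k is None:
        k = len(codes)
    if k < len(codes):
        raise ValueError(f"k={k} smaller than {len(codes)} observed states")
    index = {t: codes.index(states[t]) for t in tips}
    return index, codes, k


def _partials(
    tree: PhylogeneticTree,
    tip_index: Mapping[str, int],
    r: float,
    k: int,
) -> tuple[dict[int, np.ndarray], float]:
    """Post-order conditional likelihoods per node, with log rescaling.

    Returns (partials keyed by id(node), accumulated log scale).  The
    partial of a node is the probability of the tip data below it given
    each possible state at the node, up to the returned scale factor.
    """
    partials: dict[int, np.ndarray] = {}
    log_scale = 0.0
    for node in tree.postorder():
        if node.is_tip:
            p = np.zeros(k)
            p[tip_index[node.label]] = 1.0
        else:
            p = np.ones(k)
            for child in node.children:
                P = transition_matrix(r, k, child.length)
                p = p * (P @ partials[id(child)])
            m = p.max()
            if m <= 0.0:
                # data impossible under this rate (e.g. r = 0 with
                # conflicting tips); signal via -inf scale
                partials[id(node)] = p
                return partials, -math.inf
            # rescale at every internal node so products never underflow
            p = p / m
            log_scale += math.log(m)
        partials[id(node)] = p
    return partials, log_scale


def mk_log_likelihood(
    tree: PhylogeneticTree,
    states: Mapping[str, int],
    r: float,
    k: int | None = None,
) -> float:
    """Log-probability of the tip states under symmetric Mk at rate ``r``.

    Computed by the pruning recursion with the uniform (stationary) root
    prior.  ``k`` defaults to the number of distinct observed states and
    may be larger; it may not be smaller.  Returns ``-inf`` when the data
    have probability zero (conflicting tips at r = 0).
    """
    if r < 0:
        raise ValueError("rate must be non-negative")
    tip_index, _, k = _index_states(states, tree.tip_labels, k)
    partials, log_scale = _partials(tree, tip_index, r, k)
    if not math.isfinite(log_scale):
        return -math.inf
    root_sum = partials[id(tree.root)].sum() / k
    if root_sum <= 0.0:
        return -math.inf
    return math.log(root_sum) + log_scale


def fit_mk_rate(
    tree: PhylogeneticTree,
    states: Mapping[str, int],
    k: int | None = None,
) -> MkFit:
    """Maximum-likelihood Mk rate by bounded search on log r.

    The search runs over ``[RATE_MIN, RATE_MAX]`` per unit branch length
    with a log-scale tolerance of 1e-8.  Constant characters are returned
    immediately at the lower bound with ``status="boundary"``; fits whose
    optimum lands within numerical reach of either bound are likewise
    flagged ``"boundary"``.
    """
    tips = tree.tip_labels
    if len(tips) < 2:
        raise UnanalysableTrait("rate fitting needs at least two tips")
    tip_index, codes, k = _index_states(states, tips, k)
    if len(codes) == 1:
        ll = mk_log_likelihood(tree, states, RATE_MIN, k)
        return MkFit(k=k, rate=RATE_MIN, log_likelihood=ll, status="boundary")

    def neg_ll(log_r: float) -> float:
        val = mk_log_likelihood(tree, states, math.exp(log_r), k)
        return math.inf if not math.isfinite(val) else -val

    lo, hi = math.log(RATE_MIN), math.log(RATE_MAX)
    res = minimize_scalar(
        neg_ll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
    )
    if not res.success:
        raise RuntimeError(f"Mk rate optimisation failed: {res.message}")
    log_r = float(res.x)
    status = "boundary" if (log_r - lo < 1e-5 or hi - log_r < 1e-5) else "ok"
    return MkFit(k=k, rate=math.exp(log_r), log_likelihood=-float(res.fun), status=status)


# -- endpoint-conditioned branch paths --------------------------------


def forward_branch_path(
    start: int, t: float, r: float, k: int, rng: np.random.Generator
) -> tuple[list[tuple[float, int, int]], int]:
    """Simulate the Mk chain forward along one branch (unconditioned end).

    Returns the event list ``(position, from, to)`` and the end state.
    The leaving rate of each state is ``(k-1) r``, so the unconditional
    expected number of events is ``(k-1) r t``.
    """
    leave = (k - 1) * r
    state = start
    events: list[tuple[float, int, int]] = []
    if leave <= 0.0 or t <= 0.0:
        return events, state
    pos = rng.exponential(1.0 / leave)
    while pos < t:
        new = int(rng.integers(k - 1))
        if new >= state:
            new += 1
        events.append((pos, state, new))
        state = new
        pos += rng.exponential(1.0 / leave)
    return events, state


def sample_branch_path_rejection(
    a: int,
    b: int,
    t: float,
    r: float,
    k: int,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> list[tuple[float, int, int]] | None:
    """Endpoint-conditioned path by forward-simulation rejection.

    Simulates forward from ``a`` and accepts when the end state is ``b``.
    Returns ``None`` after ``max_attempts`` rejections (the caller falls
    back to the exact uniformization sampler).
    """
    for _ in range(max_attempts):
        events, end = forward_branch_path(a, t, r, k, rng)
        if end == b:
            return events
    return None


def _positive_poisson(lam: float, rng: np.random.Generator) -> int:
    """Draw from Poisson(lam) conditioned to be >= 1."""
    if lam > 0.01:
        for _ in range(100000):
            n = int(rng.poisson(lam))
            if n > 0:
                return n
        raise RuntimeError("positive-Poisson sampling failed")  # pragma: no cover
    # Tiny lam: inverse transform on the zero-truncated pmf.
    u = rng.random()
    norm = math.expm1(lam)  # e^lam - 1
    n, term, cum = 1, lam, 0.0
    while True:
        cum += term / norm
        if u <= cum or n > 1000:
            return n
        n += 1
        term *= lam / n


def sample_branch_path_uniformization(
    a: int, b: int, t: float, r: float, k: int, rng: np.random.Generator
) -> list[tuple[float, int, int]]:
    """Exact endpoint-conditioned path via uniformization.

    At uniformization rate ``k r`` the symmetric-Mk auxiliary jump chain
    is uniform over all states, so given the number of auxiliary jumps
    ``n`` the intermediate states are i.i.d. uniform and the final jump
    lands on ``b`` by construction.  ``n`` itself is Poisson(k r t)
    reweighted by the endpoint: weight 1 for ``n = 0`` (only if a == b)
    and ``1/k`` for every ``n >= 1``.  Virtual (self) jumps are dropped.
    """
    lam = k * r * t
    if lam <= 0.0:
        if a != b:
            raise ValueError("zero-length/zero-rate branch with differing endpoints")
        return []
    if a == b:
        # P(N=0 | a,a) = e^-lam / P_aa(t), with
        # P_aa(t) = e^-lam + (1 - e^-lam)/k  (uniformized identity).
        p_aa = math.exp(-lam) + (-math.expm1(-lam)) / k
        if rng.random() < math.exp(-lam) / p_aa:
            return []
    n = _positive_poisson(lam, rng)
    times = np.sort(rng.random(n)) * t
    seq = np.empty(n, dtype=np.int64)
    if n > 1:
        seq[:-1] = rng.integers(k, size=n - 1)
    seq[-1] = b
    events: list[tuple[float, int, int]] = []
    state = a
    for pos, nxt in zip(times, seq):
        nxt = int(nxt)
        if nxt != state:
            events.append((float(pos), state, nxt))
            state = nxt
    return events


# -- whole-tree stochastic maps ---------------------------------------


def sample_stochastic_map(
    tree: PhylogeneticTree,
    states: Mapping[str, int],
    r: float,
    k: int | None = None,
    rng: np.random.Generator | None = None,
    method: str = "rejection",
    max_attempts: int = 1000,
) -> CharacterHistory:
    """Draw one character history conditional on tip data and rate ``r``.

    Node states are sampled from their exact joint conditional
    distribution (root from prior x root partials, then pre-order
    conditional sampling through the stored partial likelihoods); each
    branch path is then drawn conditional on its endpoints by the chosen
    ``method`` (``"rejection"`` with uniformization fallback, or
    ``"uniformization"`` directly).  Histories are reported in the
    original state codes.
    """
    if rng is None:
        raise ValueError("an explicitly seeded numpy Generator is required")
    if method not in ("rejection", "uniformization"):
        raise ValueError(f"unknown path-sampling method {method!r}")
    tip_index, codes, k = _index_states(states, tree.tip_labels, k)
    partials, log_scale = _partials(tree, tip_index, r, k)
    if not math.isfinite(log_scale):
        raise ValueError("tip data have probability zero at this rate")

    nodes = list(tree.preorder())
    node_pos = {id(n): i for i, n in enumerate(nodes)}
    node_states: dict[int, int] = {}
    events: dict[int, list[tuple[float, int, int]]] = {}

    # Pre-order joint sampling of node states.
    sampled: dict[int, int] = {}
    root = tree.root
    w = partials[id(root)].copy()  # uniform prior cancels in normalisation
    sampled[id(root)] = _categorical(w, rng)
    for node in nodes:
        for child in node.children:
            P = transition_matrix(r, k, child.length)
            w = P[sampled[id(node)], :] * partials[id(child)]
            sampled[id(child)] = _categorical(w, rng)

    # Branch paths conditional on sampled endpoints.
    for node in nodes:
        node_states[node_pos[id(node)]] = sampled[id(node)]
        if node is root:
            continue
        a, b = sampled[id(node.parent)], sampled[id(node)]
        if method == "rejection":
            path = sample_branch_path_rejection(
                a, b, node.length, r, k, rng, max_attempts=max_attempts
            )
            if path is None:
                path = sample_branch_path_uniformization(
                    a, b, node.length, r, k, rng
                )
        else:
            path = sample_branch_path_uniformization(a, b, node.length, r, k, rng)
        events[node_pos[id(node)]] = path

    # Report in original codes.
    decode = {i: c for i, c in enumerate(codes)}
    decode_any = lambda s: decode.get(s, s)  # unobserved model states keep index
    return CharacterHistory(
        node_states={i: decode_any(s) for i, s in node_states.items()},
        events={
            i: [(pos, decode_any(x), decode_any(y)) for pos, x, y in ev]
            for i, ev in events.items()
        },
    )


def _categorical(weights: np.ndarray, rng: np.random.Generator) -> int:
    total = weights.sum()
    if total <= 0.0:
        raise ValueError("degenerate conditional state distribution")
    return int(rng.choice(len(weights), p=weights / total))


# -- trait-level summaries --------------------------------------------


def scm_counts(
    sample: TreeSample,
    v: TraitVariable,
    n_maps: int = 20,
    seed: int = 0,
    stream: tuple[int, ...] = (),
    method: str = "rejection",
) -> tuple[np.ndarray, list[MkFit]]:
    """Per-(tree, map) SCM change counts and per-tree rate fits.

    For each tree the pipeline prunes to the coded societies, sets the
    model state count to the number of distinct observed states, fits the
    rate by maximum likelihood, and draws ``n_maps`` histories at that
    tree's fitted rate (each tree has its own branch-length scale, so
    rates are not pooled across trees).  Randomness is drawn from
    substreams derived deterministically from ``(seed, *stream, tree,
    map)``, so results are reproducible and independent of execution
    order.

    A trait that is constant on its coded societies admits no changes:
    its counts are all zero and its fit sits at the rate floor.
    """
    coded, n, _ = trait_coverage(v)
    if n < 2:
        raise UnanalysableTrait(f"variable {v.id}: only {n} coded societies")
    tip_states = v.coded_states()
    counts = np.empty((len(sample), n_maps), dtype=float)
    fits: list[MkFit] = []
    for ti, tree in enumerate(sample):
        pruned = tree.prune_to_taxa(coded)
        observed = {tip_states[t] for t in pruned.tip_labels}
        if len(observed) == 1:
            fits.append(
                MkFit(k=1, rate=RATE_MIN, log_likelihood=0.0, status="boundary")
            )
            counts[ti, :] = 0.0
            continue
        fit = fit_mk_rate(pruned, tip_states)
        fits.append(fit)
        for mi in range(n_maps):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, *stream, ti, mi])
            )
            history = sample_stochastic_map(
                pruned, tip_states, fit.rate, fit.k, rng, method=method
            )
            counts[ti, mi] = history.n_changes
    return counts, fits


def mean_scm_changes(
    sample: TreeSample,
    v: TraitVariable,
    n_maps: int = 20,
    seed: int = 0,
    stream: tuple[int, ...] = (),
    method: str = "rejection",
) -> float:
    """Grand mean SCM change count over trees x maps for one trait."""
    counts, _ = scm_counts(
        sample, v, n_maps=n_maps, seed=seed, stream=stream, method=method
    )
    return float(counts.mean())
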