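"""Synthetic paired families with known ground-truth rates.

The generator builds everything the pipeline consumes — two tree samples,
two trait matrices, a codebook, and a ground-truth table — for a pair of
independent "language families" in which the hypothesis under test is
true by construction: each trait has ONE true rate shared by both
families, with rates spread over a configurable fold-range.  Measured
change counts should then correlate across families once sample size and
category count are controlled, and traits assigned slow rates should show
low residual rates in both families.

Trees are pure-birth (Yule) trees rescaled to unit mean root-to-tip
depth, so true rates are expressed per unit tree depth.  Each family's
trait states are evolved on a dedicated generating tree.  The analysis
sample consists, by default, of branch-length-jittered copies of the
generating tree ("perturb" mode): real posterior tree samples are
inferred from the very societies whose traits are analysed and therefore
approximate the generating history, which is the assumption the whole
comparative method rests on.  An "independent" mode (fresh Yule draws)
is available as a deliberate mis-specification stress: with trees
unrelated to the generating history the data look saturated, Mk rate
estimates diverge, and change counts become erratic — useful for probing
robustness, not a model of a posterior sample.

Missingness is injected per (trait, family) at a random fraction, either
completely at random or concentrated inside one clade ("clustered" mode,
stressing the pruning path).  Random draws come from named substreams of
the master seed, so the same seed yields byte-identical output files and
the uncorrupted entries do not depend on the missingness settings.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .mk import transition_matrix
from .traits import MISSING, TraitMatrix, TraitVariable
from .tree import Node, PhylogeneticTree, TreeSample, write_trees

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "simulate_yule_tree",
    "evolve_discrete_trait",
    "generate_paired_families",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for a paired-family simulation.

    Defaults mirror the cross-cultural design this package targets: two
    families of about a hundred societies each, 28 multistate traits with
    2-10 database categories, per-trait missingness up to half the
    societies, shared true rates spanning 20-fold, and ten "ecological"
    traits occupying the slow end of the rate spectrum.
    """

    n_taxa: tuple[int, int] = (100, 112)
    n_trees: tuple[int, int] = (10, 10)
    n_traits: int = 28
    rate_range: tuple[float, float] = (0.05, 1.0)  # log-uniform, per tree depth
    cats_range: tuple[int, int] = (2, 10)
    missing_range: tuple[float, float] = (0.0, 0.5)
    n_eco: int = 10
    eco_rule: str = "slowest"  # or "random"
    posterior_mode: str = "perturb"  # or "independent"
    perturb_frac: float = 0.2
    missing_mode: str = "random"  # or "clustered"
    family_labels: tuple[str, str] = ("A", "B")
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_taxa) < 2 or min(self.n_trees) < 1 or self.n_traits < 1:
            raise ValueError("counts must be positive")
        if not 0 < self.rate_range[0] <= self.rate_range[1]:
            raise ValueError("rates must be positive and ordered")
        if not 0 <= self.missing_range[0] <= self.missing_range[1] < 1:
            raise ValueError("missing fractions must lie in [0, 1)")
        if not 2 <= self.cats_range[0] <= self.cats_range[1]:
            raise ValueError("category counts must be >= 2 and ordered")
        if not 0 < self.n_eco < self.n_traits:
            raise ValueError("n_eco must leave both classes non-empty")
        if self.eco_rule not in ("slowest", "random"):
            raise ValueError(f"unknown eco_rule {self.eco_rule!r}")
        if self.posterior_mode not in ("independent", "perturb"):
            raise ValueError(f"unknown posterior_mode {self.posterior_mode!r}")
        if self.missing_mode not in ("random", "clustered"):
            raise ValueError(f"unknown missing_mode {self.missing_mode!r}")


@dataclass
class SyntheticDataset:
    """A generated paired-family dataset plus its ground truth."""

    spec: SyntheticSpec
    tree_samples: tuple[TreeSample, TreeSample]
    generating_trees: tuple[PhylogeneticTree, PhylogeneticTree]
    trait_matrices: tuple[TraitMatrix, TraitMatrix]
    codebook: pd.DataFrame
    truth: pd.DataFrame  # variable, true_rate, class, cats

    def write(self, outdir: str | os.PathLike) -> dict[str, str]:
        """Write all pipeline input files plus truth/metadata; returns paths."""
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        paths: dict[str, str] = {}
        for fam, sample, gen_tree, matrix in zip(
            self.spec.family_labels,
            self.tree_samples,
            self.generating_trees,
            self.trait_matrices,
        ):
            p = os.path.join(outdir, f"trees_{fam}.nwk")
            write_trees(sample, p)
            paths[f"trees_{fam}"] = p
            p = os.path.join(outdir, f"generating_tree_{fam}.nwk")
            write_trees([gen_tree], p)
            paths[f"generating_tree_{fam}"] = p
            p = os.path.join(outdir, f"traits_{fam}.csv")
            _matrix_to_frame(matrix).to_csv(p, index=False)
            paths[f"traits_{fam}"] = p
        p = os.path.join(outdir, "codebook.csv")
        self.codebook.to_csv(p, index=False)
        paths["codebook"] = p
        p = os.path.join(outdir, "truth.csv")
        self.truth.to_csv(p, index=False, float_format="%.12g")
        paths["truth"] = p
        p = os.path.join(outdir, "spec.json")
        with open(p, "w", encoding="utf-8") as fh:
            json.dump(asdict(self.spec), fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths["spec"] = p
        return paths


def _matrix_to_frame(matrix: TraitMatrix, missing_code: str = "?") -> pd.DataFrame:
    data = {"society": matrix.societies}
    for v in matrix.variables:
        data[v.id] = [
            missing_code if v.states[s] is MISSING else str(v.states[s])
            for s in matrix.societies
        ]
    return pd.DataFrame(data)


def simulate_yule_tree(
    n_taxa: int, rng: np.random.Generator, labels: list[str] | None = None
) -> PhylogeneticTree:
    """Pure-birth tree on ``n_taxa`` tips, unit mean root-to-tip depth.

    The crown process starts with two lineages; inter-speciation waiting
    times are Exponential(m) with m extant lineages, the splitting lineage
    is uniform, and a final Exponential(n) stretch extends all pendant
    branches so the last speciation does not sit at the present.  All
    branch lengths are then rescaled so that the mean root-to-tip depth is
    exactly 1, putting trait rates on a common per-depth scale.
    """
    if n_taxa < 2:
        raise ValueError("a tree needs at least two tips")
    root = Node()
    active = [root.add_child(Node(length=0.0)), root.add_child(Node(length=0.0))]
    while len(active) < n_taxa:
        wait = rng.exponential(1.0 / len(active))
        for node in active:
            node.length += wait
        split = active.pop(int(rng.integers(len(active))))
        active.append(split.add_child(Node(length=0.0)))
        active.append(split.add_child(Node(length=0.0)))
    final = rng.exponential(1.0 / n_taxa)
    for node in active:
        node.length += final
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_taxa)]
    for node, label in zip(active, labels):
        node.label = label
    tree = PhylogeneticTree(root)
    mean_depth = float(np.mean(list(tree.tip_depths().values())))
    for node in tree.postorder():
        if node is not tree.root:
            node.length /= mean_depth
    return tree


def evolve_discrete_trait(
    tree: PhylogeneticTree, k: int, r: float, rng: np.random.Generator
) -> dict[str, int]:
    """Forward-simulate a k-state symmetric Markov trait; tip codes in 1..k.

    The root state is uniform (the stationary distribution) and each
    child state is drawn from the closed-form transition probabilities
    along its branch.
    """
    if k < 2 or r <= 0:
        raise ValueError("need k >= 2 and r > 0")
    state: dict[int, int] = {id(tree.root): int(rng.integers(k))}
    tips: dict[str, int] = {}
    for node in tree.preorder():
        if node is not tree.root:
            parent_state = state[id(node.parent)]
            p_same = 1.0 / k + (k - 1) / k * math.exp(-k * r * node.length)
            if rng.random() < p_same:
                s = parent_state
            else:
                s = int(rng.integers(k - 1))
                if s >= parent_state:
                    s += 1
            state[id(node)] = s
            if node.is_tip:
                tips[node.label] = s + 1
    return tips


def _perturb_tree(
    tree: PhylogeneticTree, frac: float, rng: np.random.Generator
) -> PhylogeneticTree:
    """Jitter every branch length by a uniform factor in [1-frac, 1+frac]."""
    new = tree.copy()
    for node in new.postorder():
        if node is not new.root:
            node.length *= float(rng.uniform(1.0 - frac, 1.0 + frac))
    return new


def _clade_tips(tree: PhylogeneticTree, rng: np.random.Generator) -> list[str]:
    internals = [n for n in tree.postorder() if not n.is_tip and n is not tree.root]
    node = internals[int(rng.integers(len(internals)))]
    return PhylogeneticTree(node, validate=False).tip_labels


def _inject_missing(
    states: dict[str, int],
    tree: PhylogeneticTree,
    frac: float,
    mode: str,
    rng: np.random.Generator,
) -> dict[str, int | None]:
    societies = sorted(states)
    n_missing = int(math.floor(frac * len(societies)))
    out: dict[str, int | None] = dict(states)
    if n_missing == 0:
        return out
    if mode == "clustered":
        pool = [s for s in _clade_tips(tree, rng) if s in out]
        chosen = pool[:n_missing]
        remaining = [s for s in societies if s not in set(chosen)]
        extra = n_missing - len(chosen)
        if extra > 0:
            idx = rng.choice(len(remaining), size=extra, replace=False)
            chosen += [remaining[i] for i in idx]
    else:
        idx = rng.choice(len(societies), size=n_missing, replace=False)
        chosen = [societies[i] for i in idx]
    for s in chosen:
        out[s] = MISSING
    return out


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


# fixed substream tags, so adding draws to one stage never shifts another
_TREES, _PARAMS, _STATES, _MISSINGNESS = 11, 12, 13, 14


def generate_paired_families(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a full paired-family dataset under ``spec``.

    Per trait, one true rate (log-uniform over ``rate_range``) and one
    category count are drawn and shared by both families; class labels
    follow ``eco_rule`` ("slowest": the ``n_eco`` lowest-rate traits are
    ecological — the generative analogue of slow-evolving
    environment-linked traits).  States are evolved independently per
    family on that family's generating tree, then masked by per-family
    missingness.
    """
    rng_p = _substream(spec.seed, _PARAMS)
    lo, hi = spec.rate_range
    rates = np.exp(rng_p.uniform(math.log(lo), math.log(hi), size=spec.n_traits))
    cats = rng_p.integers(
        spec.cats_range[0], spec.cats_range[1] + 1, size=spec.n_traits
    )
    if spec.eco_rule == "slowest":
        eco_idx = set(np.argsort(rates)[: spec.n_eco].tolist())
    else:
        eco_idx = set(
            rng_p.choice(spec.n_traits, size=spec.n_eco, replace=False).tolist()
        )
    classes = ["eco" if i in eco_idx else "social" for i in range(spec.n_traits)]
    var_ids = [f"v{i + 1}" for i in range(spec.n_traits)]

    codebook = pd.DataFrame(
        {
            "id": var_ids,
            "description": [f"synthetic trait {v}" for v in var_ids],
            "n_categories": cats,
            "class": classes,
        }
    )
    truth = pd.DataFrame(
        {"variable": var_ids, "true_rate": rates, "class": classes, "cats": cats}
    )

    tree_samples: list[TreeSample] = []
    generating_trees: list[PhylogeneticTree] = []
    matrices: list[TraitMatrix] = []
    for fam_i, (fam, n_taxa, n_trees) in enumerate(
        zip(spec.family_labels, spec.n_taxa, spec.n_trees)
    ):
        rng_t = _substream(spec.seed, _TREES, fam_i)
        gen_tree = simulate_yule_tree(n_taxa, rng_t)
        if spec.posterior_mode == "independent":
            trees = [simulate_yule_tree(n_taxa, rng_t) for _ in range(n_trees)]
        else:
            trees = [
                _perturb_tree(gen_tree, spec.perturb_frac, rng_t)
                for _ in range(n_trees)
            ]
        sample = TreeSample(trees=trees, label=fam)
        societies = sorted(sample.taxa)

        variables: list[TraitVariable] = []
        for ti, vid in enumerate(var_ids):
            rng_s = _substream(spec.seed, _STATES, fam_i, ti)
            tip_states = evolve_discrete_trait(
                gen_tree, int(cats[ti]), float(rates[ti]), rng_s
            )
            rng_m = _substream(spec.seed, _MISSINGNESS, fam_i, ti)
            frac = float(rng_m.uniform(*spec.missing_range))
            masked = _inject_missing(
                tip_states, gen_tree, frac, spec.missing_mode, rng_m
            )
            variables.append(
                TraitVariable(
                    id=vid,
                    description=f"synthetic trait {vid}",
                    n_categories=int(cats[ti]),
                    trait_class=classes[ti],
                    states={s: masked[s] for s in societies},
                )
            )
        tree_samples.append(sample)
        generating_trees.append(gen_tree)
        matrices.append(
            TraitMatrix(family=fam, societies=societies, variables=variables)
        )

    return SyntheticDataset(
        spec=spec,
        tree_samples=(tree_samples[0], tree_samples[1]),
        generating_trees=(generating_trees[0], generating_trees[1]),
        trait_matrices=(matrices[0], matrices[1]),
        codebook=codebook,
        truth=truth,
    )
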