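"""Rooted phylogenies with branch lengths, and posterior tree samples.

The in-memory tree is a plain parent/children structure sized for the
post-order dynamic programmes used by the parsimony and Markov-model
modules (Fitch/Sankoff scoring, pruning-algorithm likelihoods, stochastic
character mapping).  Polytomies are first-class: every algorithm in this
package iterates over ``node.children`` rather than assuming bifurcation.
Branch lengths are in whatever units the input trees carry (for language
phylogenies typically expected amounts of lexical change, not time); the
package only ever uses them relatively, so no unit conversion happens here.

Parsing and serialization of newick and NEXUS (including TRANSLATE tables,
quoted labels and bracket comments) are delegated to dendropy; the
conversion layer keeps this module's structure free of dendropy objects.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "TreeError",
    "Node",
    "PhylogeneticTree",
    "TreeSample",
    "parse_trees",
    "write_trees",
]


class TreeError(ValueError):
    """Raised for malformed or invariant-violating trees."""


class Node:
    """A tree node: tips carry a label, non-root nodes a branch length."""

    __slots__ = ("parent", "children", "length", "label")

    def __init__(self, length: float | None = None, label: str | None = None):
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.length = length
        self.label = label

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = f"tip {self.label!r}" if self.is_tip else f"internal({len(self.children)})"
        return f"<Node {kind} length={self.length}>"


class PhylogeneticTree:
    """A rooted tree with unique tip labels and non-negative branch lengths.

    Invariants enforced by :meth:`validate`:

    * tip labels are unique non-empty strings;
    * every non-root node has a branch length >= 0 (zero is legal and
      contributes identity transition probability / zero expected events);
    * no node has exactly one child (unifurcations are suppressed by
      summing branch lengths whenever they arise, e.g. after pruning).

    The tree is treated as rooted exactly as read.  The downstream
    character models (unordered parsimony, symmetric Mk with stationary
    root prior) are invariant under the root placement, which the test
    suite asserts instead of rerooting.
    """

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        if validate:
            self.validate()

    # -- traversal ----------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        """Yield nodes children-before-parents (iterative, stack safe)."""
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_tip:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def tips(self) -> Iterator[Node]:
        return (n for n in self.postorder() if n.is_tip)

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tips())

    # -- invariants ---------------------------------------------------

    def validate(self) -> None:
        seen: set[str] = set()
        for node in self.postorder():
            if node.is_tip:
                if not node.label:
                    raise TreeError("tip with empty label")
                if node.label in seen:
                    raise TreeError(f"duplicate tip label {node.label!r}")
                seen.add(node.label)
            elif len(node.children) == 1:
                raise TreeError("unifurcation (internal node with one child)")
            if node is self.root:
                continue
            if node.length is None:
                raise TreeError(
                    f"missing branch length above {'tip ' + node.label if node.is_tip else 'an internal node'}"
                )
            if node.length < 0:
                raise TreeError(f"negative branch length {node.length}")
        if self.root.parent is not None:
            raise TreeError("root has a parent")
        if len(seen) < 2:
            raise TreeError("tree must have at least two tips")

    def total_branch_length(self) -> float:
        """Sum of all branch lengths (the root carries none)."""
        return sum(n.length for n in self.postorder() if n is not self.root)

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length for every tip."""
        depth: dict[int, float] = {id(self.root): 0.0}
        out: dict[str, float] = {}
        for node in self.preorder():
            if node is self.root:
                continue
            d = depth[id(node.parent)] + node.length
            depth[id(node)] = d
            if node.is_tip:
                out[node.label] = d
        return out

    # -- copy / prune -------------------------------------------------

    def copy(self) -> "PhylogeneticTree":
        mapping: dict[int, Node] = {}
        for node in self.postorder():
            clone = Node(length=node.length, label=node.label)
            for child in node.children:
                clone.add_child(mapping[id(child)])
            mapping[id(node)] = clone
        return PhylogeneticTree(mapping[id(self.root)], validate=False)

    def prune_to_taxa(self, keep: Iterable[str]) -> "PhylogeneticTree":
        """Restrict the tree to ``keep``, preserving kept-tip path lengths.

        Tips outside ``keep`` are removed; internal nodes left childless are
        removed recursively; unifurcations are suppressed by summing branch
        lengths, so the path length between any two retained tips is exactly
        what it was in the input tree.

        Raises
        ------
        TreeError
            If ``keep`` contains an unknown label or fewer than two labels
            (a character observed on fewer than two taxa carries no
            phylogenetic change signal and is flagged un-analysable by the
            calling layer).
        """
        keep = set(keep)
        tipset = set(self.tip_labels)
        unknown = keep - tipset
        if unknown:
            raise TreeError(f"labels not in tree: {sorted(unknown)}")
        if len(keep) < 2:
            raise TreeError("pruning to fewer than two taxa")
        if keep == tipset:
            return self.copy()

        new = self.copy()
        # Drop unwanted tips and, cascading in postorder, emptied internals.
        for node in list(new.postorder()):
            if node is new.root:
                continue
            drop = (node.label is not None and node.label not in keep) or (
                node.label is None and not node.children
            )
            if drop:
                node.parent.children.remove(node)
                node.parent = None
        # Suppress unifurcations bottom-up, summing lengths.
        root = new.root
        for node in list(PhylogeneticTree(root, validate=False).postorder()):
            if len(node.children) == 1 and node.parent is not None:
                child = node.children[0]
                child.length += node.length
                parent = node.parent
                parent.children[parent.children.index(node)] = child
                child.parent = parent
        while len(root.children) == 1:
            # Edges above the surviving subtree's MRCA do not enter any
            # tip-to-tip path; the lone child becomes the new root.
            root = root.children[0]
            root.parent = None
            root.length = None
        return PhylogeneticTree(root)

    # -- I/O ----------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_tip:
                s = _quote_label(node.label)
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.length is not None:
                s += f":{node.length:.12g}"
            return s

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhylogeneticTree":
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
        return cls._from_dendropy(dtree)

    @classmethod
    def _from_dendropy(cls, dtree: dendropy.Tree) -> "PhylogeneticTree":
        mapping: dict[int, Node] = {}
        for dnode in dtree.postorder_node_iter():
            label = None
            if dnode.is_leaf():
                if dnode.taxon is not None:
                    label = dnode.taxon.label
                else:  # leaves without taxa can appear in hand-built trees
                    label = dnode.label
            length = dnode.edge.length
            if dnode.parent_node is None:
                length = None  # root edge length, if any, is discarded
            elif length is None:
                raise TreeError("tree has a non-root edge without a branch length")
            node = Node(length=length, label=label)
            for dchild in dnode.child_nodes():
                node.add_child(mapping[id(dchild)])
            mapping[id(dnode)] = node
        return cls(mapping[id(dtree.seed_node)])

    def _to_dendropy(
        self, taxon_namespace: dendropy.TaxonNamespace | None = None
    ) -> dendropy.Tree:
        tns = taxon_namespace or dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=tns)

        def build(node: Node, dnode: dendropy.Node) -> None:
            dnode.edge.length = node.length
            if node.is_tip:
                dnode.taxon = tns.require_taxon(label=node.label)
            for child in node.children:
                build(child, dnode.new_child())

        build(self.root, dtree.seed_node)
        return dtree


def _quote_label(label: str) -> str:
    if any(c in label for c in " (),:;[]'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass
class TreeSample:
    """An ordered collection of trees over one shared taxon set.

    Typically a Bayesian posterior sample: analysing every tree and
    averaging propagates topology and branch-length uncertainty instead of
    conditioning on a single point estimate.
    """

    trees: list[PhylogeneticTree]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.trees:
            raise TreeError("empty tree sample")
        taxa = set(self.trees[0].tip_labels)
        for i, tree in enumerate(self.trees[1:], start=2):
            if set(tree.tip_labels) != taxa:
                raise TreeError(
                    f"tree {i} in sample {self.label!r} has a different tip set"
                )

    @property
    def taxa(self) -> set[str]:
        return set(self.trees[0].tip_labels)

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[PhylogeneticTree]:
        return iter(self.trees)

    def __getitem__(self, i: int) -> PhylogeneticTree:
        return self.trees[i]


def _read_source(source: str | os.PathLike | IO[str]) -> str:
    if hasattr(source, "read"):
        return source.read()
    path = os.fspath(source)
    if os.path.exists(path):
        with open(path, "r", encoding="utf-8") as fh:
            return fh.read()
    # Fall back to treating the string as literal tree data.
    stripped = path.lstrip()
    if stripped.startswith("(") or stripped.upper().startswith("#NEXUS"):
        return path
    raise FileNotFoundError(path)


def parse_trees(
    source: str | os.PathLike | IO[str],
    format: str = "newick",
    label: str = "",
) -> TreeSample:
    """Read a tree sample from newick (one tree per line) or NEXUS.

    NEXUS TRANSLATE tables are resolved to full labels and bracketed
    comments are ignored.  Every tree must carry branch lengths on all
    non-root edges and all trees must share one tip-label set.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {format!r}")
    data = _read_source(source)
    try:
        dtrees = dendropy.TreeList.get(
            data=data, schema=format, preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises assorted parse error types
        raise TreeError(f"could not parse {format} input: {exc}") from exc
    if not dtrees:
        raise TreeError("no trees found in input")
    return TreeSample(
        trees=[PhylogeneticTree._from_dendropy(t) for t in dtrees], label=label
    )


def write_trees(
    sample: TreeSample | Sequence[PhylogeneticTree],
    dest: str | os.PathLike | IO[str],
    format: str = "newick",
) -> None:
    """Write a tree sample as multi-tree newick or a NEXUS trees block."""
    trees = list(sample.trees if isinstance(sample, TreeSample) else sample)
    if format == "newick":
        text = "\n".join(t.to_newick() for t in trees) + "\n"
    elif format == "nexus":
        tns = dendropy.TaxonNamespace()
        dlist = dendropy.TreeList(taxon_namespace=tns)
        for t in trees:
            dlist.append(t._to_dendropy(taxon_namespace=tns))
        text = dlist.as_string(schema="nexus")
    else:
        raise ValueError(f"unknown tree format {format!r}")
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(os.fspath(dest), "w", encoding="utf-8") as fh:
            fh.write(text)
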