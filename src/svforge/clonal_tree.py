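"""Clonal phylogeny to variant allele fractions.

A clonal-evolution scenario is a strictly binary tree: each internal node is a
bifurcation at which part of a parental cell population gains one structural
variant.  The node carries the variant's label and the *conditional* fraction
f in [0,1] of parental cells that gain it; leaves are the terminal somatic
genotypes.  Which child inherits the variant is a convention (first listed
child by default, switchable).

A root-to-leaf path fully determines a terminal genotype, encoded as a
tertiary path vector c[i,j] in {0,1,2}: 0 = variant j not on leaf i's path,
1 = on the path but not carried, 2 = on the path and carried.  The terminal
population frequency is the product of the branch probabilities along the
path,

    F(C_i) = prod over {j : c[i,j] > 0} of [ f(V_j)       if c[i,j] = 2
                                             1 - f(V_j)   if c[i,j] = 1 ],

and a variant's marginal carrier fraction is the sum over carrying leaves,

    F(V_j) = sum_i 1{c[i,j] = 2} F(C_i).

Frequencies of all leaves sum to one, and along any carrying lineage an
ancestor's F is never below a descendant's.  A bifurcation with f in {0,1}
expresses a deceased population (a leaf of frequency zero).

Trees arrive in NEWICK, internal labels naming variants and branch weights
giving f, e.g. ``((C1, C2) V5: 0.8, ((C3, C4) V4:0.8, (C5, C6) V3: 0.9)
V2:0.6) V1:0.5``.  A multiclonal origin uses the reserved empty label ``-``
at the root with both child fractions 1.  Parsing is delegated to dendropy.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .formats import ValidationError, VariantSpec

__all__ = [
    "ClonalNode",
    "ClonalTree",
    "FrequencyTable",
    "path_vectors",
    "leaf_frequency",
    "variant_frequency",
    "frequency_table",
    "tree2var",
    "ascii_tree",
]

EMPTY_EVENT = "-"  # internal-node label for an event-free bifurcation

ATOL = 1e-9


@dataclass
class ClonalNode:
    label: str
    fraction: float | None = None  # conditional fraction f (internal nodes)
    weight: float | None = None  # optional informational leaf weight
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class ClonalTree:
    """Strictly binary clonal tree with conditional bifurcation fractions.

    ``gaining_child`` selects which child of each bifurcation inherits the
    node's variant: 0 = first listed in the NEWICK string (default), 1 =
    second.
    """

    def __init__(self, root: ClonalNode, gaining_child: int = 0):
        if gaining_child not in (0, 1):
            raise ValueError("gaining_child must be 0 (first) or 1 (second)")
        self.root = root
        self.gaining_child = gaining_child
        self._validate()
        # preorder indexing: internal nodes -> variants, leaves -> genotypes
        self.internal_nodes: list[ClonalNode] = []
        self.leaves: list[ClonalNode] = []
        self._index(root)

    # construction ---------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, gaining_child: int = 0) -> "ClonalTree":
        text = newick.strip()
        if not text.endswith(";"):
            text += ";"
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
        )

        def convert(node) -> ClonalNode:
            label = node.label if node.label is not None else ""
            children = [convert(c) for c in node.child_nodes()]
            if children:
                if node.edge.length is None:
                    raise ValidationError(
                        f"internal node {label or '?'} has no conditional fraction"
                    )
                return ClonalNode(label=label, fraction=float(node.edge.length),
                                  children=children)
            return ClonalNode(
                label=label,
                weight=None if node.edge.length is None else float(node.edge.length),
            )

        return cls(convert(tree.seed_node), gaining_child=gaining_child)

    def _validate(self) -> None:
        def walk(node: ClonalNode):
            if node.is_leaf:
                if not node.label:
                    raise ValidationError("leaf without a genotype label")
                return
            if len(node.children) != 2:
                raise ValidationError(
                    f"internal node {node.label or '?'} has {len(node.children)} "
                    "children; the clonal tree must be strictly binary"
                )
            if node.fraction is None or not 0.0 <= node.fraction <= 1.0:
                raise ValidationError(
                    f"internal node {node.label or '?'} fraction {node.fraction} "
                    "outside [0,1]"
                )
            if not node.label:
                raise ValidationError(
                    f"unlabeled internal node (use {EMPTY_EVENT!r} for an "
                    "event-free bifurcation)"
                )
            for c in node.children:
                walk(c)

        if self.root.is_leaf:
            raise ValidationError("tree has no bifurcation")
        walk(self.root)

    def _index(self, node: ClonalNode) -> None:
        def walk(n: ClonalNode):
            if n.is_leaf:
                self.leaves.append(n)
                return
            self.internal_nodes.append(n)
            for c in n.children:
                walk(c)

        walk(node)
        seen: set[str] = set()
        for n in self.internal_nodes + self.leaves:
            if n.label == EMPTY_EVENT:
                continue
            if n.label in seen:
                raise ValidationError(f"duplicate node label {n.label!r}")
            seen.add(n.label)

    # convenience ----------------------------------------------------------
    @property
    def variant_labels(self) -> list[str]:
        return [n.label for n in self.internal_nodes]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves]


@dataclass(frozen=True)
class FrequencyTable:
    """Final leaf-population and marginal variant frequencies of one tree."""

    leaf_labels: tuple
    variant_labels: tuple
    leaf_freq: np.ndarray  # F(C_i)
    variant_freq: np.ndarray  # F(V_j)

    def leaf(self, label: str) -> float:
        return float(self.leaf_freq[self.leaf_labels.index(label)])

    def variant(self, label: str) -> float:
        return float(self.variant_freq[self.variant_labels.index(label)])


def path_vectors(tree: ClonalTree) -> np.ndarray:
    """Tertiary path-vector matrix, leaves x internal nodes (preorder order)."""
    n, m = len(tree.leaves), len(tree.internal_nodes)
    node_ix = {id(node): j for j, node in enumerate(tree.internal_nodes)}
    leaf_ix = {id(node): i for i, node in enumerate(tree.leaves)}
    c = np.zeros((n, m), dtype=np.int8)

    def walk(node: ClonalNode, path: list[tuple[int, int]]):
        if node.is_leaf:
            for j, code in path:
                c[leaf_ix[id(node)], j] = code
            return
        j = node_ix[id(node)]
        for which, child in enumerate(node.children):
            code = 2 if which == tree.gaining_child else 1
            walk(child, path + [(j, code)])

    walk(tree.root, [])
    return c


def _fractions(tree: ClonalTree) -> np.ndarray:
    return np.array([n.fraction for n in tree.internal_nodes], dtype=float)


def leaf_frequency(tree: ClonalTree, i: int) -> float:
    """Final population frequency F(C_i) of leaf i (preorder index)."""
    c = path_vectors(tree)[i]
    f = _fractions(tree)
    on = c > 0
    factors = np.where(c[on] == 2, f[on], 1.0 - f[on])
    return float(np.prod(factors))


def variant_frequency(tree: ClonalTree, j: int) -> float:
    """Marginal carrier fraction F(V_j) of internal node j (preorder index)."""
    return float(frequency_table(tree).variant_freq[j])


def frequency_table(tree: ClonalTree) -> FrequencyTable:
    c = path_vectors(tree)
    f = _fractions(tree)
    branch = np.where(c == 2, f[None, :], np.where(c == 1, 1.0 - f[None, :], 1.0))
    leaf_freq = branch.prod(axis=1)
    variant_freq = ((c == 2) * leaf_freq[:, None]).sum(axis=0)
    total = leaf_freq.sum()
    if abs(total - 1.0) > 1e-12 * max(1, len(leaf_freq)):
        raise AssertionError(f"leaf frequencies sum to {total}, not 1")
    return FrequencyTable(
        leaf_labels=tuple(tree.leaf_labels),
        variant_labels=tuple(tree.variant_labels),
        leaf_freq=leaf_freq,
        variant_freq=variant_freq,
    )


def tree2var(
    tree: ClonalTree,
    variants: list[VariantSpec],
    ascii_to=sys.stderr,
) -> list[VariantSpec]:
    """Rewrite VAR allele fractions from the clonal tree's marginal frequencies.

    Every non-empty internal-node label must match a vid in ``variants``;
    unmatched VAR records pass through untouched.  An ASCII rendering of the
    parsed tree is printed to ``ascii_to`` (pass None to silence).
    """
    table = frequency_table(tree)
    freq_by_label = {
        lbl: round(float(fv), 12)  # trim accumulated product noise below ATOL
        for lbl, fv in zip(table.variant_labels, table.variant_freq)
        if lbl != EMPTY_EVENT
    }
    vids = {v.vid for v in variants}
    missing = sorted(set(freq_by_label) - vids)
    if missing:
        raise ValidationError(
            "tree variant labels with no matching VAR record: " + ", ".join(missing)
        )
    if ascii_to is not None:
        print(ascii_tree(tree, table), file=ascii_to)
        _warn_leaf_weights(tree, table, ascii_to)
    return [
        v.with_fraction(freq_by_label[v.vid]) if v.vid in freq_by_label else v
        for v in variants
    ]


def _warn_leaf_weights(tree: ClonalTree, table: FrequencyTable, out) -> None:
    # optional NEWICK leaf weights are informational; computed F(C_i) wins
    for i, leaf in enumerate(tree.leaves):
        if leaf.weight is not None and abs(leaf.weight - table.leaf_freq[i]) > ATOL:
            print(
                f"warning: leaf {leaf.label} weight {leaf.weight} differs from "
                f"computed F={table.leaf_freq[i]:.6g}",
                file=out,
            )


def ascii_tree(tree: ClonalTree, table: FrequencyTable | None = None) -> str:
    """Indented ASCII rendering with conditional and final frequencies."""
    if table is None:
        table = frequency_table(tree)
    lines: list[str] = []

    def walk(node: ClonalNode, prefix: str, tail: bool):
        branch = "" if not prefix and not tail else ("`-- " if tail else "|-- ")
        if node.is_leaf:
            fc = table.leaf(node.label)
            lines.append(f"{prefix}{branch}{node.label}  F={fc:.4g}")
            return
        fv = table.variant(node.label) if node.label != EMPTY_EVENT else None
        note = f"  F={fv:.4g}" if fv is not None else ""
        lines.append(f"{prefix}{branch}{node.label}  f={node.fraction:.4g}{note}")
        ext = "" if not prefix and not tail else ("    " if tail else "|   ")
        for k, child in enumerate(node.children):
            walk(child, prefix + ext, k == len(node.children) - 1)

    walk(tree.root, "", False)
    return "\n".join(lines)
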