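"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

# The worked clonal-evolution example tree: five variants, six terminal
# genotypes, conditional bifurcation fractions on the internal branches.
EXAMPLE_NEWICK = "((C1, C2) V5: 0.8, ((C3, C4) V4:0.8, (C5, C6) V3: 0.9) V2:0.6) V1:0.5"


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


@pytest.fixture
def example_tree():
    from svforge.clonal_tree import ClonalTree

    return ClonalTree.from_newick(EXAMPLE_NEWICK)


def random_sequence(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


@pytest.fixture
def make_template(tmp_path, rng):
    def _make(lengths: dict, name="template.fa"):
        path = tmp_path / name
        write_fasta(path, [(c, random_sequence(rng, n)) for c, n in lengths.items()])
        return str(path)

    return _make


# ---------------------------------------------------------------------------
# independent Monte-Carlo population oracle for the clonal tree
#
# Push a cohort of cells down the bifurcation cascade: at each internal node
# a Binomial(f) share gains the node's variant and continues into the gaining
# subtree, the rest into the other.  Carrier fractions and terminal genotype
# frequencies are then simple counts -- no path vectors, no closed forms.


def mc_population_frequencies(tree, n_cells: int, rng):
    leaf_counts: dict[str, int] = {}
    variant_counts: dict[str, int] = {}

    def descend(node, n):
        if node.is_leaf:
            leaf_counts[node.label] = leaf_counts.get(node.label, 0) + n
            return
        gained = int(rng.binomial(n, node.fraction))
        variant_counts[node.label] = variant_counts.get(node.label, 0) + gained
        children = list(node.children)
        gaining = children[tree.gaining_child]
        other = children[1 - tree.gaining_child]
        descend(gaining, gained)
        descend(other, n - gained)

    descend(tree.root, n_cells)
    return (
        {k: v / n_cells for k, v in leaf_counts.items()},
        {k: v / n_cells for k, v in variant_counts.items()},
    )


def binomial_se(p: float, n: int) -> float:
    return np.sqrt(max(p * (1 - p), 1e-12) / n)


# ---------------------------------------------------------------------------
# independent naive string-edit oracle for forge


def naive_edit(seq: str, svtype: str, pos: int, del_len: int, ins_seq: str) -> str:
    """Single-expression reference edits, written without the piece machinery."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = lambda s: "".join(comp[b] for b in reversed(s.upper()))
    i = pos - 1
    seg = seq[i : i + del_len]
    if svtype in ("DEL", "TDEL"):
        return seq[:i] + seq[i + del_len :]
    if svtype in ("INS", "TINS", "ITINS"):
        return seq[:i] + ins_seq + seq[i:]
    if svtype == "DELINS":
        return seq[:i] + ins_seq + seq[i + del_len :]
    if svtype == "DUP":
        return seq[: i + del_len] + seg + seq[i + del_len :]
    if svtype == "IDUP":
        return seq[: i + del_len] + rc(seg) + seq[i + del_len :]
    if svtype == "INV":
        return seq[:i] + rc(seg) + seq[i + del_len :]
    raise ValueError(svtype)
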