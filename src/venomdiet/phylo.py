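"""Phylogeny handling: tree samples, MCC selection, pruning, Brownian covariance.

Trees are dated (branch lengths in time units, e.g. Myr) and rooted; a
posterior sample of such trees shares one tip set.  From a sample we select
the maximum clade credibility (MCC) tree — the sample tree maximizing the
product of its clades' sample frequencies — and from a single tree we build
the Brownian-motion covariance matrix C with

    C_ij = depth (shared root-to-MRCA branch length) of tips i and j,

the residual covariance structure assumed by the phylogenetic regression.

Parsing and pruning are delegated to dendropy; taxon labels are normalized by
replacing underscores with spaces so Newick and Nexus sources agree.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .errors import DataFormatError, ValidationError

Phylogeny = dendropy.Tree
TreeSample = dendropy.TreeList

ULTRAMETRIC_RTOL = 1e-3


def _normalize_label(label: str) -> str:
    return " ".join(label.replace("_", " ").split())


def _normalize_taxa(trees: TreeSample | Phylogeny) -> None:
    ns = trees.taxon_namespace
    for taxon in ns:
        taxon.label = _normalize_label(taxon.label)


def tip_labels(tree: Phylogeny) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def check_ultrametric(tree: Phylogeny, rtol: float = ULTRAMETRIC_RTOL) -> bool:
    """True if all root-to-tip path lengths agree within relative tolerance.

    Violations warn rather than fail: dated trees should be ultrametric, but
    rounding in published Newick strings often breaks exact equality.
    """
    depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
    dmax = max(depths)
    ok = dmax == 0 or (dmax - min(depths)) <= rtol * dmax
    if not ok:
        warnings.warn(
            f"tree is not ultrametric within rtol={rtol:g} "
            f"(tip depths range {min(depths):.6g}..{dmax:.6g})",
            stacklevel=2,
        )
    return ok


def read_trees(path: str | Path) -> TreeSample:
    """Read a Newick or Nexus (multi-)tree file into a shared-tip-set sample.

    The schema is sniffed (``#NEXUS`` magic vs Newick).  Trees are forced
    rooted at their outermost node — dated posterior samples are rooted, and
    re-rooting would change the covariance matrix.  Raises
    :class:`DataFormatError` if unparseable or empty and
    :class:`ValidationError` if the trees disagree on their tip sets
    (the symmetric difference is reported).
    """
    path = Path(path)
    text = path.read_text()
    schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    try:
        trees = dendropy.TreeList.get(
            data=text, schema=schema, rooting="force-rooted", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise DataFormatError(f"could not parse {path} as {schema}: {exc}") from exc
    if len(trees) == 0:
        raise DataFormatError(f"{path}: no trees found")
    _normalize_taxa(trees)

    tip_sets = [frozenset(tip_labels(t)) for t in trees]
    first = tip_sets[0]
    for i, s in enumerate(tip_sets[1:], start=2):
        if s != first:
            diff = sorted(first ^ s)
            raise ValidationError(
                f"{path}: tree 1 and tree {i} have different tip sets; "
                f"symmetric difference: {diff}"
            )
    for t in trees:
        for edge in t.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValidationError(f"{path}: negative branch length {edge.length}")
    return trees


def write_tree(tree: Phylogeny, path: str | Path) -> None:
    """Write a single tree as Newick, spaces in labels rendered as underscores."""

    def _fmt(node: dendropy.Node) -> str:
        if node.is_leaf():
            body = node.taxon.label.replace(" ", "_")
        else:
            body = "(" + ",".join(_fmt(ch) for ch in node.child_nodes()) + ")"
        if node.edge.length is not None:
            body += f":{node.edge.length:.10g}"
        return body

    Path(path).write_text(_fmt(tree.seed_node) + ";\n")


# ---------------------------------------------------------------------------
# maximum clade credibility
# ---------------------------------------------------------------------------

def _nontrivial_clades(tree: Phylogeny) -> set[frozenset[str]]:
    """Tip-label bitsets of internal clades, excluding single tips and the
    full tip set (trivial clades carry no topological information)."""
    all_tips = frozenset(tip_labels(tree))
    clades: set[frozenset[str]] = set()
    for node in tree.preorder_internal_node_iter():
        clade = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if 1 < len(clade) < len(all_tips):
            clades.add(clade)
    return clades


def clade_frequencies(sample: TreeSample) -> dict[frozenset[str], float]:
    """Frequency of each non-trivial clade across the sample."""
    counts: dict[frozenset[str], int] = {}
    for tree in sample:
        for clade in _nontrivial_clades(tree):
            counts[clade] = counts.get(clade, 0) + 1
    n = len(sample)
    return {clade: c / n for clade, c in counts.items()}


def mcc_score(tree: Phylogeny, freqs: dict[frozenset[str], float]) -> float:
    """Sum of log clade credibilities of the tree's non-trivial clades."""
    return sum(math.log(freqs[c]) for c in _nontrivial_clades(tree) if c in freqs)


def mcc_tree(sample: TreeSample) -> tuple[Phylogeny, float]:
    """Select the maximum clade credibility tree from a sample.

    The winner is the tree *in the sample* whose non-trivial clades maximize
    the summed log of clade frequencies (equivalently the product of clade
    credibilities, as in phangorn's maxCladeCred).  Branch lengths are those
    of the selected tree; ties break toward the first tree in file order.
    """
    if len(sample) == 0:
        raise ValidationError("empty tree sample")
    freqs = clade_frequencies(sample)
    best_tree, best_score = None, -math.inf
    for tree in sample:
        score = mcc_score(tree, freqs)
        if score > best_score:
            best_tree, best_score = tree, score
    return best_tree, best_score


# ---------------------------------------------------------------------------
# pruning and covariance
# ---------------------------------------------------------------------------

def prune_to_taxa(tree: Phylogeny, taxa: Iterable[str]) -> Phylogeny:
    """Induced subtree on the requested tips.

    Pairwise path lengths between retained tips are preserved; degree-2
    internal nodes created by pruning are suppressed with their branch
    lengths summed.  Unknown taxa raise :class:`ValidationError` naming them.
    """
    wanted = [_normalize_label(t) for t in taxa]
    if not wanted:
        raise ValidationError("empty taxon set")
    present = set(tip_labels(tree))
    missing = sorted(set(wanted) - present)
    if missing:
        raise ValidationError(f"taxa absent from tree: {missing}")
    pruned = tree.extract_tree_with_taxa_labels(wanted)
    pruned.taxon_namespace = dendropy.TaxonNamespace(
        [leaf.taxon for leaf in pruned.leaf_node_iter()]
    )
    return pruned


@dataclass
class PhyloCovariance:
    """Brownian-motion covariance matrix with its taxon ordering."""

    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValidationError(
                f"covariance shape {self.matrix.shape} does not match {n} taxa"
            )

    @property
    def n(self) -> int:
        return len(self.taxa)

    def reorder(self, taxa: Sequence[str]) -> "PhyloCovariance":
        """Return the covariance restricted/permuted to the given taxon order."""
        index = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in index]
        if missing:
            raise ValidationError(f"taxa absent from covariance: {missing}")
        idx = np.array([index[t] for t in taxa])
        return PhyloCovariance(taxa=list(taxa), matrix=self.matrix[np.ix_(idx, idx)])

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.matrix, index=self.taxa, columns=self.taxa).to_csv(
            path, sep="\t", index_label="taxon"
        )


def bm_covariance(tree: Phylogeny) -> PhyloCovariance:
    """Brownian covariance C_ij = depth of MRCA(i, j) measured from the root.

    Computed by a single postorder sweep: each internal node contributes its
    depth to every tip pair split across distinct child subtrees; diagonals
    are root-to-tip distances.  For an ultrametric tree all diagonals are
    equal (checked with a warning, not an error).
    """
    leaves = list(tree.leaf_node_iter())
    taxa = [leaf.taxon.label for leaf in leaves]
    pos = {id(leaf): i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))

    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length = node.edge.length if node.edge.length is not None else 0.0
        if length < 0:
            raise ValidationError(f"negative branch length {length}")
        depth[id(node)] = depth[id(node.parent_node)] + length

    below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = pos[id(node)]
            below[id(node)] = [i]
            C[i, i] = depth[id(node)]
            continue
        children = [below[id(ch)] for ch in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in children[a]:
                    for j in children[b]:
                        C[i, j] = C[j, i] = d
        below[id(node)] = [i for ch in children for i in ch]

    check_ultrametric(tree)
    return PhyloCovariance(taxa=taxa, matrix=C)
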