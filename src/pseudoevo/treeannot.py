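"""Annotate species trees with per-node protein-distance statistics.

Each internal node is colored by how far apart, under a chosen distance
model, the species on the two sides of that split are: by default the
mean of the defined pairwise distances between leaves of different
child subtrees ("cross-child mean"; a within-clade mean over all
descendant pairs is available as an alternative). Output is a Newick
file with stable internal-node labels plus a tab-separated annotation
sidecar mapping node labels to values and ramp colors (warm = low
distance = closely related).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
from matplotlib import colormaps
from matplotlib.colors import to_hex

from .distances import DistanceMatrix
from .seqio import tree_to_newick

SENTINEL_COLOR = "#808080"


@dataclass
class AnnotatedTree:
    tree: dendropy.Tree
    node_values: dict[str, float]  # internal-node label -> statistic (NaN undefined)
    pruned_species: list[str] = field(default_factory=list)
    statistic: str = "cross_child_mean"


def annotate(
    tree: dendropy.Tree,
    dmatrix: DistanceMatrix,
    statistic: str = "cross_child_mean",
) -> AnnotatedTree:
    """Attach a distance statistic to every internal node of ``tree``.

    Species missing from the distance matrix are pruned (and logged).
    Undefined pairwise distances are excluded from the means; nodes with
    no defined pair get NaN.
    """
    if statistic not in ("cross_child_mean", "within_clade_mean"):
        raise ValueError(f"unknown statistic {statistic!r}")
    tree = tree.clone(depth=1)
    matrix_species = set(dmatrix.species)
    leaf_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    shared = leaf_labels & matrix_species
    if len(shared) < 2:
        raise ValueError("fewer than 2 species shared between tree and matrix")
    pruned = sorted(leaf_labels - matrix_species)
    if pruned:
        tree.retain_taxa_with_labels(sorted(shared))

    index = {sp: k for k, sp in enumerate(dmatrix.species)}
    D = dmatrix.D

    def mean_over(pairs) -> float:
        vals = [D[index[a], index[b]] for a, b in pairs]
        vals = [v for v in vals if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    node_values: dict[str, float] = {}
    counter = itertools.count(1)
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        label = f"N{next(counter)}"
        node.label = label
        child_leafsets = [
            [lf.taxon.label for lf in child.leaf_iter()] for child in node.child_nodes()
        ]
        if statistic == "cross_child_mean":
            pairs = [
                (a, b)
                for (s1, s2) in itertools.combinations(child_leafsets, 2)
                for a in s1
                for b in s2
            ]
        else:
            leaves = [lf for group in child_leafsets for lf in group]
            pairs = list(itertools.combinations(leaves, 2))
        node_values[label] = mean_over(pairs) if pairs else float("nan")
    return AnnotatedTree(tree, node_values, pruned, statistic)


def node_colors(annotated: AnnotatedTree, palette: str = "coolwarm") -> dict[str, str]:
    """Hex color per node: warm end for the lowest (most related) distances."""
    cmap = colormaps[palette]
    defined = {k: v for k, v in annotated.node_values.items() if np.isfinite(v)}
    out: dict[str, str] = {}
    if defined:
        lo, hi = min(defined.values()), max(defined.values())
        span = (hi - lo) or 1.0
        for label, v in defined.items():
            t = (v - lo) / span
            out[label] = to_hex(cmap(1.0 - t))  # low distance -> warm end
    for label, v in annotated.node_values.items():
        if not np.isfinite(v):
            out[label] = SENTINEL_COLOR
    return out


def export_annotation(
    annotated: AnnotatedTree, newick_path, annotation_path, palette: str = "coolwarm"
) -> None:
    """Write labeled Newick plus a (node, value, color) sidecar."""
    with open(newick_path, "w") as fh:
        fh.write(tree_to_newick(annotated.tree))
        fh.write("\n")
    colors = node_colors(annotated, palette)
    with open(annotation_path, "w") as fh:
        fh.write("node\tvalue\tcolor\n")
        for label in sorted(annotated.node_values, key=lambda s: int(s[1:])):
            v = annotated.node_values[label]
            vs = "NA" if not np.isfinite(v) else f"{v:.10g}"
            fh.write(f"{label}\t{vs}\t{colors[label]}\n")


def read_annotation(path) -> dict[str, float]:
    values: dict[str, float] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            node, value, _color = line.rstrip("\n").split("\t")
            values[node] = float("nan") if value == "NA" else float(value)
    return values
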