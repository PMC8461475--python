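"""Strain phylogeny from concatenated core genes.

Core genes are concatenated into a nucleotide supermatrix (gap-filled for
strains missing a core gene), pairwise Jukes-Cantor distances are computed
over shared non-gap columns, a neighbor-joining tree is built and rooted at
the midpoint of its longest tip-to-tip path.  NJ is exact on additive
distance matrices, which is all the downstream stages need from the tree
(topology plus branch lengths); the pipeline equally accepts a
user-supplied rooted Newick tree instead.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .pangenome import GeneRecord, HomologCluster
from .tree import Tree

SATURATION_CEILING = 5.0


class PhylogenyError(ValueError):
    pass


def concatenate_core(clusters: Sequence[HomologCluster],
                     genes: Mapping[str, GeneRecord]) -> dict[str, str]:
    """Per-strain supermatrix from the core clusters, ordered by cluster id.

    Core genes are assumed column-homologous (equal lengths within a
    cluster); a strain missing a cluster's gene gets a gap block of the
    cluster's length.
    """
    core = sorted((c for c in clusters if c.status == "core"),
                  key=lambda c: c.cluster_id)
    if not core:
        raise PhylogenyError("no core clusters")
    strains = sorted({g.strain for g in genes.values()})
    parts: dict[str, list[str]] = {s: [] for s in strains}
    for cluster in core:
        by_strain: dict[str, str] = {}
        length = None
        for gid in cluster.members:
            g = genes[gid]
            if length is None:
                length = len(g.sequence)
            elif len(g.sequence) != length:
                raise PhylogenyError(
                    f"length mismatch within cluster {cluster.cluster_id}")
            by_strain[g.strain] = g.sequence
        for s in strains:
            parts[s].append(by_strain.get(s, "-" * length))
    return {s: "".join(p) for s, p in parts.items()}


def jc_distance(supermatrix: Mapping[str, str],
                saturation_ceiling: float = SATURATION_CEILING
                ) -> DistanceMatrix:
    """Jukes-Cantor distances d = -(3/4) ln(1 - 4p/3) over shared non-gap
    columns; mismatch proportions p >= 0.75 are mapped to a saturation
    ceiling with a warning."""
    strains = sorted(supermatrix)
    if len(strains) < 2:
        raise PhylogenyError("need >= 2 strains")
    arrs = {s: np.frombuffer(supermatrix[s].encode(), dtype="S1")
            for s in strains}
    lengths = {len(supermatrix[s]) for s in strains}
    if len(lengths) != 1:
        raise PhylogenyError("unequal supermatrix row lengths")
    gap = np.bytes_("-")
    n = len(strains)
    d = np.zeros((n, n))
    for i in range(n):
        ai = arrs[strains[i]]
        for j in range(i + 1, n):
            aj = arrs[strains[j]]
            shared = (ai != gap) & (aj != gap)
            total = int(shared.sum())
            if total == 0:
                raise PhylogenyError(
                    f"no shared non-gap columns between {strains[i]} "
                    f"and {strains[j]}")
            p = float((ai[shared] != aj[shared]).sum()) / total
            if p >= 0.75:
                warnings.warn(
                    f"saturated distance between {strains[i]} and "
                    f"{strains[j]} (p={p:.3f}); using ceiling",
                    stacklevel=2)
                dist = saturation_ceiling
            else:
                dist = -0.75 * np.log1p(-4.0 * p / 3.0)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(d, ids=strains)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor joining; negative inferred branch lengths are clamped to 0
    with the deficit shifted to the sister branch."""
    if len(dm.ids) < 3:
        raise PhylogenyError("neighbor joining needs >= 3 strains")
    tree = nj(dm)
    for node in tree.postorder():
        if node.length is not None and node.length < 0:
            deficit = -node.length
            node.length = 0.0
            if node.parent is not None:
                for sib in node.parent.children:
                    if sib is not node and sib.length is not None:
                        sib.length = max(0.0, sib.length + deficit)
                        break
    return tree


def midpoint_root(unrooted: TreeNode) -> Tree:
    """Root at the midpoint of the longest tip-to-tip path."""
    total = sum(n.length or 0.0 for n in unrooted.traverse())
    if total <= 0:
        raise PhylogenyError("all branch lengths zero; cannot midpoint-root")
    rooted = unrooted.root_at_midpoint()
    newick = str(rooted).strip()
    tree = Tree.from_newick(newick)
    tree.root.length = 0.0
    return tree


def build_tree(clusters: Sequence[HomologCluster],
               genes: Mapping[str, GeneRecord]) -> Tree:
    """concatenate -> JC distances -> NJ -> midpoint root."""
    supermatrix = concatenate_core(clusters, genes)
    dm = jc_distance(supermatrix)
    return midpoint_root(nj_tree(dm))
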