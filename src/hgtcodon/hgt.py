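"""HGT inference from phyletic patterns on the strain tree.

For every accessory cluster the per-strain gene copy numbers form a
phyletic pattern.  Marginal ancestral state reconstruction under the
equal-rates model yields a presence probability P(copy > 0) at every node;
a transfer is called on a branch when presence is below 0.5 at the parent
node and above 0.5 at the child node (exact 0.5 calls nothing).  Clusters
present at the root are removed (their accessory status reflects repeated
loss, not transfer).  Scattered patterns at one insertion locus are merged
to the last common ancestor of the separate calls; genes called on the
same branch at consecutive positions of one locus are grouped into a
single HGT event; each carrying leaf is assigned a residence time measured
from the leaf to the midpoint of the event branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .asr import MarginalASR, marginal_posteriors
from .tree import Tree


class HGTError(ValueError):
    pass


@dataclass
class PhyleticPattern:
    cluster_id: str
    copy_numbers: dict[str, int]  # strain -> copies (0 allowed)

    def states(self, tips: Sequence[str]) -> dict[str, np.ndarray]:
        return {t: np.array([self.copy_numbers.get(t, 0)]) for t in tips}

    @property
    def max_state(self) -> int:
        return max(self.copy_numbers.values())


@dataclass
class NodePosterior:
    cluster_id: str
    presence: dict[str, float]  # node -> P(copy > 0)
    rate: float
    asr: MarginalASR | None = None


@dataclass
class HGTEvent:
    event_id: str
    branch: str
    locus: str
    clusters: list[str]
    leaves: list[str]


@dataclass
class GeneAcquisition:
    cluster_id: str
    strain: str
    branch: str
    residence_time: float


def asr_marginal(tree: Tree, pattern: PhyleticPattern,
                 rate: float | None = None) -> NodePosterior:
    """Marginal presence posteriors for one cluster's phyletic pattern.

    The state space is {0, ..., max observed copy number} with equal rates
    between all states; the rate is fitted by maximum likelihood unless
    given.  Presence probability is 1 - P(state 0).
    """
    if pattern.max_state < 1:
        raise HGTError(f"cluster {pattern.cluster_id}: no tip carries it")
    k = pattern.max_state + 1
    tips = tree.tip_names()
    asr = marginal_posteriors(tree, pattern.states(tips), k=k, rate=rate)
    presence = {name: float(1.0 - post[0, 0])
                for name, post in asr.posteriors.items()}
    return NodePosterior(cluster_id=pattern.cluster_id, presence=presence,
                         rate=asr.rate, asr=asr)


def call_hgt(posterior: NodePosterior, tree: Tree) -> list[str]:
    """Branches (child-node names) with P(presence) < 0.5 at the parent and
    > 0.5 at the child.  Strict inequalities: exactly 0.5 calls nothing."""
    calls = []
    for node in tree.branches():
        parent_p = posterior.presence[node.parent.name]
        child_p = posterior.presence[node.name]
        if parent_p < 0.5 and child_p > 0.5:
            calls.append(node.name)
    return calls


def drop_root_present(posteriors: Mapping[str, NodePosterior],
                      tree: Tree) -> tuple[list[str], list[str]]:
    """Split cluster ids into (retained, root_present) by root presence
    probability > 0.5."""
    retained, root_present = [], []
    root = tree.root.name
    for cid, post in posteriors.items():
        (root_present if post.presence[root] > 0.5 else retained).append(cid)
    return retained, root_present


def merge_scattered(calls: list[str], tree: Tree) -> list[str] | None:
    """Replace multiple calls at one insertion locus by a single call on
    the branch ending at the LCA of the called branches' child nodes.

    Returns the merged call list, or None when the LCA is the root itself
    (no branch ends there: the cluster behaves like an ancestrally present
    gene and should be excluded)."""
    if len(calls) <= 1:
        return calls
    lca = tree.lca(calls)
    if lca is tree.root:
        return None
    return [lca.name]


@dataclass
class HGTInference:
    """Per-cluster outcome of the full calling pipeline."""

    calls: dict[str, list[str]] = field(default_factory=dict)
    root_present: list[str] = field(default_factory=list)
    uncalled: list[str] = field(default_factory=list)
    posteriors: dict[str, NodePosterior] = field(default_factory=dict)


def infer_hgt(tree: Tree, patterns: Sequence[PhyleticPattern],
              loci: Mapping[str, str] | None = None,
              rate: float | None = None) -> HGTInference:
    """ASR, root-presence filtering, calling and scattered-pattern merging
    for a set of accessory clusters.

    ``loci`` maps cluster_id -> insertion locus; clusters whose multiple
    calls sit at one locus are merged to the LCA branch.  Clusters with
    calls at distinct loci are left as independent transfers.
    """
    inf = HGTInference()
    for pattern in patterns:
        post = asr_marginal(tree, pattern, rate=rate)
        inf.posteriors[pattern.cluster_id] = post

    retained, inf.root_present = drop_root_present(inf.posteriors, tree)
    for cid in retained:
        calls = call_hgt(inf.posteriors[cid], tree)
        if not calls:
            inf.uncalled.append(cid)
            continue
        if len(calls) > 1 and loci is not None and cid in loci:
            merged = merge_scattered(calls, tree)
            if merged is None:
                inf.root_present.append(cid)
                continue
            calls = merged
        inf.calls[cid] = calls
    return inf


def group_adjacent_into_events(calls: Mapping[str, list[str]],
                               positions: Mapping[str, tuple[str, int]]
                               ) -> list[HGTEvent]:
    """Group clusters called on one branch at consecutive positions of one
    insertion locus into single HGT events.

    ``positions`` maps cluster_id -> (locus, position index).  Runs break
    wherever a position index is skipped; calls at distinct loci or
    branches always form separate events.
    """
    buckets: dict[tuple[str, str], list[tuple[int, str]]] = {}
    for cid, branch_list in calls.items():
        locus, pos = positions[cid]
        for branch in branch_list:
            buckets.setdefault((branch, locus), []).append((pos, cid))

    events = []
    for (branch, locus) in sorted(buckets):
        entries = sorted(buckets[(branch, locus)])
        run: list[str] = []
        last_pos = None
        for pos, cid in entries:
            if last_pos is not None and pos != last_pos + 1:
                events.append((branch, locus, run))
                run = []
            run.append(cid)
            last_pos = pos
        if run:
            events.append((branch, locus, run))

    return [HGTEvent(event_id=f"E{i:04d}", branch=branch, locus=locus,
                     clusters=members, leaves=[])
            for i, (branch, locus, members) in enumerate(events)]


def residence_times(events: Sequence[HGTEvent], tree: Tree,
                    carriers: Mapping[str, Sequence[str]]
                    ) -> list[GeneAcquisition]:
    """Residence time per (cluster, carrying leaf): path length from the
    leaf up to the event branch's child node plus half that branch's
    length.  ``carriers`` maps cluster_id -> strains carrying the gene."""
    depths = tree.depths()
    out = []
    for event in events:
        child = tree.node(event.branch)
        half = 0.5 * child.length
        child_depth = depths[event.branch]
        for cid in event.clusters:
            for strain in carriers.get(cid, ()):
                if not tree.is_descendant(strain, event.branch):
                    raise HGTError(
                        f"leaf {strain} does not descend from branch "
                        f"{event.branch} (cluster {cid})")
                rt = depths[strain] - child_depth + half
                out.append(GeneAcquisition(cluster_id=cid, strain=strain,
                                           branch=event.branch,
                                           residence_time=rt))
                if strain not in event.leaves:
                    event.leaves.append(strain)
    return out
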