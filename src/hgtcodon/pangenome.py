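"""Pan-genome construction: homolog clustering and core/accessory calls.

Genes are clustered by single-linkage over pairwise similarity hits that
pass both an identity threshold (default 0.6) and an overlap threshold
(default 0.7, with the longer sequence as the denominator, which penalises
fragments).  Single-copy clusters present in at least 95 % of strains are
core; multi-copy clusters meeting the same prevalence are split into
single-copy sub-clusters by shared insertion locus first.  Accessory
clusters whose members hit a different cluster with high identity (>0.90)
but low overlap (<0.70) are flagged pseudo-accessory (truncated copies of
resident genes, not transfers) and excluded downstream.

Pairwise similarity uses an exact 18-mer seed prefilter followed by an
edit-distance alignment (edlib) of the shorter sequence inside the longer
one; identity is the fraction of identical aligned columns and overlap the
aligned span over the longer sequence's length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib

_VALID_SEQ = re.compile(r"^[ACGT]+$")
SEED_LENGTH = 18


class PangenomeError(ValueError):
    pass


@dataclass
class GeneRecord:
    """A coding sequence with its genomic context.

    ``locus`` names the insertion locus (intergenic position between core
    genes); ``pos`` is the gene's position index within that locus, so that
    physically adjacent genes have consecutive indices.  The two optional
    ``*_truth`` fields carry simulator ground truth and are never consulted
    by the analysis itself.
    """

    gene_id: str
    strain: str
    locus: str
    pos: int
    sequence: str
    family_truth: str | None = None
    is_core_truth: bool | None = None

    def validate(self) -> "GeneRecord":
        if len(self.sequence) < 3 or len(self.sequence) % 3 != 0:
            raise PangenomeError(
                f"gene {self.gene_id!r}: sequence length must be >= 3 "
                "and divisible by 3")
        if not _VALID_SEQ.match(self.sequence):
            raise PangenomeError(
                f"gene {self.gene_id!r}: non-ACGT characters in sequence")
        return self


@dataclass
class SimilarityHit:
    query: str
    subject: str
    identity: float
    overlap: float
    aln_length: int


@dataclass
class HomologCluster:
    cluster_id: str
    members: list[str]
    status: str = "accessory"  # core | accessory | pseudo_accessory
    copy_profile: dict[str, int] = field(default_factory=dict)

    @property
    def n_strains(self) -> int:
        return len(self.copy_profile)

    @property
    def is_single_copy(self) -> bool:
        return all(n == 1 for n in self.copy_profile.values())


# ---------------------------------------------------------------------------
# Pairwise similarity
# ---------------------------------------------------------------------------

def _cigar_stats(cigar: str) -> tuple[int, int, int]:
    m = i = d = 0
    for length, op in re.findall(r"(\d+)([MIDX=])", cigar):
        n = int(length)
        if op in "M=X":
            m += n
        elif op == "I":
            i += n
        elif op == "D":
            d += n
    return m, i, d


def _shares_seed(a: str, b: str, k: int = SEED_LENGTH) -> bool:
    if len(a) < k or len(b) < k:
        return False
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    kmers = {long_[j:j + k] for j in range(len(long_) - k + 1)}
    return any(short[j:j + k] in kmers
               for j in range(len(short) - k + 1))


def pairwise_similarity(a: GeneRecord, b: GeneRecord,
                        seed_length: int = SEED_LENGTH
                        ) -> SimilarityHit | None:
    """Best local similarity of two genes, or None without a shared seed.

    The shorter sequence is aligned as an infix of the longer one;
    ``identity`` is (identical columns) / (aligned columns) and ``overlap``
    the aligned span divided by the longer sequence's length.
    """
    a.validate()
    b.validate()
    if not _shares_seed(a.sequence, b.sequence, seed_length):
        return None
    return _align_pair(a.sequence, b.sequence, a.gene_id, b.gene_id)


def _align_pair(sa: str, sb: str, qid: str, sid: str) -> SimilarityHit:
    if len(sa) <= len(sb):
        query, target = sa, sb
    else:
        query, target = sb, sa
    res = edlib.align(query, target, mode="HW", task="path")
    m, ins, dele = _cigar_stats(res["cigar"])
    aligned_cols = m + ins + dele
    mismatches = res["editDistance"] - ins - dele
    matches = m - mismatches
    span_target = m + ins  # columns consuming the target
    identity = matches / aligned_cols if aligned_cols else 0.0
    overlap = span_target / max(len(sa), len(sb))
    return SimilarityHit(query=qid, subject=sid, identity=identity,
                         overlap=overlap, aln_length=aligned_cols)


# ---------------------------------------------------------------------------
# All-against-all hits with a k-mer seed index
# ---------------------------------------------------------------------------

def all_pairwise_hits(genes: Sequence[GeneRecord],
                      seed_length: int = SEED_LENGTH,
                      index_step: int = 3, query_step: int = 30
                      ) -> list[SimilarityHit]:
    """Candidate pairs from shared exact ``seed_length``-mers, then one
    alignment per pair.

    The index stores k-mers every ``index_step`` positions and queries probe
    every ``query_step`` positions; both steps are multiples of 3 so that
    codon-aligned homologs (the no-indel regime of this pipeline's inputs)
    always co-sample the same frame.
    """
    genes = list(genes)
    for g in genes:
        g.validate()
    index: dict[str, list[int]] = {}
    for gi, g in enumerate(genes):
        seq = g.sequence
        for j in range(0, len(seq) - seed_length + 1, index_step):
            index.setdefault(seq[j:j + seed_length], []).append(gi)

    pairs: set[tuple[int, int]] = set()
    for gi, g in enumerate(genes):
        seq = g.sequence
        for j in range(0, len(seq) - seed_length + 1, query_step):
            bucket = index.get(seq[j:j + seed_length])
            if not bucket:
                continue
            for gj in bucket:
                if gj != gi:
                    pairs.add((min(gi, gj), max(gi, gj)))

    hits = []
    for gi, gj in sorted(pairs):
        a, b = genes[gi], genes[gj]
        hits.append(_align_pair(a.sequence, b.sequence,
                                a.gene_id, b.gene_id))
    return hits


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_homologs(genes: Sequence[GeneRecord],
                     hits: Sequence[SimilarityHit] | None = None,
                     min_overlap: float = 0.7,
                     min_identity: float = 0.6) -> list[HomologCluster]:
    """Single-linkage connected components over hits passing BOTH
    thresholds; genes with no passing hit form singletons."""
    if not (0 < min_overlap <= 1 and 0 < min_identity <= 1):
        raise PangenomeError("thresholds must be in (0, 1]")
    genes = list(genes)
    if hits is None:
        hits = all_pairwise_hits(genes)
    by_id = {g.gene_id: g for g in genes}
    if len(by_id) != len(genes):
        raise PangenomeError("duplicate gene ids")

    uf = _UnionFind(by_id)
    for h in hits:
        if h.identity >= min_identity and h.overlap >= min_overlap:
            uf.union(h.query, h.subject)

    components: dict[str, list[str]] = {}
    for gid in by_id:
        components.setdefault(uf.find(gid), []).append(gid)

    clusters = []
    for i, root in enumerate(sorted(components)):
        members = sorted(components[root])
        profile: dict[str, int] = {}
        for gid in members:
            strain = by_id[gid].strain
            profile[strain] = profile.get(strain, 0) + 1
        clusters.append(HomologCluster(cluster_id=f"C{i:05d}",
                                       members=members,
                                       copy_profile=profile))
    return clusters


def split_multicopy(cluster: HomologCluster,
                    genes: Mapping[str, GeneRecord]) -> list[HomologCluster]:
    """Partition a multi-copy cluster into single-copy sub-clusters.

    Members sharing an insertion locus across strains are grouped (the
    positional orthology signal); remaining same-strain duplicates within a
    locus are separated by position index.  Already single-copy clusters
    are returned unchanged.
    """
    if cluster.is_single_copy:
        return [cluster]
    groups: dict[tuple, list[str]] = {}
    for gid in cluster.members:
        g = genes[gid]
        groups.setdefault((g.locus, g.pos), []).append(gid)
    # merge (locus, pos) groups that never conflict? keep positional split:
    subs = []
    for j, key in enumerate(sorted(groups)):
        members = sorted(groups[key])
        profile: dict[str, int] = {}
        for gid in members:
            strain = genes[gid].strain
            profile[strain] = profile.get(strain, 0) + 1
        subs.append(HomologCluster(
            cluster_id=f"{cluster.cluster_id}.{j}", members=members,
            copy_profile=profile))
    # a strain may still carry duplicates at one (locus, pos): split greedily
    out = []
    for sub in subs:
        if sub.is_single_copy:
            out.append(sub)
            continue
        buckets: list[dict[str, str]] = []
        for gid in sub.members:
            strain = genes[gid].strain
            placed = False
            for b in buckets:
                if strain not in b:
                    b[strain] = gid
                    placed = True
                    break
            if not placed:
                buckets.append({strain: gid})
        for j, b in enumerate(buckets):
            members = sorted(b.values())
            out.append(HomologCluster(
                cluster_id=f"{sub.cluster_id}.{j}", members=members,
                copy_profile={genes[g].strain: 1 for g in members}))
    return out


def classify_core_accessory(clusters: Sequence[HomologCluster],
                            n_strains: int,
                            genes: Mapping[str, GeneRecord] | None = None,
                            core_fraction: float = 0.95
                            ) -> list[HomologCluster]:
    """Label clusters core/accessory by strain prevalence.

    A cluster is core when it is single-copy and present in at least
    floor(core_fraction * n_strains) strains; multi-copy clusters meeting
    the prevalence rule are first split into single-copy sub-clusters by
    locus (``genes`` required for the split).
    """
    if n_strains < 1:
        raise PangenomeError("n_strains must be >= 1")
    threshold = int(core_fraction * n_strains)
    out = []
    for cluster in clusters:
        if cluster.n_strains >= threshold and not cluster.is_single_copy:
            if genes is None:
                raise PangenomeError(
                    "gene records needed to split multi-copy clusters")
            subs = split_multicopy(cluster, genes)
        else:
            subs = [cluster]
        for sub in subs:
            sub.status = ("core" if sub.n_strains >= threshold
                          and sub.is_single_copy else "accessory")
            out.append(sub)
    return out


def filter_pseudo_accessory(clusters: Sequence[HomologCluster],
                            genes: Mapping[str, GeneRecord],
                            hits: Sequence[SimilarityHit],
                            min_identity: float = 0.90,
                            max_overlap: float = 0.70,
                            min_aln_length: int = 150
                            ) -> tuple[list[HomologCluster],
                                       list[HomologCluster]]:
    """Flag accessory clusters that look like truncated resident genes.

    An accessory cluster becomes pseudo-accessory when any member has a
    significant cross-cluster hit: identity > ``min_identity`` with overlap
    < ``max_overlap`` over an alignment of at least ``min_aln_length`` nt.
    Returns (retained clusters, pseudo clusters); core clusters are always
    retained.
    """
    cluster_of: dict[str, str] = {}
    for c in clusters:
        for gid in c.members:
            cluster_of[gid] = c.cluster_id

    flagged: set[str] = set()
    for h in hits:
        ca, cb = cluster_of.get(h.query), cluster_of.get(h.subject)
        if ca is None or cb is None or ca == cb:
            continue
        if (h.identity > min_identity and h.overlap < max_overlap
                and h.aln_length >= min_aln_length):
            flagged.add(ca)
            flagged.add(cb)

    retained, pseudo = [], []
    for c in clusters:
        if c.status == "accessory" and c.cluster_id in flagged:
            c.status = "pseudo_accessory"
            pseudo.append(c)
        else:
            retained.append(c)
    return retained, pseudo


def build_pangenome(genes: Sequence[GeneRecord], n_strains: int | None = None,
                    min_overlap: float = 0.7, min_identity: float = 0.6
                    ) -> tuple[list[HomologCluster], list[HomologCluster]]:
    """Cluster, classify and pseudo-filter in one call.

    Returns (retained clusters with core/accessory status, pseudo clusters).
    """
    genes = list(genes)
    if n_strains is None:
        n_strains = len({g.strain for g in genes})
    by_id = {g.gene_id: g for g in genes}
    hits = all_pairwise_hits(genes)
    clusters = cluster_homologs(genes, hits, min_overlap, min_identity)
    clusters = classify_core_accessory(clusters, n_strains, by_id)
    return filter_pseudo_accessory(clusters, by_id, hits)
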