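"""Homolog clustering: redundancy reduction, k-mer similarity graph, Markov clustering.

The similarity search is a k-mer-seeded ungapped identity comparison: two
sequences are compared only if they share at least one exact k-mer (k=12 by
default); the alignment offset is chosen by seed voting and identity is the
match fraction over the ungapped overlap.  At the identity levels that
matter here (>= 0.7) seeding is essentially lossless, while unrelated
sequences (expected identity ~0.25 for random DNA) are never paired.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .tree import taxon_of

__all__ = [
    "SequenceRecord",
    "HomologCluster",
    "record_id",
    "reduce_redundancy",
    "build_similarity_graph",
    "markov_cluster",
    "filter_clusters",
]


def record_id(sample_id: str, copy_index: int) -> str:
    """Canonical record identity; copy 1 is the bare sample id."""
    return sample_id if copy_index == 1 else f"{sample_id}@{copy_index}"


def parse_record_id(rid: str) -> tuple[str, int]:
    if "@" in rid:
        sample, idx = rid.split("@", 1)
        return sample, int(idx)
    return rid, 1


@dataclass(frozen=True)
class SequenceRecord:
    """One (possibly gapped) nucleotide sequence from one sample."""

    sample_id: str
    copy_index: int
    seq: str

    @property
    def rid(self) -> str:
        return record_id(self.sample_id, self.copy_index)

    @property
    def ungapped(self) -> str:
        return self.seq.replace("-", "")


@dataclass
class HomologCluster:
    """A similarity cluster of sequence records; taxa are the distinct samples."""

    cluster_id: str
    members: frozenset  # record ids

    @property
    def taxa(self) -> set[str]:
        return {taxon_of(m) for m in self.members}


# ---------------------------------------------------------------------------
# redundancy reduction (cd-hit-style greedy longest-first, -c 0.99)
# ---------------------------------------------------------------------------


def _containment_identity(short: str, long_: str) -> float:
    """Identity of the shorter sequence against the longer.

    Exact containment scores 1.0; otherwise matches over the shared prefix
    divided by the shorter length (full-length identity).  No gapped
    alignment: redundancy here means near-exact duplicates or truncated
    copies of the same transcript.
    """
    if short in long_:
        return 1.0
    a = np.frombuffer(short.encode(), dtype="S1")
    b = np.frombuffer(long_[: len(short)].encode(), dtype="S1")
    return float((a == b).sum()) / len(short)


def reduce_redundancy(records, identity_threshold: float = 0.99):
    """Greedy longest-first clustering of one sample's records at the given
    identity; returns the representatives (longest of each redundancy group).

    The default threshold 0.99 collapses assembly near-duplicates while
    leaving distinct paralogs (< 99% identical) untouched.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    samples = {r.sample_id for r in records}
    if len(samples) > 1:
        raise ValueError("reduce_redundancy expects records from a single sample")
    ordered = sorted(records, key=lambda r: (-len(r.ungapped), r.rid))
    reps: list[SequenceRecord] = []
    for rec in ordered:
        s = rec.ungapped
        absorbed = False
        for rep in reps:
            if _containment_identity(s, rep.ungapped) >= identity_threshold:
                absorbed = True
                break
        if not absorbed:
            reps.append(rec)
    return reps


# ---------------------------------------------------------------------------
# similarity graph
# ---------------------------------------------------------------------------


def _pair_identity(sa: str, sb: str, k: int) -> float | None:
    """Ungapped identity at the best seed-voted offset, or None without seeds."""
    pos_a: dict[str, list[int]] = defaultdict(list)
    for i in range(len(sa) - k + 1):
        pos_a[sa[i : i + k]].append(i)
    votes: Counter = Counter()
    for j in range(len(sb) - k + 1):
        for i in pos_a.get(sb[j : j + k], ()):
            votes[i - j] += 1
    if not votes:
        return None
    offset = max(votes.items(), key=lambda kv: (kv[1], -abs(kv[0]), kv[0]))[0]
    start_b = max(0, -offset)
    end_b = min(len(sb), len(sa) - offset)
    if end_b - start_b < k:
        return None
    a = np.frombuffer(sa[start_b + offset : end_b + offset].encode(), dtype="S1")
    b = np.frombuffer(sb[start_b:end_b].encode(), dtype="S1")
    return float((a == b).sum()) / (end_b - start_b)


def build_similarity_graph(records, min_identity: float = 0.7, k: int = 12) -> nx.Graph:
    """All-by-all k-mer-seeded identity graph over the representatives.

    Nodes are record ids; an undirected edge carries ``weight`` = identity,
    present iff identity >= ``min_identity``.  Every record appears as a
    node even when isolated.
    """
    recs = list(records)
    if len(recs) < 2:
        g = nx.Graph()
        for r in recs:
            g.add_node(r.rid, sample_id=r.sample_id)
        return g
    g = nx.Graph()
    seqs = []
    for r in recs:
        g.add_node(r.rid, sample_id=r.sample_id)
        seqs.append(r.ungapped)
    index: dict[str, set[int]] = defaultdict(set)
    for idx, s in enumerate(seqs):
        for i in range(len(s) - k + 1):
            index[s[i : i + k]].add(idx)
    candidates: set[tuple[int, int]] = set()
    for ids in index.values():
        if len(ids) > 1:
            members = sorted(ids)
            for x in range(len(members)):
                for y in range(x + 1, len(members)):
                    candidates.add((members[x], members[y]))
    for i, j in sorted(candidates):
        ident = _pair_identity(seqs[i], seqs[j], k)
        if ident is not None and ident >= min_identity:
            g.add_edge(recs[i].rid, recs[j].rid, weight=ident)
    return g


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------


def markov_cluster(
    g: nx.Graph,
    inflation: float = 1.4,
    max_iter: int = 100,
    tol: float = 1e-6,
    prune: float = 1e-8,
):
    """MCL on the weighted adjacency; returns (clusters, converged).

    Self-loops are added with each node's maximum incident weight (1.0 for
    isolated nodes), columns are normalised, and expansion (matrix square)
    alternates with inflation (elementwise power + renormalisation, entries
    below ``prune`` zeroed) until the matrix changes by less than ``tol``
    or ``max_iter`` sweeps.  Clusters are the connected components of the
    converged matrix support, so every node lands in exactly one cluster.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted(g.nodes())
    n = len(nodes)
    if n == 0:
        return [], True
    a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    loop = a.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(a, loop)
    m = a / a.sum(axis=0)
    converged = False
    for _ in range(max_iter):
        m2 = m @ m
        np.power(m2, inflation, out=m2)
        m2[m2 < prune] = 0.0
        m2 /= m2.sum(axis=0)
        delta = float(np.abs(m2 - m).max())
        m = m2
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge; returning the current partition", stacklevel=2)
    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(m > tol)
    support.add_edges_from((int(i), int(j)) for i, j in zip(rows, cols) if i != j)
    clusters = [sorted(nodes[i] for i in comp) for comp in nx.connected_components(support)]
    clusters.sort(key=lambda c: (-len(c), c))
    return clusters, converged


def filter_clusters(clusters, min_taxa: int = 4):
    """Keep clusters with at least ``min_taxa`` distinct taxa.

    Returns (kept HomologClusters, report dict with kept/dropped counts).
    """
    kept: list[HomologCluster] = []
    dropped = 0
    for i, members in enumerate(clusters):
        hc = HomologCluster(cluster_id=f"cluster_{i:05d}", members=frozenset(members))
        if len(hc.taxa) >= min_taxa:
            kept.append(hc)
        else:
            dropped += 1
    return kept, {"kept": len(kept), "dropped": dropped}
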