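"""Cross-dataset agreement, geographic contiguity, and species delimitation.

Clusters from independent datasets are compared by the Hubert–Arabie
adjusted Rand index, merged when diffuse (high cross-pair classification
uncertainty plus broadly overlapping ranges), and combined into a
conservative species hypothesis: specimens co-clustered by two or more
intrinsic datasets form candidate species groups, each screened for
geographic contiguity on a pruned Delaunay graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import MultiPoint
from sklearn.metrics import adjusted_rand_score

from .errors import IdError
from .mixtures import Partition


@dataclass
class CongruenceReport:
    """Pairwise adjusted Rand indices over a set of partitions."""

    dataset_tags: list[str]
    ari_matrix: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ari_matrix, index=self.dataset_tags, columns=self.dataset_tags)


@dataclass
class SpeciesHypothesis:
    """Disjoint candidate species groups with support and contiguity audit."""

    groups: list[list[str]]                  # specimen ids per group
    support: list[int]                       # min co-assignment support within group
    contiguous: list[bool]
    contiguity_scores: list[float]
    audit: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, (members, sup, flag, score) in enumerate(
            zip(self.groups, self.support, self.contiguous, self.contiguity_scores), start=1
        ):
            for sid in members:
                rows.append((sid, g, sup, flag, round(score, 4)))
        return pd.DataFrame(rows, columns=["specimen_id", "group", "support", "contiguous", "contiguity_score"])


def _join_labels(p: dict[str, int], q: dict[str, int]) -> tuple[list[int], list[int]]:
    common = [sid for sid in p if sid in q]
    if not common:
        raise IdError("partitions share no specimens")
    return [p[s] for s in common], [q[s] for s in common]


def adjusted_rand(p: dict[str, int], q: dict[str, int]) -> float:
    """Hubert–Arabie adjusted Rand index between two labelings keyed by id."""
    a, b = _join_labels(p, q)
    return float(adjusted_rand_score(a, b))


def _pruned_delaunay_edges(coords: np.ndarray, prune_quantile: float = 0.95):
    """Delaunay edges over all localities with the longest edges pruned.

    Edges strictly longer than the ``prune_quantile`` length are
    removed. Fewer than 3 points (or a degenerate point set) falls back
    to the complete graph.
    """
    n = coords.shape[0]
    if n < 3:
        return [(i, j) for i in range(n) for j in range(i + 1, n)]
    try:
        tri = Delaunay(coords)
    except QhullError:
        return [(i, j) for i in range(n) for j in range(i + 1, n)]
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                i, j = sorted((simplex[a], simplex[b]))
                edges.add((i, j))
    edges = sorted(edges)
    lengths = np.array([np.hypot(*(coords[i] - coords[j])) for i, j in edges])
    cutoff = np.quantile(lengths, prune_quantile)
    return [e for e, L in zip(edges, lengths) if L <= cutoff]


def contiguity(
    member_ids: list[str],
    localities: dict[str, tuple[float, float]],
    prune_quantile: float = 0.95,
    flag_threshold: float = 0.9,
) -> tuple[bool, float]:
    """Geographic contiguity of a cluster on the pruned Delaunay graph.

    The Delaunay graph is built over *all* specimen localities, edges
    longer than the 95th percentile are pruned, and the score is
    1 - (components(member-induced subgraph) - 1)/max(1, members - 1):
    1 when the members form one connected patch, 0 when every member is
    isolated. The flag is score >= ``flag_threshold``.
    """
    all_ids = list(localities)
    coords = np.array([localities[s] for s in all_ids], dtype=float)
    index = {s: i for i, s in enumerate(all_ids)}
    members = [index[s] for s in member_ids if s in index]
    if not members:
        raise IdError("no cluster member has coordinates")
    m = len(members)
    if m == 1:
        return True, 1.0
    edges = _pruned_delaunay_edges(coords, prune_quantile)
    member_set = set(members)
    sub_edges = [(i, j) for i, j in edges if i in member_set and j in member_set]
    remap = {node: k for k, node in enumerate(members)}
    if sub_edges:
        rows = [remap[i] for i, j in sub_edges] + [remap[j] for i, j in sub_edges]
        cols = [remap[j] for i, j in sub_edges] + [remap[i] for i, j in sub_edges]
        graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))
        n_comp, _ = connected_components(graph, directed=False)
    else:
        n_comp = m
    score = 1.0 - (n_comp - 1) / max(1, m - 1)
    return score >= flag_threshold, float(score)


def _hull_overlap_fraction(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection area of two convex hulls over the smaller hull's area.

    Degenerate hulls (points/segments, zero area) overlap fully if the
    geometries intersect at all, else not at all.
    """
    ha = MultiPoint([tuple(p) for p in a]).convex_hull
    hb = MultiPoint([tuple(p) for p in b]).convex_hull
    smaller = min(ha.area, hb.area)
    inter = ha.intersection(hb)
    if smaller == 0:
        return 1.0 if not inter.is_empty else 0.0
    return inter.area / smaller


def merge_diffuse_clusters(
    partition: Partition,
    specimen_ids: list[str],
    localities: dict[str, tuple[float, float]],
    uncertainty_threshold: float = 0.25,
    overlap_threshold: float = 0.20,
) -> tuple[Partition, list[str]]:
    """Merge cluster pairs that are both uncertain and range-overlapping.

    A pair merges when the mean classification uncertainty over the
    union of its members exceeds ``uncertainty_threshold`` and their
    locality convex hulls overlap by more than ``overlap_threshold`` of
    the smaller hull. Merging iterates to a fixed point; the returned
    audit log records each merge. Clusters that are confidently
    separated, or uncertain but allopatric, are left alone.
    """
    labels = partition.labels.copy()
    posterior = partition.posterior.copy()
    audit: list[str] = []
    coords = np.array([localities[s] for s in specimen_ids], dtype=float)

    while True:
        uniq = np.unique(labels)
        merged = False
        for ai in range(len(uniq)):
            for bi in range(ai + 1, len(uniq)):
                a, b = uniq[ai], uniq[bi]
                sel = (labels == a) | (labels == b)
                mean_unc = partition.uncertainty[sel].mean()
                if mean_unc <= uncertainty_threshold:
                    continue
                overlap = _hull_overlap_fraction(coords[labels == a], coords[labels == b])
                if overlap <= overlap_threshold:
                    continue
                audit.append(
                    f"merge {b}->{a}: mean uncertainty {mean_unc:.3f}, hull overlap {overlap:.3f}"
                )
                labels[labels == b] = a
                posterior[:, a - 1] += posterior[:, b - 1]
                posterior[:, b - 1] = 0.0
                merged = True
                break
            if merged:
                break
        if not merged:
            break

    # renumber 1..K by descending size and rebuild uncertainty
    uniq, raw = np.unique(labels, return_inverse=True)
    sizes = np.bincount(raw)
    order = np.argsort(-sizes, kind="stable")
    rank = np.empty(len(uniq), dtype=int)
    rank[order] = np.arange(1, len(uniq) + 1)
    new_labels = rank[raw]
    new_post = np.zeros((len(labels), len(uniq)))
    for k, lab in enumerate(uniq):
        new_post[:, rank[k] - 1] = posterior[:, lab - 1]
    row_sums = new_post.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    new_post = new_post / row_sums
    out = Partition(
        labels=new_labels, posterior=new_post, uncertainty=1.0 - new_post.max(axis=1)
    )
    return out, audit


def congruence_report(partitions: dict[str, dict[str, int]]) -> CongruenceReport:
    """Pairwise ARI matrix over named partitions (specimen_id -> label)."""
    tags = list(partitions)
    n = len(tags)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = adjusted_rand(partitions[tags[i]], partitions[tags[j]])
    return CongruenceReport(dataset_tags=tags, ari_matrix=mat)


def delimit(
    partitions: dict[str, dict[str, int]],
    localities: dict[str, tuple[float, float]],
    min_support: int = 2,
) -> SpeciesHypothesis:
    """Conservative species hypothesis from two or more intrinsic partitions.

    Specimens are joined across partitions (inner join on id); an edge
    links two specimens co-clustered in at least ``min_support``
    datasets; connected components are the candidate species groups —
    the most inclusive sets of congruent clusters. Each group is then
    screened for geographic contiguity; failures are flagged, not
    dissolved. Deterministic and invariant to partition order.
    """
    if len(partitions) < 2:
        raise ValueError("delimitation needs at least two partitions")
    common: set[str] | None = None
    for p in partitions.values():
        common = set(p) if common is None else common & set(p)
    if not common:
        raise IdError("partitions share no specimens")
    ids = sorted(common)
    n = len(ids)
    support_counts = np.zeros((n, n), dtype=int)
    for p in partitions.values():
        lab = np.array([p[s] for s in ids])
        support_counts += lab[:, None] == lab[None, :]
    adj = support_counts >= min_support
    np.fill_diagonal(adj, False)
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    groups, supports, flags, scores = [], [], [], []
    order = np.argsort([-np.sum(comp == c) for c in range(n_comp)], kind="stable")
    audit = []
    for c in order:
        members = [ids[i] for i in np.flatnonzero(comp == c)]
        idx = np.flatnonzero(comp == c)
        if len(idx) > 1:
            sup = int(min(support_counts[i, j] for i in idx for j in idx if i != j and adj[i, j]))
        else:
            sup = len(partitions)
        if localities:
            with_coords = [s for s in members if s in localities]
            if with_coords:
                flag, score = contiguity(with_coords, localities)
            else:
                flag, score = True, 1.0
        else:
            flag, score = True, 1.0
        groups.append(members)
        supports.append(sup)
        flags.append(flag)
        scores.append(score)
        if not flag:
            audit.append(f"group of {len(members)} failed contiguity (score {score:.3f})")
    return SpeciesHypothesis(
        groups=groups, support=supports, contiguous=flags,
        contiguity_scores=scores, audit=audit,
    )
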