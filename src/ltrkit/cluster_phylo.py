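"""Redundancy reduction and distance/NJ phylogeny support.

Concatenated PROT-RT-RH-INT domain proteins are clustered at 80% identity
over 90% of the shorter sequence (single-linkage over pairwise local
alignments); a CD-HIT-style greedy pass at 0.90 identity picks the sequence
best representing each cluster. Observed (p-) distances from precomputed
alignments feed a classic neighbor-joining tree builder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import ElementRecord, PipelineConfig
from .domain_scan import local_align, make_protein_aligner

CONCAT_ORDER = ("PROT", "RT", "RH", "INT")


@dataclass
class Cluster:
    members: list[str]
    representative: str


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        self.matrix = m

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.matrix):
                fh.write(lab + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def concat_domains(element: ElementRecord) -> str | None:
    """Concatenated PROT+RT+RH+INT protein of one element, in that fixed
    order regardless of superfamily genomic order; None (skip with warning)
    if any of the four domains is missing."""
    if element.architecture is None:
        return None
    parts = []
    for dtype in CONCAT_ORDER:
        calls = element.architecture.calls_of_type(dtype)
        if not calls:
            return None
        parts.append(max(calls, key=lambda c: c.score).protein)
    return "".join(parts)


def cluster_by_identity(
    proteins: dict[str, str],
    min_identity: float = 80.0,
    min_coverage: float = 90.0,
    config: PipelineConfig | None = None,
) -> list[Cluster]:
    """Single-linkage clusters: a pair is linked iff local-alignment identity
    >= min_identity percent over an aligned span covering >= min_coverage
    percent of the shorter sequence. Output is independent of input order
    (members and clusters sorted)."""
    if not proteins:
        return []
    if config is not None:
        min_identity = config.cluster_min_identity
        min_coverage = config.cluster_min_coverage
    ids = sorted(proteins)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    aligner = make_protein_aligner()
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if find(a) == find(b):
                continue
            score, ident, q_iv, r_iv = local_align(proteins[a], proteins[b], aligner)
            if score <= 0:
                continue
            shorter = min(len(proteins[a]), len(proteins[b]))
            span = min(q_iv[1] - q_iv[0], r_iv[1] - r_iv[0])
            if ident >= min_identity and span >= min_coverage / 100.0 * shorter:
                parent[find(a)] = find(b)
    comps: dict[str, list[str]] = {}
    for i in ids:
        comps.setdefault(find(i), []).append(i)
    clusters = []
    for members in sorted(comps.values(), key=lambda m: m[0]):
        rep = select_representative(members, proteins)
        clusters.append(Cluster(sorted(members), rep))
    return clusters


def select_representative(
    members: list[str], proteins: dict[str, str], identity: float = 0.90
) -> str:
    """CD-HIT-style greedy representative: members sorted by length
    descending (ties: id); the first is a seed, each later member joins the
    first seed it matches at >= identity, else founds a new seed; the
    representative is the seed of the largest sub-group (ties: longest
    seed)."""
    if not members:
        raise ValueError("empty cluster")
    order = sorted(members, key=lambda m: (-len(proteins[m]), m))
    aligner = make_protein_aligner()
    seeds: list[str] = []
    group_size: dict[str, int] = {}
    for m in order:
        joined = None
        for s in seeds:
            _score, ident, _qi, _ri = local_align(proteins[m], proteins[s], aligner)
            if ident >= identity * 100.0:
                joined = s
                break
        if joined is None:
            seeds.append(m)
            group_size[m] = 1
        else:
            group_size[joined] += 1
    return max(seeds, key=lambda s: (group_size[s], len(proteins[s]), s))


# ---------------------------------------------------------------------------
# observed distances


def observed_distance_matrix(alignment: list[tuple[str, str]]) -> DistanceMatrix:
    """Observed (p-) distances from an alignment: per pair, 1 - fraction of
    identical columns over columns where neither row has a gap."""
    if not alignment:
        raise ValueError("empty alignment")
    labels = [a[0] for a in alignment]
    rows = [a[1].upper() for a in alignment]
    L = len(rows[0])
    if any(len(r) != L for r in rows):
        raise ValueError("ragged alignment: rows differ in length")
    arr = np.array([list(r) for r in rows])
    gap = (arr == "-") | (arr == ".")
    n = len(rows)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            comparable = int(ok.sum())
            if comparable == 0:
                raise ValueError(f"no comparable columns between {labels[i]} and {labels[j]}")
            ident = int((arr[i][ok] == arr[j][ok]).sum())
            m[i, j] = m[j, i] = 1.0 - ident / comparable
    return DistanceMatrix(labels, m)


# ---------------------------------------------------------------------------
# neighbor joining


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []  # list of (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def nj_tree(dm: DistanceMatrix) -> str:
    """Classic Saitou-Nei neighbor joining; returns an unrooted newick tree
    (trifurcating root) with branch lengths.

    Negative branch lengths are clamped to zero with the deficit moved to the
    sister branch, preserving the path length between the joined pair. On an
    additive matrix the tree's path lengths reproduce the input exactly.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes = [_Node(lab) for lab in dm.labels]
    d = dm.matrix.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        m = len(active)
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj, li = d[i, j], 0.0
        if lj < 0:
            li, lj = d[i, j], 0.0
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to the remaining taxa
        k_new = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[k_new, k] = d[k, k_new] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [k_new]

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    branches = []
    for idx, bl in ((i, li), (j, lj), (k, lk)):
        branches.append((nodes[idx], max(bl, 0.0)))
    root = _Node(children=branches)
    return root.newick() + ";"
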