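"""Gene clustering, family construction, NJ phylogenetics, ancestry labels.

Clusters chain genes whose consecutive midpoints lie within 200 kb.
Families are single-linkage components over pairwise edges with >= 70%
nucleotide identity AND >= 70% coverage (global end-gap-free alignment).
Trees are built with Saitou-Nei neighbor joining; on additive distance
matrices the topology and branch lengths are recovered exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InputError
from .genome_io import GeneModel

CLUSTER_DISTANCE = 200_000
FAMILY_THRESHOLD = 0.70


@dataclass
class GeneCluster:
    cluster_id: str
    chrom: str
    members: tuple[str, ...]  # ordered by position


@dataclass
class FamilyAssignment:
    gene_id: str
    clade_id: str
    family_size: int
    ancestry: str  # ancestral | cross_species | species_specific
    paralog_status: str  # paralog | singleton


def detect_clusters(
    genes: Sequence[GeneModel], max_gap: int = CLUSTER_DISTANCE
) -> list[GeneCluster]:
    """Maximal chains of genes with consecutive midpoints within max_gap.

    Genes must lie on one chromosome; singletons are excluded.
    """
    if not genes:
        return []
    chroms = {g.chrom for g in genes}
    if len(chroms) > 1:
        raise InputError(f"detect_clusters expects one chromosome, got {sorted(chroms)}")
    ordered = sorted(genes, key=lambda g: (g.midpoint, g.gene_id))
    chains: list[list[GeneModel]] = [[ordered[0]]]
    for g in ordered[1:]:
        if g.midpoint - chains[-1][-1].midpoint <= max_gap:
            chains[-1].append(g)
        else:
            chains.append([g])
    chrom = ordered[0].chrom
    out = []
    for chain in chains:
        if len(chain) >= 2:
            out.append(
                GeneCluster(
                    cluster_id=f"{chrom}_cl{len(out)}",
                    chrom=chrom,
                    members=tuple(g.gene_id for g in chain),
                )
            )
    return out


def detect_clusters_genome(
    genes: Iterable[GeneModel], max_gap: int = CLUSTER_DISTANCE
) -> list[GeneCluster]:
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: list[GeneCluster] = []
    for chrom in sorted(by_chrom):
        out.extend(detect_clusters(by_chrom[chrom], max_gap))
    return out


# ---------------------------------------------------------------------------
# pairwise identity / coverage

_ALIGNER = None


def _get_aligner():
    global _ALIGNER
    if _ALIGNER is None:
        from Bio import Align

        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 1.0
        a.mismatch_score = -1.0
        a.open_gap_score = -2.0
        a.extend_gap_score = -0.5
        try:  # free end gaps (attribute names differ across Biopython versions)
            a.end_insertion_score = 0.0
            a.end_deletion_score = 0.0
        except AttributeError:
            a.target_end_gap_score = 0.0
            a.query_end_gap_score = 0.0
        _ALIGNER = a
    return _ALIGNER


def alignment_score(seq_a: str, seq_b: str) -> float:
    return float(_get_aligner().score(seq_a, seq_b))


def pairwise_identity_coverage(seq_a: str, seq_b: str) -> tuple[float, float]:
    """(identity, coverage) from a global end-gap-free DNA alignment.

    identity = matches / aligned columns excluding end gaps; coverage =
    span of the longer sequence inside the alignment / its length.  The
    metrics are symmetric in their arguments.
    """
    if not seq_a or not seq_b:
        raise InputError("empty sequence")
    # canonical argument order makes the traceback (and any tie-break)
    # independent of the call order
    a, b = sorted((seq_a, seq_b), key=lambda s: (len(s), s), reverse=True)
    aln = _get_aligner().align(a, b)[0]
    blocks = aln.aligned  # pairs of (target, query) block coordinate arrays
    if len(blocks[0]) == 0:
        return 0.0, 0.0
    ta, qa = blocks
    matches = 0
    paired = 0
    for (ts, te), (qs, qe) in zip(ta, qa):
        paired += te - ts
        matches += sum(x == y for x, y in zip(a[ts:te], b[qs:qe]))
    span_a = int(ta[-1][1] - ta[0][0])
    span_b = int(qa[-1][1] - qa[0][0])
    columns = span_a + span_b - paired
    identity = matches / columns if columns else 0.0
    coverage = span_a / len(a)  # a is the longer sequence
    return identity, coverage


# ---------------------------------------------------------------------------
# families


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def build_families(
    genes: Sequence[GeneModel],
    pair_metrics: Mapping[tuple[str, str], tuple[float, float]],
    threshold: float = FAMILY_THRESHOLD,
) -> list[FamilyAssignment]:
    """Single-linkage families over identity/coverage edges.

    ``pair_metrics`` maps unordered gene-id pairs to (identity, coverage);
    an edge joins a pair when both metrics reach ``threshold``.  Clade ids
    are canonical (sorted member lists), hence stable under permutation of
    the input.
    """
    ids = [g.gene_id for g in genes]
    species = {g.gene_id: g.species for g in genes}
    uf = _UnionFind(ids)
    for (a, b), (ident, cov) in pair_metrics.items():
        if a in uf.parent and b in uf.parent and ident >= threshold and cov >= threshold:
            uf.union(a, b)
    components: dict[str, list[str]] = {}
    for gid in ids:
        components.setdefault(uf.find(gid), []).append(gid)
    clades = sorted((sorted(members) for members in components.values()), key=lambda m: m[0])
    out: list[FamilyAssignment] = []
    for i, members in enumerate(clades):
        clade_id = f"clade{i:04d}"
        sp = {species[m] for m in members}
        if len(sp) >= 3:
            ancestry = "ancestral"
        elif len(sp) == 2:
            ancestry = "cross_species"
        else:
            ancestry = "species_specific"
        sp_counts: dict[str, int] = {}
        for m in members:
            sp_counts[species[m]] = sp_counts.get(species[m], 0) + 1
        for m in members:
            out.append(
                FamilyAssignment(
                    gene_id=m,
                    clade_id=clade_id,
                    family_size=len(members),
                    ancestry=ancestry,
                    paralog_status=(
                        "paralog" if sp_counts[species[m]] >= 2 else "singleton"
                    ),
                )
            )
    return sorted(out, key=lambda a: a.gene_id)


def classify_ancestry(species_labels: Iterable[str]) -> str:
    """Ancestry label for one clade from its members' species."""
    sp = set(species_labels)
    if len(sp) >= 3:
        return "ancestral"
    if len(sp) == 2:
        return "cross_species"
    return "species_specific"


# ---------------------------------------------------------------------------
# neighbor joining


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf:
            return self.name or ""
        inner = ",".join(f"{c._newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner}){self.name or ''}"

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Patristic distances between all leaf pairs."""
        dists: dict[str, dict[str, float]] = {}

        def collect(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            sub = []
            for child, bl in node.children:
                d = collect(child)
                sub.append({k: v + bl for k, v in d.items()})
            merged: dict[str, float] = {}
            for i, di in enumerate(sub):
                for j in range(i + 1, len(sub)):
                    for li, vi in di.items():
                        for lj, vj in sub[j].items():
                            key = tuple(sorted((li, lj)))
                            dists[key] = vi + vj  # type: ignore[index]
                merged.update(di)
            return merged

        collect(self)
        return {k: v for k, v in dists.items()}  # type: ignore[return-value]


@dataclass
class PhyloTree:
    root: TreeNode
    labels: tuple[str, ...]

    def to_newick(self) -> str:
        return self.root.to_newick()

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        return self.root.leaf_distances()


def nj_tree(distance: np.ndarray, labels: Sequence[str]) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Requires a symmetric non-negative matrix over >= 3 taxa.  Q-matrix ties
    break on the lowest (i, j) index pair in the current node order;
    negative branch lengths are clamped to zero with the deficit moved to
    the sister branch.
    """
    d = np.array(distance, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n != len(labels):
        raise InputError("distance matrix / label mismatch")
    if np.isnan(d).any():
        raise InputError("NaN in distance matrix")
    if not np.allclose(d, d.T, atol=1e-12):
        raise InputError("distance matrix not symmetric")
    if n < 3:
        raise InputError("NJ requires at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    while len(nodes) > 2:
        r = len(nodes)
        row_sums = d.sum(axis=1)
        q = (r - 2) * d - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) among ties
        best = None
        qmin = q.min()
        ties = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        for i, j in ties:
            if i < j:
                best = (int(i), int(j))
                break
        i, j = best  # type: ignore[misc]
        li = 0.5 * d[i, j] + (row_sums[i] - row_sums[j]) / (2.0 * (r - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode(children=[(nodes[i], float(li)), (nodes[j], float(lj))])
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        d2 = np.empty((r - 1, r - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = dnew[keep]
        d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]
    # attach the remaining pair; root at an internal node when available
    (u, v), duv = nodes, float(d[0, 1])
    if v.is_leaf and not u.is_leaf:
        u.children.append((v, duv))
        root = u
    elif u.is_leaf and not v.is_leaf:
        v.children.append((u, duv))
        root = v
    else:
        root = TreeNode(children=[(u, 0.5 * duv), (v, 0.5 * duv)])
    return PhyloTree(root=root, labels=tuple(labels))


# ---------------------------------------------------------------------------
# cluster composition


def clustered_fraction(
    clusters: Iterable[GeneCluster],
    strata: Mapping[str, str],
) -> dict[str, float | None]:
    """Fraction of genes located in clusters, per stratum label.

    ``strata`` maps gene_id -> label (selection call, paralog status,
    ancestry...).  Empty strata yield None, not 0.
    """
    in_cluster = {gid for c in clusters for gid in c.members}
    out: dict[str, float | None] = {}
    for label in sorted(set(strata.values())):
        members = [g for g, l in strata.items() if l == label]
        out[label] = (
            sum(g in in_cluster for g in members) / len(members) if members else None
        )
    return out
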