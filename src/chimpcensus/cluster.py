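"""UPGMA dendrograms, duplicate-cluster calling, and outlier flagging.

The dendrogram is built by plain average-linkage (UPGMA) agglomeration with
deterministic tie-breaking: among equally close cluster pairs the one whose
lexicographically smallest member ID sorts first wins.  Node heights are
cophenetic half-distances, so the pendant branch of a leaf in a cherry
equals half the pair's IBS distance — the quantity the duplicate-calling
edge threshold is applied to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Node:
    """A dendrogram node; leaves carry a name, internal nodes children."""

    height: float
    name: str | None = None
    children: tuple["Node", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]


@dataclass
class Dendrogram:
    """Ultrametric UPGMA tree over a sample set."""

    root: Node
    samples: list[str]

    def pendant_lengths(self) -> dict[str, float]:
        """Leaf -> length of its pendant branch (parent height)."""
        out: dict[str, float] = {}

        def walk(node: Node) -> None:
            for child in node.children:
                if child.is_leaf:
                    out[child.name] = node.height
                else:
                    walk(child)

        if self.root.is_leaf:
            out[self.root.name] = 0.0
        else:
            walk(self.root)
        return out

    def cophenetic(self) -> pd.DataFrame:
        """Ultrametric leaf-to-leaf distances (twice the merge half-height)."""
        n = len(self.samples)
        idx = {s: i for i, s in enumerate(self.samples)}
        mat = np.zeros((n, n))

        def walk(node: Node) -> list[str]:
            if node.is_leaf:
                return [node.name]
            groups = [walk(c) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = 2 * node.height
            return [s for g in groups for s in g]

        walk(self.root)
        return pd.DataFrame(mat, index=self.samples, columns=self.samples)

    def newick(self) -> str:
        def fmt(node: Node, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.name}:{bl:.10g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{bl:.10g}"

        if self.root.is_leaf:
            return f"{self.root.name};"
        inner = ",".join(fmt(c, self.root.height) for c in self.root.children)
        return f"({inner});"


def upgma(dist: pd.DataFrame) -> Dendrogram:
    """Average-linkage agglomeration of a symmetric distance matrix."""
    d = dist.to_numpy(dtype=float)
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any():
        raise ValueError("distances must be nonnegative")
    samples = list(dist.index)
    clusters: dict[int, dict] = {
        i: {"node": Node(0.0, name=s), "size": 1, "key": s}
        for i, s in enumerate(samples)
    }
    dd = {(i, j): d[i, j] for i in range(len(samples))
          for j in range(i + 1, len(samples))}
    next_id = len(samples)
    while len(clusters) > 1:
        best = min(dd, key=lambda ij: (dd[ij],
                                       *sorted((clusters[ij[0]]["key"],
                                                clusters[ij[1]]["key"]))))
        i, j = best
        h = dd[best] / 2.0
        ci, cj = clusters.pop(i), clusters.pop(j)
        first, second = sorted((ci, cj), key=lambda c: c["key"])
        merged = {"node": Node(h, children=(first["node"], second["node"])),
                  "size": ci["size"] + cj["size"],
                  "key": min(ci["key"], cj["key"])}
        new_d = {}
        for k in clusters:
            dik = dd.pop((min(i, k), max(i, k)))
            djk = dd.pop((min(j, k), max(j, k)))
            new_d[k] = (ci["size"] * dik + cj["size"] * djk) / merged["size"]
        del dd[best]
        clusters[next_id] = merged
        for k, v in new_d.items():
            dd[(min(next_id, k), max(next_id, k))] = v
        next_id += 1
    root = next(iter(clusters.values()))["node"]
    return Dendrogram(root=root, samples=samples)


def flag_outliers(dist: pd.DataFrame, threshold: float = 0.1) -> set[str]:
    """Flag samples distant (> threshold) from the cohort's main group.

    Builds the graph connecting pairs at distance <= threshold and keeps the
    largest connected component (ties broken toward the component holding
    the lexicographically smallest sample ID); everything outside it —
    isolated contaminants as well as mutually close contaminant clades — is
    flagged.  A homogeneous cohort forms a single component and nothing is
    flagged.
    """
    samples = list(dist.index)
    if len(samples) < 3:
        raise ValueError("outlier flagging needs at least 3 samples")
    d = dist.to_numpy(dtype=float)
    n = len(samples)
    # union-find over the <= threshold graph
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] <= threshold and not math.isnan(d[i, j]):
                parent[find(i)] = find(j)
    comps: dict[int, list[str]] = {}
    for i, s in enumerate(samples):
        comps.setdefault(find(i), []).append(s)
    # tie-break: among equally large components prefer the one containing
    # the smallest sample ID
    biggest = max(len(c) for c in comps.values())
    candidates = [c for c in comps.values() if len(c) == biggest]
    main = min(candidates, key=lambda c: min(c))
    return set(samples) - set(main)


@dataclass
class DuplicateCluster:
    """A called set of samples believed to come from one donor."""

    cluster_id: int
    members: list[str]
    support: str                      # 'edge_only' | 'edge_plus_metadata'
    representative: str | None = field(default=None)

    def __post_init__(self) -> None:
        if self.support not in ("edge_only", "edge_plus_metadata"):
            raise ValueError(f"unknown support {self.support!r}")


def _metadata_supports(members: list[str], meta: pd.DataFrame | None,
                       age_tol: float) -> bool:
    """True when sex and age agree (non-missing) across all members."""
    if meta is None:
        return False
    sub = meta[meta["sample_id"].isin(members)]
    if len(sub) < len(members):
        return False
    sexes = sub["sex"]
    ages = pd.to_numeric(sub["age"], errors="coerce")
    if sexes.isna().any() or ages.isna().any():
        return False
    if sexes.nunique() != 1:
        return False
    return (ages.max() - ages.min()) <= age_tol


def call_duplicates(tree: Dendrogram, meta: pd.DataFrame | None = None,
                    edge_threshold: float = 0.006,
                    age_tol: float = 1.0) -> list[DuplicateCluster]:
    """Call duplicate/replicate clusters from the UPGMA tree.

    Maximal clades whose merge height stays below ``edge_threshold`` become
    clusters (for a pair this is exactly the terminal-edge rule, since a
    cherry's pendant edges equal its height).  Where two such clusters are
    siblings under a taller node, they are merged anyway if sex matches and
    ages agree within ``age_tol`` for every member — missing metadata never
    counts as agreement.  Singleton leaves are their own cluster.
    """

    roots: list[Node] = []

    def collect(node: Node) -> None:
        if node.height < edge_threshold:       # leaves have height 0
            roots.append(node)
            return
        for c in node.children:
            collect(c)

    collect(tree.root)

    cluster_of = {id(r): r for r in roots}
    merged_pairs: list[tuple[list[str], str]] = []
    consumed: set[int] = set()

    def visit(node: Node) -> None:
        if node.is_leaf:
            return
        kids = node.children
        if (all(id(k) in cluster_of for k in kids)
                and id(node) not in cluster_of
                and not any(id(k) in consumed for k in kids)):
            members = node.leaf_names()
            if _metadata_supports(members, meta, age_tol):
                merged_pairs.append((members, "edge_plus_metadata"))
                consumed.update(id(k) for k in kids)
        for c in kids:
            visit(c)

    visit(tree.root)

    clusters: list[tuple[list[str], str]] = list(merged_pairs)
    clusters.extend((r.leaf_names(), "edge_only")
                    for r in roots if id(r) not in consumed)
    clusters.sort(key=lambda c: min(c[0]))
    return [DuplicateCluster(cluster_id=i + 1, members=sorted(m), support=sup)
            for i, (m, sup) in enumerate(clusters)]


def collapse_replicates(clusters: list[DuplicateCluster],
                        relatedness: pd.DataFrame, seed: int = 0,
                        ) -> list[str]:
    """Pick one representative per cluster.

    Size-2 clusters are resolved by a seeded random draw; larger clusters
    keep the member with the highest mean relatedness to the rest of the
    cluster (ties by sample ID).  Representatives are stored on the clusters
    and returned sorted.
    """
    rng = np.random.default_rng(seed)
    reps = []
    for cl in clusters:
        if len(cl.members) == 1:
            rep = cl.members[0]
        elif len(cl.members) == 2:
            rep = cl.members[int(rng.integers(0, 2))]
        else:
            scores = {}
            for s in cl.members:
                others = [o for o in cl.members if o != s]
                scores[s] = float(np.nanmean(
                    [relatedness.loc[s, o] for o in others]))
            best = max(scores.values())
            rep = min(s for s, v in scores.items() if v >= best - 1e-12)
        cl.representative = rep
        reps.append(rep)
    return sorted(reps)
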