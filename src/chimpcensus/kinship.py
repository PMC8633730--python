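"""Relationship classification and unrelated-set extraction.

Pairs are classed from their IBD Z-triplet with fixed thresholds
(configurable): identical when Z2 >= 0.65 and Z0 < 0.10; parent/offspring
when Z1 >= 0.7; full siblings when Z2 >= 0.30, Z1 >= 0.30 and Z0 <= 0.40;
second degree when 0.4 <= Z1 < 0.7; otherwise unrelated.  Precedence runs
identical > parent/offspring > sibling > second degree: the sibling rule is
the stricter multi-condition one, so it wins in the Z1 in [0.4, 0.7) region
where both could fire.  The relatedness coefficient is carried along for
audit (>= 0.5 corroborates identity) but the Z rules are decisive.

Identical pairs are collapsed to single individuals before building the
relative graph, and a maximal mutually unrelated set is obtained by
iteratively removing a maximum-degree individual (seeded tie-breaking, so
the surviving count can vary across seeds exactly as removing "one relative
or the other" does).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .pairwise import IBDEstimate

RELATED_CLASSES = ("parent_offspring", "full_sibling", "second_degree")


@dataclass(frozen=True)
class KinshipThresholds:
    identical_z2: float = 0.65
    identical_z0_max: float = 0.10
    parent_offspring_z1: float = 0.7
    sibling_z2: float = 0.30
    sibling_z1: float = 0.30
    sibling_z0_max: float = 0.40
    second_degree_z1_min: float = 0.4
    second_degree_z1_max: float = 0.7


DEFAULT_THRESHOLDS = KinshipThresholds()


@dataclass(frozen=True)
class RelationshipCall:
    sample_a: str
    sample_b: str
    relationship: str
    z: tuple[float, float, float]
    relatedness: float
    rule: str


def classify_pair(sample_a: str, sample_b: str, ibd: IBDEstimate,
                  relatedness: float = float("nan"),
                  thresholds: KinshipThresholds = DEFAULT_THRESHOLDS,
                  ) -> RelationshipCall:
    """Classify one pair from its Z-triplet (relatedness is advisory)."""
    t = thresholds
    z0, z1, z2 = ibd.as_tuple()
    if z2 >= t.identical_z2 and z0 < t.identical_z0_max:
        cls, rule = "identical", f"Z2>={t.identical_z2} & Z0<{t.identical_z0_max}"
    elif z1 >= t.parent_offspring_z1:
        cls, rule = "parent_offspring", f"Z1>={t.parent_offspring_z1}"
    elif z2 >= t.sibling_z2 and z1 >= t.sibling_z1 and z0 <= t.sibling_z0_max:
        cls, rule = "full_sibling", (f"Z2>={t.sibling_z2} & Z1>={t.sibling_z1}"
                                     f" & Z0<={t.sibling_z0_max}")
    elif t.second_degree_z1_min <= z1 < t.second_degree_z1_max:
        cls, rule = "second_degree", (f"{t.second_degree_z1_min}<=Z1"
                                      f"<{t.second_degree_z1_max}")
    else:
        cls, rule = "unrelated", "default"
    return RelationshipCall(sample_a, sample_b, cls, (z0, z1, z2),
                            relatedness, rule)


def calls_from_table(ibd_table: pd.DataFrame,
                     relatedness: pd.DataFrame | None = None,
                     thresholds: KinshipThresholds = DEFAULT_THRESHOLDS,
                     ) -> list[RelationshipCall]:
    """Classify every row of a long-format IBD table."""
    calls = []
    for row in ibd_table.itertuples(index=False):
        rel = float("nan")
        if relatedness is not None:
            rel = float(relatedness.loc[row.sample_a, row.sample_b])
        calls.append(classify_pair(row.sample_a, row.sample_b,
                                   IBDEstimate(row.z0, row.z1, row.z2),
                                   rel, thresholds))
    return calls


def build_relative_graph(calls: list[RelationshipCall]) -> nx.Graph:
    """Undirected graph of first/second-degree edges over individuals.

    Samples called identical are first merged into one node (union of
    transitive chains); each node carries a ``members`` attribute listing
    the collapsed sample IDs, and its name is the smallest member.
    """
    samples = sorted({s for c in calls for s in (c.sample_a, c.sample_b)})
    parent = {s: s for s in samples}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for c in calls:
        if c.relationship == "identical":
            ra, rb = find(c.sample_a), find(c.sample_b)
            if ra != rb:
                keep, drop = sorted((ra, rb))
                parent[drop] = keep
    members: dict[str, list[str]] = {}
    for s in samples:
        members.setdefault(find(s), []).append(s)

    g = nx.Graph()
    for rep, mem in members.items():
        g.add_node(rep, members=sorted(mem))
    for c in calls:
        if c.relationship in RELATED_CLASSES:
            a, b = find(c.sample_a), find(c.sample_b)
            if a != b:
                g.add_edge(a, b, relationship=c.relationship)
    return g


def extract_unrelated(graph: nx.Graph, seed: int = 0,
                      ) -> tuple[set[str], list[str]]:
    """Greedy maximum-degree removal until no related pair remains.

    Returns the surviving individual set (always an independent set of the
    input graph) and the removal log.  Ties among maximum-degree nodes are
    broken by a seeded random draw, so different seeds can remove either
    member of a symmetric pair.
    """
    g = graph.copy()
    rng = np.random.default_rng(seed)
    removed: list[str] = []
    while g.number_of_edges() > 0:
        degrees = dict(g.degree())
        dmax = max(degrees.values())
        top = sorted(n for n, d in degrees.items() if d == dmax)
        victim = top[int(rng.integers(0, len(top)))]
        g.remove_node(victim)
        removed.append(victim)
    return set(g.nodes), removed


def unrelated_set_range(graph: nx.Graph, n_replicates: int = 10,
                        seed: int = 0) -> tuple[int, int, list[int]]:
    """Min–max surviving-set size across seeded removal replicates."""
    ss = np.random.SeedSequence(seed)
    sizes = [len(extract_unrelated(graph, int(child.generate_state(1)[0] % 2**31))[0])
             for child in ss.spawn(n_replicates)]
    return min(sizes), max(sizes), sizes


def summarize_relationships(calls: list[RelationshipCall],
                            groups: dict[str, str] | None = None,
                            ) -> pd.DataFrame:
    """Pair counts per relationship class, overall and per sampling site.

    A pair counts toward a group only when both members belong to it;
    groups with no members are omitted.
    """
    order = ["identical", "parent_offspring", "second_degree", "full_sibling"]
    cols: dict[str, dict[str, int]] = {"all": {k: 0 for k in order}}
    if groups:
        for gname in sorted(set(groups.values())):
            cols[gname] = {k: 0 for k in order}
    for c in calls:
        if c.relationship not in order:
            continue
        cols["all"][c.relationship] += 1
        if groups:
            ga, gb = groups.get(c.sample_a), groups.get(c.sample_b)
            if ga is not None and ga == gb:
                cols[ga][c.relationship] += 1
    return pd.DataFrame(cols, index=order)
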