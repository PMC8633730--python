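"""UPGMA construction, outlier flagging, duplicate calling, collapsing."""

import numpy as np
import pandas as pd
import pytest

from chimpcensus import cluster as clu
from chimpcensus import pairwise, popsim
from chimpcensus.genio import matrix_from_arrays
from chimpcensus.popsim import SimConfig


def dist_frame(names, entries):
    d = pd.DataFrame(0.0, index=names, columns=names)
    for (a, b), v in entries.items():
        d.loc[a, b] = d.loc[b, a] = v
    return d


class TestUpgma:
    def test_hand_agglomerated_triplet(self):
        d = dist_frame(list("ABC"), {("A", "B"): 0.2, ("A", "C"): 0.6,
                                     ("B", "C"): 0.6})
        tree = clu.upgma(d)
        assert tree.root.height == pytest.approx(0.3)
        pend = tree.pendant_lengths()
        assert pend["A"] == pend["B"] == pytest.approx(0.1)
        assert pend["C"] == pytest.approx(0.3)
        assert tree.newick().startswith("((A:0.1,B:0.1)")

    def test_equal_distances_tie_break_deterministic(self):
        names = list("DBCA")
        d = dist_frame(names, {(a, b): 0.4 for i, a in enumerate(names)
                               for b in names[i + 1:]})
        t1 = clu.upgma(d)
        t2 = clu.upgma(d)
        assert t1.newick() == t2.newick()
        # first merge joins the lexicographically smallest pair (A, B)
        assert "(A:0.2,B:0.2)" in t1.newick()

    def test_identical_samples_have_zero_pendant_edges(self):
        d = dist_frame(list("XYZ"), {("X", "Y"): 0.0, ("X", "Z"): 0.5,
                                     ("Y", "Z"): 0.5})
        pend = clu.upgma(d).pendant_lengths()
        assert pend["X"] == pend["Y"] == 0.0

    def test_asymmetric_matrix_rejected(self):
        d = dist_frame(list("AB"), {("A", "B"): 0.1})
        d.iloc[0, 1] = 0.3
        with pytest.raises(ValueError):
            clu.upgma(d)

    @pytest.mark.parametrize("seed", range(4))
    def test_cophenetic_matches_scipy_average_linkage(self, seed):
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        m = rng.uniform(0.05, 1.0, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        names = [f"s{i}" for i in range(n)]
        d = pd.DataFrame(m, index=names, columns=names)
        mine = clu.upgma(d).cophenetic().to_numpy()
        ref = squareform(cophenet(linkage(squareform(m), method="average")))
        np.testing.assert_allclose(mine, ref, atol=1e-9)

    def test_newick_parses_and_is_ultrametric(self):
        import dendropy

        rng = np.random.default_rng(3)
        m = rng.uniform(0.1, 1.0, size=(6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        names = [f"s{i}" for i in range(6)]
        tree = clu.upgma(pd.DataFrame(m, index=names, columns=names))
        dt = dendropy.Tree.get(data=tree.newick(), schema="newick")
        depths = []
        for leaf in dt.leaf_node_iter():
            depth, node = 0.0, leaf
            while node.parent_node is not None:
                depth += node.edge.length or 0.0
                node = node.parent_node
            depths.append(depth)
        assert max(depths) - min(depths) < 1e-9


class TestFlagOutliers:
    def test_single_simulated_contaminant_flagged(self):
        cfg = SimConfig(n_sites=3_000, seed=13, drift={"pop": 0.2})
        panel = popsim.draw_reference_freqs(cfg, {"pop": 20})
        vecs = {f"s{i:02d}": panel.genotypes[i] for i in range(20)}
        vecs["weird"] = popsim.make_contaminant(cfg, 3_000, seed=4)
        dist = pairwise.ibs_distance_matrix(matrix_from_arrays(vecs))
        assert clu.flag_outliers(dist, threshold=0.42) == {"weird"}

    def test_homogeneous_cohort_unflagged(self):
        d = dist_frame(list("ABCD"), {(a, b): 0.05 for a in "ABCD"
                                      for b in "ABCD" if a < b})
        assert clu.flag_outliers(d, threshold=0.1) == set()

    def test_mutually_close_contaminant_pair_flagged_jointly(self):
        names = ["a", "b", "c", "x", "y"]
        entries = {}
        for i, p in enumerate(names):
            for q in names[i + 1:]:
                both_in = p in "abc" and q in "abc"
                both_out = p in "xy" and q in "xy"
                entries[(p, q)] = 0.05 if (both_in or both_out) else 0.5
        d = dist_frame(names, entries)
        assert clu.flag_outliers(d, threshold=0.1) == {"x", "y"}

    def test_needs_three_samples(self):
        d = dist_frame(list("AB"), {("A", "B"): 0.2})
        with pytest.raises(ValueError):
            clu.flag_outliers(d)

    def test_removal_does_not_perturb_remaining_clustering(self):
        cfg = SimConfig(n_sites=2_000, seed=17, drift={"pop": 0.2})
        panel = popsim.draw_reference_freqs(cfg, {"pop": 10})
        vecs = {f"s{i:02d}": panel.genotypes[i] for i in range(10)}
        vecs["weird"] = popsim.make_contaminant(cfg, 2_000, seed=9)
        dist = pairwise.ibs_distance_matrix(matrix_from_arrays(vecs))
        flagged = clu.flag_outliers(dist, threshold=0.42)
        keep = [s for s in dist.index if s not in flagged]
        before = clu.upgma(dist.loc[keep, keep]).newick()
        after = clu.upgma(
            pairwise.ibs_distance_matrix(
                matrix_from_arrays({k: vecs[k] for k in keep}))).newick()
        assert before == after


class TestCallDuplicates:
    def meta(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "study_id",
                                           "donor_label", "sex", "age",
                                           "tissue"])

    def test_replicate_pair_forms_cluster(self):
        d = dist_frame(["r1", "r2", "u"], {("r1", "r2"): 0.004,
                                           ("r1", "u"): 0.3, ("r2", "u"): 0.3})
        clusters = clu.call_duplicates(clu.upgma(d))
        by_size = sorted((sorted(c.members) for c in clusters), key=len)
        assert by_size == [["u"], ["r1", "r2"]]
        dup = next(c for c in clusters if len(c.members) == 2)
        assert dup.support == "edge_only"

    def test_unrelated_pair_stays_singletons(self):
        d = dist_frame(["a", "b"], {("a", "b"): 0.3})
        clusters = clu.call_duplicates(clu.upgma(d))
        assert sorted(len(c.members) for c in clusters) == [1, 1]

    def test_two_replicate_groups_not_merged(self):
        # all four leaves have short pendants, but the groups are distant
        d = dist_frame(["a1", "a2", "b1", "b2"],
                       {("a1", "a2"): 0.004, ("b1", "b2"): 0.004,
                        ("a1", "b1"): 0.3, ("a1", "b2"): 0.3,
                        ("a2", "b1"): 0.3, ("a2", "b2"): 0.3})
        clusters = clu.call_duplicates(clu.upgma(d))
        members = sorted(sorted(c.members) for c in clusters)
        assert members == [["a1", "a2"], ["b1", "b2"]]

    def test_borderline_pair_merged_only_with_metadata_support(self):
        d = dist_frame(["p", "q", "u"], {("p", "q"): 0.016,
                                         ("p", "u"): 0.3, ("q", "u"): 0.3})
        tree = clu.upgma(d)
        good = self.meta([("p", "S1", "d", "F", 12, "brain"),
                          ("q", "S2", "d", "F", 12.5, "heart"),
                          ("u", "S1", "e", "M", 30, "liver")])
        clusters = clu.call_duplicates(tree, good, edge_threshold=0.006)
        dup = next(c for c in clusters if len(c.members) == 2)
        assert dup.members == ["p", "q"]
        assert dup.support == "edge_plus_metadata"
        # discordant sex: no merge
        bad = good.copy()
        bad.loc[bad["sample_id"] == "q", "sex"] = "M"
        assert all(len(c.members) == 1
                   for c in clu.call_duplicates(tree, bad, 0.006))

    def test_missing_metadata_never_counts_as_agreement(self):
        d = dist_frame(["p", "q", "u"], {("p", "q"): 0.016,
                                         ("p", "u"): 0.3, ("q", "u"): 0.3})
        meta = self.meta([("p", "S1", "d", "F", np.nan, "brain"),
                          ("q", "S2", "d", "F", np.nan, "heart"),
                          ("u", "S1", "e", "M", 30, "liver")])
        clusters = clu.call_duplicates(clu.upgma(d), meta, 0.006)
        assert all(len(c.members) == 1 for c in clusters)


class TestCollapseReplicates:
    def rel(self, names, entries):
        return dist_frame(names, entries)

    def test_mean_relatedness_picks_representative(self):
        rel = self.rel(["a", "b", "c"], {("a", "b"): 0.9, ("a", "c"): 0.9,
                                         ("b", "c"): 0.8})
        cl = clu.DuplicateCluster(1, ["a", "b", "c"], "edge_only")
        reps = clu.collapse_replicates([cl], rel, seed=0)
        assert reps == ["a"]
        assert cl.representative == "a"

    def test_singleton_is_its_own_representative(self):
        cl = clu.DuplicateCluster(1, ["solo"], "edge_only")
        assert clu.collapse_replicates([cl], pd.DataFrame(), seed=0) == ["solo"]

    def test_pair_choice_is_seeded(self):
        rel = self.rel(["a", "b"], {("a", "b"): 0.9})
        picks = set()
        for seed in range(10):
            cl = clu.DuplicateCluster(1, ["a", "b"], "edge_only")
            picks.add(clu.collapse_replicates([cl], rel, seed=seed)[0])
        cl = clu.DuplicateCluster(1, ["a", "b"], "edge_only")
        again = clu.collapse_replicates([cl], rel, seed=3)
        cl2 = clu.DuplicateCluster(1, ["a", "b"], "edge_only")
        assert again == clu.collapse_replicates([cl2], rel, seed=3)
        assert picks == {"a", "b"}   # both outcomes reachable across seeds
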