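"""Pairwise IBS/relatedness/IBD statistics against independent oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chimpcensus import pairwise, popsim
from chimpcensus.genio import matrix_from_arrays
from chimpcensus.pairwise import estimate_ibd, relatedness
from chimpcensus.popsim import MISSING, SimConfig


def naive_pair_counts(a, b):
    """Per-site double loop: the oracle for every pairwise count."""
    out = dict(n=0, ibs0=0, ibs1=0, ibs2=0, shared_hets=0, hets_a=0, hets_b=0)
    for x, y in zip(a, b):
        if x == MISSING or y == MISSING:
            continue
        out["n"] += 1
        shared = 2 - abs(int(x) - int(y))
        out[f"ibs{shared}"] += 1
        if x == 1 and y == 1:
            out["shared_hets"] += 1
        if x == 1:
            out["hets_a"] += 1
        if y == 1:
            out["hets_b"] += 1
    return out


class TestCountsOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_all_counts_match_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        n, L = 10, 50
        d = rng.integers(0, 3, size=(n, L)).astype(np.int8)
        d[rng.random(d.shape) < 0.15] = MISSING
        g = matrix_from_arrays({f"s{i}": d[i] for i in range(n)})
        c = pairwise.pair_counts(g)
        for i, j in itertools.combinations(range(n), 2):
            ref = naive_pair_counts(d[i], d[j])
            assert c["n"][i, j] == ref["n"]
            assert c["ibs0"][i, j] == ref["ibs0"]
            assert c["ibs1"][i, j] == ref["ibs1"]
            assert c["ibs2"][i, j] == ref["ibs2"]
            assert c["shared_hets"][i, j] == ref["shared_hets"]
            assert c["hets_a"][i, j] == ref["hets_a"]
            assert c["hets_a"].T[i, j] == ref["hets_b"]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_and_partition(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.integers(0, 3, size=(5, 30)).astype(np.int8)
        d[rng.random(d.shape) < 0.2] = MISSING
        g = matrix_from_arrays({f"s{i}": d[i] for i in range(5)})
        c = pairwise.pair_counts(g)
        for key in ("n", "ibs0", "ibs1", "ibs2", "shared_hets"):
            np.testing.assert_array_equal(c[key], c[key].T)
        np.testing.assert_array_equal(
            c["ibs0"] + c["ibs1"] + c["ibs2"], c["n"])


class TestIbsDistance:
    @pytest.mark.parametrize("a,b,expected", [
        ([0, 1, 2, 1], [0, 1, 2, 1], 0.0),      # identical
        ([0, 0], [2, 2], 1.0),                  # maximal dissimilarity
        ([0, 1], [2, 1], 0.5),                  # shares 2 of 4 alleles
    ])
    def test_known_values(self, a, b, expected):
        g = matrix_from_arrays({"a": np.array(a), "b": np.array(b)})
        d = pairwise.ibs_distance_matrix(g)
        assert d.loc["a", "b"] == pytest.approx(expected)
        assert d.loc["a", "a"] == 0.0

    def test_pair_without_shared_sites_is_nan(self):
        g = matrix_from_arrays({"a": np.array([1, MISSING]),
                                "b": np.array([MISSING, 1]),
                                "c": np.array([1, 1])})
        d = pairwise.ibs_distance_matrix(g)
        assert np.isnan(d.loc["a", "b"])
        assert d.loc["a", "c"] == 0.0


class TestRelatedness:
    def test_self_pair_is_one(self, rng):
        a = rng.integers(0, 3, 200).astype(np.int8)
        assert relatedness(a, a) == pytest.approx(1.0)

    def test_enumerated_example(self):
        a = np.array([1, 1, 0, 2, 1], dtype=np.int8)
        b = np.array([1, 2, 0, 2, 0], dtype=np.int8)
        # shared_hets=1, ibs0=0, hets=(3,1) -> 1.0
        assert relatedness(a, b) == pytest.approx(1.0)

    def test_opposite_homozygotes_penalized(self):
        a = np.array([0, 1], dtype=np.int8)
        b = np.array([2, 1], dtype=np.int8)
        assert relatedness(a, b) == pytest.approx(-1.0)

    def test_no_heterozygotes_is_undefined(self):
        a = np.array([0, 2], dtype=np.int8)
        assert np.isnan(relatedness(a, a))

    def test_matrix_agrees_with_scalar(self, rng):
        d = rng.integers(0, 3, size=(6, 80)).astype(np.int8)
        d[rng.random(d.shape) < 0.1] = MISSING
        g = matrix_from_arrays({f"s{i}": d[i] for i in range(6)})
        mat = pairwise.relatedness_matrix(g)
        for i, j in itertools.combinations(range(6), 2):
            expected = relatedness(d[i], d[j])
            got = mat.iloc[i, j]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)


@pytest.fixture(scope="module")
def population():
    cfg = SimConfig(n_sites=20_000, seed=21, drift={"pop": 0.1})
    panel = popsim.draw_reference_freqs(cfg, {"pop": 40})
    g = panel.genotypes
    freq = g.mean(0) / 2
    return g, freq, 2 * g.shape[0]


class TestIbd:

    def test_unrelated_pair_z0_near_one(self, population):
        g, freq, n = population
        z = estimate_ibd(g[0], g[1], freq, n)
        assert z.z0 == pytest.approx(1.0, abs=0.05)

    def test_parent_offspring_z1_near_one(self, population):
        g, freq, n = population
        child = popsim.drop_offspring(g[2], g[3], seed=5)
        z = estimate_ibd(g[2], child, freq, n)
        assert z.z1 == pytest.approx(1.0, abs=0.05)

    def test_duplicate_z2_near_one(self, population):
        g, freq, n = population
        z = estimate_ibd(g[4], g[4].copy(), freq, n)
        assert z.z2 == pytest.approx(1.0, abs=0.05)
        assert z.pi_hat == pytest.approx(1.0, abs=0.05)

    def test_triplet_is_simplex(self, population):
        g, freq, n = population
        for i in range(0, 10, 2):
            z = estimate_ibd(g[i], g[i + 1], freq, n)
            assert 0 <= min(z.as_tuple()) and max(z.as_tuple()) <= 1
            assert sum(z.as_tuple()) == pytest.approx(1.0)

    def test_few_sites_warns(self, population, caplog):
        g, freq, n = population
        import logging
        with caplog.at_level(logging.WARNING):
            estimate_ibd(g[0][:100], g[1][:100], freq[:100], n)
        assert any("usable sites" in r.message for r in caplog.records)


class TestExpectedClassRecovery:
    """Mean Z-triplets over simulated pairs per relationship class."""

    def test_class_means_match_theory(self):
        cfg = SimConfig(n_sites=8_000, seed=31, drift={"pop": 0.1})
        panel = popsim.draw_reference_freqs(cfg, {"pop": 160})
        g = panel.genotypes
        rng = np.random.default_rng(8)
        children, po, sibs, second, unrel = [], [], [], [], []
        for k in range(50):
            f1, f2, f3 = g[3 * k], g[3 * k + 1], g[3 * k + 2]
            c1 = popsim.drop_offspring(f1, f2, int(rng.integers(2**31)))
            c2 = popsim.drop_offspring(f1, f2, int(rng.integers(2**31)))
            link = popsim.drop_offspring(f1, f2, int(rng.integers(2**31)))
            gc = popsim.drop_offspring(link, f3, int(rng.integers(2**31)))
            children.extend([c1, c2, gc])
            po.append((f1, c1))
            sibs.append((c1, c2))
            second.append((f2, gc))
            unrel.append((f3, g[(3 * k + 5) % 150]))
        cohort = np.vstack([g, np.vstack(children)])
        freq = cohort.mean(0) / 2
        n = 2 * cohort.shape[0]

        def mean_z(pairs):
            zs = np.array([estimate_ibd(a, b, freq, n).as_tuple()
                           for a, b in pairs])
            return zs.mean(0)

        np.testing.assert_allclose(mean_z(unrel), (1, 0, 0), atol=0.05)
        np.testing.assert_allclose(mean_z(po), (0, 1, 0), atol=0.05)
        np.testing.assert_allclose(mean_z(sibs), (0.25, 0.5, 0.25), atol=0.05)
        np.testing.assert_allclose(mean_z(second), (0.5, 0.5, 0), atol=0.05)


class TestMafPrefilter:
    def test_maf_filter_keeps_self_relatedness_at_one(self, rng):
        from chimpcensus.genio import filter_maf

        d = rng.binomial(2, rng.uniform(0.05, 0.5, 2_000), size=(4, 2_000))
        g = matrix_from_arrays({f"s{i}": d[i].astype(np.int8)
                                for i in range(4)})
        filtered = filter_maf(g, 0.25)
        assert filtered.n_sites < g.n_sites
        rel = pairwise.relatedness_matrix(filtered)
        for s in g.samples:
            assert rel.loc[s, s] == pytest.approx(1.0)
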