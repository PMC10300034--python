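import numpy as np
import pandas as pd
import pytest

import mitogeo as mg
from mitogeo.diversity import DiversityError, _components


def profile(sid, muts, missing=()):
    return mg.make_profile(sid, muts, missing=missing)


def brute_force_distance(p1, p2, mask=mg.EMPTY_MASK):
    """Independent double-loop over every site either profile touches."""
    skip = p1.missing | p2.missing
    sites = {m.site for m in p1.mutations} | {m.site for m in p2.mutations}
    d = 0
    for site in sites:
        a = next((m.canonical() for m in p1.mutations
                  if m.site == site and not mask.is_masked(m)), None)
        b = next((m.canonical() for m in p2.mutations
                  if m.site == site and not mask.is_masked(m)), None)
        if site[0] not in skip and a != b:
            d += 1
    return d


class TestPairwiseDistances:
    def test_identical_profiles_zero(self):
        p = profile("a", ["A263G"])
        q = profile("b", ["A263G"])
        assert mg.pairwise_difference(p, q) == 0

    def test_one_extra_mutation(self):
        assert mg.pairwise_difference(profile("a", ["A263G"]),
                                      profile("b", ["A263G", "C16223T"])) == 1

    def test_missing_sites_excluded_pairwise(self):
        p = profile("a", ["A263G"], missing={16223})
        q = profile("b", ["C16223T"])
        assert mg.pairwise_difference(p, q) == 1  # only 263 compared

    def test_matrix_matches_brute_force(self):
        rng = np.random.default_rng(4)
        sites = list(range(100, 400, 10))
        profiles = []
        for i in range(10):
            muts = [f"A{p}G" for p in sites if rng.random() < 0.3]
            profiles.append(profile(f"s{i}", muts))
        dist = mg.pairwise_distances(profiles)
        for i in range(10):
            for j in range(10):
                expected = brute_force_distance(profiles[i], profiles[j]) if i != j else 0
                assert dist.values[i, j] == expected

    def test_mask_reduces_distance(self):
        mask = mg.RecurrentSiteMask(masked_positions=frozenset({16519}))
        p, q = profile("a", ["T16519C"]), profile("b", [])
        assert mg.pairwise_difference(p, q, mask) == 0


class TestDiversityIndices:
    def test_haplotype_diversity_closed_forms(self):
        mono = [profile(f"s{i}", ["A263G"]) for i in range(6)]
        assert mg.haplotype_diversity(mono)[0] == 0.0
        for n in (2, 5, 17):
            distinct = [profile(f"s{i}", [f"A{100 + i}G"]) for i in range(n)]
            assert mg.haplotype_diversity(distinct)[0] == pytest.approx(1.0)

    def test_haplotype_diversity_two_pairs(self):
        pops = [profile("a", ["A100G"]), profile("b", ["A100G"]),
                profile("c", ["A200G"]), profile("d", ["A200G"])]
        h, se = mg.haplotype_diversity(pops)
        assert h == pytest.approx(2 / 3)
        assert se > 0

    def test_nucleotide_diversity_single_pair(self):
        p = profile("a", ["A100G", "A200G", "A300G"])
        q = profile("b", [])
        assert mg.nucleotide_diversity([p, q], 16569) == pytest.approx(3 / 16569)

    def test_nucleotide_diversity_matches_brute_force(self):
        rng = np.random.default_rng(7)
        profiles = [profile(f"s{i}", [f"A{p}G" for p in range(100, 300, 10)
                                      if rng.random() < 0.4]) for i in range(8)]
        expected = np.mean([
            brute_force_distance(profiles[i], profiles[j]) / 16569
            for i in range(8) for j in range(i + 1, 8)])
        assert mg.nucleotide_diversity(profiles, 16569) == pytest.approx(expected)

    def test_small_samples_rejected(self):
        with pytest.raises(DiversityError):
            mg.haplotype_diversity([profile("a", [])])
        with pytest.raises(DiversityError):
            mg.nucleotide_diversity([profile("a", [])], 16569)


def brute_force_amova(values, groups):
    """Independent AMOVA oracle from the definitional sums of squares."""
    n = len(values)
    ids = list(range(n))
    ssd_total = sum(values[i][j] ** 2 for i in ids for j in ids) / (2.0 * n)
    ssd_within = 0.0
    for g in groups:
        ssd_within += sum(values[i][j] ** 2 for i in g for j in g) / (2.0 * len(g))
    ssd_among = ssd_total - ssd_within
    k = len(groups)
    ms_among = ssd_among / (k - 1)
    ms_within = ssd_within / (n - k)
    n_prime = (n - sum(len(g) ** 2 for g in groups) / n) / (k - 1)
    sigma_w = ms_within
    sigma_a = (ms_among - ms_within) / n_prime
    return sigma_a, sigma_w


class TestAmova:
    def toy_instance(self):
        # fixed 6-sample, 2-group distance matrix
        vals = np.array([
            [0, 1, 2, 5, 6, 5],
            [1, 0, 1, 6, 5, 6],
            [2, 1, 0, 5, 6, 5],
            [5, 6, 5, 0, 1, 2],
            [6, 5, 6, 1, 0, 1],
            [5, 6, 5, 2, 1, 0],
        ], dtype=float)
        ids = [f"s{i}" for i in range(6)]
        grouping = {f"s{i}": ("g1" if i < 3 else "g2") for i in range(6)}
        return mg.DistanceMatrix(ids, vals), grouping, vals

    def test_components_match_brute_force(self):
        dist, grouping, vals = self.toy_instance()
        res = mg.amova(dist, grouping, n_permutations=99, seed=1)
        exp_a, exp_w = brute_force_amova(vals, [[0, 1, 2], [3, 4, 5]])
        assert res.sigma2_among == pytest.approx(exp_a, abs=1e-9)
        assert res.sigma2_within == pytest.approx(exp_w, abs=1e-9)
        assert res.phi_st == pytest.approx(exp_a / (exp_a + exp_w), abs=1e-9)
        assert res.pct_among + res.pct_within == pytest.approx(100.0, abs=1e-9)

    def test_identical_groups_phi_zero(self):
        # two groups that are copies of the same haplotype set
        vals = np.array([
            [0, 3, 0, 3],
            [3, 0, 3, 0],
            [0, 3, 0, 3],
            [3, 0, 3, 0],
        ], dtype=float)
        dist = mg.DistanceMatrix(["a1", "a2", "b1", "b2"], vals)
        res = mg.amova(dist, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
                       n_permutations=99, seed=0)
        assert res.phi_st <= 0.0 + 1e-12
        assert res.pct_among <= 0.0 + 1e-12

    def test_random_input_matches_brute_force(self):
        rng = np.random.default_rng(11)
        n, k = 12, 3
        x = rng.integers(0, 10, size=(n, n)).astype(float)
        vals = np.triu(x, 1) + np.triu(x, 1).T
        ids = [f"s{i}" for i in range(n)]
        grouping = {f"s{i}": f"g{i % k}" for i in range(n)}
        groups = [[i for i in range(n) if i % k == j] for j in range(k)]
        exp_a, exp_w = brute_force_amova(vals, groups)
        sigma_a, sigma_w = _components(vals**2, [np.array(g) for g in groups])
        assert sigma_a == pytest.approx(exp_a, abs=1e-9)
        assert sigma_w == pytest.approx(exp_w, abs=1e-9)
        # within-component equals SSD_within / (N - k) by construction
        d2 = vals**2
        ssd_within = sum(d2[np.ix_(g, g)].sum() / (2 * len(g)) for g in groups)
        assert sigma_w == pytest.approx(ssd_within / (n - k))

    def test_permutations_reproducible(self):
        dist, grouping, _ = self.toy_instance()
        a = mg.amova(dist, grouping, n_permutations=199, seed=42)
        b = mg.amova(dist, grouping, n_permutations=199, seed=42)
        assert a.p_value == b.p_value

    def test_add_one_correction(self):
        dist, grouping, _ = self.toy_instance()
        res = mg.amova(dist, grouping, n_permutations=99, seed=1)
        assert res.p_value >= 1 / 100

    def test_singleton_group_named(self):
        vals = np.zeros((3, 3))
        dist = mg.DistanceMatrix(["a", "b", "c"], vals)
        with pytest.raises(DiversityError, match="lonely"):
            mg.amova(dist, {"a": "g1", "b": "g1", "c": "lonely"}, 9, 0)


class TestPairwisePhist:
    def test_matches_amova_on_pair(self):
        rng = np.random.default_rng(3)
        n = 9
        x = rng.integers(0, 8, size=(n, n)).astype(float)
        vals = np.triu(x, 1) + np.triu(x, 1).T
        ids = [f"s{i}" for i in range(n)]
        grouping = {ids[i]: ("A", "B", "C")[i % 3] for i in range(n)}
        dist = mg.DistanceMatrix(ids, vals)
        phi, pval = mg.pairwise_phist(dist, grouping, n_permutations=99, seed=5)
        keep = [i for i in ids if grouping[i] in ("A", "B")]
        res = mg.amova(dist.submatrix(keep), grouping, n_permutations=99, seed=5)
        assert phi.loc["A", "B"] == pytest.approx(res.phi_st)
        assert pval.loc["A", "B"] == res.p_value

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(9)
        n = 8
        x = rng.integers(0, 8, size=(n, n)).astype(float)
        vals = np.triu(x, 1) + np.triu(x, 1).T
        ids = [f"s{i}" for i in range(n)]
        grouping = {ids[i]: ("A", "B")[i % 2] for i in range(n)}
        phi, _ = mg.pairwise_phist(mg.DistanceMatrix(ids, vals), grouping, 9, 0)
        assert phi.loc["A", "B"] == phi.loc["B", "A"]
        assert phi.loc["A", "A"] == 0.0


class TestFrequencyPca:
    def freq_table(self):
        return pd.DataFrame(
            [[0.6, 0.3, 0.1], [0.5, 0.2, 0.3], [0.1, 0.7, 0.2], [0.3, 0.3, 0.4]],
            index=["P1", "P2", "P3", "P4"], columns=["H/HV", "M1", "L"])

    def test_identical_populations_at_origin(self):
        freq = pd.DataFrame([[0.5, 0.5], [0.5, 0.5]], index=["A", "B"],
                            columns=["x", "y"])
        res = mg.frequency_pca(freq)
        assert res.coordinates.shape[1] == 0 and res.explained_variance == []

    def test_explained_variance_fractions(self):
        res = mg.frequency_pca(self.freq_table())
        ev = res.explained_variance
        assert sum(ev) == pytest.approx(1.0)
        assert all(ev[i] >= ev[i + 1] for i in range(len(ev) - 1))

    def test_full_rank_isometry(self):
        freq = self.freq_table()
        res = mg.frequency_pca(freq)
        centered = freq.to_numpy() - freq.to_numpy().mean(axis=0)
        coords = res.coordinates.to_numpy()
        for i in range(4):
            for j in range(4):
                assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(
                    np.linalg.norm(centered[i] - centered[j]), abs=1e-9)

    def test_euclidean_distance_closed_form(self):
        freq = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["A", "B"],
                            columns=["x", "y"])
        d = mg.frequency_distance(freq)
        assert d.values[0, 1] == pytest.approx(np.sqrt(2))

    def test_euclidean_matches_brute_force(self):
        freq = self.freq_table()
        d = mg.frequency_distance(freq)
        x = freq.to_numpy()
        for i in range(4):
            for j in range(4):
                assert d.values[i, j] == pytest.approx(
                    np.sqrt(((x[i] - x[j]) ** 2).sum()))
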