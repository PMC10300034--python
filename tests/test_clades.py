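import itertools

import numpy as np
import pytest

import mitogeo as mg
from mitogeo.clades import CladeError
from conftest import exhaustive_clades, random_profiles


def meta(region_by_id):
    return {sid: mg.SampleMetadata(sid, region, region)
            for sid, region in region_by_id.items()}


FOCAL = "NorthAfrica"


class TestSelectHaplogroups:
    def test_min_count_filter(self):
        calls = {"a": "H1", "b": "H1", "c": "H1", "d": "H1", "e": "H1",
                 "f": "U6a"}
        md = meta({sid: FOCAL for sid in calls})
        assert mg.select_haplogroups(calls, md, FOCAL, min_count=2) == ["H1"]
        assert mg.select_haplogroups(calls, md, FOCAL, min_count=1) == ["H1", "U6a"]

    def test_external_samples_not_counted(self):
        calls = {"a": "H1", "b": "H1"}
        md = meta({"a": FOCAL, "b": "Europe"})
        assert mg.select_haplogroups(calls, md, FOCAL, min_count=2) == []

    def test_tie_order_deterministic(self):
        calls = {"a": "T2", "b": "T2", "c": "J1", "d": "J1"}
        md = meta({sid: FOCAL for sid in calls})
        assert mg.select_haplogroups(calls, md, FOCAL) == ["J1", "T2"]


class TestFindFocalClades:
    def test_direct_rule_application(self):
        profiles = [
            mg.make_profile("f1", ["A5000G", "A100G"]),
            mg.make_profile("f2", ["A5000G", "A200G"]),
            mg.make_profile("f3", ["A5000G"]),
            mg.make_profile("x1", ["A300G"]),
            mg.make_profile("x2", []),
        ]
        md = meta({"f1": FOCAL, "f2": FOCAL, "f3": FOCAL,
                   "x1": "Europe", "x2": "Europe"})
        clades = mg.find_focal_clades(profiles, md, FOCAL, haplogroup="H1")
        assert len(clades) == 1
        assert clades[0].member_ids == {"f1", "f2", "f3"}
        assert clades[0].defining_mutations == {"A5000G"}

    def test_masked_shared_mutation_defines_no_clade(self):
        profiles = [
            mg.make_profile("f1", ["T16519C"]),
            mg.make_profile("f2", ["T16519C"]),
            mg.make_profile("x1", []),
        ]
        md = meta({"f1": FOCAL, "f2": FOCAL, "x1": "Europe"})
        mask = mg.default_mask()
        assert mg.find_focal_clades(profiles, md, FOCAL, mask) == []

    def test_nested_carrier_set_is_substructure(self):
        profiles = [
            mg.make_profile("s1", ["A5000G", "C6000T"]),
            mg.make_profile("s2", ["A5000G", "C6000T"]),
            mg.make_profile("s3", ["A5000G"]),
            mg.make_profile("x1", []),
        ]
        md = meta({"s1": FOCAL, "s2": FOCAL, "s3": FOCAL, "x1": "Europe"})
        clades = mg.find_focal_clades(profiles, md, FOCAL)
        assert len(clades) == 1
        assert clades[0].member_ids == {"s1", "s2", "s3"}
        assert (frozenset({"s1", "s2"}), frozenset({"C6000T"})) in clades[0].substructure

    def test_carrier_spanning_external_disqualifies(self):
        profiles = [
            mg.make_profile("f1", ["A5000G"]),
            mg.make_profile("f2", ["A5000G"]),
            mg.make_profile("x1", ["A5000G"]),
        ]
        md = meta({"f1": FOCAL, "f2": FOCAL, "x1": "Europe"})
        assert mg.find_focal_clades(profiles, md, FOCAL) == []

    def test_mixed_haplogroup_labels_rejected(self):
        profiles = [mg.make_profile("a", []), mg.make_profile("b", [])]
        md = meta({"a": FOCAL, "b": FOCAL})
        with pytest.raises(CladeError):
            mg.find_focal_clades(profiles, md, FOCAL, calls={"a": "H1", "b": "U6"})

    def test_oracle_equivalence_on_random_panels(self):
        """Carrier-set calls equal exhaustive subset enumeration."""
        rng = np.random.default_rng(2024)
        for _ in range(40):
            profiles, md = random_profiles(rng, n_samples=int(rng.integers(4, 13)))
            got = mg.find_focal_clades(profiles, md, FOCAL)
            expected = exhaustive_clades(profiles, md, FOCAL)
            assert {c.member_ids: c.defining_mutations for c in got} == expected

    def test_masking_monotonicity(self):
        rng = np.random.default_rng(5)
        profiles, md = random_profiles(rng, n_samples=10)
        base = mg.find_focal_clades(profiles, md, FOCAL)
        positions = sorted({m.position for p in profiles for m in p.mutations})
        mask = mg.RecurrentSiteMask(masked_positions=frozenset(positions[:3]))
        masked = mg.find_focal_clades(profiles, md, FOCAL, mask)
        base_by_members = {c.member_ids: c.defining_mutations for c in base}
        for c in masked:
            if c.member_ids in base_by_members:
                assert len(c.defining_mutations) <= len(base_by_members[c.member_ids])

    def test_soundness_validator(self):
        """Every emitted call satisfies the clade-definition invariants."""
        rng = np.random.default_rng(77)
        for _ in range(20):
            profiles, md = random_profiles(rng, n_samples=int(rng.integers(4, 13)))
            muts_of = {p.sample_id: set(p.canonical_strings()) for p in profiles}
            focal = {sid for sid, m in md.items() if m.macro_region == FOCAL}
            for c in mg.find_focal_clades(profiles, md, FOCAL):
                assert c.member_ids <= focal and len(c.member_ids) >= 2
                assert c.defining_mutations
                for v in c.defining_mutations:
                    carriers = {sid for sid, mm in muts_of.items() if v in mm}
                    assert carriers == c.member_ids


class TestIdenticalClusters:
    def test_three_identical_one_distinct(self):
        profiles = [mg.make_profile(s, ["A100G"]) for s in ("a", "b", "c")]
        profiles.append(mg.make_profile("d", ["A200G"]))
        clusters = mg.find_identical_clusters(profiles)
        assert len(clusters) == 1
        assert clusters[0].member_ids == {"a", "b", "c"}
        assert clusters[0].is_identical_cluster

    def test_all_distinct_empty(self):
        profiles = [mg.make_profile(f"s{i}", [f"A{100 + i}G"]) for i in range(4)]
        assert mg.find_identical_clusters(profiles) == []

    def test_identical_after_masking(self):
        mask = mg.RecurrentSiteMask(masked_positions=frozenset({16519}))
        profiles = [mg.make_profile("a", ["A100G", "T16519C"]),
                    mg.make_profile("b", ["A100G"])]
        clusters = mg.find_identical_clusters(profiles, mask)
        assert len(clusters) == 1 and clusters[0].member_ids == {"a", "b"}

    def test_private_defining_mutations_vs_panel(self):
        profiles = [mg.make_profile("a", ["A100G", "A200G"]),
                    mg.make_profile("b", ["A100G", "A200G"])]
        others = [mg.make_profile("x", ["A200G"])]
        clusters = mg.find_identical_clusters(profiles, other_profiles=others)
        assert clusters[0].defining_mutations == {"A100G"}


class TestClosestExternal:
    def panel(self):
        profiles = [
            mg.make_profile("f1", ["A5000G", "A100G"]),
            mg.make_profile("f2", ["A5000G"]),
            mg.make_profile("near", ["A5000G", "A300G", "A400G"]),
            mg.make_profile("far", ["A1G", "A10G", "A20G", "A30G", "A40G"]),
        ]
        md = meta({"f1": FOCAL, "f2": FOCAL, "near": "Europe", "far": "Sahel"})
        clade = mg.CladeCall("H", frozenset({"f1", "f2"}), frozenset({"A5000G"}))
        return clade, profiles, md

    def test_picks_minimum_distance(self):
        clade, profiles, md = self.panel()
        sid, region, dist = mg.closest_external(clade, profiles, md, FOCAL)
        assert (sid, region, dist) == ("near", "Europe", 2)

    def test_tie_breaks_deterministic(self):
        profiles = [
            mg.make_profile("f1", ["A5000G"]),
            mg.make_profile("f2", ["A5000G", "A100G"]),
            mg.make_profile("xb", ["A5000G", "A300G"]),
            mg.make_profile("xa", ["A5000G", "A400G"]),
        ]
        md = meta({"f1": FOCAL, "f2": FOCAL, "xb": "Europe", "xa": "Europe"})
        clade = mg.CladeCall("H", frozenset({"f1", "f2"}), frozenset({"A5000G"}))
        sid, _, dist = mg.closest_external(clade, profiles, md, FOCAL)
        assert dist == 1 and sid == "xa"  # equal min and mean: lexicographic

    def test_matches_brute_force(self):
        rng = np.random.default_rng(13)
        profiles, md = random_profiles(rng, n_samples=20, focal_frac=0.5)
        focal_ids = [sid for sid, m in md.items() if m.macro_region == FOCAL]
        clade = mg.CladeCall("H", frozenset(focal_ids[:4]), frozenset({"dummy"}))
        sid, _, dist = mg.closest_external(clade, profiles, md, FOCAL)
        members = [p for p in profiles if p.sample_id in clade.member_ids]
        best = min(
            (min(mg.pairwise_difference(e, m) for m in members),
             np.mean([mg.pairwise_difference(e, m) for m in members]), e.sample_id)
            for e in profiles
            if md[e.sample_id].macro_region != FOCAL)
        assert (sid, dist) == (best[2], best[0])

    def test_no_externals_rejected(self):
        profiles = [mg.make_profile("f1", []), mg.make_profile("f2", [])]
        md = meta({"f1": FOCAL, "f2": FOCAL})
        clade = mg.CladeCall("H", frozenset({"f1", "f2"}), frozenset({"x"}))
        with pytest.raises(CladeError):
            mg.closest_external(clade, profiles, md, FOCAL)


class TestReverseDirection:
    def test_external_clade_detected(self):
        profiles = [
            mg.make_profile("e1", ["A7000G", "A100G"]),
            mg.make_profile("e2", ["A7000G"]),
        ] + [mg.make_profile(f"n{i}", [f"A{200 + 10 * i}G"]) for i in range(5)]
        md = meta({"e1": "Europe", "e2": "Europe",
                   **{f"n{i}": FOCAL for i in range(5)}})
        clades, singletons = mg.reverse_direction_clades(profiles, md, FOCAL,
                                                         haplogroup="U6")
        assert len(clades) == 1
        assert clades[0].member_ids == {"e1", "e2"}
        assert singletons == []

    def test_singleton_paired_with_closest_focal(self):
        profiles = [
            mg.make_profile("e1", ["A100G", "A200G"]),
            mg.make_profile("n1", ["A100G"]),
            mg.make_profile("n2", ["A900G", "A910G", "A920G"]),
        ]
        md = meta({"e1": "Europe", "n1": FOCAL, "n2": FOCAL})
        clades, singletons = mg.reverse_direction_clades(profiles, md, FOCAL)
        assert clades == []
        assert singletons == [("e1", "n1", "Europe", 1)]

    def test_symmetry_with_relabeled_input(self):
        rng = np.random.default_rng(21)
        profiles, md = random_profiles(rng, n_samples=10, focal_frac=0.5)
        swapped = {
            sid: mg.SampleMetadata(sid, m.locality,
                                   FOCAL if m.macro_region != FOCAL else "Europe")
            for sid, m in md.items()}
        rev, _ = mg.reverse_direction_clades(profiles, md, FOCAL)
        fwd = mg.find_focal_clades(profiles, swapped, FOCAL)
        assert ({c.member_ids for c in rev} ==
                {c.member_ids for c in fwd})


class TestNetwork:
    def test_two_haplotypes_single_edge(self):
        profiles = [mg.make_profile("a", ["A100G", "A200G", "A300G"]),
                    mg.make_profile("b", [])]
        net = mg.build_network(profiles)
        assert len(net.edges) == 1 and net.edges[0][2] == 3

    def test_equidistant_ties_retained(self):
        profiles = [mg.make_profile("a", ["A100G"]),
                    mg.make_profile("b", ["A200G"]),
                    mg.make_profile("c", ["A300G"])]
        net = mg.build_network(profiles)
        assert len(net.edges) == 3  # all pairwise distance 2: full tie set

    def test_identical_haplotypes_collapse(self):
        profiles = [mg.make_profile("a", ["A100G"]), mg.make_profile("b", ["A100G"]),
                    mg.make_profile("c", [])]
        net = mg.build_network(profiles)
        assert sorted(len(v) for v in net.nodes.values()) == [1, 2]

    def test_spanning_weight_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(31)
        profiles, _ = random_profiles(rng, n_samples=6, mut_prob=0.4)
        net = mg.build_network(profiles)
        keys = sorted(net.nodes)
        n = len(keys)
        if n < 3:
            pytest.skip("degenerate draw")
        reps = {k: next(p for p in profiles
                        if tuple(p.canonical_strings()) == k) for k in keys}
        w = {(i, j): max(1, mg.pairwise_difference(reps[keys[i]], reps[keys[j]]))
             for i in range(n) for j in range(i + 1, n)}
        best = np.inf
        for tree_edges in itertools.combinations(w, n - 1):
            import networkx as nx
            g = nx.Graph(tree_edges)
            if g.number_of_nodes() == n and nx.is_connected(g):
                best = min(best, sum(w[e] for e in tree_edges))
        # any single MST inside the returned tie-union has the optimal weight
        import networkx as nx
        g = nx.Graph()
        for a, b, weight in net.edges:
            g.add_edge(keys.index(a), keys.index(b), weight=weight)
        mst_w = sum(d["weight"] for _, _, d in
                    nx.minimum_spanning_edges(g, data=True))
        assert mst_w == best


class TestPanelSubset:
    def test_keeps_k_nearest_per_haplotype(self):
        focal = [mg.make_profile("f1", ["A100G"])]
        # external i carries i extra private mutations: distance grows with i
        externals = [
            mg.make_profile(f"x{i}", [f"A{300 + 10 * j}G" for j in range(i)])
            for i in range(6)
        ]
        keep = mg.subset_panel(focal, externals, k=3)
        assert keep == ["x0", "x1", "x2"]
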