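import itertools

import dendropy
import numpy as np
import pytest

from arabpop import synthdata as sd
from arabpop import ylineage as yl
from conftest import make_matrix


def patristic_oracle(stree):
    """Independent all-pairs patristic distances via dendropy."""
    pdm = stree.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in stree.tree.taxon_namespace}
    return lambda a, b: pdm.patristic_distance(taxa[a], taxa[b])


def run_pick(sim, cutoff=None):
    stree = yl.SupportTree.from_newick(sim.newick)
    collapsed = yl.collapse_low_support(stree)
    if cutoff is None:
        cutoff, _ = yl.scan_cutoffs(collapsed,
                                    [1e-5, 5e-5, 1e-4, 5e-4, 1e-3, 4e-3])
    clusters, singles = yl.pick_clusters(collapsed, cutoff)
    return collapsed, clusters, singles, cutoff


class TestCollapseLowSupport:
    NWK = "((a:1,b:1)0.95:1,((c:1,d:1)0.5:2,e:3)0.99:1);"

    def test_full_support_tree_unchanged(self):
        t = yl.SupportTree.from_newick("((a:1,b:1)1.0:1,(c:1,d:1)1.0:1);")
        out = yl.collapse_low_support(t)
        assert len(out.tree.internal_nodes()) == len(t.tree.internal_nodes())

    def test_zero_support_becomes_star(self):
        t = yl.SupportTree.from_newick("((a:1,b:1)0.0:1,((c:1,d:1)0.0:1,e:2)0.0:1);")
        out = yl.collapse_low_support(t)
        assert len(out.tree.seed_node.child_nodes()) == 5

    def test_single_weak_edge_contracted(self):
        t = yl.SupportTree.from_newick(self.NWK)
        out = yl.collapse_low_support(t)
        # the 0.5-supported (c,d) clade dissolves; others survive
        internal = [sorted(lf.taxon.label for lf in n.leaf_iter())
                    for n in out.tree.preorder_internal_node_iter()
                    if n is not out.tree.seed_node]
        assert ["a", "b"] in internal
        assert ["c", "d"] not in internal
        assert ["c", "d", "e"] in internal

    def test_leaf_depths_preserved(self):
        t = yl.SupportTree.from_newick(self.NWK)
        out = yl.collapse_low_support(t)
        for tree in (t, out):
            tree.tree.calc_node_ages(ultrametricity_precision=False)
        dist = {}
        for tree, tag in ((t, "pre"), (out, "post")):
            for lf in tree.tree.leaf_node_iter():
                d, node = 0.0, lf
                while node.parent_node is not None:
                    d += node.edge.length or 0.0
                    node = node.parent_node
                dist[(tag, lf.taxon.label)] = d
        for leaf in "abcde":
            assert dist[("pre", leaf)] == pytest.approx(dist[("post", leaf)])


class TestPickClusters:
    def test_cutoff_above_diameter_yields_single_cluster(self, y_locus):
        collapsed, clusters, singles, _ = run_pick(y_locus, cutoff=1.0)
        assert len(clusters) == 1
        assert sorted(clusters[0].members) == sorted(y_locus.haplotypes.samples)
        assert singles == []

    def test_tiny_cutoff_yields_all_singletons(self, y_locus):
        collapsed, clusters, singles, _ = run_pick(y_locus, cutoff=1e-12)
        assert clusters == []
        assert sorted(singles) == sorted(y_locus.haplotypes.samples)

    def test_nonpositive_cutoff_rejected(self, y_locus):
        stree = yl.SupportTree.from_newick(y_locus.newick)
        with pytest.raises(ValueError):
            yl.pick_clusters(stree, 0.0)

    def test_planted_partition_recovered(self, y_locus):
        _, clusters, singles, cutoff = run_pick(y_locus)
        got = sorted(tuple(sorted(c.members)) for c in clusters)
        truth = {}
        for s, c in y_locus.true_clusters.items():
            truth.setdefault(c, []).append(s)
        assert got == sorted(tuple(sorted(v)) for v in truth.values())
        assert singles == []

    def test_clusters_are_disjoint_clades_within_cutoff(self, y_locus):
        collapsed, clusters, _, cutoff = run_pick(y_locus)
        seen = set()
        dist = patristic_oracle(collapsed)
        for cl in clusters:
            assert not seen & set(cl.members)
            seen |= set(cl.members)
            worst = max(dist(a, b) for a, b in
                        itertools.combinations(cl.members, 2))
            assert worst <= cutoff + 1e-12
            assert cl.max_distance == pytest.approx(worst, abs=1e-12)


class TestScanCutoffs:
    def test_single_cutoff_chosen(self, y_locus):
        stree = yl.collapse_low_support(yl.SupportTree.from_newick(y_locus.newick))
        chosen, tally = yl.scan_cutoffs(stree, [5e-5])
        assert chosen == 5e-5
        assert len(tally) == 1

    def test_planted_all_large_clusters_found(self, y_locus):
        stree = yl.collapse_low_support(yl.SupportTree.from_newick(y_locus.newick))
        chosen, tally = yl.scan_cutoffs(stree, [1e-5, 5e-5, 1e-4, 5e-4, 1e-3])
        best = tally.loc[tally["cutoff"] == chosen, "n_large_clusters"].iloc[0]
        assert best == 4  # 4 planted clusters of size 12 > 10

    def test_tally_matches_per_cutoff_brute_force(self, y_locus):
        stree = yl.collapse_low_support(yl.SupportTree.from_newick(y_locus.newick))
        grid = [1e-5, 5e-5, 5e-4]
        _, tally = yl.scan_cutoffs(stree, grid, large_min=10)
        for cut in grid:
            clusters, singles = yl.pick_clusters(stree, cut)
            row = tally.set_index("cutoff").loc[cut]
            assert row["n_clusters"] == len(clusters)
            assert row["n_large_clusters"] == sum(
                1 for c in clusters if len(c.members) > 10)
            assert row["n_singletons"] == len(singles)

    def test_tie_breaks_to_smaller_cutoff(self, y_locus):
        stree = yl.collapse_low_support(yl.SupportTree.from_newick(y_locus.newick))
        chosen, tally = yl.scan_cutoffs(stree, [5e-5, 8e-5])
        counts = tally["n_large_clusters"]
        if counts.iloc[0] == counts.iloc[1]:
            assert chosen == 5e-5

    def test_empty_grid_rejected(self, y_locus):
        stree = yl.SupportTree.from_newick(y_locus.newick)
        with pytest.raises(ValueError):
            yl.scan_cutoffs(stree, [])


class TestInformativeSnps:
    def test_planted_private_snvs_recovered_exactly(self, y_locus):
        _, clusters, _, _ = run_pick(y_locus)
        per_cluster, haps = yl.informative_snps(y_locus.haplotypes, clusters)
        got = sorted(tuple(v) for v in per_cluster.values())
        want = sorted(tuple(v) for v in y_locus.private_snvs.values())
        assert got == want
        assert len(haps) == 4

    def test_each_private_snv_in_exactly_one_set(self, y_locus):
        _, clusters, _, _ = run_pick(y_locus)
        per_cluster, _ = yl.informative_snps(y_locus.haplotypes, clusters)
        all_sites = [j for v in per_cluster.values() for j in v]
        assert len(all_sites) == len(set(all_sites))

    def test_segregating_site_excluded(self):
        # site 0 private+fixed in cluster {s0,s1}; site 1 segregates inside
        gt = np.array([[1, 1], [1, 0], [0, 0], [0, 0]], dtype=np.int8)
        hap = make_matrix(gt, ploidy=1)
        cl = yl.HaploCluster(members=["s0", "s1"], max_distance=0.0,
                             cutoff=1e-4, cluster_id="c")
        per_cluster, _ = yl.informative_snps(hap, [cl],
                                             exclude_singletons=False)
        assert per_cluster["c"] == [0]

    def test_defining_snv_soundness(self, y_locus):
        """Members are all-derived at defining sites; non-members are not."""
        _, clusters, _, _ = run_pick(y_locus)
        _, haps = yl.informative_snps(y_locus.haplotypes, clusters)
        hap = y_locus.haplotypes
        for hg in haps:
            inside = [hap.samples.index(s) for s in hg.members]
            outside = [i for i in range(hap.n_samples) if i not in inside]
            block = hap.gt[np.ix_(inside, hg.defining_sites)]
            assert np.all(block == 1)
            out_block = hap.gt[np.ix_(outside, hg.defining_sites)]
            assert np.all(out_block.min(axis=1) == 0)

    def test_identical_defining_sets_merge(self, y_locus):
        _, clusters, _, _ = run_pick(y_locus)
        # split one true cluster into two sub-clusters with the same stem SNVs
        big = clusters[0]
        half = len(big.members) // 2
        sub1 = yl.HaploCluster(members=big.members[:half], max_distance=0.0,
                               cutoff=1e-4, cluster_id="a")
        sub2 = yl.HaploCluster(members=big.members[half:], max_distance=0.0,
                               cutoff=1e-4, cluster_id="b")
        per_cluster, haps = yl.informative_snps(y_locus.haplotypes, [sub1, sub2])
        shared = set(per_cluster["a"]) & set(per_cluster["b"])
        merged = [h for h in haps if set(h.source_clusters) == {"a", "b"}]
        if shared and per_cluster["a"] == per_cluster["b"]:
            assert len(merged) == 1
            assert sorted(merged[0].members) == sorted(big.members)


class TestDateLineages:
    def _hg(self, counts):
        counts = np.asarray(counts, dtype=float)
        return yl.SubHaplogroup(hap_id="H", members=[f"s{i}" for i in
                                                     range(len(counts))],
                                defining_sites=[0],
                                mean_derived_count=float(counts.mean()),
                                per_member_counts=counts)

    def test_arithmetic(self):
        hg = self._hg([100] * 5)
        yl.date_lineages([hg], mu=1e-9, L=10_000_000)
        assert hg.age_years == pytest.approx(10_000.0)

    def test_doubling_mu_halves_age(self):
        hg1, hg2 = self._hg([80] * 6), self._hg([80] * 6)
        yl.date_lineages([hg1], mu=1e-9, L=10_000_000)
        yl.date_lineages([hg2], mu=2e-9, L=10_000_000)
        assert hg2.age_years == pytest.approx(hg1.age_years / 2)

    def test_per_generation_parameterization(self):
        hg_y, hg_g = self._hg([91] * 6), self._hg([91] * 6)
        yl.date_lineages([hg_y], mu=0.76e-9, L=10_000_000)
        yl.date_lineages([hg_g], mu=0.76e-9 * 30, L=10_000_000, g=30.0)
        assert hg_g.age_years == pytest.approx(hg_y.age_years)

    def test_zero_counts_flagged(self):
        hg = self._hg([0, 0, 0])
        with pytest.warns(UserWarning, match="undefined"):
            yl.date_lineages([hg], mu=1e-9, L=1_000_000)
        assert np.isnan(hg.age_years)

    def test_simulated_tmrca_recovered(self, y_locus):
        _, clusters, _, _ = run_pick(y_locus)
        _, haps = yl.informative_snps(y_locus.haplotypes, clusters)
        yl.date_lineages(haps, mu=y_locus.mu_per_site_year,
                         L=y_locus.region_len_bp, seed=1)
        for hg in haps:
            assert hg.age_years == pytest.approx(12_000, rel=0.25)


class TestCompareGroupAges:
    def test_identical_groups_p_one(self):
        u, p = yl.compare_group_ages([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_separated_groups_exact_enumeration(self):
        u, p = yl.compare_group_ages([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert u == 0.0
        assert p == pytest.approx(2 / 252)

    def test_exact_and_asymptotic_agree_at_n20(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.5, 1, 10)
        _, p_exact = yl.compare_group_ages(a, b, exact_max_n=20)
        _, p_asym = yl.compare_group_ages(a, b, exact_max_n=0)
        assert abs(p_exact - p_asym) < 0.01

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            yl.compare_group_ages([1.0], [2.0, 3.0, 4.0])


class TestEndToEnd:
    @pytest.mark.parametrize("n_clusters", [3, 6])
    def test_full_pipeline_recovery(self, n_clusters):
        sim = sd.simulate_y_locus(n_clusters, sizes=12, mu=0.76e-9,
                                  region_len_bp=10_000_000,
                                  depth_years=12_000, seed=700 + n_clusters)
        _, clusters, singles, cutoff = run_pick(sim)
        got = sorted(tuple(sorted(c.members)) for c in clusters)
        truth = {}
        for s, c in sim.true_clusters.items():
            truth.setdefault(c, []).append(s)
        assert got == sorted(tuple(sorted(v)) for v in truth.values())
        per_cluster, haps = yl.informative_snps(sim.haplotypes, clusters)
        assert sorted(tuple(v) for v in per_cluster.values()) == \
            sorted(tuple(v) for v in sim.private_snvs.values())
        assert len(haps) <= len(clusters)
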