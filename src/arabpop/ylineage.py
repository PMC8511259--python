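"""Sub-haplogroup discovery on a haploid locus.

Pipeline: collapse weakly supported branches of a rooted tree, pick
clusters of leaves under a patristic-distance cutoff (scanning a cutoff
grid for the one maximizing the number of large clusters), define each
cluster by its fixed private SNPs (haploid FST = 1 and within-cluster
derived AF = 1), date the lineages from per-member derived-SNP counts, and
compare group ages with a rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from arabpop.core import MISSING, GenotypeMatrix
from arabpop.fstats import hudson_fst_site

MU_PER_SITE_YEAR = 0.76e-9
REGION_LEN_BP = 10_000_000
YEARS_PER_GENERATION = 30.0


@dataclass
class SupportTree:
    """Rooted tree with branch lengths (subs/site) and internal supports."""

    tree: dendropy.Tree

    @classmethod
    def from_newick(cls, text: str) -> "SupportTree":
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True,
                                 preserve_underscores=True,
                                 rooting="force-rooted")
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.label is None:
                node.support = None
            else:
                node.support = float(node.label)
        return cls(tree=tree)

    @classmethod
    def from_file(cls, path) -> "SupportTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def clone(self) -> "SupportTree":
        t2 = self.tree.clone(depth=1)
        for n1, n2 in zip(self.tree.preorder_node_iter(),
                          t2.preorder_node_iter()):
            n2.support = getattr(n1, "support", None)
        return SupportTree(tree=t2)


def collapse_low_support(stree: SupportTree,
                         min_support: float = 0.9) -> SupportTree:
    """Contract internal edges with support < min_support into polytomies.

    The removed edge's length is added to each child edge, which preserves
    root-to-leaf path lengths. The root is exempt; leaves are never removed.
    """
    out = stree.clone()
    tree = out.tree
    changed = True
    while changed:
        changed = False
        for node in list(tree.preorder_internal_node_iter()):
            if node is tree.seed_node or node.is_leaf():
                continue
            sup = getattr(node, "support", None)
            if sup is not None and sup < min_support:
                elen = node.edge.length or 0.0
                parent = node.parent_node
                for ch in list(node.child_nodes()):
                    node.remove_child(ch)
                    ch.edge.length = (ch.edge.length or 0.0) + elen
                    parent.add_child(ch)
                parent.remove_child(node)
                changed = True
    return out


@dataclass
class HaploCluster:
    members: list[str]
    max_distance: float
    cutoff: float
    cluster_id: str = ""

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("clusters need >= 2 members")


def _subtree_stats(tree: dendropy.Tree):
    """Per-node (max depth to a leaf below, max leaf-leaf distance below)."""
    depth: dict = {}
    diam: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            depth[node] = 0.0
            diam[node] = 0.0
            continue
        reach = [(ch.edge.length or 0.0) + depth[ch] for ch in node.child_nodes()]
        depth[node] = max(reach)
        best = max(diam[ch] for ch in node.child_nodes())
        if len(reach) >= 2:
            top2 = sorted(reach, reverse=True)[:2]
            best = max(best, top2[0] + top2[1])
        diam[node] = best
    return depth, diam


def pick_clusters(stree: SupportTree, distance_cutoff: float) -> tuple[list[HaploCluster], list[str]]:
    """Maximal clades whose leaf diameter is <= cutoff, with >= 2 leaves.

    Depth-first from the root; once a clade qualifies it is emitted and not
    descended into. Returns (clusters, singleton leaf labels).
    """
    if distance_cutoff <= 0:
        raise ValueError("distance cutoff must be > 0")
    tree = stree.tree
    _, diam = _subtree_stats(tree)
    clusters: list[HaploCluster] = []
    singles: list[str] = []

    def visit(node):
        if node.is_leaf():
            singles.append(node.taxon.label)
            return
        if diam[node] <= distance_cutoff:
            members = sorted(lf.taxon.label for lf in node.leaf_iter())
            clusters.append(HaploCluster(members=members,
                                         max_distance=diam[node],
                                         cutoff=distance_cutoff))
            return
        for ch in node.child_nodes():
            visit(ch)

    visit(tree.seed_node)
    for i, cl in enumerate(clusters):
        cl.cluster_id = f"cl{i}"
    return clusters, singles


def scan_cutoffs(stree: SupportTree, grid, large_min: int = 10):
    """Choose the cutoff maximizing the count of clusters with size > large_min.

    Ties break toward the smaller cutoff (finer resolution). Returns
    (chosen_cutoff, tally DataFrame with per-cutoff cluster counts).
    """
    grid = sorted(float(g) for g in grid)
    if not grid:
        raise ValueError("empty cutoff grid")
    rows = []
    for cut in grid:
        clusters, singles = pick_clusters(stree, cut)
        n_large = sum(1 for c in clusters if len(c.members) > large_min)
        rows.append((cut, len(clusters), n_large, len(singles)))
    tally = pd.DataFrame(rows, columns=["cutoff", "n_clusters",
                                        "n_large_clusters", "n_singletons"])
    best = tally.loc[tally["n_large_clusters"].idxmax(), "cutoff"]
    # idxmax returns the first maximum; grid is ascending, so this is the
    # smallest qualifying cutoff.
    return float(best), tally


@dataclass
class SubHaplogroup:
    hap_id: str
    members: list[str]
    defining_sites: list[int]          # site indices in the haplotype matrix
    mean_derived_count: float          # S-bar since the cluster MRCA
    per_member_counts: np.ndarray = field(default_factory=lambda: np.array([]))
    site_carrier_counts: np.ndarray = field(default_factory=lambda: np.array([]))
    age_years: float = np.nan
    age_ci: tuple[float, float] = (np.nan, np.nan)
    source_clusters: list[str] = field(default_factory=list)


def informative_snps(hap: GenotypeMatrix, clusters: list[HaploCluster],
                     max_missingness: float = 0.01,
                     exclude_singletons: bool = True,
                     fst_tol: float = 1e-12):
    """Defining SNV sets per cluster and merged SubHaplogroup definitions.

    A site defines a cluster when its haploid Hudson FST between cluster
    and rest equals 1 (within tolerance) and the derived allele is fixed
    within the cluster. Haplogroups with identical defining sets merge.
    Returns (per-cluster site sets, list of SubHaplogroup).
    """
    if hap.ploidy != 1:
        raise ValueError("haploid genotypes required")
    ok_sites = hap.site_missingness() <= max_missingness
    if exclude_singletons:
        ok_sites &= hap.alt_allele_count() != 1
    s_index = {s: i for i, s in enumerate(hap.samples)}

    per_cluster: dict[str, list[int]] = {}
    usable_clusters: list[HaploCluster] = []
    for cl in clusters:
        if len(cl.members) < 2:
            warnings.warn(f"cluster {cl.cluster_id!r} smaller than 2; skipped")
            continue
        usable_clusters.append(cl)
        inside = np.array([s_index[s] for s in cl.members])
        outside = np.array([i for i in range(hap.n_samples)
                            if i not in set(inside)])
        gin = hap.gt[inside, :]
        gout = hap.gt[outside, :]
        cin = gin != MISSING
        cout = gout != MISSING
        n1 = cin.sum(axis=0).astype(float)
        n2 = cout.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p1 = np.where(cin, gin, 0).sum(axis=0) / n1
            p2 = np.where(cout, gout, 0).sum(axis=0) / n2
        sites = []
        for j in np.flatnonzero(ok_sites & (n1 >= 2) & (n2 >= 2)):
            if p1[j] != 1.0:
                continue
            fst = hudson_fst_site(p1[j], p2[j], n1[j], n2[j])
            if np.isfinite(fst) and abs(fst - 1.0) <= fst_tol:
                sites.append(int(j))
        per_cluster[cl.cluster_id] = sites

    merged: dict[tuple, SubHaplogroup] = {}
    for cl in usable_clusters:
        sites = tuple(per_cluster[cl.cluster_id])
        if not sites:
            continue
        if sites in merged:
            hg = merged[sites]
            hg.members = sorted(set(hg.members) | set(cl.members))
            hg.source_clusters.append(cl.cluster_id)
        else:
            merged[sites] = SubHaplogroup(
                hap_id="", members=list(cl.members),
                defining_sites=list(sites), mean_derived_count=np.nan,
                source_clusters=[cl.cluster_id])
    haplogroups = list(merged.values())
    for i, hg in enumerate(haplogroups):
        hg.hap_id = f"H{i:02d}"
        per_member, carriers = _derived_since_mrca(hap, hg.members)
        hg.per_member_counts = per_member
        hg.site_carrier_counts = carriers
        hg.mean_derived_count = float(per_member.mean())
    return per_cluster, haplogroups


def _derived_since_mrca(hap: GenotypeMatrix, members: list[str]):
    """Post-MRCA mutation load of a cluster.

    Sites where the derived allele is fixed across the cluster are carried
    by the MRCA itself and do not count toward post-MRCA accumulation.
    Returns (per-member derived counts, per-site within-cluster carrier
    counts over the non-fixed derived sites).
    """
    idx = [hap.samples.index(s) for s in members]
    sub = hap.gt[idx, :]
    called = sub != MISSING
    der = (sub == 1)
    n_der = der.sum(axis=0)
    n_cal = called.sum(axis=0)
    fixed = (n_der == n_cal) & (n_cal > 0)
    active = ~fixed & (n_der > 0)
    per_member = (der & active[None, :]).sum(axis=1).astype(float)
    return per_member, n_der[active].astype(float)


def date_lineages(subhaps: list[SubHaplogroup],
                  mu: float = MU_PER_SITE_YEAR, L: int = REGION_LEN_BP,
                  g: float | None = None, n_bootstrap: int = 1000,
                  seed: int = 0) -> list[SubHaplogroup]:
    """Estimate lineage ages t = S-bar / (mu * L) with bootstrap CIs.

    `mu` is per site per year; pass `g` (years/generation) only when `mu`
    is per generation, in which case t = S-bar * g / (mu_gen * L).
    Haplogroups with S-bar = 0 are flagged with NaN age.

    The 95% CI comes from a Poisson-weighted bootstrap over the cluster's
    post-MRCA mutation sites. Under infinite sites those mutations are the
    independent units; resampling members instead badly undercovers because
    members share the mutations on internal branches.
    """
    scale = (g if g is not None else 1.0) / (mu * L)
    rng = np.random.default_rng(seed)
    for hg in subhaps:
        if hg.mean_derived_count == 0:
            warnings.warn(f"{hg.hap_id}: zero derived SNPs since MRCA; age undefined")
            hg.age_years = np.nan
            hg.age_ci = (np.nan, np.nan)
            continue
        hg.age_years = float(hg.mean_derived_count * scale)
        n = len(hg.per_member_counts)
        k = hg.site_carrier_counts
        if k.size:
            w = rng.poisson(1.0, size=(n_bootstrap, k.size))
            boots = (w @ k) / n * scale
        else:
            boots = rng.choice(hg.per_member_counts,
                               size=(n_bootstrap, n)).mean(axis=1) * scale
        lo, hi = np.percentile(boots, [2.5, 97.5])
        hg.age_ci = (float(lo), float(hi))
    return subhaps


def compare_group_ages(ages_a, ages_b, exact_max_n: int = 20):
    """Two-sided Mann-Whitney rank-sum comparison of two age samples.

    Exact enumeration when the combined sample is small and tie-free;
    normal approximation with tie correction otherwise. Returns (U, p).
    """
    a = np.asarray(ages_a, dtype=float)
    b = np.asarray(ages_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size < 3 or b.size < 3:
        raise ValueError("need >= 3 ages per group")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size + b.size <= exact_max_n and not has_ties) \
        else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def haplogroup_report(subhaps: list[SubHaplogroup]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.hap_id, len(h.members), len(h.defining_sites),
          h.mean_derived_count, h.age_years, h.age_ci[0], h.age_ci[1],
          ",".join(h.source_clusters))
         for h in subhaps],
        columns=["haplogroup", "n_members", "n_defining_snvs", "mean_derived",
                 "age_years", "age_ci_lo", "age_ci_hi", "source_clusters"])
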