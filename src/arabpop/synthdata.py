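"""Synthetic cohorts with known ground truth.

Four generators: (1) admixed diploid cohorts with Balding-Nichols-drifted
population allele frequencies and Dirichlet admixture proportions, (2)
planted autozygous tracts, (3) a haploid locus evolving on a simulated
ultrametric tree with cluster-private fixed mutations, and (4)
reference/target panel splits for imputation benchmarking. Every artifact
carries a truth registry so downstream detectors can be scored exactly.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from arabpop._rng import substream
from arabpop.core import MISSING, GenotypeMatrix, QMatrix
from arabpop.vcfio import write_manifest, write_vcf

DEFAULT_CHROMS = {"1": 50_000_000, "2": 50_000_000}


@dataclass
class AncestralModel:
    """K ancestral populations drifted from a shared frequency spectrum."""

    K: int
    n_sites: int
    ancestral_freqs: np.ndarray
    drift: np.ndarray
    seed: int
    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROMS))

    def __post_init__(self) -> None:
        self.ancestral_freqs = np.asarray(self.ancestral_freqs, dtype=float)
        self.drift = np.asarray(self.drift, dtype=float)
        if self.ancestral_freqs.shape != (self.n_sites,):
            raise ValueError("ancestral_freqs must have length n_sites")
        if np.any(self.ancestral_freqs <= 0) or np.any(self.ancestral_freqs >= 1):
            raise ValueError("ancestral_freqs must lie strictly inside (0, 1)")
        if self.drift.shape != (self.K,):
            raise ValueError("drift must have length K")
        if np.any(self.drift < 0) or np.any(self.drift >= 1):
            raise ValueError("drift values must lie in [0, 1)")

    @classmethod
    def uniform(cls, K: int, n_sites: int, drift, seed: int,
                freq_low: float = 0.05, freq_high: float = 0.95,
                chrom_lengths: dict[str, int] | None = None) -> "AncestralModel":
        """Model with Uniform(freq_low, freq_high) ancestral frequencies."""
        rng = substream(seed, "ancestral_freqs")
        freqs = rng.uniform(freq_low, freq_high, size=n_sites)
        drift = np.broadcast_to(np.asarray(drift, dtype=float), (K,)).copy()
        return cls(K=K, n_sites=n_sites, ancestral_freqs=freqs, drift=drift,
                   seed=seed,
                   chrom_lengths=dict(chrom_lengths or DEFAULT_CHROMS))


@dataclass
class AdmixSpec:
    """Per-group Dirichlet admixture parameters and group sizes."""

    group_names: list[str]
    alphas: np.ndarray      # (n_groups, K), rows may be scaled indicators
    sizes: np.ndarray       # (n_groups,)

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        if len(self.group_names) != len(self.sizes) or self.alphas.shape[0] != len(self.sizes):
            raise ValueError("group_names, alphas and sizes must agree in length")
        if np.any(self.sizes < 1):
            raise ValueError("empty admixture groups are not allowed")
        if np.any(self.alphas <= 0):
            raise ValueError("Dirichlet parameters must be > 0")

    @classmethod
    def unadmixed(cls, sizes_by_pop: dict[str, int], K: int,
                  concentration: float = 1e6) -> "AdmixSpec":
        """One group per ancestral population with q ~ indicator rows.

        A very large concentration on a single component makes Dirichlet
        draws numerically equal to the indicator vector.
        """
        names = list(sizes_by_pop)
        alphas = np.full((len(names), K), 1e-9)
        for g, name in enumerate(names):
            alphas[g, g % K] = concentration
        return cls(group_names=names, alphas=alphas,
                   sizes=np.array([sizes_by_pop[n] for n in names]))


@dataclass
class SimCohort:
    genotypes: GenotypeMatrix
    true_Q: QMatrix
    true_roh: list[tuple]            # (sample, chrom, start_bp, end_bp, class)
    provenance: dict

    def write(self, outdir: str | os.PathLike) -> None:
        os.makedirs(outdir, exist_ok=True)
        write_vcf(self.genotypes, os.path.join(outdir, "cohort.vcf"),
                  contig_lengths=self.provenance.get("chrom_lengths"))
        with open(os.path.join(outdir, "true_q.tsv"), "w") as fh:
            fh.write("sample\t" + "\t".join(self.true_Q.components) + "\n")
            for s, row in zip(self.true_Q.samples, self.true_Q.q):
                fh.write(s + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
        with open(os.path.join(outdir, "true_roh.tsv"), "w") as fh:
            fh.write("sample\tchrom\tstart\tend\tclass\n")
            for rec in self.true_roh:
                fh.write("\t".join(str(x) for x in rec) + "\n")


def _site_positions(chrom_lengths: dict[str, int], n_sites: int,
                    rng: np.random.Generator):
    """Distribute sites across chromosomes proportionally to length."""
    total = sum(chrom_lengths.values())
    chroms, pos = [], []
    names = list(chrom_lengths)
    counts = [int(round(n_sites * chrom_lengths[c] / total)) for c in names]
    counts[-1] = n_sites - sum(counts[:-1])
    for c, k in zip(names, counts):
        p = np.sort(rng.choice(chrom_lengths[c] - 1, size=k, replace=False) + 1)
        chroms.extend([c] * k)
        pos.extend(p.tolist())
    return np.array(chroms, dtype=object), np.array(pos, dtype=np.int64)


def draw_population_freqs(model: AncestralModel,
                          rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols frequencies, shape (K, n_sites).

    Population k, site j: Beta(p(1-F)/F, (1-p)(1-F)/F) with
    p = ancestral_freqs[j], F = drift[k]. F = 0 is the no-drift limit where
    the frequency equals p exactly.
    """
    p = model.ancestral_freqs
    out = np.empty((model.K, model.n_sites))
    for k in range(model.K):
        F = model.drift[k]
        if F == 0.0:
            out[k] = p
        else:
            ratio = (1.0 - F) / F
            out[k] = rng.beta(p * ratio, (1.0 - p) * ratio)
    return out


_NUC = np.array(["A", "C", "G", "T"], dtype=object)


def simulate_admixed_cohort(model: AncestralModel, admix_spec: AdmixSpec,
                            missing_rate: float = 0.0) -> SimCohort:
    """Simulate diploid genotypes under admixture of drifted populations.

    Individual i in group g draws q_i ~ Dirichlet(alpha_g); its genotype at
    site j is Binomial(2, sum_k q_ik p_kj). Deterministic for a fixed model
    seed.
    """
    rng = substream(model.seed, "simulate_admixed_cohort")
    chrom, pos = _site_positions(model.chrom_lengths, model.n_sites, rng)
    ref = _NUC[rng.integers(0, 4, size=model.n_sites)]
    alt = np.array([_NUC[(np.flatnonzero(_NUC == r)[0] + rng.integers(1, 4)) % 4]
                    for r in ref], dtype=object)

    pop_freqs = draw_population_freqs(model, rng)

    samples, pops, q_rows = [], [], []
    for g, name in enumerate(admix_spec.group_names):
        size = int(admix_spec.sizes[g])
        q = rng.dirichlet(admix_spec.alphas[g], size=size)
        q_rows.append(q)
        samples.extend(f"{name}_{i:04d}" for i in range(size))
        pops.extend([name] * size)
    q_all = np.vstack(q_rows)
    q_all /= q_all.sum(axis=1, keepdims=True)

    dosage_p = q_all @ pop_freqs                     # (n_ind, n_sites)
    gt = rng.binomial(2, dosage_p).astype(np.int8)
    if missing_rate > 0:
        gt[rng.random(gt.shape) < missing_rate] = MISSING

    gm = GenotypeMatrix(samples=samples, chrom=chrom, pos=pos, ref=ref, alt=alt,
                        gt=gt, ploidy=2, populations=np.array(pops, dtype=object))
    true_q = QMatrix(samples=samples,
                     components=[f"K{k}" for k in range(model.K)], q=q_all,
                     row_tol=1e-9)
    prov = {"model": model, "admix_spec": admix_spec,
            "chrom_lengths": dict(model.chrom_lengths),
            "missing_rate": missing_rate}
    return SimCohort(genotypes=gm, true_Q=true_q, true_roh=[], provenance=prov)


@dataclass
class TractClass:
    """One size class of autozygous tracts to plant."""

    label: str
    count: int
    length_bp: tuple[int, int]   # uniform (lo, hi); lo == hi for fixed length


def plant_roh(cohort: SimCohort, tract_spec: list[TractClass],
              het_error: float = 0.0, seed: int | None = None,
              max_retries: int = 200) -> SimCohort:
    """Plant homozygous tracts into a cohort; registry returned in true_roh.

    Inside a tract each genotype becomes homozygous for an allele drawn at
    the cohort frequency, then flipped to heterozygous with probability
    het_error. Overlapping placements for one sample are resolved by
    rejection-resampling.
    """
    if not 0.0 <= het_error <= 0.05:
        raise ValueError("het_error must be in [0, 0.05]")
    model = cohort.provenance.get("model")
    seed = model.seed if seed is None and model is not None else (seed or 0)
    rng = substream(seed, "plant_roh")

    gm = cohort.genotypes.copy()
    chrom_lengths = cohort.provenance.get("chrom_lengths", DEFAULT_CHROMS)
    chrom_names = list(chrom_lengths)
    for tc in tract_spec:
        if tc.length_bp[1] >= max(chrom_lengths.values()):
            raise ValueError(f"tract class {tc.label!r} longer than any chromosome")

    af = np.nan_to_num(gm.alt_freq(), nan=0.5)
    placed: dict[int, list[tuple[str, int, int]]] = {}
    registry: list[tuple] = []
    for tc in tract_spec:
        for _ in range(tc.count):
            for attempt in range(max_retries):
                i = int(rng.integers(0, gm.n_samples))
                c = chrom_names[int(rng.integers(0, len(chrom_names)))]
                length = int(rng.integers(tc.length_bp[0], tc.length_bp[1] + 1))
                if length >= chrom_lengths[c]:
                    continue
                start = int(rng.integers(1, chrom_lengths[c] - length))
                end = start + length - 1
                clash = any(cc == c and not (end < s or start > e)
                            for cc, s, e in placed.get(i, []))
                if not clash:
                    break
            else:
                raise RuntimeError(
                    f"could not place a {tc.label!r} tract after {max_retries} retries")
            placed.setdefault(i, []).append((c, start, end))
            registry.append((gm.samples[i], c, start, end, tc.label))
            in_tract = (gm.chrom == c) & (gm.pos >= start) & (gm.pos <= end)
            idx = np.flatnonzero(in_tract)
            hom = (rng.random(idx.size) < af[idx]).astype(np.int8) * 2
            flip = rng.random(idx.size) < het_error
            hom[flip] = 1
            keep_missing = gm.gt[i, idx] == MISSING
            hom[keep_missing] = MISSING
            gm.gt[i, idx] = hom

    return SimCohort(genotypes=gm, true_Q=cohort.true_Q,
                     true_roh=cohort.true_roh + registry,
                     provenance=dict(cohort.provenance, het_error=het_error))


# ---------------------------------------------------------------------------
# Haploid locus on a simulated tree
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    name: str | None
    time: float                      # years before present (leaves at 0)
    children: list = field(default_factory=list)
    muts: int = 0                    # mutations on the edge above
    edge_years: float = 0.0


@dataclass
class SimYLocus:
    newick: str
    haplotypes: GenotypeMatrix
    true_clusters: dict[str, str]     # sample -> cluster id
    private_snvs: dict[str, list[int]]  # cluster id -> site indices
    mu_per_site_year: float
    region_len_bp: int
    depth_years: dict[str, float]

    def write(self, outdir: str | os.PathLike) -> None:
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "ylocus.nwk"), "w") as fh:
            fh.write(self.newick + "\n")
        write_vcf(self.haplotypes, os.path.join(outdir, "ylocus.vcf"))
        with open(os.path.join(outdir, "true_clusters.tsv"), "w") as fh:
            for s, c in self.true_clusters.items():
                fh.write(f"{s}\t{c}\n")
        with open(os.path.join(outdir, "private_snvs.tsv"), "w") as fh:
            fh.write("cluster\tsite_index\n")
            for c, sites in self.private_snvs.items():
                for j in sites:
                    fh.write(f"{c}\t{j}\n")


def _random_ultrametric(leaves: list[str], depth: float,
                        rng: np.random.Generator) -> _Node:
    """Random bifurcating ultrametric subtree with root at `depth` years."""
    nodes = [_Node(name=s, time=0.0) for s in leaves]
    if len(nodes) == 1:
        return nodes[0]
    times = np.sort(rng.uniform(0.0, depth, size=len(nodes) - 2)).tolist() + [depth]
    for t in times:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = _Node(name=None, time=t, children=[a, b])
        a.edge_years = t - a.time
        b.edge_years = t - b.time
        nodes.append(parent)
    return nodes[0]


def _iter_edges(node: _Node):
    for ch in node.children:
        yield ch
        yield from _iter_edges(ch)


def _leaves_below(node: _Node) -> list[str]:
    if not node.children:
        return [node.name]
    out = []
    for ch in node.children:
        out.extend(_leaves_below(ch))
    return out


def _to_newick(node: _Node, L: int) -> str:
    bl = node.muts / L
    if not node.children:
        return f"{node.name}:{bl:.10f}"
    inner = ",".join(_to_newick(ch, L) for ch in node.children)
    return f"({inner})1.0:{bl:.10f}"


def simulate_y_locus(n_clusters: int, sizes, mu: float, region_len_bp: int,
                     depth_years, seed: int,
                     root_depth_factor: float = 4.0) -> SimYLocus:
    """Haploid locus: per-cluster ultrametric subtrees joined at a deep root.

    Mutations drop on each branch as Poisson(mu * region_len_bp * years)
    under infinite sites; each cluster's stem is guaranteed >= 1 private
    mutation (forced with a warning if the Poisson draw is zero). Newick
    branch lengths are realized substitutions/site; all supports are 1.0.
    """
    sizes = np.broadcast_to(np.asarray(sizes, dtype=int), (n_clusters,))
    depth_years = np.broadcast_to(np.asarray(depth_years, dtype=float), (n_clusters,))
    if np.any(sizes < 2):
        raise ValueError("cluster sizes must be >= 2")
    if np.any(depth_years <= 0):
        raise ValueError("depth_years must be > 0")
    rng = substream(seed, "simulate_y_locus")

    root_time = float(depth_years.max() * root_depth_factor)
    root = _Node(name=None, time=root_time)
    cluster_roots = []
    cluster_ids = [f"C{c}" for c in range(n_clusters)]
    true_clusters: dict[str, str] = {}
    for c, cid in enumerate(cluster_ids):
        leaves = [f"{cid}_{i:03d}" for i in range(sizes[c])]
        for s in leaves:
            true_clusters[s] = cid
        sub = _random_ultrametric(leaves, float(depth_years[c]), rng)
        sub.edge_years = root_time - sub.time
        root.children.append(sub)
        cluster_roots.append(sub)

    # Drop mutations; force >= 1 on each cluster stem.
    for ch in _iter_edges(root):
        ch.muts = int(rng.poisson(mu * region_len_bp * ch.edge_years))
    for c, sub in enumerate(cluster_roots):
        if mu * region_len_bp * sub.edge_years < 1.0 and sub.muts == 0:
            warnings.warn(
                f"cluster {cluster_ids[c]}: expected stem mutations < 1; "
                "planting one private SNV")
        if sub.muts == 0:
            sub.muts = 1

    samples = sorted(true_clusters)
    s_index = {s: i for i, s in enumerate(samples)}
    total_muts = sum(ch.muts for ch in _iter_edges(root))
    if total_muts > region_len_bp:
        raise ValueError("mutation count exceeds region length (infinite-sites violation)")
    positions = np.sort(rng.choice(region_len_bp, size=total_muts, replace=False) + 1)
    order = rng.permutation(total_muts)  # branch -> site assignment

    gt = np.zeros((len(samples), total_muts), dtype=np.int8)
    private: dict[str, list[int]] = {cid: [] for cid in cluster_ids}
    m = 0
    stem_ids = {id(sub): cid for sub, cid in zip(cluster_roots, cluster_ids)}
    for ch in _iter_edges(root):
        below = [s_index[s] for s in _leaves_below(ch)]
        for _ in range(ch.muts):
            j = int(order[m])
            gt[below, j] = 1
            if id(ch) in stem_ids:
                private[stem_ids[id(ch)]].append(j)
            m += 1
    for cid in private:
        private[cid].sort()

    ref = _NUC[rng.integers(0, 4, size=total_muts)]
    alt = np.array([_NUC[(np.flatnonzero(_NUC == r)[0] + rng.integers(1, 4)) % 4]
                    for r in ref], dtype=object)
    hap = GenotypeMatrix(samples=samples,
                         chrom=np.array(["Y"] * total_muts, dtype=object),
                         pos=positions, ref=ref, alt=alt, gt=gt, ploidy=1)
    return SimYLocus(newick=_to_newick_root(root, region_len_bp),
                     haplotypes=hap, true_clusters=true_clusters,
                     private_snvs=private, mu_per_site_year=mu,
                     region_len_bp=region_len_bp,
                     depth_years={cid: float(d) for cid, d
                                  in zip(cluster_ids, depth_years)})


def _to_newick_root(root: _Node, L: int) -> str:
    inner = ",".join(_to_newick(ch, L) for ch in root.children)
    return f"({inner});"


def make_panel_pair(cohort: SimCohort, n_ref: int, n_target: int,
                    array_fraction: float, outdir: str | os.PathLike,
                    seed: int | None = None):
    """Split a cohort into a reference panel and an imputation target set.

    Writes reference.vcf, target_truth.vcf and manifest.tsv under `outdir`
    and returns the three paths. The manifest lists the pseudo-array (typed)
    subset of sites.
    """
    gm = cohort.genotypes
    if n_ref + n_target > gm.n_samples:
        raise ValueError("n_ref + n_target exceeds cohort size")
    if not 0.0 < array_fraction < 1.0:
        raise ValueError("array_fraction must be in (0, 1)")
    model = cohort.provenance.get("model")
    seed = model.seed if seed is None and model is not None else (seed or 0)
    rng = substream(seed, "make_panel_pair")

    perm = rng.permutation(gm.n_samples)
    ref_idx = np.sort(perm[:n_ref])
    tgt_idx = np.sort(perm[n_ref:n_ref + n_target])

    n_typed = int(round(array_fraction * gm.n_sites))
    typed = np.sort(rng.choice(gm.n_sites, size=n_typed, replace=False))
    for c in dict.fromkeys(gm.chrom):
        if np.count_nonzero(gm.chrom[typed] == c) < 2:
            raise ValueError(
                f"array_fraction leaves fewer than 2 typed sites on chromosome {c}")

    os.makedirs(outdir, exist_ok=True)
    ref_path = os.path.join(outdir, "reference.vcf")
    tgt_path = os.path.join(outdir, "target_truth.vcf")
    man_path = os.path.join(outdir, "manifest.tsv")
    lengths = cohort.provenance.get("chrom_lengths")
    write_vcf(gm.take_samples(ref_idx), ref_path, contig_lengths=lengths)
    write_vcf(gm.take_samples(tgt_idx), tgt_path, contig_lengths=lengths)
    write_manifest(gm.chrom[typed], gm.pos[typed], man_path)
    return ref_path, tgt_path, man_path
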