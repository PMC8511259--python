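"""f3 and D admixture statistics, pairwise FST and block-jackknife errors.

All statistics run off a SiteFrequencyTable (per-population allele counts
per site); significance comes from a weighted block jackknife over
contiguous genomic blocks (default 5 Mb), with blocks weighted by their
usable-site counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from arabpop.core import MISSING, BlockStatResult, GenotypeMatrix

DEFAULT_BLOCK_BP = 5_000_000


@dataclass
class SiteFrequencyTable:
    """Per-population non-reference allele counts over a shared site list."""

    chrom: np.ndarray
    pos: np.ndarray
    alt_count: dict[str, np.ndarray]     # population -> per-site alt alleles
    n_called: dict[str, np.ndarray]      # population -> per-site sampled alleles
    het_count: dict[str, np.ndarray] = field(default_factory=dict)  # diploid only
    ploidy: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        for p in self.alt_count:
            a, n = self.alt_count[p], self.n_called[p]
            if np.any(a < 0) or np.any(a > n):
                raise ValueError(f"population {p!r}: allele counts out of range")

    @property
    def populations(self) -> list[str]:
        return list(self.alt_count)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def freq(self, pop: str) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_called[pop] > 0,
                            self.alt_count[pop] / self.n_called[pop], np.nan)

    @classmethod
    def from_genotypes(cls, gm: GenotypeMatrix,
                       labels: dict[str, str] | None = None) -> "SiteFrequencyTable":
        if labels is None:
            if gm.populations is None:
                raise ValueError("no population labels available")
            labels = dict(zip(gm.samples, gm.populations))
        alt_count, n_called, het_count, ploidy = {}, {}, {}, {}
        for pop in dict.fromkeys(labels.values()):
            idx = [i for i, s in enumerate(gm.samples) if labels.get(s) == pop]
            sub = gm.gt[idx, :]
            called = sub != MISSING
            alt_count[pop] = np.where(called, sub, 0).sum(axis=0).astype(np.int64)
            n_called[pop] = called.sum(axis=0).astype(np.int64) * gm.ploidy
            if gm.ploidy == 2:
                het_count[pop] = (sub == 1).sum(axis=0).astype(np.int64)
            ploidy[pop] = gm.ploidy
        return cls(chrom=gm.chrom, pos=gm.pos, alt_count=alt_count,
                   n_called=n_called, het_count=het_count, ploidy=ploidy)


def block_ids(chrom: np.ndarray, pos: np.ndarray,
              block_size_bp: int = DEFAULT_BLOCK_BP) -> np.ndarray:
    """Contiguous-block label per site (chromosome-bounded)."""
    labels = np.array([f"{c}:{p // block_size_bp}" for c, p in zip(chrom, pos)],
                      dtype=object)
    _, ids = np.unique(labels, return_inverse=True)
    return ids


def weighted_block_jackknife(block_num: np.ndarray, block_den: np.ndarray,
                             block_sizes: np.ndarray):
    """Weighted delete-one-block jackknife for a ratio-of-sums statistic.

    `block_num[j]` and `block_den[j]` are per-block sums; the statistic is
    sum(num)/sum(den). Block weights are `block_sizes` (usable sites).
    Returns (estimate, se). Uses the weighted-jackknife variance with
    pseudovalues h_j*theta - (h_j-1)*theta_{-j}, h_j = n/m_j.
    """
    block_num = np.asarray(block_num, dtype=float)
    block_den = np.asarray(block_den, dtype=float)
    m = np.asarray(block_sizes, dtype=float)
    g = len(m)
    if g < 2:
        raise ValueError("block jackknife needs >= 2 blocks")
    n = m.sum()
    tot_num, tot_den = block_num.sum(), block_den.sum()
    if tot_den == 0:
        raise ZeroDivisionError("zero denominator in jackknife statistic")
    theta = tot_num / tot_den
    loo = (tot_num - block_num) / (tot_den - block_den)
    h = n / m
    theta_j = g * theta - np.sum((1 - m / n) * loo)
    tau = h * theta - (h - 1) * loo
    var = np.sum((tau - theta_j) ** 2 / (h - 1)) / g
    return float(theta), float(np.sqrt(var))


def _mean_stat_result(terms: np.ndarray, usable: np.ndarray, chrom, pos,
                      block_size_bp: int, populations: dict) -> BlockStatResult:
    """Block-jackknifed mean of per-site terms over usable sites."""
    idx = np.flatnonzero(usable)
    if idx.size == 0:
        raise ValueError("no usable sites")
    bid = block_ids(chrom[idx], pos[idx], block_size_bp)
    g = bid.max() + 1
    sums = np.bincount(bid, weights=terms[idx], minlength=g)
    sizes = np.bincount(bid, minlength=g).astype(float)
    est, se = weighted_block_jackknife(sums, sizes, sizes)
    z = est / se if se > 0 else np.inf * np.sign(est)
    return BlockStatResult(statistic=est, se=se, z=float(z), n_blocks=int(g),
                           n_sites_used=int(idx.size), populations=populations)


def f3_statistic(freqs: SiteFrequencyTable, A: str, B: str, C: str,
                 block_size_bp: int = DEFAULT_BLOCK_BP) -> BlockStatResult:
    """Admixture f3(C; A, B) with finite-sample correction on C.

    Per-site term (c-a)(c-b) - c(1-c)/(n_C - 1); the statistic is the mean
    over usable sites with a weighted block-jackknife SE. A significantly
    negative value (Z < -3) indicates C is admixed between sources related
    to A and B.
    """
    a, b, c = freqs.freq(A), freqs.freq(B), freqs.freq(C)
    n_c = freqs.n_called[C].astype(float)
    usable = (np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
              & (freqs.n_called[A] >= 2) & (freqs.n_called[B] >= 2)
              & (n_c >= 2))
    for pop, mask in ((A, freqs.n_called[A] >= 2), (B, freqs.n_called[B] >= 2),
                      (C, n_c >= 2)):
        if not mask.any():
            raise ValueError(f"population {pop!r} has zero usable sites")
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = (c - a) * (c - b) - c * (1 - c) / (n_c - 1)
    return _mean_stat_result(terms, usable, freqs.chrom, freqs.pos,
                             block_size_bp,
                             {"A": A, "B": B, "C": C, "statistic": "f3"})


def d_statistic(freqs: SiteFrequencyTable, W: str, X: str, Y: str, Z_out: str,
                block_size_bp: int = DEFAULT_BLOCK_BP,
                outgroup_poly_tol: float = 0.01) -> BlockStatResult:
    """Patterson's D(W, X; Y, Outgroup) on derived-allele frequencies.

    The outgroup's major allele defines the ancestral state; sites where the
    outgroup is polymorphic beyond `outgroup_poly_tol` are dropped.
    D = sum[(w-x)(y-z)] / sum[(w+x-2wx)(y+z-2yz)] with a block-jackknife Z.
    Positive D means excess Y-sharing with W relative to X.
    """
    w, x = freqs.freq(W), freqs.freq(X)
    y, z = freqs.freq(Y), freqs.freq(Z_out)
    usable = np.isfinite(w) & np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    minor_out = np.minimum(z, 1 - z)
    usable &= minor_out <= outgroup_poly_tol
    # polarize: outgroup major allele is ancestral
    flip = z > 0.5
    w = np.where(flip, 1 - w, w)
    x = np.where(flip, 1 - x, x)
    y = np.where(flip, 1 - y, y)
    z = np.where(flip, 1 - z, z)

    num = (w - x) * (y - z)
    den = (w + x - 2 * w * x) * (y + z - 2 * y * z)
    idx = np.flatnonzero(usable)
    if idx.size == 0:
        raise ValueError("no usable sites for D statistic")
    bid = block_ids(freqs.chrom[idx], freqs.pos[idx], block_size_bp)
    g = bid.max() + 1
    bnum = np.bincount(bid, weights=num[idx], minlength=g)
    bden = np.bincount(bid, weights=den[idx], minlength=g)
    if bden.sum() == 0:
        raise ZeroDivisionError(
            f"zero D denominator over {idx.size} usable sites")
    sizes = np.bincount(bid, minlength=g).astype(float)
    est, se = weighted_block_jackknife(bnum, bden, sizes)
    zscore = est / se if se > 0 else (0.0 if est == 0 else np.inf * np.sign(est))
    return BlockStatResult(statistic=est, se=se, z=float(zscore),
                           n_blocks=int(g), n_sites_used=int(idx.size),
                           populations={"W": W, "X": X, "Y": Y, "Z": Z_out,
                                        "statistic": "D"})


def _hudson_components(p1, p2, n1, n2):
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / (n1 - 1)
           - p2 * (1 - p2) / (n2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def _wc_components(p1, p2, n1, n2, h1, h2):
    """Weir & Cockerham (1984) two-population variance components a, a+b+c.

    n1/n2 are sampled individuals, h1/h2 observed heterozygote counts.
    """
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1 ** 2 + n2 ** 2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (h1 + h2) / (n1 + n2)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, a + b + c


def fst_pairwise(freqs: SiteFrequencyTable, pop1: str, pop2: str,
                 estimator: str = "hudson", ploidy: int | None = None):
    """Mean FST between two populations (ratio of averages) + per-site values.

    Returns (mean_fst, DataFrame with per-site num/den and clipped fst).
    """
    if estimator not in ("hudson", "weir_cockerham"):
        raise ValueError(f"unknown FST estimator {estimator!r}")
    p1, p2 = freqs.freq(pop1), freqs.freq(pop2)
    n1 = freqs.n_called[pop1].astype(float)
    n2 = freqs.n_called[pop2].astype(float)
    usable = np.isfinite(p1) & np.isfinite(p2) & (n1 >= 2) & (n2 >= 2)

    with np.errstate(invalid="ignore", divide="ignore"):
        if estimator == "hudson":
            num, den = _hudson_components(p1, p2, n1, n2)
        else:
            pl = ploidy or freqs.ploidy.get(pop1, 2)
            if pl == 2:
                h1 = freqs.het_count.get(pop1)
                h2 = freqs.het_count.get(pop2)
                if h1 is None or h2 is None:
                    raise ValueError("Weir-Cockerham (diploid) needs het counts")
                num, den = _wc_components(p1, p2, n1 / 2, n2 / 2, h1, h2)
            else:
                # haploid: no heterozygotes; individuals = allele counts
                num, den = _wc_components(p1, p2, n1, n2,
                                          np.zeros_like(p1), np.zeros_like(p2))

    idx = np.flatnonzero(usable & np.isfinite(num) & np.isfinite(den))
    tot_den = den[idx].sum()
    if tot_den == 0:
        raise ZeroDivisionError("zero FST denominator")
    mean_fst = float(num[idx].sum() / tot_den)
    with np.errstate(invalid="ignore", divide="ignore"):
        persite = np.where(den[idx] != 0, num[idx] / den[idx], np.nan)
    table = pd.DataFrame({
        "chrom": freqs.chrom[idx], "pos": freqs.pos[idx],
        "num": num[idx], "den": den[idx],
        "fst": np.clip(persite, -1.0, 1.0),
    })
    return mean_fst, table


def hudson_fst_site(p1: float, p2: float, n1: float, n2: float) -> float:
    """Single-site Hudson FST (used for haplogroup-defining SNP scans)."""
    num, den = _hudson_components(np.asarray(p1, dtype=float), np.asarray(p2, dtype=float),
                                  np.asarray(n1, dtype=float), np.asarray(n2, dtype=float))
    return float(num / den) if den != 0 else np.nan


@dataclass
class AdmixtureNetwork:
    target: str
    edges: list[tuple[str, str, float]]      # (A, B, Z)

    @property
    def degrees(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for a, b, _ in self.edges:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        return deg

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["donor_a", "donor_b", "z"]) \
            .assign(target=self.target)


def build_admixture_network(f3_results: list[BlockStatResult],
                            z_threshold: float = -3.0) -> dict[str, AdmixtureNetwork]:
    """Per-target networks of donor pairs with f3 < 0 and Z < threshold."""
    nets: dict[str, AdmixtureNetwork] = {}
    for res in f3_results:
        if res.statistic < 0 and res.z < z_threshold:
            tgt = res.populations["C"]
            nets.setdefault(tgt, AdmixtureNetwork(target=tgt, edges=[]))
            nets[tgt].edges.append((res.populations["A"], res.populations["B"],
                                    res.z))
    return nets
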