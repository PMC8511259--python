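"""Runs of homozygosity: two-state HMM caller, Gaussian-mixture size
classes, inbreeding coefficients and gene-overlap summaries.

The caller runs on hard genotype calls; a small heterozygote emission error
(default 1e-3) absorbs genotyping error. Transitions decay exponentially
with inter-site distance under a two-state Markov jump process
parameterized by expected tract lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from arabpop.core import MISSING, GenotypeMatrix
from arabpop.vcfio import BedInterval


@dataclass
class ROHParams:
    het_emission_error: float = 1e-3     # P(het | autozygous)
    expected_az_bp: float = 1_000_000    # mean autozygous tract
    expected_hw_bp: float = 10_000_000   # mean non-autozygous tract
    min_quality: float = 50.0            # keep segments with quality > this
    min_sites: int = 3


@dataclass
class ROHSegment:
    sample: str
    chrom: str
    start_bp: int       # 1-based inclusive
    end_bp: int
    n_sites: int
    quality: float
    label: str | None = None

    def __post_init__(self) -> None:
        if self.end_bp < self.start_bp or self.n_sites < 1 or self.quality < 0:
            raise ValueError("invalid ROH segment")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def _forward_backward(log_em: np.ndarray, trans: np.ndarray,
                      pi: np.ndarray) -> np.ndarray:
    """Scaled forward-backward, batched over samples.

    log_em: (S, T, 2) emission log-likelihoods; trans: (T-1, 2, 2) shared
    across samples. Returns posteriors (S, T, 2).
    """
    S, T, _ = log_em.shape
    em = np.exp(log_em - log_em.max(axis=2, keepdims=True))
    alpha = np.empty((S, T, 2))
    beta = np.empty((S, T, 2))
    a = pi[None, :] * em[:, 0]
    alpha[:, 0] = a / a.sum(axis=1, keepdims=True)
    for t in range(1, T):
        a = (alpha[:, t - 1] @ trans[t - 1]) * em[:, t]
        alpha[:, t] = a / a.sum(axis=1, keepdims=True)
    beta[:, T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        b = (em[:, t + 1] * beta[:, t + 1]) @ trans[t].T
        beta[:, t] = b / b.sum(axis=1, keepdims=True)
    post = alpha * beta
    return post / post.sum(axis=2, keepdims=True)


def call_roh(gm: GenotypeMatrix, params: ROHParams | None = None,
             apply_quality_filter: bool = True) -> list[ROHSegment]:
    """Detect autozygous segments per sample with a two-state HMM.

    States: AZ (autozygous) and HW (Hardy-Weinberg). Emission of a
    heterozygous call is `het_emission_error` under AZ and 2p(1-p) under HW
    with p the cohort allele frequency; homozygous calls emit the
    complements. Segments are maximal runs decoded AZ by posterior
    decoding (P(AZ) > 0.5); segment quality is the mean of per-site phred
    confidences -10*log10(1 - P(AZ)), which unlike a phred of the mean
    posterior is not saturated by the handful of boundary sites.
    """
    params = params or ROHParams()
    if gm.ploidy != 2:
        raise ValueError("ROH calling requires diploid genotypes")
    if not gm.sorted_by_position():
        raise ValueError("positions must be sorted within chromosomes")

    p = np.nan_to_num(gm.alt_freq(), nan=0.0)
    p_het_hw = np.clip(2 * p * (1 - p), 1e-6, 1 - 1e-6)
    e = params.het_emission_error
    q_az = 1.0 / params.expected_az_bp      # rate of leaving AZ
    q_hw = 1.0 / params.expected_hw_bp
    pi_az = q_hw / (q_az + q_hw)
    pi = np.array([pi_az, 1 - pi_az])       # state order: [AZ, HW]

    log_e_het = np.log(e) if e > 0 else -745.0
    log_e_hom = np.log1p(-e)
    segments: list[ROHSegment] = []
    for c in dict.fromkeys(gm.chrom):
        sel = np.flatnonzero(gm.chrom == c)
        pos = gm.pos[sel]
        hw_het = p_het_hw[sel]

        def _transitions(positions: np.ndarray) -> np.ndarray:
            dd = np.diff(positions).astype(float)
            dec = np.exp(-(q_az + q_hw) * dd)
            tr = np.empty((len(dd), 2, 2))
            tr[:, 0, 0] = pi[0] + pi[1] * dec
            tr[:, 0, 1] = pi[1] * (1 - dec)
            tr[:, 1, 0] = pi[0] * (1 - dec)
            tr[:, 1, 1] = pi[1] + pi[0] * dec
            return tr

        def _emit_segments(sample_ids, obs, post_az):
            # post_az: (n_samples_in_batch, n_obs_sites)
            for bi, sample in enumerate(sample_ids):
                in_az = post_az[bi] > 0.5
                edges = np.diff(np.concatenate(([0], in_az.view(np.int8), [0])))
                for s0, e0 in zip(np.flatnonzero(edges == 1),
                                  np.flatnonzero(edges == -1) - 1):
                    run = obs[s0:e0 + 1]
                    if run.size < params.min_sites:
                        continue
                    phred = -10.0 * np.log10(
                        np.clip(1.0 - post_az[bi, s0:e0 + 1], 1e-10, 1.0))
                    segments.append(ROHSegment(
                        sample=sample, chrom=c, start_bp=int(pos[run[0]]),
                        end_bp=int(pos[run[-1]]), n_sites=int(run.size),
                        quality=float(phred.mean())))

        gsub = gm.gt[:, sel]
        complete = ~np.any(gsub == MISSING, axis=1)

        # samples with no missing data share transitions -> one batched pass
        batch = np.flatnonzero(complete)
        if batch.size and len(pos) >= params.min_sites:
            het = gsub[batch] == 1
            log_em = np.empty((batch.size, len(pos), 2))
            log_em[:, :, 0] = np.where(het, log_e_het, log_e_hom)
            log_em[:, :, 1] = np.where(het, np.log(hw_het)[None, :],
                                       np.log1p(-hw_het)[None, :])
            post = _forward_backward(log_em, _transitions(pos), pi)[:, :, 0]
            _emit_segments([gm.samples[i] for i in batch],
                           np.arange(len(pos)), post)

        for i in np.flatnonzero(~complete):
            g = gsub[i]
            obs = np.flatnonzero(g != MISSING)
            if obs.size < params.min_sites:
                continue
            het = g[obs] == 1
            log_em = np.empty((1, obs.size, 2))
            log_em[0, :, 0] = np.where(het, log_e_het, log_e_hom)
            log_em[0, :, 1] = np.where(het, np.log(hw_het[obs]),
                                       np.log1p(-hw_het[obs]))
            post = _forward_backward(log_em, _transitions(pos[obs]), pi)[:, :, 0]
            _emit_segments([gm.samples[i]], obs, post)
    segments.sort(key=lambda s: (s.sample, s.chrom, s.start_bp))
    if apply_quality_filter:
        segments = [s for s in segments if s.quality > params.min_quality]
    return segments


@dataclass
class ROHClassModel:
    population: str
    means: np.ndarray       # log10(bp), increasing
    sds: np.ndarray
    weights: np.ndarray
    boundaries: tuple[float, float]   # (b1, b2) in log10(bp), b1 < b2
    fallback: bool = False
    log_likelihood: float = np.nan

    def classify(self, length_bp) -> np.ndarray:
        x = np.log10(np.asarray(length_bp, dtype=float))
        b1, b2 = self.boundaries
        return np.select([x <= b1, x <= b2], ["short", "medium"],
                         default="long")


def _posterior_crossing(m1, s1, w1, m2, s2, w2) -> float:
    """log-length between two component means where responsibility flips."""
    grid = np.linspace(m1, m2, 2001)
    from scipy.stats import norm
    r1 = w1 * norm.pdf(grid, m1, s1)
    r2 = w2 * norm.pdf(grid, m2, s2)
    flip = np.flatnonzero(r2 >= r1)
    if flip.size == 0:
        return float((m1 + m2) / 2)
    return float(grid[flip[0]])


def fit_roh_classes(segments: list[ROHSegment],
                    populations: dict[str, str] | None = None,
                    n_restarts: int = 5, random_state: int = 0,
                    min_segments: int = 30) -> dict[str, ROHClassModel]:
    """Three-component Gaussian mixture on log10(length) per population.

    Populations with fewer than `min_segments` segments fall back to a
    pooled model (with a warning). Components are ordered by mean; class
    boundaries are the responsibility flip points between adjacent
    components. Segment labels are set in place.
    """
    if not segments:
        raise ValueError("no segments to classify")
    if populations is None:
        populations = {}
    pop_of = lambda s: populations.get(s.sample, "ALL")
    groups: dict[str, list[ROHSegment]] = {}
    for seg in segments:
        groups.setdefault(pop_of(seg), []).append(seg)

    pooled = _fit_single([np.log10(s.length_bp) for s in segments], "POOLED",
                         n_restarts, random_state)
    models: dict[str, ROHClassModel] = {}
    for pop, segs in groups.items():
        if len(segs) < min_segments:
            warnings.warn(f"population {pop!r}: only {len(segs)} segments; "
                          "using pooled class model")
            models[pop] = ROHClassModel(
                population=pop, means=pooled.means, sds=pooled.sds,
                weights=pooled.weights, boundaries=pooled.boundaries,
                fallback=True, log_likelihood=pooled.log_likelihood)
        else:
            models[pop] = _fit_single([np.log10(s.length_bp) for s in segs],
                                      pop, n_restarts, random_state)
        for s in segs:
            s.label = str(models[pop].classify([s.length_bp])[0])
    return models


def _fit_single(logs, population: str, n_restarts: int,
                random_state: int) -> ROHClassModel:
    x = np.asarray(logs, dtype=float).reshape(-1, 1)
    try:
        gmm = GaussianMixture(n_components=3, n_init=n_restarts,
                              random_state=random_state, reg_covar=1e-6)
        gmm.fit(x)
        means = gmm.means_.ravel()
        sds = np.sqrt(gmm.covariances_.ravel())
        weights = gmm.weights_.ravel()
        order = np.argsort(means)
        means, sds, weights = means[order], sds[order], weights[order]
        if weights.min() < 1e-3 or sds.min() < 1e-4:
            raise ValueError("degenerate mixture fit")
        b1 = _posterior_crossing(means[0], sds[0], weights[0],
                                 means[1], sds[1], weights[1])
        b2 = _posterior_crossing(means[1], sds[1], weights[1],
                                 means[2], sds[2], weights[2])
        if not b1 < b2:
            raise ValueError("boundaries not ordered")
        return ROHClassModel(population=population, means=means, sds=sds,
                             weights=weights, boundaries=(b1, b2),
                             log_likelihood=float(gmm.score(x) * len(x)))
    except Exception as exc:  # EM degeneracy -> quantile fallback
        warnings.warn(f"mixture fit failed for {population!r} ({exc}); "
                      "quantile fallback boundaries")
        b1, b2 = np.quantile(x, [1 / 3, 2 / 3])
        return ROHClassModel(population=population,
                             means=np.quantile(x, [1 / 6, 0.5, 5 / 6]),
                             sds=np.full(3, x.std() + 1e-9),
                             weights=np.full(3, 1 / 3),
                             boundaries=(float(b1), float(b2)), fallback=True)


@dataclass
class InbreedingReport:
    table: pd.DataFrame   # sample, obs_hom, exp_hom, n_usable, F


def inbreeding_f(gm: GenotypeMatrix, min_usable: int = 100) -> InbreedingReport:
    """Method-of-moments excess-homozygosity F per sample.

    F = (O - E) / (M - E) with O the observed homozygous count, E the
    expected count under Hardy-Weinberg at cohort frequencies (with the
    n/(n-1) small-sample correction on heterozygosity) and M the usable
    site count. Samples with fewer than `min_usable` usable sites get NaN.
    Cohort frequencies include the focal sample (documented behavior).
    """
    if gm.ploidy != 2:
        raise ValueError("inbreeding F requires diploid genotypes")
    p = gm.alt_freq()
    n_alleles = gm.called_allele_count().astype(float)
    poly = np.isfinite(p) & (p > 0) & (p < 1) & (n_alleles >= 2)
    exp_het = 2 * p * (1 - p) * np.where(n_alleles > 1,
                                         n_alleles / (n_alleles - 1), np.nan)

    rows = []
    for i, s in enumerate(gm.samples):
        usable = poly & (gm.gt[i] != MISSING)
        m = int(usable.sum())
        obs_hom = int(((gm.gt[i] == 0) | (gm.gt[i] == 2))[usable].sum())
        exp_hom = float((1 - exp_het[usable]).sum())
        if m < min_usable or m == exp_hom:
            f = np.nan
        else:
            f = (obs_hom - exp_hom) / (m - exp_hom)
        rows.append((s, obs_hom, exp_hom, m, f))
    return InbreedingReport(table=pd.DataFrame(
        rows, columns=["sample", "obs_hom", "exp_hom", "n_usable", "F"]))


def roh_summaries(segments: list[ROHSegment], gene_bed: list[BedInterval],
                  classes: tuple[str, ...] = ("short", "medium", "long")) -> pd.DataFrame:
    """Per-sample per-class cumulative length/count plus contained-gene count.

    A gene counts only when its interval is completely inside one segment
    (BED half-open intervals reconciled to 1-based inclusive coordinates).
    """
    by_sample: dict[str, list[ROHSegment]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample, []).append(seg)

    genes = sorted(((iv.chrom, iv.start + 1, iv.end) for iv in gene_bed
                    if iv.end > iv.start))
    rows = []
    for sample, segs in sorted(by_sample.items()):
        rec: dict = {"sample": sample}
        for cl in classes:
            sel = [s for s in segs if s.label == cl]
            rec[f"n_{cl}"] = len(sel)
            rec[f"bp_{cl}"] = int(sum(s.length_bp for s in sel))
        rec["n_segments"] = len(segs)
        rec["bp_total"] = int(sum(s.length_bp for s in segs))
        # sorted sweep over (chrom, start)
        seg_sorted = sorted(segs, key=lambda s: (s.chrom, s.start_bp))
        count = 0
        for gchrom, gstart, gend in genes:
            for s in seg_sorted:
                if s.chrom != gchrom or s.start_bp > gstart:
                    continue
                if s.end_bp >= gend:
                    count += 1
                    break
        rec["n_genes_contained"] = count
        rows.append(rec)
    return pd.DataFrame(rows)


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.sample, s.chrom, s.start_bp, s.end_bp, s.n_sites, s.quality,
          s.label or "") for s in segments],
        columns=["sample", "chrom", "start", "end", "n_sites", "quality",
                 "class"])
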