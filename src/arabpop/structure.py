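"""Population-structure summaries: LD pruning, PCA, allele sharing and
dominant-ancestry cluster assignment from admixture fractions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from arabpop.core import MISSING, GenotypeMatrix, QMatrix

ADMIXED = "ADMIXED"


def _imputed_dosage(gm: GenotypeMatrix) -> np.ndarray:
    """Float dosage matrix with missing calls replaced by the site mean."""
    x = gm.gt.astype(float)
    x[gm.gt == MISSING] = np.nan
    means = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
    means = np.nan_to_num(means, nan=0.0)
    ii = np.where(np.isnan(x))
    x[ii] = means[ii[1]]
    return x


def ld_prune(gm: GenotypeMatrix, r2_max: float = 0.2, window_snps: int = 50,
             step_snps: int = 5) -> np.ndarray:
    """Greedy windowed LD pruning; returns retained site indices.

    Within each sliding window, correlated pairs (r^2 > r2_max, pairs
    visited left to right) drop the member with the lower minor allele
    frequency (tie: the later position). Monomorphic sites are skipped from
    the r^2 computation and always retained.
    """
    if window_snps < 2:
        raise ValueError("window must span >= 2 SNPs")
    x = _imputed_dosage(gm)
    sd = x.std(axis=0)
    maf = np.minimum(np.nan_to_num(gm.alt_freq(), nan=0.0),
                     1 - np.nan_to_num(gm.alt_freq(), nan=0.0))
    keep = np.ones(gm.n_sites, dtype=bool)

    for c in dict.fromkeys(gm.chrom):
        idx = np.flatnonzero(gm.chrom == c)
        for start in range(0, len(idx), step_snps):
            win = idx[start:start + window_snps]
            active = [j for j in win if keep[j] and sd[j] > 0]
            if len(active) < 2:
                continue
            sub = x[:, active]
            r = np.corrcoef(sub, rowvar=False)
            for a in range(len(active)):
                ja = active[a]
                if not keep[ja]:
                    continue
                for b in range(a + 1, len(active)):
                    jb = active[b]
                    if not keep[jb]:
                        continue
                    if r[a, b] ** 2 > r2_max:
                        if maf[ja] < maf[jb]:
                            keep[ja] = False
                            break
                        elif maf[jb] < maf[ja]:
                            keep[jb] = False
                        else:  # tie -> drop the later position
                            keep[jb] = False
            if start + window_snps >= len(idx):
                break
    return np.flatnonzero(keep)


@dataclass
class PCAResult:
    scores: np.ndarray        # (n_samples, n_components)
    eigenvalues: np.ndarray   # non-increasing
    loadings: np.ndarray      # (n_sites_used, n_components)
    site_index: np.ndarray    # sites that entered (polymorphic)
    total_variance: float


def pca(gm: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """PCA of standardized genotypes.

    Sites are mean-imputed, centered by 2*p_hat and scaled by
    sqrt(2*p_hat*(1-p_hat)); the sample covariance matrix is
    eigendecomposed. Sign convention: the largest-magnitude loading of each
    component is positive.
    """
    x = _imputed_dosage(gm)
    p = x.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    site_index = np.flatnonzero(poly)
    z = (x[:, poly] - 2 * p[poly]) / np.sqrt(2 * p[poly] * (1 - p[poly]))

    m = z.shape[1]
    cov = z @ z.T / m
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0, None)

    rank = int((evals > 1e-10 * max(evals[0], 1)).sum())
    if n_components > rank:
        import warnings
        warnings.warn(f"requested {n_components} components but rank is {rank}; truncating")
        n_components = rank
    evals_k = evals[:n_components]
    u = evecs[:, :n_components]

    with np.errstate(divide="ignore", invalid="ignore"):
        load = z.T @ u / np.sqrt(np.where(evals_k > 0, evals_k * m, 1.0))
    for k in range(n_components):
        j = np.argmax(np.abs(load[:, k]))
        if load[j, k] < 0:
            load[:, k] *= -1
            u[:, k] *= -1
    scores = u * np.sqrt(evals_k)
    return PCAResult(scores=scores, eigenvalues=evals_k, loadings=load,
                     site_index=site_index, total_variance=float(np.trace(cov)))


def allele_sharing(cohort_a: GenotypeMatrix, cohort_b: GenotypeMatrix) -> float:
    """Fraction of A's segregating sites that also segregate in B.

    Both cohorts must already be harmonized to the same site universe
    (see qc.intersect_sites). "Segregating" means the non-reference allele
    is observed at least once. Not symmetric by design.
    """
    keys_a = cohort_a.site_keys()
    keys_b = cohort_b.site_keys()
    if keys_a != keys_b:
        raise ValueError("cohorts are not harmonized to the same site universe")
    seg_a = cohort_a.alt_allele_count() > 0
    seg_b = cohort_b.alt_allele_count() > 0
    n_a = int(seg_a.sum())
    if n_a == 0:
        raise ValueError("cohort A has no segregating sites; sharing undefined")
    return float((seg_a & seg_b).sum() / n_a)


@dataclass
class AncestryAssignment:
    labels: dict[str, str]     # sample -> component label or ADMIXED
    max_fraction: dict[str, float]
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample": list(self.labels),
            "label": list(self.labels.values()),
            "max_q": [self.max_fraction[s] for s in self.labels],
        })


def assign_dominant_ancestry(qm: QMatrix, threshold: float = 0.5) -> AncestryAssignment:
    """Label each sample by its dominant ancestry component.

    A sample gets the argmax component label iff its maximum fraction meets
    the threshold and is unique; exact ties (e.g. 0.5/0.5 at threshold 0.5)
    and sub-threshold maxima are ADMIXED.
    """
    qm.validate_rows()
    labels: dict[str, str] = {}
    max_frac: dict[str, float] = {}
    for s, row in zip(qm.samples, qm.q):
        mx = row.max()
        max_frac[s] = float(mx)
        if mx >= threshold and int((row == mx).sum()) == 1:
            labels[s] = qm.components[int(np.argmax(row))]
        else:
            labels[s] = ADMIXED
    return AncestryAssignment(labels=labels, max_fraction=max_frac,
                              threshold=threshold)
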