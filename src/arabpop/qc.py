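"""Sample- and variant-level quality control.

Variant rules (applied in documented order: missingness -> minor allele
count -> Hardy-Weinberg -> exclusion regions) and per-sample missingness /
outlier screening. The HWE test is the exact conditional test rather than
chi-square, so it stays valid at the rare-variant end where the default
1e-5 threshold bites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from arabpop.core import MISSING, GenotypeMatrix
from arabpop.vcfio import BedInterval

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class VariantFilterSpec:
    max_missingness: float = 0.01
    min_minor_allele_count: int = 3       # excludes MAC <= 2
    hwe_p_threshold: float = 1e-5
    exclusion_regions: list[BedInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missingness <= 1.0:
            raise ValueError("max_missingness must be in [0, 1]")
        if self.min_minor_allele_count < 0:
            raise ValueError("min_minor_allele_count must be >= 0")
        if not 0.0 <= self.hwe_p_threshold <= 1.0:
            raise ValueError("hwe_p_threshold must be in [0, 1]")


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg p-value.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities that do not exceed the observed
    configuration's probability. Monomorphic sites return 1 by convention.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be >= 0")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotype required")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    # Probabilities over feasible het counts (same parity as n_rare), built
    # by recurrence from the mode outward for numerical stability.
    het_values = list(range(n_rare % 2, n_rare + 1, 2))
    mid = int(round(n_rare * (2 * n - n_rare) / (2.0 * n - 1.0)))
    if mid % 2 != n_rare % 2:
        mid += 1 if mid < n_rare else -1
    probs = {mid: 1.0}
    # going down: P(h-2) = P(h) * h(h-1) / ((r-h+2)(c-h+2)) with
    # r = n_rare homs*2 relation; derive from multinomial-conditional pmf.
    h = mid
    while h >= 2:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
    h = mid
    while h + 2 <= n_rare:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2) * (h + 1))
        h += 2
    total = sum(probs.values())
    obs = probs[n_het] / total
    p = sum(v for v in probs.values() if v / total <= obs * (1 + 1e-12)) / total
    return min(1.0, p)


@dataclass
class SampleQCReport:
    table: pd.DataFrame        # one row per input sample
    retained: list[str]
    excluded: dict[str, list[str]]   # sample -> rules that fired

    RULES = ("total_missingness", "per_chrom_missingness",
             "outlier_variant_count", "outlier_nonref_count",
             "outlier_het_count", "outlier_het_ratio", "outlier_titv")


def sample_qc(gm: GenotypeMatrix, total_missingness_max: float = 0.05,
              per_chrom_missingness_max: float = 0.20,
              sd_multiplier: float = 3.0,
              exclude_outliers: bool = False):
    """Per-sample metrics, missingness exclusions and 3-SD outlier flags.

    Missingness rules exclude; outlier rules only flag unless
    `exclude_outliers` is set. Returns (SampleQCReport, retained list).
    """
    if gm.n_samples < 2:
        raise ValueError("sample QC needs >= 2 samples")
    called = gm.called_mask()
    miss_total = gm.sample_missingness()

    chroms = list(dict.fromkeys(gm.chrom))
    per_chrom = {}
    for c in chroms:
        sel = gm.chrom == c
        per_chrom[c] = 1.0 - called[:, sel].mean(axis=1)
    worst_chrom_miss = np.max(np.vstack(list(per_chrom.values())), axis=0) \
        if chroms else np.zeros(gm.n_samples)

    nonref = ((gm.gt > 0) & called).sum(axis=1)
    het = (gm.gt == 1).sum(axis=1)
    hom_alt = (gm.gt == 2).sum(axis=1)
    n_variants = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_ratio = np.where(het + hom_alt > 0, het / (het + hom_alt), np.nan)

    is_ts = np.array([(r, a) in TRANSITIONS for r, a in zip(gm.ref, gm.alt)])
    ts = ((gm.gt > 0) & called)[:, is_ts].sum(axis=1)
    tv = ((gm.gt > 0) & called)[:, ~is_ts].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        titv = np.where(tv > 0, ts / tv, np.nan)

    def _outliers(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        ok = np.isfinite(x)
        if ok.sum() < 2:
            return np.zeros_like(x, dtype=bool)
        mu, sd = x[ok].mean(), x[ok].std(ddof=0)
        if sd == 0:
            return np.zeros_like(x, dtype=bool)
        return ok & (np.abs(x - mu) > sd_multiplier * sd)

    flags: dict[str, list[str]] = {s: [] for s in gm.samples}
    for i, s in enumerate(gm.samples):
        if miss_total[i] > total_missingness_max:
            flags[s].append("total_missingness")
        if worst_chrom_miss[i] > per_chrom_missingness_max:
            flags[s].append("per_chrom_missingness")
    for name, metric in (("outlier_variant_count", n_variants),
                         ("outlier_nonref_count", nonref),
                         ("outlier_het_count", het),
                         ("outlier_het_ratio", het_ratio),
                         ("outlier_titv", titv)):
        for i in np.flatnonzero(_outliers(metric)):
            flags[gm.samples[i]].append(name)

    hard = {"total_missingness", "per_chrom_missingness"}
    if exclude_outliers:
        hard = set(SampleQCReport.RULES)
    excluded = {s: f for s, f in flags.items() if set(f) & hard}
    retained = [s for s in gm.samples if s not in excluded]
    if not retained:
        tally: dict[str, int] = {}
        for f in excluded.values():
            for r in f:
                tally[r] = tally.get(r, 0) + 1
        raise RuntimeError(f"sample QC excluded every sample; rule tally: {tally}")

    table = pd.DataFrame({
        "sample": gm.samples,
        "missingness": miss_total,
        "worst_chrom_missingness": worst_chrom_miss,
        "n_variants": n_variants,
        "n_nonref": nonref,
        "n_het": het,
        "het_ratio": het_ratio,
        "titv": titv,
        "flags": [";".join(flags[s]) for s in gm.samples],
        "retained": [s in set(retained) for s in gm.samples],
    })
    for c in chroms:
        table[f"missingness_{c}"] = per_chrom[c]
    return SampleQCReport(table=table, retained=retained, excluded=excluded), retained


def _in_regions(chrom: np.ndarray, pos: np.ndarray,
                regions: list[BedInterval]) -> np.ndarray:
    hit = np.zeros(len(pos), dtype=bool)
    for iv in regions:
        # BED is 0-based half-open; VCF pos is 1-based.
        hit |= (chrom == iv.chrom) & (pos - 1 >= iv.start) & (pos - 1 < iv.end)
    return hit


def site_hwe_pvalues(gm: GenotypeMatrix) -> np.ndarray:
    """Exact HWE p per site from non-missing diploid genotype counts."""
    if gm.ploidy != 2:
        raise ValueError("HWE is defined for diploid genotypes")
    n_hom_ref = (gm.gt == 0).sum(axis=0)
    n_het = (gm.gt == 1).sum(axis=0)
    n_hom_alt = (gm.gt == 2).sum(axis=0)
    return np.array([
        hwe_exact_test(int(a), int(b), int(c)) if a + b + c > 0 else 1.0
        for a, b, c in zip(n_hom_ref, n_het, n_hom_alt)
    ])


def variant_filter(gm: GenotypeMatrix, spec: VariantFilterSpec | None = None):
    """Apply site filters; returns (filtered matrix, per-rule exclusion counts).

    A site survives iff missingness <= max, MAC >= min, HWE p >= threshold
    and it lies outside every exclusion region. Counts attribute each
    excluded site to the first failing rule.
    """
    spec = spec or VariantFilterSpec()
    miss = gm.site_missingness()
    alt = gm.alt_allele_count()
    tot = gm.called_allele_count()
    mac = np.minimum(alt, tot - alt)
    hwe_p = site_hwe_pvalues(gm) if gm.ploidy == 2 else np.ones(gm.n_sites)
    in_region = _in_regions(gm.chrom, gm.pos, spec.exclusion_regions)

    fail_miss = miss > spec.max_missingness
    fail_mac = mac < spec.min_minor_allele_count
    fail_hwe = hwe_p < spec.hwe_p_threshold
    keep = ~(fail_miss | fail_mac | fail_hwe | in_region)

    first_fail = np.full(gm.n_sites, "", dtype=object)
    for name, mask in (("missingness", fail_miss), ("mac", fail_mac),
                       ("hwe", fail_hwe), ("region", in_region)):
        first_fail[(first_fail == "") & mask] = name
    counts = {name: int((first_fail == name).sum())
              for name in ("missingness", "mac", "hwe", "region")}
    return gm.take_sites(np.flatnonzero(keep)), counts


def intersect_sites(cohorts: list[GenotypeMatrix]):
    """Merge >= 2 cohorts on their common (chrom,pos,ref,alt) site set.

    Sites present at the same (chrom,pos) in every cohort but with
    mismatched ref/alt are dropped and counted (no strand flipping).
    Returns (merged GenotypeMatrix, n_allele_mismatch_dropped).
    """
    if len(cohorts) < 2:
        raise ValueError("need >= 2 cohorts to intersect")
    ploidy = cohorts[0].ploidy
    if any(c.ploidy != ploidy for c in cohorts):
        raise ValueError("cohorts differ in ploidy")
    all_samples = [s for c in cohorts for s in c.samples]
    if len(set(all_samples)) != len(all_samples):
        raise ValueError("duplicate sample IDs across cohorts")

    full_keys = [dict(zip(zip(c.chrom, c.pos, c.ref, c.alt),
                          range(c.n_sites))) for c in cohorts]
    pos_keys = [set(zip(c.chrom, c.pos)) for c in cohorts]

    base = cohorts[0]
    kept_rows: list[tuple] = []
    mismatched = 0
    for j in range(base.n_sites):
        key = (base.chrom[j], base.pos[j], base.ref[j], base.alt[j])
        if all(key in fk for fk in full_keys[1:]):
            kept_rows.append(key)
        elif all(key[:2] in pk for pk in pos_keys[1:]):
            mismatched += 1

    if not kept_rows:
        import warnings
        warnings.warn("site intersection is empty")
    idx_per = [[fk[k] for k in kept_rows] for fk in full_keys]
    gt = (np.vstack([c.gt[:, idx] for c, idx in zip(cohorts, idx_per)])
          if kept_rows else
          np.empty((len(all_samples), 0), dtype=np.int8))
    pops = None
    if all(c.populations is not None for c in cohorts):
        pops = np.concatenate([c.populations for c in cohorts])
    merged = GenotypeMatrix(
        samples=all_samples,
        chrom=np.array([k[0] for k in kept_rows], dtype=object),
        pos=np.array([k[1] for k in kept_rows], dtype=np.int64),
        ref=np.array([k[2] for k in kept_rows], dtype=object),
        alt=np.array([k[3] for k in kept_rows], dtype=object),
        gt=gt, ploidy=ploidy, populations=pops)
    return merged, mismatched
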