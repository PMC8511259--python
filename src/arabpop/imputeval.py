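"""Imputation-panel evaluation: variant-discovery saturation, pseudo-array
masking, simple stand-in imputers and aggregate-R2 accuracy in allele
frequency bins.

The stand-in imputers exist only to exercise the evaluator end-to-end;
their quality scores are NOT comparable to a real imputation engine's r2
(the quality threshold is applied to whatever score column is supplied).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from arabpop.core import MISSING, GenotypeMatrix

DEFAULT_BIN_EDGES = (0.001, 0.01, 0.1, 0.5, 1.0)


@dataclass
class SaturationCurve:
    counts: np.ndarray          # (n_permutations, n_samples) cumulative sites
    mean_curve: np.ndarray
    log_slope: float            # sites per unit ln(samples) over the tail
    growth_per_100: float       # % growth per 100 samples at the cohort end


def saturation_curve(gm: GenotypeMatrix, n_permutations: int = 10,
                     seed: int = 0) -> SaturationCurve:
    """Distinct segregating sites discovered as samples accumulate.

    For each random sample ordering, counts sites carrying >= 1
    non-reference allele among the first k samples. The tail (second half)
    of the mean curve is fit as count ~ a + b*ln(k).
    """
    if gm.n_samples < 2:
        raise ValueError("saturation needs >= 2 samples")
    rng = np.random.default_rng(seed)
    carrier = (gm.gt > 0)
    n, m = gm.n_samples, gm.n_sites
    curves = np.zeros((n_permutations, n), dtype=np.int64)
    for r in range(n_permutations):
        perm = rng.permutation(n)
        ranks = np.empty(n, dtype=np.int64)
        ranks[perm] = np.arange(n)
        first = np.where(carrier, ranks[:, None], n).min(axis=0)
        counts = np.bincount(first[first < n], minlength=n)
        curves[r] = np.cumsum(counts)
    mean_curve = curves.mean(axis=0)

    tail = np.arange(max(1, n // 2), n)
    if tail.size >= 2 and np.ptp(mean_curve[tail]) > 0:
        A = np.vstack([np.ones(tail.size), np.log(tail + 1)]).T
        coef, *_ = np.linalg.lstsq(A, mean_curve[tail], rcond=None)
        slope = float(coef[1])
    else:
        slope = 0.0
    if n > 1 and mean_curve[-1] > 0:
        prev = mean_curve[max(0, n - 101)]
        growth = 100.0 * (mean_curve[-1] - prev) / prev if prev > 0 else np.nan
    else:
        growth = np.nan
    return SaturationCurve(counts=curves, mean_curve=mean_curve,
                           log_slope=slope, growth_per_100=float(growth))


def make_pseudo_array(truth: GenotypeMatrix, manifest: pd.DataFrame):
    """Restrict a truth callset to manifest (typed) sites.

    Returns (typed GenotypeMatrix, typed site indices, withheld site
    indices, n_manifest_rows_dropped). Manifest rows matching no truth site
    are dropped and counted; an empty intersection is fatal.
    """
    truth_keys = {(c, p): j for j, (c, p) in enumerate(zip(truth.chrom, truth.pos))}
    typed, dropped = [], 0
    for c, p in zip(manifest["chrom"], manifest["pos"]):
        j = truth_keys.get((str(c), int(p)))
        if j is None:
            dropped += 1
        else:
            typed.append(j)
    if not typed:
        raise ValueError("manifest shares no sites with the truth callset")
    typed = np.unique(typed)
    withheld = np.setdiff1d(np.arange(truth.n_sites), typed)
    return truth.take_sites(typed), typed, withheld, dropped


def impute_naive(pseudo: GenotypeMatrix, panel: GenotypeMatrix,
                 typed_idx: np.ndarray, withheld_idx: np.ndarray,
                 method: str = "nearest_haplotype"):
    """Stand-in imputers over a shared site universe.

    `panel` covers the full site universe (typed + withheld);`pseudo` holds
    the target genotypes at typed sites only, in `typed_idx` order.

    freq: every withheld dosage is 2 x panel non-reference AF (constant per
    site); quality 0 by convention. nearest_haplotype: per target sample,
    the panel sample minimizing genotype mismatches at typed sites (tie:
    lowest panel index) donates its genotypes at withheld sites; quality is
    1 - mismatch rate of the chosen donor.

    Returns (dosages (n_targets, n_withheld), per-site quality scores).
    """
    if panel.n_samples == 0:
        raise ValueError("empty reference panel")
    n_t = pseudo.n_samples
    n_w = len(withheld_idx)
    paf = np.nan_to_num(panel.alt_freq()[withheld_idx], nan=0.0)

    if method == "freq":
        dos = np.tile(2.0 * paf, (n_t, 1))
        return dos, np.zeros(n_w)
    if method != "nearest_haplotype":
        raise ValueError(f"unknown imputation method {method!r}")

    panel_typed = panel.gt[:, typed_idx]
    dos = np.empty((n_t, n_w))
    match_rates = np.empty(n_t)
    for i in range(n_t):
        g = pseudo.gt[i]
        ok = (g != MISSING) & (panel_typed != MISSING)
        mism = ((panel_typed != g[None, :]) & ok).sum(axis=1)
        denom = np.maximum(ok.sum(axis=1), 1)
        rates = mism / denom
        best = int(np.argmin(mism))      # tie -> lowest panel index
        donor = panel.gt[best, withheld_idx].astype(float)
        miss = donor == MISSING
        donor[miss] = 2.0 * paf[miss]
        dos[i] = donor
        match_rates[i] = 1.0 - rates[best]
    quality = np.full(n_w, float(match_rates.mean()))
    return dos, quality


@dataclass
class AFBinSpec:
    edges: tuple = DEFAULT_BIN_EDGES

    def __post_init__(self) -> None:
        e = tuple(self.edges)
        if any(b <= a for a, b in zip(e, e[1:])) or e[-1] != 1.0:
            raise ValueError("bin edges must be strictly increasing and end at 1")
        self.edges = e

    def labels(self) -> list[str]:
        lo = (0.0,) + self.edges[:-1]
        return [f"({a},{b}]" for a, b in zip(lo, self.edges)]

    def assign(self, af: np.ndarray) -> np.ndarray:
        """Bin index per frequency; -1 for af <= 0 (monomorphic reference)."""
        idx = np.searchsorted(np.asarray(self.edges), af, side="left")
        idx = np.where(af <= 0, -1, np.minimum(idx, len(self.edges) - 1))
        return idx


def aggregate_r2(truth: GenotypeMatrix, dosages: np.ndarray,
                 withheld_idx: np.ndarray, bins: AFBinSpec | None = None,
                 af: np.ndarray | None = None,
                 panel: GenotypeMatrix | None = None,
                 quality: np.ndarray | None = None,
                 quality_min: float | None = None) -> pd.DataFrame:
    """Pooled squared correlation between truth genotypes and dosages per AF bin.

    AF for bin membership comes from `af` if given, else the panel's
    non-reference AF, else the truth AF. Pairs pool across all variants and
    samples in a bin; bins with < 2 pairs or zero-variance truth are
    flagged undefined. When `quality`/`quality_min` are given, the per-bin
    count of variants above the threshold is reported and the R2 is also
    computed on that subset.
    """
    bins = bins or AFBinSpec()
    if af is None:
        src = panel if panel is not None else truth
        af = np.nan_to_num(src.alt_freq()[withheld_idx], nan=0.0)
    af = np.asarray(af, dtype=float)
    tr = truth.gt[:, withheld_idx].astype(float)
    tr[truth.gt[:, withheld_idx] == MISSING] = np.nan
    bin_idx = bins.assign(af)

    rows = []
    for b, label in enumerate(bins.labels()):
        in_bin = np.flatnonzero(bin_idx == b)
        t = tr[:, in_bin].ravel()
        d = np.asarray(dosages)[:, in_bin].ravel()
        ok = np.isfinite(t)
        t, d = t[ok], d[ok]
        n_pairs = t.size
        r2, reason = _pooled_r2(t, d)
        n_hq = np.nan
        if quality is not None and quality_min is not None:
            n_hq = int((np.asarray(quality)[in_bin] > quality_min).sum())
        rows.append({"bin": label, "n_variants": int(in_bin.size),
                     "n_pairs": int(n_pairs), "r2": r2, "undefined_reason": reason,
                     "n_quality_pass": n_hq})
    return pd.DataFrame(rows)


def _pooled_r2(t: np.ndarray, d: np.ndarray):
    if t.size < 2:
        return np.nan, "fewer than 2 pairs"
    if np.var(t) == 0:
        return np.nan, "constant truth"
    if np.var(d) == 0:
        return 0.0, ""
    r = np.corrcoef(t, d)[0, 1]
    return float(r ** 2), ""


def per_variant_r2(truth: GenotypeMatrix, dosages: np.ndarray,
                   withheld_idx: np.ndarray) -> np.ndarray:
    """Diagnostic per-variant squared correlation (NaN where undefined)."""
    tr = truth.gt[:, withheld_idx].astype(float)
    tr[truth.gt[:, withheld_idx] == MISSING] = np.nan
    out = np.full(len(withheld_idx), np.nan)
    for j in range(len(withheld_idx)):
        t = tr[:, j]
        ok = np.isfinite(t)
        if ok.sum() < 2 or np.var(t[ok]) == 0 or np.var(dosages[ok, j]) == 0:
            continue
        out[j] = np.corrcoef(t[ok], dosages[ok, j])[0, 1] ** 2
    return out
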