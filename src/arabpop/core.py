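"""Core in-memory data structures shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1  # sentinel for a missing genotype call


@dataclass
class GenotypeMatrix:
    """Samples x biallelic variants.

    Genotypes are stored as an int8 array of shape ``(n_samples, n_sites)``
    holding alternate-allele dosages: 0/1/2 for diploid calls, 0/1 for
    haploid calls, and -1 for missing. Positions are 1-based (VCF
    convention) and must be sorted within each chromosome.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    gt: np.ndarray
    ploidy: int = 2
    populations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        if self.gt.shape != (len(self.samples), len(self.pos)):
            raise ValueError(
                f"genotype matrix shape {self.gt.shape} does not match "
                f"{len(self.samples)} samples x {len(self.pos)} sites"
            )
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        hi = self.ploidy
        bad = (self.gt > hi) | (self.gt < MISSING)
        if bad.any():
            raise ValueError("genotype values out of range for ploidy")
        if self.populations is not None:
            self.populations = np.asarray(self.populations, dtype=object)
            if len(self.populations) != len(self.samples):
                raise ValueError("populations length != sample count")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def site_keys(self) -> list[tuple]:
        """(chrom, pos, ref, alt) identity key per site."""
        return list(zip(self.chrom, self.pos, self.ref, self.alt))

    def called_mask(self) -> np.ndarray:
        return self.gt != MISSING

    def alt_allele_count(self) -> np.ndarray:
        """Per-site alternate allele count over non-missing calls."""
        g = np.where(self.gt == MISSING, 0, self.gt)
        return g.sum(axis=0).astype(np.int64)

    def called_allele_count(self) -> np.ndarray:
        """Per-site number of observed alleles (ploidy x called samples)."""
        return self.called_mask().sum(axis=0).astype(np.int64) * self.ploidy

    def alt_freq(self) -> np.ndarray:
        """Per-site alternate allele frequency; NaN where no calls."""
        n = self.called_allele_count()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, self.alt_allele_count() / n, np.nan)

    def site_missingness(self) -> np.ndarray:
        return 1.0 - self.called_mask().mean(axis=0)

    def sample_missingness(self) -> np.ndarray:
        if self.n_sites == 0:
            return np.zeros(self.n_samples)
        return 1.0 - self.called_mask().mean(axis=1)

    @staticmethod
    def _index_array(idx) -> np.ndarray:
        idx = np.asarray(idx)
        if idx.dtype == bool:
            return np.flatnonzero(idx)
        return idx.astype(np.int64)

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = self._index_array(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            gt=self.gt[:, idx],
            ploidy=self.ploidy,
            populations=self.populations,
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = self._index_array(idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            gt=self.gt[idx, :],
            ploidy=self.ploidy,
            populations=None if self.populations is None else self.populations[idx],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            gt=self.gt.copy(),
            ploidy=self.ploidy,
            populations=None if self.populations is None else self.populations.copy(),
        )

    def sorted_by_position(self) -> bool:
        for c in dict.fromkeys(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                return False
        return True


def percentage(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage share of `count` in `total`, rounded to `ndigits`."""
    if total <= 0:
        raise ValueError("total must be positive")
    if count < 0 or count > total:
        raise ValueError("count must lie in [0, total]")
    return round(100.0 * count / total, ndigits)


@dataclass
class QMatrix:
    """Per-sample ancestry fractions over K components."""

    samples: list[str]
    components: list[str]
    q: np.ndarray
    row_tol: float = 1e-6

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (len(self.samples), len(self.components)):
            raise ValueError("Q shape does not match samples x components")
        if len(self.components) < 2:
            raise ValueError("QMatrix needs K >= 2 components")
        if np.any(self.q < -1e-12) or np.any(self.q > 1 + 1e-12):
            raise ValueError("Q fractions must lie in [0, 1]")

    @property
    def k(self) -> int:
        return len(self.components)

    def validate_rows(self, tol: float | None = None) -> None:
        tol = self.row_tol if tol is None else tol
        sums = self.q.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > tol):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"Q row for sample {self.samples[bad]!r} sums to {sums[bad]:.8f}"
            )


@dataclass
class BlockStatResult:
    """An f-statistic with block-jackknife uncertainty."""

    statistic: float
    se: float
    z: float
    n_blocks: int
    n_sites_used: int
    populations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_blocks < 2:
            raise ValueError("block jackknife needs >= 2 blocks")
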