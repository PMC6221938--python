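"""Fixed-bin copy-number profiling.

The pipeline divides the genome into non-overlapping fixed-width bins
(50 kb by default), counts read starts per bin, forms library-normalized
tumor/normal log2 ratios, and offers profile comparison, an
instability score (fraction of genome altered) and an amplitude
attenuation factor between two profiles.

No GC/mappability correction and no segmentation are performed; bins with
unreliable normal coverage are masked instead of smoothed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeBuild, is_sex_chrom

#: p-values below this are reported textually as "< 2.2e-16" (R convention).
P_FLOOR = 2.2e-16


class DegenerateInputError(ValueError):
    """Raised when a statistic is undefined (zero variance, too few bins)."""


# ---------------------------------------------------------------------------
# binning


@dataclass(frozen=True)
class GenomeBinning:
    """Non-overlapping, exhaustive fixed-width binning of a genome build.

    Bins are 0-based half-open ``(chrom, start, end)`` triples in build
    chromosome order; the last bin of each chromosome may be truncated.
    The tuple index is the stable global bin index.
    """

    build: GenomeBuild
    bin_size: int
    bins: tuple[tuple[str, int, int], ...]
    _chrom_offset: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        offsets: dict[str, int] = {}
        pos = 0
        for name, length in self.build.chromosomes:
            offsets[name] = pos
            pos += -(-length // self.bin_size)
        if pos != len(self.bins):
            raise ValueError("bins do not tile the build")
        object.__setattr__(self, "_chrom_offset", offsets)

    def __len__(self) -> int:
        return len(self.bins)

    def chrom_offset(self, chrom: str) -> int:
        return self._chrom_offset[chrom]

    def n_bins_of(self, chrom: str) -> int:
        return -(-self.build.length_of(chrom) // self.bin_size)

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing 0-based position ``pos``."""
        if chrom not in self.build:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < self.build.length_of(chrom):
            raise ValueError(f"position {pos} outside {chrom}")
        return self._chrom_offset[chrom] + pos // self.bin_size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.bins, columns=["chrom", "start", "end"])


def make_bins(build: GenomeBuild, bin_size: int = 50_000) -> GenomeBinning:
    """Tile every chromosome with ``bin_size`` bins, truncating the last.

    Per chromosome the bins are ``[0,b), [b,2b), ...``; ordering follows the
    build's chromosome order, then start coordinate.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    bins: list[tuple[str, int, int]] = []
    for name, length in build.chromosomes:
        for start in range(0, length, bin_size):
            bins.append((name, start, min(start + bin_size, length)))
    return GenomeBinning(build=build, bin_size=int(bin_size), bins=tuple(bins))


# ---------------------------------------------------------------------------
# counts


@dataclass
class BinnedCounts:
    """Per-bin non-negative read counts over a :class:`GenomeBinning`."""

    binning: GenomeBinning
    counts: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.binning),):
            raise ValueError(
                f"counts length {self.counts.shape} does not match binning ({len(self.binning)} bins)"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    def scaled(self, factor: int) -> "BinnedCounts":
        """Counts multiplied by an integer factor (library-size scaling)."""
        return BinnedCounts(self.binning, self.counts * int(factor), self.sample_id)

    def to_frame(self) -> pd.DataFrame:
        df = self.binning.to_frame()
        df["count"] = self.counts
        return df


def count_reads(
    reads: pd.DataFrame,
    binning: GenomeBinning,
    on_unknown_chrom: str = "error",
) -> BinnedCounts:
    """Assign each read to exactly one bin by its 5'-most start coordinate.

    Parameters
    ----------
    reads
        BED-like frame with ``chrom`` and ``start`` columns (0-based starts).
    on_unknown_chrom
        ``"error"`` (default) raises on a read whose chromosome is not in
        the build; ``"skip"`` drops such reads (counted in no bin).
    """
    if on_unknown_chrom not in ("error", "skip"):
        raise ValueError("on_unknown_chrom must be 'error' or 'skip'")
    counts = np.zeros(len(binning), dtype=np.int64)
    if len(reads) == 0:
        return BinnedCounts(binning, counts)

    chroms = reads["chrom"].to_numpy()
    starts = reads["start"].to_numpy(dtype=np.int64)
    known = np.isin(chroms, binning.build.names)
    if not known.all():
        bad = sorted(set(chroms[~known]))
        if on_unknown_chrom == "error":
            raise KeyError(f"reads on chromosomes absent from build: {bad}")
        chroms, starts = chroms[known], starts[known]
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        s = starts[sel]
        length = binning.build.length_of(chrom)
        if (s < 0).any() or (s >= length).any():
            raise ValueError(f"read start outside chromosome {chrom}")
        idx = binning.chrom_offset(chrom) + s // binning.bin_size
        np.add.at(counts, idx, 1)
    return BinnedCounts(binning, counts)


# ---------------------------------------------------------------------------
# logR profiles


@dataclass
class CNVProfile:
    """Per-bin log2 ratio profile with a validity mask.

    ``logr`` is NaN wherever ``mask`` is True; unmasked values are finite.
    """

    binning: GenomeBinning
    logr: np.ndarray
    mask: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.logr = np.asarray(self.logr, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.logr.shape != (len(self.binning),) or self.mask.shape != self.logr.shape:
            raise ValueError("logr/mask length must match binning")
        if not np.isfinite(self.logr[~self.mask]).all():
            raise ValueError("unmasked logr values must be finite")

    @property
    def unmasked_logr(self) -> np.ndarray:
        return self.logr[~self.mask]

    def autosome_selector(self) -> np.ndarray:
        return np.array([not is_sex_chrom(c) for c, _, _ in self.binning.bins])

    def to_frame(self) -> pd.DataFrame:
        df = self.binning.to_frame()
        df["logr"] = self.logr
        df["masked"] = self.mask
        df.insert(0, "sample", self.sample_id)
        return df


def compute_logr(
    tumor: BinnedCounts,
    normal: BinnedCounts,
    min_normal_count: int = 10,
) -> CNVProfile:
    """Library-normalized, median-centered tumor/normal log2 ratio per bin.

    Bins whose normal count falls below ``min_normal_count`` are masked.
    For unmasked bins ``logr = log2((t_i/T) / (n_i/N))`` with per-bin counts
    t, n and library totals T, N; a tumor count of zero is replaced by 0.5
    to keep the ratio finite without inventing signal. The profile is then
    centered by subtracting the median of unmasked values, so a balanced
    genome sits at zero.
    """
    if tumor.binning is not normal.binning and tumor.binning != normal.binning:
        raise ValueError("tumor and normal counts must share a binning")
    if tumor.total_reads == 0 or normal.total_reads == 0:
        raise ValueError("both samples need non-zero total reads")
    t = tumor.counts.astype(float)
    n = normal.counts.astype(float)
    mask = n < min_normal_count
    if mask.all():
        raise DegenerateInputError("all bins masked: normal coverage too low everywhere")
    t = np.where(t == 0, 0.5, t)
    logr = np.full(len(t), np.nan)
    valid = ~mask
    logr[valid] = np.log2((t[valid] / tumor.total_reads) / (n[valid] / normal.total_reads))
    logr[valid] -= np.median(logr[valid])
    return CNVProfile(tumor.binning, logr, mask, sample_id=tumor.sample_id)


@dataclass(frozen=True)
class ProfileComparison:
    """Pearson correlation between two profiles over jointly unmasked bins."""

    r: float
    p: float
    n_bins: int

    @property
    def p_text(self) -> str:
        return f"< {P_FLOOR:g}" if self.p < P_FLOOR else f"{self.p:.4g}"


def _joint_values(
    a: CNVProfile, b: CNVProfile, exclude_sex_chroms: bool
) -> tuple[np.ndarray, np.ndarray]:
    if a.binning != b.binning:
        raise ValueError("profiles must share a binning")
    ok = ~a.mask & ~b.mask
    if exclude_sex_chroms:
        ok &= a.autosome_selector()
    return a.logr[ok], b.logr[ok]


def compare_profiles(
    a: CNVProfile, b: CNVProfile, exclude_sex_chroms: bool = True
) -> ProfileComparison:
    """Pearson r and two-sided p (t-transform, n-2 df) between two profiles."""
    x, y = _joint_values(a, b, exclude_sex_chroms)
    if len(x) < 3:
        raise DegenerateInputError("need at least 3 jointly unmasked bins")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("degenerate (constant) profile")
    res = stats.pearsonr(x, y)
    return ProfileComparison(r=float(res.statistic), p=float(res.pvalue), n_bins=len(x))


def instability_score(
    profile: CNVProfile,
    logr_threshold: float = 0.15,
    exclude_sex_chroms: bool = True,
) -> float:
    """Fraction of unmasked bins with ``|logr| >= logr_threshold`` (FGA)."""
    if logr_threshold <= 0:
        raise ValueError("logr_threshold must be positive")
    ok = ~profile.mask
    if exclude_sex_chroms:
        ok &= profile.autosome_selector()
    values = profile.logr[ok]
    if len(values) == 0:
        raise DegenerateInputError("no unmasked bins")
    return float(np.mean(np.abs(values) >= logr_threshold))


def attenuation_factor(
    observed: CNVProfile, reference: CNVProfile, exclude_sex_chroms: bool = True
) -> float:
    """Through-origin least-squares slope of observed on reference logR.

    1 means equal amplitude; below 1 the observed profile is attenuated
    toward zero (low tumor fraction or heterogeneity).
    """
    x, y = _joint_values(reference, observed, exclude_sex_chroms)
    if len(x) < 3:
        raise DegenerateInputError("need at least 3 jointly unmasked bins")
    denom = float(np.dot(x, x))
    if denom == 0:
        raise DegenerateInputError("reference profile has no amplitude")
    return float(np.dot(x, y) / denom)


def profile_to_seg_frame(profile: CNVProfile) -> pd.DataFrame:
    """SEG-like per-bin TSV frame (sample, chrom, start, end, logr, masked)."""
    return profile.to_frame()
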