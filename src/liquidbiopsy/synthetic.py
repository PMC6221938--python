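"""Synthetic inputs with known ground truth for every pipeline stage.

Generators emulate the statistical structure the analysis assumes: Poisson
loading of template molecules into ~20,000 nanoliter droplets, tumor/normal
binned read counts under a segmental integer-copy-number truth with tumor
purity, and annotated variant tables with known survivor sets for the
filter cascade.

Every generator takes an explicit seed and is bit-reproducible; there is no
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cnv import BinnedCounts, GenomeBinning
from .ddpcr import DropletWell
from .genome import GenomeBuild
from .variants import Consequence, Sift, VariantRecord

DEFAULT_BIN_SIZE = 50_000

# Small invented census list for synthetic cancer-census hits; the real
# census is user-supplied at the CLI boundary.
_SYNTH_COSMIC_GENES = ("TP53", "KRAS", "ERG", "BRAF", "PIK3CA", "PTEN")
_SYNTH_NET_GENES = ("MEN1", "DAXX", "ATRX", "EPAS1")
_SYNTH_NEUTRAL_GENES = ("GPR15", "SULF2", "DOCK2", "NBEAL1", "MYH11", "ZZZ3")

VARIANT_CATEGORIES = (
    "common",
    "synonymous",
    "low_vaf",
    "net_gene",
    "cosmic",
    "high_cadd",
    "fail_all",
)


def default_build(
    n_chromosomes: int = 22,
    bins_per_chromosome: int = 136,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> GenomeBuild:
    """Toy desk-scale build: 22 chromosomes of 6.8 Mb (~3,000 50 kb bins).

    Chromosome lengths are exact multiples of ``bin_size`` so truth-segment
    boundaries snapped to bin edges tile chromosomes exactly.
    """
    length = bins_per_chromosome * bin_size
    return GenomeBuild(tuple((f"chr{i}", length) for i in range(1, n_chromosomes + 1)))


# ---------------------------------------------------------------------------
# copy-number truth


@dataclass(frozen=True)
class CopyNumberTruth:
    """Ground-truth integer copy segments covering a build, plus purity."""

    build: GenomeBuild
    segments: tuple[tuple[str, int, int, int], ...]  # chrom, start, end, copies
    purity: float = 1.0
    ploidy_normal: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must lie in [0, 1]")
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for chrom, start, end, copies in self.segments:
            if copies < 0:
                raise ValueError("copy number must be >= 0")
            if not 0 <= start < end <= self.build.length_of(chrom):
                raise ValueError(f"segment {chrom}:{start}-{end} out of bounds")
            by_chrom.setdefault(chrom, []).append((start, end, copies))
        for name, length in self.build.chromosomes:
            segs = sorted(by_chrom.get(name, []))
            pos = 0
            for start, end, _ in segs:
                if start != pos:
                    raise ValueError(f"coverage gap/overlap on {name} at {pos}")
                pos = end
            if pos != length:
                raise ValueError(f"{name} not fully covered by segments")

    @classmethod
    def from_events(
        cls,
        build: GenomeBuild,
        events: Sequence[tuple[str, int, int, int]],
        purity: float = 1.0,
    ) -> "CopyNumberTruth":
        """Build a full truth from non-diploid events; gaps become copy 2."""
        by_chrom: dict[str, list[tuple[str, int, int, int]]] = {
            name: [] for name, _ in build.chromosomes
        }
        for chrom, start, end, copies in events:
            by_chrom[chrom].append((chrom, start, end, copies))
        segments: list[tuple[str, int, int, int]] = []
        for name, length in build.chromosomes:
            pos = 0
            for chrom, start, end, copies in sorted(by_chrom[name], key=lambda e: e[1]):
                if start < pos:
                    raise ValueError(f"overlapping events on {name}")
                if start > pos:
                    segments.append((name, pos, start, 2))
                segments.append((name, start, end, copies))
                pos = end
            if pos < length:
                segments.append((name, pos, length, 2))
        return cls(build=build, segments=tuple(segments), purity=purity)

    def copy_at(self, chrom: str, pos: int) -> int:
        for c, start, end, copies in self.segments:
            if c == chrom and start <= pos < end:
                return copies
        raise ValueError(f"position {chrom}:{pos} not covered")

    def copy_per_bin(self, binning: GenomeBinning) -> np.ndarray:
        """Truth copy number of each bin, assigned by bin midpoint."""
        out = np.full(len(binning), self.ploidy_normal, dtype=np.int64)
        for chrom, start, end, copies in self.segments:
            if copies == self.ploidy_normal:
                continue
            offset = binning.chrom_offset(chrom)
            # midpoints of bins [i*b, (i+1)*b) fall in [start, end) iff the
            # midpoint coordinate does; segment edges are bin-aligned in
            # generated truths, so this is exact there.
            for i in range(binning.n_bins_of(chrom)):
                b_start, b_end = binning.bins[offset + i][1:3]
                mid = (b_start + b_end) // 2
                if start <= mid < end:
                    out[offset + i] = copies
        return out

    def expected_depth_factor(self, binning: GenomeBinning) -> np.ndarray:
        """Per-bin depth multiplier: (purity*c + (1-purity)*ploidy) / ploidy."""
        c = self.copy_per_bin(binning).astype(float)
        return (self.purity * c + (1.0 - self.purity) * self.ploidy_normal) / self.ploidy_normal

    @property
    def n_non_diploid_segments(self) -> int:
        return sum(1 for *_, copies in self.segments if copies != self.ploidy_normal)

    def to_dict(self) -> dict:
        return {
            "purity": self.purity,
            "ploidy_normal": self.ploidy_normal,
            "segments": [list(s) for s in self.segments],
        }


def simulate_copy_number_truth(
    build: GenomeBuild,
    n_events: int,
    seed: int,
    copy_range: tuple[int, int] = (0, 4),
    purity: float = 1.0,
    event_bins_range: tuple[int, int] = (10, 60),
    bin_size: int = DEFAULT_BIN_SIZE,
    max_tries: int = 1000,
) -> CopyNumberTruth:
    """Place ``n_events`` non-diploid segments uniformly without overlap.

    Segment boundaries are snapped to ``bin_size`` edges so bins never
    straddle truth segments. Copy numbers are drawn uniformly from
    ``copy_range`` excluding the diploid value. Raises if the events cannot
    be placed on the build within ``max_tries`` attempts each.
    """
    lo, hi = copy_range
    if not (0 <= lo <= hi <= 8):
        raise ValueError("copy_range must lie within [0, 8]")
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    allowed_copies = [c for c in range(lo, hi + 1) if c != 2]
    if n_events > 0 and not allowed_copies:
        raise ValueError("copy_range contains no non-diploid copy number")

    rng = np.random.default_rng(seed)
    chrom_bins = {name: length // bin_size for name, length in build.chromosomes}
    names = list(chrom_bins)
    weights = np.array([chrom_bins[n] for n in names], dtype=float)
    weights /= weights.sum()

    placed: dict[str, list[tuple[int, int]]] = {n: [] for n in names}  # bin spans
    events: list[tuple[str, int, int, int]] = []
    for _ in range(n_events):
        for attempt in range(max_tries):
            chrom = names[rng.choice(len(names), p=weights)]
            n_bins = chrom_bins[chrom]
            span = int(rng.integers(event_bins_range[0], event_bins_range[1] + 1))
            span = min(span, n_bins)
            start_bin = int(rng.integers(0, n_bins - span + 1))
            end_bin = start_bin + span
            if all(end_bin <= s or start_bin >= e for s, e in placed[chrom]):
                placed[chrom].append((start_bin, end_bin))
                copies = int(allowed_copies[rng.integers(len(allowed_copies))])
                events.append((chrom, start_bin * bin_size, end_bin * bin_size, copies))
                break
        else:
            raise ValueError(
                f"could not place {n_events} non-overlapping events on this build"
            )
    return CopyNumberTruth.from_events(build, events, purity=purity)


def simulate_binned_counts(
    truth: CopyNumberTruth,
    binning: GenomeBinning,
    mean_depth_per_bin: float,
    dispersion: float = 0.0,
    seed: int = 0,
    sample_id: str = "",
) -> BinnedCounts:
    """Draw per-bin read counts under the truth's copy state and purity.

    Each bin's expectation is ``mean_depth_per_bin * (purity*c +
    (1-purity)*2) / 2`` with c the truth copy number at the bin midpoint.
    ``dispersion=0`` gives Poisson draws; ``dispersion>0`` gives a
    gamma-Poisson mixture with variance ``mean * (1 + dispersion * mean)``.
    """
    if mean_depth_per_bin <= 0:
        raise ValueError("mean_depth_per_bin must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    mu = mean_depth_per_bin * truth.expected_depth_factor(binning)
    if dispersion == 0:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / dispersion
        lam = np.where(mu > 0, rng.gamma(shape, np.maximum(mu, 1e-300) / shape), 0.0)
        counts = rng.poisson(lam)
    return BinnedCounts(binning, counts.astype(np.int64), sample_id=sample_id)


def simulate_read_positions(
    counts: BinnedCounts, seed: int = 0, read_length: int = 100
) -> pd.DataFrame:
    """Emit a BED-like frame with exactly ``counts[b]`` reads inside bin b.

    Each read interval lies fully within its bin, so re-counting by read
    start reproduces ``counts`` exactly (round-trip identity).
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, int, int]] = []
    for (chrom, start, end), k in zip(counts.binning.bins, counts.counts):
        if k == 0:
            continue
        length = min(read_length, end - start)
        starts = rng.integers(start, end - length + 1, size=int(k))
        rows.extend((chrom, int(s), int(s) + length) for s in np.sort(starts))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# droplets


@dataclass(frozen=True)
class DropletTruth:
    """Generative parameters for one simulated well."""

    lambda_mut: float
    lambda_wt: float
    n_droplets: int = 20_000
    droplet_volume_nl: float = 0.85

    def __post_init__(self) -> None:
        if self.lambda_mut < 0 or self.lambda_wt < 0:
            raise ValueError("lambdas must be >= 0")
        if self.n_droplets <= 0:
            raise ValueError("n_droplets must be positive")
        if self.droplet_volume_nl <= 0:
            raise ValueError("droplet_volume_nl must be positive")


def simulate_droplet_well(truth: DropletTruth, seed: int = 0) -> DropletWell:
    """Poisson-load mutant and WT molecules independently into droplets.

    Each droplet's class follows from the presence of each molecule type;
    class counts always sum to ``n_droplets``.
    """
    rng = np.random.default_rng(seed)
    mut = rng.poisson(truth.lambda_mut, truth.n_droplets) > 0
    wt = rng.poisson(truth.lambda_wt, truth.n_droplets) > 0
    return DropletWell(
        n_mut_only=int(np.sum(mut & ~wt)),
        n_wt_only=int(np.sum(~mut & wt)),
        n_double=int(np.sum(mut & wt)),
        n_negative=int(np.sum(~mut & ~wt)),
    )


DEFAULT_CHANNEL_MEANS = ((1000.0, 8000.0), (900.0, 6000.0))


def simulate_droplet_amplitudes(
    well: DropletWell,
    channel_means: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_CHANNEL_MEANS,
    noise_sd: float = 200.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-channel amplitudes for every droplet of a classified well.

    ``channel_means`` is ``((ch1_negative, ch1_positive), (ch2_negative,
    ch2_positive))``; channel 1 carries the mutant probe, channel 2 the WT
    probe. Gaussian noise with independent channels; the positive and
    negative means must be separated by at least 4 * ``noise_sd`` per
    channel so that thresholding recovers the input classes exactly.
    """
    (ch1_neg, ch1_pos), (ch2_neg, ch2_pos) = channel_means
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for neg, pos in channel_means:
        if pos - neg < 4 * noise_sd or pos <= neg:
            raise ValueError(
                "channel means not separable: positive mean must exceed negative "
                "mean by at least 4 * noise_sd"
            )
    rng = np.random.default_rng(seed)
    # class -> (mutant present, WT present)
    spec = [
        (well.n_mut_only, True, False),
        (well.n_wt_only, False, True),
        (well.n_double, True, True),
        (well.n_negative, False, False),
    ]
    ch1 = np.concatenate(
        [np.full(n, ch1_pos if m else ch1_neg) for n, m, _ in spec]
    )
    ch2 = np.concatenate(
        [np.full(n, ch2_pos if w else ch2_neg) for n, _, w in spec]
    )
    labels = np.concatenate(
        [
            np.full(well.n_mut_only, "mut_only"),
            np.full(well.n_wt_only, "wt_only"),
            np.full(well.n_double, "double"),
            np.full(well.n_negative, "negative"),
        ]
    )
    if noise_sd > 0:
        ch1 = ch1 + rng.normal(0.0, noise_sd, len(ch1))
        ch2 = ch2 + rng.normal(0.0, noise_sd, len(ch2))
    order = rng.permutation(len(ch1))
    return pd.DataFrame(
        {"ch1": ch1[order], "ch2": ch2[order], "true_class": labels[order]}
    )


# ---------------------------------------------------------------------------
# variant tables


@dataclass(frozen=True)
class VariantTableTruth:
    """Ground truth accompanying a simulated variant table."""

    survivor_keys: frozenset[str]
    target_key: Optional[str]
    category_of: dict[str, str] = field(default_factory=dict)


def _draw_position(rng: np.random.Generator, used: set[tuple[str, int]]) -> tuple[str, int]:
    while True:
        chrom = f"chr{int(rng.integers(1, 23))}"
        pos = int(rng.integers(1, 10_000_000))
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            return chrom, pos


def simulate_variant_table(
    seed: int,
    n_per_category: Optional[Mapping[str, int]] = None,
    cadd_min: float = 20.0,
    min_vaf: float = 0.20,
    max_af: float = 0.01,
) -> tuple[list[VariantRecord], VariantTableTruth]:
    """Generate an annotated variant table exercising every cascade clause.

    Categories: ``common`` (population AF above cutoff), ``synonymous``,
    ``low_vaf`` (below the VAF floor), ``net_gene`` / ``cosmic`` /
    ``high_cadd`` (filter-passing with the respective priority hook) and
    ``fail_all`` (filter-passing but matching no priority tier).

    CADD scores are drawn distinct across the table so the expected target
    is unique; the returned truth carries the survivor key set and the
    expected selected target. Record order is shuffled.
    """
    counts = {c: 0 for c in VARIANT_CATEGORIES}
    if n_per_category:
        unknown = set(n_per_category) - set(VARIANT_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown variant categories: {sorted(unknown)}")
        counts.update({k: int(v) for k, v in n_per_category.items()})
    if any(v < 0 for v in counts.values()):
        raise ValueError("category counts must be >= 0")

    rng = np.random.default_rng(seed)
    total = sum(counts.values())
    # distinct CADD values on a 0.01 grid in [0, cadd_min) and [cadd_min, 45]
    low_grid = np.arange(0.0, cadd_min - 0.5, 0.01)
    high_grid = np.arange(cadd_min, 45.0, 0.01)
    low_cadd = list(rng.choice(low_grid, size=min(total, len(low_grid)), replace=False))
    high_cadd = list(rng.choice(high_grid, size=min(total, len(high_grid)), replace=False))

    bases = "ACGT"
    used: set[tuple[str, int]] = set()
    records: list[VariantRecord] = []
    category_of: dict[str, str] = {}

    def base_pair() -> tuple[str, str]:
        ref = bases[rng.integers(4)]
        alt = bases[rng.integers(4)]
        while alt == ref:
            alt = bases[rng.integers(4)]
        return ref, alt

    def rare_afs() -> dict:
        out = {}
        for name in ("af_dbsnp", "af_exac", "af_1000g"):
            if rng.random() < 0.5:
                out[name] = None  # absent from database counts as rare
            else:
                out[name] = float(rng.uniform(0, max_af * 0.9))
        return out

    def high_vaf() -> float:
        return float(rng.uniform(min_vaf, 0.9))

    for category, n in counts.items():
        for _ in range(n):
            chrom, pos = _draw_position(rng, used)
            ref, alt = base_pair()
            gene = str(rng.choice(_SYNTH_NEUTRAL_GENES))
            kwargs = dict(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene=gene,
                consequence=Consequence.NONSYNONYMOUS,
                vaf_tumor=high_vaf(),
                cadd_phred=float(low_cadd.pop()),
                sift=Sift.TOLERATED,
                in_net_genes=False,
                in_cosmic_census=False,
                **rare_afs(),
            )
            if category == "common":
                hot = str(rng.choice(("af_dbsnp", "af_exac", "af_1000g")))
                kwargs[hot] = float(rng.uniform(max_af, 0.5))
            elif category == "synonymous":
                kwargs["consequence"] = Consequence.SYNONYMOUS
            elif category == "low_vaf":
                kwargs["vaf_tumor"] = float(rng.uniform(0.0, min_vaf * 0.95))
            elif category == "net_gene":
                kwargs["gene"] = str(rng.choice(_SYNTH_NET_GENES))
                kwargs["in_net_genes"] = True
                kwargs["cadd_phred"] = float(high_cadd.pop())
                kwargs["sift"] = Sift.DELETERIOUS
            elif category == "cosmic":
                kwargs["gene"] = str(rng.choice(_SYNTH_COSMIC_GENES))
                kwargs["in_cosmic_census"] = True
                kwargs["cadd_phred"] = float(high_cadd.pop())
            elif category == "high_cadd":
                kwargs["cadd_phred"] = float(high_cadd.pop())
                kwargs["sift"] = Sift.DELETERIOUS
            # fail_all keeps the low CADD, tolerated SIFT, no gene-set flags
            record = VariantRecord(**kwargs)
            records.append(record)
            category_of[record.key] = category

    order = rng.permutation(len(records))
    records = [records[i] for i in order]

    surviving_categories = ("net_gene", "cosmic", "high_cadd", "fail_all")
    survivors = frozenset(
        k for k, cat in category_of.items() if cat in surviving_categories
    )

    target_key: Optional[str] = None
    for tier_cats in (("net_gene",), ("cosmic",), ("high_cadd",), ("fail_all",)):
        tier_records = [
            r for r in records if category_of[r.key] in tier_cats
        ]
        if tier_records:
            target_key = max(tier_records, key=lambda r: r.cadd_phred).key
            break

    return records, VariantTableTruth(
        survivor_keys=survivors, target_key=target_key, category_of=category_of
    )
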