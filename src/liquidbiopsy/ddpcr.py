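"""Droplet digital PCR quantification with Poisson occupancy correction.

A reaction is partitioned into ~20,000 nanoliter droplets; each droplet is
called mutant-only, wild-type-only, double-positive or negative from its
two-channel fluorescence. Mean molecules per droplet are recovered from the
positive fraction via lambda = -ln(1 - p), which corrects for multiple
template molecules co-occupying one droplet.

Conventions (documented, configurable):

* a double-positive droplet counts toward BOTH the mutant-positive and the
  WT-positive totals — it contains at least one molecule of each;
* VAF is computed from the corrected lambdas, not raw droplet counts;
* the positivity rule and the detection limit use mutant-containing
  droplets (mutant-only + double-positive);
* the detection-limit denominator defaults to all non-negative droplets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class SaturationError(ValueError):
    """All accepted droplets positive: concentration is unquantifiable."""


class ThresholdError(ValueError):
    """Automatic thresholding failed (channel not bimodal enough)."""


# ---------------------------------------------------------------------------
# well and config


@dataclass(frozen=True)
class DropletWell:
    """Class counts for one well: mutant-only / WT-only / double / negative."""

    n_mut_only: int
    n_wt_only: int
    n_double: int
    n_negative: int

    def __post_init__(self) -> None:
        for name in ("n_mut_only", "n_wt_only", "n_double", "n_negative"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.n_accepted <= 0:
            raise ValueError("well must contain at least one accepted droplet")

    @property
    def n_accepted(self) -> int:
        return self.n_mut_only + self.n_wt_only + self.n_double + self.n_negative

    @property
    def n_mut_positive(self) -> int:
        """Droplets containing at least one mutant molecule."""
        return self.n_mut_only + self.n_double

    @property
    def n_wt_positive(self) -> int:
        return self.n_wt_only + self.n_double

    @property
    def n_any_positive(self) -> int:
        """All non-negative (informative) droplets."""
        return self.n_mut_only + self.n_wt_only + self.n_double


@dataclass(frozen=True)
class QuantConfig:
    """Volumes and thresholds for one quantification.

    ``droplet_volume_nl`` defaults to the QX200 convention (0.85 nL).
    Eluate and plasma volumes have no safe default: when either is absent
    the per-mL-plasma outputs are omitted rather than guessed.
    """

    droplet_volume_nl: float = 0.85
    reaction_volume_ul: float = 20.0
    template_volume_ul: float = 9.0
    elution_volume_ul: Optional[float] = None
    plasma_volume_ml: Optional[float] = None
    positivity_threshold: int = 2

    def __post_init__(self) -> None:
        for name in ("droplet_volume_nl", "reaction_volume_ul", "template_volume_ul"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("elution_volume_ul", "plasma_volume_ml"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when given")
        if self.positivity_threshold < 1:
            raise ValueError("positivity_threshold must be >= 1")

    @property
    def per_ml_plasma_factor(self) -> Optional[float]:
        """copies-in-reaction -> copies per mL plasma, or None if volumes missing.

        The reaction contains ``template/elution`` of the eluate, which holds
        all cfDNA from ``plasma_volume_ml`` of plasma.
        """
        if self.elution_volume_ul is None or self.plasma_volume_ml is None:
            return None
        return (self.elution_volume_ul / self.template_volume_ul) / self.plasma_volume_ml


@dataclass(frozen=True)
class QuantResult:
    """Poisson-corrected quantities for one sample/well."""

    lambda_mut: float
    lambda_wt: float
    conc_mut: float  # copies/uL of reaction
    conc_wt: float
    vaf: float
    positive: bool
    detection_limit: Optional[float]
    copies_per_ml_plasma_mut: Optional[float] = None
    copies_per_ml_plasma_wt: Optional[float] = None
    droplets_per_ml_plasma_mut: Optional[float] = None
    droplets_per_ml_plasma_wt: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "lambda_mut": self.lambda_mut,
            "lambda_wt": self.lambda_wt,
            "conc_mut_copies_per_ul": self.conc_mut,
            "conc_wt_copies_per_ul": self.conc_wt,
            "vaf": self.vaf,
            "positive": self.positive,
            "detection_limit": self.detection_limit,
            "copies_per_ml_plasma_mut": self.copies_per_ml_plasma_mut,
            "copies_per_ml_plasma_wt": self.copies_per_ml_plasma_wt,
            "droplets_per_ml_plasma_mut": self.droplets_per_ml_plasma_mut,
            "droplets_per_ml_plasma_wt": self.droplets_per_ml_plasma_wt,
        }


# ---------------------------------------------------------------------------
# droplet classification


def _two_means_1d(values: np.ndarray) -> tuple[float, float, float]:
    """Exact 1-D two-cluster split minimizing within-cluster variance.

    Returns (low_center, high_center, pooled_within_sd).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    # candidate splits: low cluster = x[:k], high = x[k:], k = 1..n-1
    k = np.arange(1, n)
    sum_lo, sq_lo = csum[k - 1], csq[k - 1]
    sum_hi, sq_hi = csum[-1] - sum_lo, csq[-1] - sq_lo
    ss_lo = sq_lo - sum_lo**2 / k
    ss_hi = sq_hi - sum_hi**2 / (n - k)
    best = int(np.argmin(ss_lo + ss_hi))
    k_best = best + 1
    lo = sum_lo[best] / k_best
    hi = sum_hi[best] / (n - k_best)
    pooled_sd = math.sqrt(max(ss_lo[best] + ss_hi[best], 0.0) / n)
    return lo, hi, pooled_sd


def auto_threshold(values: Sequence[float], min_separation_sds: float = 3.0) -> float:
    """Midpoint between the two 1-D cluster centers of ``values``.

    Raises :class:`ThresholdError` if the centers are separated by fewer
    than ``min_separation_sds`` pooled within-cluster standard deviations
    (a non-bimodal channel needs manual thresholds). The default of 3 sits
    between the ~2.7 SD separation a two-center split extracts from a
    single Gaussian and the >=4 SD separation of genuinely bimodal data.
    """
    lo, hi, sd = _two_means_1d(np.asarray(values))
    if hi == lo or (sd > 0 and (hi - lo) < min_separation_sds * sd):
        raise ThresholdError(
            "channel does not separate into two clusters; supply manual thresholds"
        )
    return (lo + hi) / 2.0


def classify_droplets(
    amplitudes: pd.DataFrame,
    thresholds: Optional[tuple[float, float]] = None,
) -> DropletWell:
    """Call each droplet from its two-channel amplitudes.

    ``amplitudes`` needs ``ch1`` (mutant probe) and ``ch2`` (WT probe)
    columns. A droplet is positive in a channel iff its amplitude exceeds
    that channel's threshold; ``thresholds=None`` derives each threshold
    automatically as the midpoint between the channel's two cluster centers.
    """
    if len(amplitudes) < 100:
        raise ValueError("need at least 100 droplets to classify")
    ch1 = amplitudes["ch1"].to_numpy(dtype=float)
    ch2 = amplitudes["ch2"].to_numpy(dtype=float)
    if thresholds is None:
        thr1, thr2 = auto_threshold(ch1), auto_threshold(ch2)
    else:
        thr1, thr2 = thresholds
    mut = ch1 > thr1
    wt = ch2 > thr2
    return DropletWell(
        n_mut_only=int(np.sum(mut & ~wt)),
        n_wt_only=int(np.sum(~mut & wt)),
        n_double=int(np.sum(mut & wt)),
        n_negative=int(np.sum(~mut & ~wt)),
    )


# ---------------------------------------------------------------------------
# Poisson quantification


def estimate_lambda(n_positive: int, n_accepted: int) -> float:
    """Mean molecules per droplet from a positive-droplet count.

    ``lambda = -ln(1 - n_positive/n_accepted)``; exactly zero when no
    droplet is positive. An all-positive well saturates the estimator.
    """
    if n_accepted <= 0:
        raise ValueError("n_accepted must be positive")
    if n_positive < 0:
        raise ValueError("n_positive must be non-negative")
    if n_positive > n_accepted:
        raise ValueError("n_positive cannot exceed n_accepted")
    if n_positive == n_accepted:
        raise SaturationError(
            f"all {n_accepted} droplets positive: concentration unquantifiable"
        )
    if n_positive == 0:
        return 0.0
    return -math.log1p(-n_positive / n_accepted)


def call_positivity(well: DropletWell, threshold: int = 2) -> bool:
    """ctDNA-positive iff mutant-containing droplets reach ``threshold``."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return well.n_mut_positive >= threshold


def detection_limit(
    well: DropletWell,
    threshold: int = 2,
    denominator: Literal["all_positive", "wt_positive"] = "all_positive",
) -> float:
    """Smallest callable mutant fraction given the informative droplets.

    ``threshold / total positive droplets``, where the denominator is all
    non-negative droplets by default (``wt_positive`` restricts it to
    WT-containing droplets).
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    total = well.n_any_positive if denominator == "all_positive" else well.n_wt_positive
    if total < threshold:
        raise ValueError(
            f"only {total} positive droplets; detection limit undefined below threshold {threshold}"
        )
    return threshold / total


def quantify(well: DropletWell, config: QuantConfig = QuantConfig()) -> QuantResult:
    """Full Poisson-corrected quantification of one well.

    Returns lambdas, concentrations (copies/uL of reaction), lambda-based
    VAF, the positivity call, the per-sample detection limit, and — when
    eluate and plasma volumes are configured — copies and raw positive
    droplets per mL plasma.
    """
    lam_mut = estimate_lambda(well.n_mut_positive, well.n_accepted)
    lam_wt = estimate_lambda(well.n_wt_positive, well.n_accepted)
    droplet_volume_ul = config.droplet_volume_nl / 1000.0
    conc_mut = lam_mut / droplet_volume_ul
    conc_wt = lam_wt / droplet_volume_ul
    vaf = 0.0 if lam_mut + lam_wt == 0 else lam_mut / (lam_mut + lam_wt)

    positive = call_positivity(well, config.positivity_threshold)
    try:
        dl = detection_limit(well, config.positivity_threshold)
    except ValueError:
        dl = None

    per_ml = config.per_ml_plasma_factor
    copies_mut = copies_wt = droplets_mut = droplets_wt = None
    if per_ml is not None:
        copies_mut = conc_mut * config.reaction_volume_ul * per_ml
        copies_wt = conc_wt * config.reaction_volume_ul * per_ml
        droplets_mut = well.n_mut_positive * per_ml
        droplets_wt = well.n_wt_positive * per_ml

    return QuantResult(
        lambda_mut=lam_mut,
        lambda_wt=lam_wt,
        conc_mut=conc_mut,
        conc_wt=conc_wt,
        vaf=vaf,
        positive=positive,
        detection_limit=dl,
        copies_per_ml_plasma_mut=copies_mut,
        copies_per_ml_plasma_wt=copies_wt,
        droplets_per_ml_plasma_mut=droplets_mut,
        droplets_per_ml_plasma_wt=droplets_wt,
    )


def merge_wells(wells: Iterable[DropletWell]) -> DropletWell:
    """Pool replicate wells by component-wise summation."""
    wells = list(wells)
    if not wells:
        raise ValueError("cannot merge an empty list of wells")
    return DropletWell(
        n_mut_only=sum(w.n_mut_only for w in wells),
        n_wt_only=sum(w.n_wt_only for w in wells),
        n_double=sum(w.n_double for w in wells),
        n_negative=sum(w.n_negative for w in wells),
    )


def correlate_vafs(pairs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Pearson r and two-sided p between paired VAF measurements.

    p comes from the t-transform ``t = r * sqrt((n-2)/(1-r^2))`` against a
    t distribution with n-2 degrees of freedom.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    a = np.asarray([p[0] for p in pairs], dtype=float)
    b = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("degenerate variance: constant coordinate")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)
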