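"""Detection of known somatic SNVs in non-indexed pools and its evaluation.

For a variant private to one pool member, the expected pooled allele
fraction is the individual-sample fraction divided by the pool size N.
A known somatic SNV counts as *detected* when its observed pooled fraction
is at least ``0.05 / N`` — half the lowest expected value under the 0.1
individual-sample calling cutoff, leaving headroom for quantification and
sampling noise.

Evaluation uses the rarity of somatic SNVs: variants validated in a sample
*outside* a pool should be absent from it, giving known negatives.  From
the resulting confusion matrix the false discovery rate is FP / (TP + FP).
Pool-composition skew is estimated as the median ratio (MR) of observed to
expected fractions (MR > 1 = over-representation of the focal sample), and
observed fractions can be rescaled by the MR to test robustness of
detection to skew.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .counts_io import SiteCounts, UndefinedAlleleFractionError, VariantSite, allele_fraction

__all__ = [
    "ConfusionMatrix",
    "DetectionThreshold",
    "PoolDetectionResult",
    "expected_pool_af",
    "detect_known",
    "confusion_matrix",
    "false_discovery_rate",
    "median_ratio",
    "scale_allele_fractions",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/TN/FP/FN tallies from pooled detection of known sites."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class DetectionThreshold:
    """Pool detection cutoff: allele fraction >= numerator / pool_size."""

    pool_size: int
    numerator: float = 0.05

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if not 0.0 < self.numerator < 1.0:
            raise ValueError("numerator must lie in (0, 1)")

    @property
    def value(self) -> float:
        return self.numerator / self.pool_size


def expected_pool_af(individual_af: float, n: int) -> float:
    """Expected pooled fraction of a single-carrier variant: individual AF / N."""
    if n < 1:
        raise ValueError(f"pool size must be >= 1, got {n}")
    return individual_af / n


def detect_known(pool_counts: SiteCounts, threshold: DetectionThreshold) -> bool:
    """True iff the observed pooled allele fraction reaches the cutoff (inclusive).

    Raises :class:`UndefinedAlleleFractionError` at depth 0 — detection is
    undetermined there and such sites are tallied separately upstream.
    """
    return allele_fraction(pool_counts) >= threshold.value


@dataclass(frozen=True)
class PoolDetectionResult:
    """Confusion matrix plus per-site classes and depth-excluded sites."""

    cm: ConfusionMatrix
    site_class: dict[VariantSite, str]  # TP | FN | FP | TN | excluded
    excluded: tuple[VariantSite, ...]


def confusion_matrix(
    pool_counts: Iterable[SiteCounts] | Mapping[VariantSite, SiteCounts],
    positives: Iterable[VariantSite],
    negatives: Iterable[VariantSite],
    threshold: DetectionThreshold,
    *,
    min_depth: int = 1,
    low_depth_policy: str = "exclude",
) -> PoolDetectionResult:
    """Tally pooled detection over known-positive and known-negative sites.

    ``positives`` are validated somatic SNVs of a sample inside the pool;
    ``negatives`` are validated somatic SNVs of a sample outside it (rare
    somatic variants are assumed non-recurrent, so they must be absent).
    Sites with pool depth below ``min_depth`` (default 1, i.e. uncovered)
    are excluded from the tallies by default and listed separately; with
    ``low_depth_policy="undetected"`` they are instead scored as not
    detected (FN over positives, TN over negatives).
    """
    if low_depth_policy not in ("exclude", "undetected"):
        raise ValueError("low_depth_policy must be 'exclude' or 'undetected'")
    if isinstance(pool_counts, Mapping):
        by_site = dict(pool_counts)
    else:
        by_site = {c.site: c for c in pool_counts}
    pos = set(positives)
    neg = set(negatives)
    overlap = pos & neg
    if overlap:
        raise ValueError(f"positive and negative site sets overlap at {len(overlap)} sites")

    tallies = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}
    site_class: dict[VariantSite, str] = {}
    excluded: list[VariantSite] = []
    for site_set, hit, miss in ((pos, "TP", "FN"), (neg, "FP", "TN")):
        for site in sorted(site_set):
            counts = by_site.get(site)
            if counts is None or counts.depth < min_depth:
                if low_depth_policy == "exclude":
                    site_class[site] = "excluded"
                    excluded.append(site)
                    continue
                label = miss
            else:
                label = hit if detect_known(counts, threshold) else miss
            tallies[label] += 1
            site_class[site] = label
    cm = ConfusionMatrix(tp=tallies["TP"], tn=tallies["TN"], fp=tallies["FP"], fn=tallies["FN"])
    return PoolDetectionResult(cm=cm, site_class=site_class, excluded=tuple(excluded))


def false_discovery_rate(cm: ConfusionMatrix, percent: bool = True) -> float:
    """False discovery rate FP / (TP + FP), as a percentage by default."""
    called = cm.tp + cm.fp
    if called == 0:
        raise ValueError("FDR undefined: no sites were detected (TP + FP == 0)")
    fraction = cm.fp / called
    return 100.0 * fraction if percent else fraction


def median_ratio(observed: Sequence[float], expected: Sequence[float]) -> float:
    """Median of observed/expected allele-fraction ratios (the MR statistic).

    MR near 1 means the pooled fractions scatter evenly around expectation;
    MR > 1 means the focal sample is over-represented in the pool.  Sites
    with an expected fraction of 0 are excluded with a warning.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.size == 0:
        raise ValueError("observed and expected must be equal-length, non-empty")
    keep = exp > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"median_ratio: excluded {n_dropped} sites with expected AF 0", stacklevel=2)
    if not keep.any():
        raise ValueError("median_ratio undefined: all expected fractions are 0")
    return float(np.median(obs[keep] / exp[keep]))


def scale_allele_fractions(afs: Sequence[float], mr: float) -> np.ndarray:
    """Rescale observed fractions by the median ratio (capped at 1.0)."""
    if mr <= 0:
        raise ValueError(f"median ratio must be > 0, got {mr}")
    return np.minimum(np.asarray(afs, dtype=float) / mr, 1.0)
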