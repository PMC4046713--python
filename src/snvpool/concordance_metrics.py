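"""Concordance and coverage-evenness statistics.

Used to compare replicated experiments (genomic vs. whole-genome-amplified
DNA, replicate pools) and to quantify how evenly a capture covers its
target sites:

* Pearson correlation and RMSE between paired allele-fraction vectors;
* coefficient of variation (CV) of per-site depths;
* Gini index of per-site depths (0 = perfectly even coverage), using the
  mean-absolute-difference definition
  G = sum_ij |x_i - x_j| / (2 n^2 mu), with the small-sample correction
  n/(n-1) available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _stats

__all__ = [
    "MetricReport",
    "pearson_correlation",
    "rmse",
    "coefficient_of_variation",
    "gini_index",
    "percent_covered",
    "compare_allele_fractions",
]


@dataclass(frozen=True)
class MetricReport:
    """Bundle of concordance/evenness metrics for one experiment pair."""

    pearson_r: float
    rmse: float
    cv: float
    gini: float
    n_sites: int


def _paired(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError(f"length mismatch: {xa.shape} vs {ya.shape}")
    return xa, ya


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length vectors."""
    xa, ya = _paired(x, y)
    if xa.size < 2:
        raise ValueError("pearson_correlation needs at least 2 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("pearson_correlation undefined for constant input")
    return float(_stats.pearsonr(xa, ya)[0])


def rmse(x: Sequence[float], y: Sequence[float]) -> float:
    """Root mean square error between paired vectors."""
    xa, ya = _paired(x, y)
    if xa.size == 0:
        raise ValueError("rmse needs at least 1 observation")
    return float(np.sqrt(np.mean((xa - ya) ** 2)))


def coefficient_of_variation(depths: Sequence[float], ddof: int = 0) -> float:
    """Standard deviation over mean of per-site depths (population SD by default)."""
    values = np.asarray(depths, dtype=float)
    if values.size == 0:
        raise ValueError("coefficient_of_variation needs at least 1 depth")
    mean = values.mean()
    if mean <= 0:
        raise ValueError("coefficient_of_variation undefined for mean <= 0")
    if values.size - ddof <= 0:
        return 0.0
    return float(values.std(ddof=ddof) / mean)


def gini_index(depths: Sequence[float], corrected: bool = False) -> float:
    """Gini index of per-site depths.

    Mean-absolute-difference form, computed via the sorted identity
    G = 2 * sum_i i * x_(i) / (n * sum x) - (n + 1) / n.  ``corrected=True``
    applies the n/(n-1) small-sample factor.
    """
    values = np.asarray(depths, dtype=float)
    if values.size == 0:
        raise ValueError("gini_index needs at least 1 depth")
    if (values < 0).any():
        raise ValueError("gini_index requires non-negative depths")
    total = values.sum()
    if total == 0:
        raise ValueError("gini_index undefined for all-zero depths")
    n = values.size
    if n == 1:
        return 0.0
    ranks = np.arange(1, n + 1)
    g = 2.0 * float(ranks @ np.sort(values)) / (n * total) - (n + 1) / n
    if corrected:
        g *= n / (n - 1)
    return float(g)


def percent_covered(covered: int, total: int) -> float:
    """Percentage of designed items actually covered (e.g. variants on a capture design)."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= covered <= total:
        raise ValueError("covered must lie in [0, total]")
    return 100.0 * covered / total


def compare_allele_fractions(
    afs_x: Sequence[float],
    afs_y: Sequence[float],
    depths: Sequence[float] | None = None,
) -> MetricReport:
    """Concordance report for two allele-fraction vectors over the same sites.

    ``depths`` (optional) feeds the CV/Gini evenness fields; otherwise they
    are reported as NaN.
    """
    xa, ya = _paired(afs_x, afs_y)
    if depths is not None:
        cv = coefficient_of_variation(depths)
        gini = gini_index(depths)
    else:
        cv = float("nan")
        gini = float("nan")
    return MetricReport(
        pearson_r=pearson_correlation(xa, ya),
        rmse=rmse(xa, ya),
        cv=cv,
        gini=gini,
        n_sites=int(xa.size),
    )
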