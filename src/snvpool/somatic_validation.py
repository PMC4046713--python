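"""Somatic SNV validation from paired tumor/normal allele fractions.

A candidate SNV is classified *somatic* when its allele fraction is at
least ``min_tumor_af`` (default 0.1) in the tumor sample and strictly below
``max_normal_af`` (default 0.01) in the matched normal, with sequence depth
of at least ``min_depth`` (default 30) in both samples.  Sites failing the
depth requirement — or missing from one of the tables, as happens under
capture dropout — are reported ``insufficient_depth`` rather than raising.

Also provides the heterozygous-SNP deviation statistic (mean absolute
deviation of observed allele fractions from the expected 0.5), used as a
precision measure for allele fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .counts_io import SiteCounts, VariantSite, allele_fraction

__all__ = [
    "ValidationThresholds",
    "SomaticStatus",
    "classify_somatic",
    "validate_cohort",
    "het_snp_deviation",
]


class SomaticStatus(str, Enum):
    SOMATIC = "somatic"
    NON_VALIDATED = "non_validated"
    INSUFFICIENT_DEPTH = "insufficient_depth"

    def __str__(self) -> str:  # tidy TSV rendering
        return self.value


@dataclass(frozen=True)
class ValidationThresholds:
    """Decision constants for tumor/normal somatic classification.

    ``min_tumor_af`` is inclusive (>=), ``max_normal_af`` exclusive (<),
    ``min_depth`` inclusive and applied to both samples.
    """

    min_tumor_af: float = 0.1
    max_normal_af: float = 0.01
    min_depth: int = 30

    def __post_init__(self) -> None:
        if not 0.0 < self.min_tumor_af < 1.0:
            raise ValueError("min_tumor_af must lie in (0, 1)")
        if not 0.0 <= self.max_normal_af < self.min_tumor_af:
            raise ValueError("max_normal_af must lie in [0, min_tumor_af)")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


def classify_somatic(
    tumor: SiteCounts,
    normal: SiteCounts,
    thresholds: ValidationThresholds = ValidationThresholds(),
) -> SomaticStatus:
    """Classify one candidate site from paired tumor/normal counts."""
    if tumor.site != normal.site:
        raise ValueError(
            f"tumor and normal counts refer to different sites: "
            f"{tumor.site.chrom}:{tumor.site.pos} vs {normal.site.chrom}:{normal.site.pos}"
        )
    if tumor.depth < thresholds.min_depth or normal.depth < thresholds.min_depth:
        return SomaticStatus.INSUFFICIENT_DEPTH
    tumor_af = allele_fraction(tumor)
    normal_af = allele_fraction(normal)
    if tumor_af >= thresholds.min_tumor_af and normal_af < thresholds.max_normal_af:
        return SomaticStatus.SOMATIC
    return SomaticStatus.NON_VALIDATED


def _index_by_site(records: Iterable[SiteCounts] | Mapping[VariantSite, SiteCounts]) -> dict[VariantSite, SiteCounts]:
    if isinstance(records, Mapping):
        return dict(records)
    indexed: dict[VariantSite, SiteCounts] = {}
    for rec in records:
        if rec.site in indexed:
            raise ValueError(f"duplicate counts at {rec.site.chrom}:{rec.site.pos}")
        indexed[rec.site] = rec
    return indexed


def validate_cohort(
    tumor_records: Iterable[SiteCounts] | Mapping[VariantSite, SiteCounts],
    normal_records: Iterable[SiteCounts] | Mapping[VariantSite, SiteCounts],
    thresholds: ValidationThresholds = ValidationThresholds(),
) -> tuple[pd.DataFrame, dict[SomaticStatus, int]]:
    """Classify every candidate site of a tumor/normal pair.

    Returns a per-site status table (one row per site in the union of the
    two inputs, sorted by coordinate) and summary counts per status.  Sites
    present in only one table are classified ``insufficient_depth``.
    """
    tumor_by_site = _index_by_site(tumor_records)
    normal_by_site = _index_by_site(normal_records)
    rows = []
    summary = {status: 0 for status in SomaticStatus}
    for site in sorted(set(tumor_by_site) | set(normal_by_site)):
        tumor = tumor_by_site.get(site)
        normal = normal_by_site.get(site)
        if tumor is None or normal is None:
            status = SomaticStatus.INSUFFICIENT_DEPTH
        else:
            status = classify_somatic(tumor, normal, thresholds)

        def _af(c: SiteCounts | None) -> float:
            return allele_fraction(c) if c is not None and c.depth > 0 else math.nan

        rows.append(
            {
                "chrom": site.chrom,
                "pos": site.pos,
                "ref": site.ref,
                "alt": site.alt,
                "tumor_af": _af(tumor),
                "normal_af": _af(normal),
                "tumor_depth": tumor.depth if tumor is not None else 0,
                "normal_depth": normal.depth if normal is not None else 0,
                "status": status.value,
            }
        )
        summary[status] += 1
    columns = ["chrom", "pos", "ref", "alt", "tumor_af", "normal_af", "tumor_depth", "normal_depth", "status"]
    return pd.DataFrame(rows, columns=columns), summary


def het_snp_deviation(afs: Sequence[float]) -> float:
    """Mean absolute deviation of allele fractions from the het expectation 0.5."""
    values = np.asarray(afs, dtype=float)
    if values.size == 0:
        raise ValueError("het_snp_deviation needs at least one allele fraction")
    return float(np.mean(np.abs(values - 0.5)))
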