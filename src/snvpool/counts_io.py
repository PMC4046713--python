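"""Per-site allele count tables and companion genomic inputs.

The pipeline contract starts at read counts: every downstream statistic
(allele fractions, somatic classification, pooled detection) consumes the
record types defined here rather than raw alignments.

On-disk formats
---------------
* **Count table** — UTF-8 tab-separated, ``#`` comment lines allowed, a
  header line, then one row per (experiment, site) with columns
  ``experiment_id, material, kind, pool_size, chrom, pos, ref, alt,
  ref_count, alt_count, other_count``.
* **Target regions** — BED3, 0-based half-open, converted to the package's
  1-based inclusive convention on load.
* **Blacklist / site lists** — two-column TSV ``(chrom, pos)`` or VCF
  restricted to SNV records.  Site lists are positional: they identify a
  genomic locus (dbSNP-style), not a specific alternate allele.

Count tables are assumed pre-filtered upstream (e.g. MAPQ-0 reads already
discarded); no base- or mapping-quality handling happens here.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from intervaltree import IntervalTree

__all__ = [
    "VariantSite",
    "SiteCounts",
    "Experiment",
    "TargetRegions",
    "CountTableError",
    "UndefinedAlleleFractionError",
    "SiteKey",
    "COUNT_TABLE_COLUMNS",
    "allele_fraction",
    "depth_filter",
    "load_count_table",
    "write_count_table",
    "load_site_list",
    "load_target_regions",
    "group_by_experiment",
]

VALID_BASES = frozenset("ACGT")
VALID_MATERIALS = frozenset({"gDNA", "wgaDNA"})
VALID_KINDS = frozenset({"tumor", "normal", "pool"})

COUNT_TABLE_COLUMNS = (
    "experiment_id",
    "material",
    "kind",
    "pool_size",
    "chrom",
    "pos",
    "ref",
    "alt",
    "ref_count",
    "alt_count",
    "other_count",
)

#: Positional site identifier used for blacklists and region membership.
SiteKey = tuple[str, int]


class CountTableError(ValueError):
    """Malformed or invalid count-table / site-list content."""


class UndefinedAlleleFractionError(ZeroDivisionError):
    """Allele fraction requested at a site with a zero denominator.

    Distinct from an allele fraction of 0: a site with no covering reads has
    no fraction at all.
    """


@dataclass(frozen=True, order=True)
class VariantSite:
    """A single-nucleotide variant locus: chromosome, 1-based position, ref and alt base."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (1-based), got {self.pos}")
        if self.ref not in VALID_BASES:
            raise ValueError(f"ref must be one of A,C,G,T, got {self.ref!r}")
        if self.alt not in VALID_BASES:
            raise ValueError(f"alt must be one of A,C,G,T, got {self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ, both are {self.ref!r}")

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class SiteCounts:
    """Read counts at one site in one experiment.

    ``other_count`` holds reads supporting neither the ref nor the alt base;
    a row carries exactly one alt allele, so two alternate alleles at one
    position are two rows.
    """

    site: VariantSite
    ref_count: int
    alt_count: int
    other_count: int = 0

    def __post_init__(self) -> None:
        for name in ("ref_count", "alt_count", "other_count"):
            value = getattr(self, name)
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")

    @property
    def depth(self) -> int:
        """Total sequence depth: ref + alt + other reads."""
        return self.ref_count + self.alt_count + self.other_count


@dataclass(frozen=True)
class Experiment:
    """One capture/sequencing experiment: an individual sample or a non-indexed pool."""

    id: str
    material: str = "gDNA"
    kind: str = "tumor"
    pool_size: int = 1
    replicate_of: str | None = None

    def __post_init__(self) -> None:
        if self.material not in VALID_MATERIALS:
            raise ValueError(f"material must be one of {sorted(VALID_MATERIALS)}, got {self.material!r}")
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {sorted(VALID_KINDS)}, got {self.kind!r}")
        if self.pool_size < 1:
            raise ValueError(f"pool_size must be >= 1, got {self.pool_size}")
        if self.replicate_of is not None and self.replicate_of == self.id:
            raise ValueError("replicate_of must name a distinct experiment")


def allele_fraction(counts: SiteCounts, denominator: str = "total") -> float:
    """Alternate-allele fraction at a covered site.

    Parameters
    ----------
    counts
        Read counts at the site.
    denominator
        ``"total"`` (default) divides by the full depth including
        ``other_count``; ``"ref_alt"`` divides by ref + alt reads only.

    Raises
    ------
    UndefinedAlleleFractionError
        If the chosen denominator is zero — an uncovered site has no
        fraction, which is not the same as a fraction of 0.
    """
    if denominator == "total":
        denom = counts.depth
    elif denominator == "ref_alt":
        denom = counts.ref_count + counts.alt_count
    else:
        raise ValueError(f"denominator must be 'total' or 'ref_alt', got {denominator!r}")
    if denom == 0:
        raise UndefinedAlleleFractionError(
            f"allele fraction undefined at {counts.site.chrom}:{counts.site.pos} (zero denominator)"
        )
    return counts.alt_count / denom


def depth_filter(records: Iterable[SiteCounts], min_depth: int) -> list[SiteCounts]:
    """Keep records with total depth >= ``min_depth`` (inclusive)."""
    if min_depth < 0:
        raise ValueError(f"min_depth must be >= 0, got {min_depth}")
    return [r for r in records if r.depth >= min_depth]


# ---------------------------------------------------------------------------
# Count-table TSV
# ---------------------------------------------------------------------------

def _parse_int(value: str, column: str, line_no: int) -> int:
    try:
        return int(value)
    except ValueError as exc:
        raise CountTableError(f"line {line_no}: column {column!r} is not an integer: {value!r}") from exc


def load_count_table(path: str | Path) -> list[tuple[Experiment, SiteCounts]]:
    """Read a count-table TSV into (experiment, site counts) records.

    Experiment metadata repeated across rows is deduplicated into shared
    :class:`Experiment` instances; inconsistent metadata for the same
    experiment id is an error.  All validation failures name the offending
    1-based line number.
    """
    path = Path(path)
    experiments: dict[str, Experiment] = {}
    records: list[tuple[Experiment, SiteCounts]] = []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header: Sequence[str] | None = None
        for line_no, row in enumerate(reader, start=1):
            if not row or (row[0].startswith("#")):
                continue
            if header is None:
                header = tuple(row)
                if header != COUNT_TABLE_COLUMNS:
                    raise CountTableError(
                        f"line {line_no}: bad header, expected {list(COUNT_TABLE_COLUMNS)}, got {list(header)}"
                    )
                continue
            if len(row) != len(COUNT_TABLE_COLUMNS):
                raise CountTableError(
                    f"line {line_no}: expected {len(COUNT_TABLE_COLUMNS)} fields, got {len(row)}"
                )
            rec = dict(zip(COUNT_TABLE_COLUMNS, row))
            try:
                site = VariantSite(
                    chrom=rec["chrom"],
                    pos=_parse_int(rec["pos"], "pos", line_no),
                    ref=rec["ref"].upper(),
                    alt=rec["alt"].upper(),
                )
                counts = SiteCounts(
                    site=site,
                    ref_count=_parse_int(rec["ref_count"], "ref_count", line_no),
                    alt_count=_parse_int(rec["alt_count"], "alt_count", line_no),
                    other_count=_parse_int(rec["other_count"], "other_count", line_no),
                )
                experiment = Experiment(
                    id=rec["experiment_id"],
                    material=rec["material"],
                    kind=rec["kind"],
                    pool_size=_parse_int(rec["pool_size"], "pool_size", line_no),
                )
            except CountTableError:
                raise
            except ValueError as exc:
                raise CountTableError(f"line {line_no}: {exc}") from exc
            known = experiments.get(experiment.id)
            if known is None:
                experiments[experiment.id] = experiment
            elif known != experiment:
                raise CountTableError(
                    f"line {line_no}: experiment {experiment.id!r} redefined with different metadata"
                )
            else:
                experiment = known
            records.append((experiment, counts))
    if header is None:
        raise CountTableError(f"{path}: empty file (missing header)")
    return records


def write_count_table(records: Iterable[tuple[Experiment, SiteCounts]], path: str | Path) -> None:
    """Write (experiment, counts) records as a count-table TSV."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(COUNT_TABLE_COLUMNS)
        for experiment, counts in records:
            site = counts.site
            writer.writerow(
                [
                    experiment.id,
                    experiment.material,
                    experiment.kind,
                    experiment.pool_size,
                    site.chrom,
                    site.pos,
                    site.ref,
                    site.alt,
                    counts.ref_count,
                    counts.alt_count,
                    counts.other_count,
                ]
            )


def group_by_experiment(
    records: Iterable[tuple[Experiment, SiteCounts]],
) -> dict[str, tuple[Experiment, dict[VariantSite, SiteCounts]]]:
    """Index flat records as experiment id -> (experiment, site -> counts)."""
    grouped: dict[str, tuple[Experiment, dict[VariantSite, SiteCounts]]] = {}
    for experiment, counts in records:
        if experiment.id not in grouped:
            grouped[experiment.id] = (experiment, {})
        _, table = grouped[experiment.id]
        if counts.site in table:
            raise CountTableError(
                f"duplicate record for experiment {experiment.id!r} at "
                f"{counts.site.chrom}:{counts.site.pos} {counts.site.ref}>{counts.site.alt}"
            )
        table[counts.site] = counts
    return grouped


# ---------------------------------------------------------------------------
# Site lists (blacklist) and target regions
# ---------------------------------------------------------------------------

def load_site_list(path: str | Path, format: str = "tsv") -> frozenset[SiteKey]:
    """Load a deduplicated positional site set (e.g. a dbSNP-proxy blacklist).

    ``format="tsv"`` expects two tab-separated columns (chrom, pos);
    ``format="vcf"`` reads SNV records from a VCF, skipping indel records
    with a warning.
    """
    path = Path(path)
    if format == "tsv":
        sites: set[SiteKey] = set()
        with path.open(encoding="utf-8") as handle:
            for line_no, line in enumerate(handle, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise CountTableError(f"line {line_no}: expected (chrom, pos), got {fields}")
                pos = _parse_int(fields[1], "pos", line_no)
                if pos < 1:
                    raise CountTableError(f"line {line_no}: pos must be >= 1, got {pos}")
                sites.add((fields[0], pos))
        return frozenset(sites)
    if format == "vcf":
        from cyvcf2 import VCF

        sites = set()
        for variant in VCF(str(path)):
            snv_alts = [a for a in variant.ALT if len(a) == 1 and a in VALID_BASES]
            if len(variant.REF) != 1 or not snv_alts:
                warnings.warn(
                    f"skipping non-SNV record at {variant.CHROM}:{variant.POS} "
                    f"({variant.REF}>{','.join(variant.ALT)})",
                    stacklevel=2,
                )
                continue
            sites.add((variant.CHROM, variant.POS))
        return frozenset(sites)
    raise ValueError(f"unknown site-list format {format!r} (expected 'tsv' or 'vcf')")


class TargetRegions:
    """Capture target regions with fast positional membership lookup.

    Intervals are stored internally 0-based half-open (as in BED); queries
    use the package's 1-based positions.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        self._trees: dict[str, IntervalTree] = {}
        self.total_bases = 0
        for chrom, start0, end0 in intervals:
            if end0 <= start0:
                raise ValueError(f"empty or inverted interval {chrom}:{start0}-{end0}")
            self._trees.setdefault(chrom, IntervalTree()).addi(start0, end0)
            self.total_bases += end0 - start0

    def contains(self, chrom: str, pos: int) -> bool:
        """True if 1-based ``pos`` falls inside a target region."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree[pos - 1])

    def __contains__(self, key: SiteKey) -> bool:
        return self.contains(*key)

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                yield (chrom, iv.begin, iv.end)


def load_target_regions(path: str | Path) -> TargetRegions:
    """Load BED3 target regions (0-based half-open on disk)."""
    path = Path(path)
    intervals: list[tuple[str, int, int]] = []
    with path.open(encoding="utf-8") as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CountTableError(f"line {line_no}: BED3 requires 3 columns, got {len(fields)}")
            intervals.append(
                (fields[0], _parse_int(fields[1], "start", line_no), _parse_int(fields[2], "end", line_no))
            )
    return TargetRegions(intervals)
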