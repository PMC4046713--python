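"""De novo variant calling in non-indexed pools.

Scans every covered target-region site of a pool for variants present in a
single (previously uncharacterized) member sample.  The expected pooled
fraction of such a variant is ``0.5 / N`` (a heterozygous carrier among N
members), and a cascade of filters removes germline SNPs and artifacts:

1. **depth** — total pool depth >= 30 per member (i.e. >= 30 * N; reads are
   unindexed, so per-sample depth is unobservable and the total is used);
2. **af_window** — observed fraction within [0.5x, 2x] of the expected
   value (inclusive); variants shared by several members land above the
   window, subclonal remnants and noise below;
3. **majority_alt** — the called alternate base must be the dominant
   non-reference base at the site;
4. **blacklist** — site not at a known-polymorphism locus (dbSNP proxy);
5. **cross_experiment** — allele fraction <= 1% in every *other* experiment
   with informative data (depth >= 30) at the site, the pool's own
   replicate exempted; this removes germline variants absent from the
   blacklist and recurrent artifacts.

A call is *high-confidence* when it is made in both replicates of the same
pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .counts_io import SiteCounts, SiteKey, VariantSite, allele_fraction

__all__ = [
    "DeNovoConfig",
    "DeNovoCall",
    "FILTER_NAMES",
    "denovo_scan",
    "replicate_intersect",
]

FILTER_NAMES = ("depth", "af_window", "majority_alt", "blacklist", "cross_experiment")


@dataclass(frozen=True)
class DeNovoConfig:
    """Filter cascade settings for de novo pool calling."""

    expected_numerator: float = 0.5
    window_low_factor: float = 0.5
    window_high_factor: float = 2.0
    per_sample_min_depth: int = 30
    cross_experiment_max_af: float = 0.01
    cross_experiment_min_depth: int = 30
    require_majority_alt: bool = True
    blacklist: frozenset[SiteKey] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not 0.0 < self.expected_numerator <= 1.0:
            raise ValueError("expected_numerator must lie in (0, 1]")
        if not 0.0 < self.window_low_factor < 1.0 < self.window_high_factor:
            raise ValueError("window factors must satisfy 0 < low < 1 < high")
        if self.per_sample_min_depth < 0 or self.cross_experiment_min_depth < 0:
            raise ValueError("depth thresholds must be >= 0")

    def expected_af(self, pool_size: int) -> float:
        return self.expected_numerator / pool_size

    def window(self, pool_size: int) -> tuple[float, float]:
        e = self.expected_af(pool_size)
        return (self.window_low_factor * e, self.window_high_factor * e)


@dataclass(frozen=True)
class DeNovoCall:
    """A candidate single-member variant called in one pool experiment."""

    site: VariantSite
    pool_id: str
    observed_af: float
    depth: int
    expected_af: float
    filters_passed: tuple[str, ...]
    high_confidence: bool = False


def denovo_scan(
    pool_counts: Iterable[SiteCounts] | Mapping[VariantSite, SiteCounts],
    pool_size: int,
    config: DeNovoConfig,
    other_experiments: Mapping[str, Mapping[VariantSite, SiteCounts]] | None = None,
    *,
    pool_id: str = "pool",
    replicate_id: str | None = None,
    stats: dict[str, int] | None = None,
) -> list[DeNovoCall]:
    """Apply the full filter cascade to every site of a pool.

    ``other_experiments`` maps experiment id to its per-site counts; the
    pool itself (``pool_id``) and its replicate (``replicate_id``) are
    skipped in the cross-experiment comparison.  When ``stats`` is given it
    is filled with per-filter attrition counts (sites failing each filter,
    plus ``n_sites`` and ``n_called``), making the cascade auditable.

    De novo calling is defined for pools: ``pool_size`` < 2 is a
    configuration error.
    """
    if pool_size < 2:
        raise ValueError("de novo pool calling requires a pool of size >= 2")
    if isinstance(pool_counts, Mapping):
        records = [pool_counts[s] for s in sorted(pool_counts)]
    else:
        records = sorted(pool_counts, key=lambda c: c.site)
    others = dict(other_experiments or {})
    expected = config.expected_af(pool_size)
    low, high = config.window(pool_size)
    min_total_depth = config.per_sample_min_depth * pool_size

    attrition = {"n_sites": len(records), "n_called": 0}
    attrition.update({f"fail_{name}": 0 for name in FILTER_NAMES})

    calls: list[DeNovoCall] = []
    for counts in records:
        site = counts.site
        passed: list[str] = []

        if counts.depth < min_total_depth:
            attrition["fail_depth"] += 1
            continue
        passed.append("depth")

        af = allele_fraction(counts)
        if not low <= af <= high:
            attrition["fail_af_window"] += 1
            continue
        passed.append("af_window")

        if config.require_majority_alt and counts.alt_count <= counts.other_count:
            attrition["fail_majority_alt"] += 1
            continue
        passed.append("majority_alt")

        if site.key in config.blacklist:
            attrition["fail_blacklist"] += 1
            continue
        passed.append("blacklist")

        seen_elsewhere = False
        for exp_id, table in others.items():
            if exp_id == pool_id or (replicate_id is not None and exp_id == replicate_id):
                continue
            other = table.get(site)
            if other is None or other.depth < config.cross_experiment_min_depth:
                continue
            if allele_fraction(other) > config.cross_experiment_max_af:
                seen_elsewhere = True
                break
        if seen_elsewhere:
            attrition["fail_cross_experiment"] += 1
            continue
        passed.append("cross_experiment")

        attrition["n_called"] += 1
        calls.append(
            DeNovoCall(
                site=site,
                pool_id=pool_id,
                observed_af=af,
                depth=counts.depth,
                expected_af=expected,
                filters_passed=tuple(passed),
            )
        )
    if stats is not None:
        stats.update(attrition)
    return calls


def replicate_intersect(calls_a: Iterable[DeNovoCall], calls_b: Iterable[DeNovoCall]) -> list[DeNovoCall]:
    """Mark calls made in both replicate pools as high-confidence.

    Returns every input call, with ``high_confidence=True`` on calls whose
    site appears in both replicates; discordant calls are retained as
    low-confidence, their ``pool_id`` recording which replicate produced
    them.
    """
    a = list(calls_a)
    b = list(calls_b)
    shared = {c.site for c in a} & {c.site for c in b}
    return [replace(c, high_confidence=c.site in shared) for c in a + b]
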