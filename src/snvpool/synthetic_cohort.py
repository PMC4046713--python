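"""Synthetic tumor cohorts and simulated deep-sequencing read counts.

Generates ground truth and per-site counts with the statistical structure of
a deep targeted-sequencing study of pooled leukemia samples:

* candidate variant sites on a small capture target (~147 kb by default),
* heterozygous germline SNPs at allele fraction 0.5 in tumor and normal,
  optionally sitting in a region of somatic loss of heterozygosity (LOH,
  tumor AF near 1),
* somatic SNVs private to one sample, with true allele fractions drawn from
  a subclonal mixture (clusters near 0.2 and 0.45 by default),
* null sites (false-positive candidates) with no variant reads beyond
  sequencing error,
* per-site depths from a negative-binomial (gamma-mixed Poisson) family,
  with a more overdispersed preset for whole-genome-amplified material,
* non-indexed pools: the pooled true allele fraction is the mixing-weight
  average of member fractions, optionally with Dirichlet quantification
  noise on the weights.

All randomness flows through numpy Generators; every public entry point is
deterministic given its seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .counts_io import Experiment, SiteCounts, VariantSite

__all__ = [
    "CohortConfig",
    "TruthRecord",
    "SampleTruth",
    "PoolSpec",
    "DepthModel",
    "GDNA_DEPTH_MODEL",
    "WGA_DEPTH_MODEL",
    "generate_cohort",
    "true_pool_af",
    "simulate_depths",
    "simulate_site_counts",
    "simulate_experiment",
    "write_truth_table",
    "load_truth_table",
]

_BASES = "ACGT"


def _as_rng(seed: int | np.random.Generator | np.random.SeedSequence | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _broadcast(value: int | Sequence[int], n: int, name: str) -> list[int]:
    """Broadcast a scalar or short sequence over n samples (last value repeats)."""
    if isinstance(value, (int, np.integer)):
        out = [int(value)] * n
    else:
        seq = [int(v) for v in value]
        if not seq:
            raise ValueError(f"{name} must not be empty")
        if len(seq) > n:
            raise ValueError(f"{name} has {len(seq)} entries for {n} samples")
        out = seq + [seq[-1]] * (n - len(seq))
    if any(v < 0 for v in out):
        raise ValueError(f"{name} entries must be non-negative")
    return out


# ---------------------------------------------------------------------------
# Configuration and truth containers
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Ground-truth generator settings.

    Defaults reflect the structure of a two-patient leukemia study: 227 and
    305 somatic SNVs in the two reference tumors, 19 shared heterozygous
    SNPs, subclonal AF clusters at 0.2 and 0.45 in equal proportion, and a
    per-base miscall rate of 1e-3.
    """

    n_samples: int = 2
    n_somatic: int | Sequence[int] = (227, 305)
    n_germline: int = 19
    n_null: int | Sequence[int] = (250, 250)
    subclone_af_means: Sequence[float] = (0.2, 0.45)
    subclone_weights: Sequence[float] = (0.5, 0.5)
    subclone_af_sd: float = 0.03
    loh_fraction: float = 0.1
    loh_tumor_af: float = 0.95
    germline_het_prob: float = 0.5
    recurrent_fraction: float = 0.0
    n_anchors: int = 0
    seq_error: float = 0.001
    seed: int = 0
    chrom: str = "1"
    region_length: int = 147_000
    sample_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if len(self.subclone_af_means) != len(self.subclone_weights):
            raise ValueError("subclone_af_means and subclone_weights must align")
        if abs(sum(self.subclone_weights) - 1.0) > 1e-9:
            raise ValueError("subclone mixture weights must sum to 1")
        if not all(0.0 < m <= 1.0 for m in self.subclone_af_means):
            raise ValueError("subclone AF means must lie in (0, 1]")
        if not 0.0 <= self.seq_error <= 0.1:
            raise ValueError("seq_error must lie in [0, 0.1]")
        if not 0.0 <= self.loh_fraction <= 1.0:
            raise ValueError(
                "loh_fraction must lie in [0, 1] (cannot place more LOH SNPs than germline SNPs)"
            )
        if not 0.0 <= self.recurrent_fraction <= 1.0:
            raise ValueError("recurrent_fraction must lie in [0, 1]")
        if self.sample_ids is not None and len(self.sample_ids) != self.n_samples:
            raise ValueError("sample_ids length must equal n_samples")

    @property
    def resolved_sample_ids(self) -> list[str]:
        if self.sample_ids is not None:
            return list(self.sample_ids)
        return [f"s{i + 1:02d}" for i in range(self.n_samples)]


@dataclass(frozen=True)
class TruthRecord:
    """True state of one site in one sample."""

    label: str  # somatic | germline | null
    true_af_tumor: float
    true_af_normal: float
    anchor: bool = False  # previously orthogonally validated somatic SNV

    def __post_init__(self) -> None:
        if self.label not in ("somatic", "germline", "null"):
            raise ValueError(f"label must be somatic/germline/null, got {self.label!r}")
        if self.label == "somatic" and self.true_af_normal != 0.0:
            raise ValueError("somatic sites must have true_af_normal == 0")
        if self.label == "germline" and self.true_af_normal != 0.5:
            raise ValueError("germline het sites must have true_af_normal == 0.5")
        if self.label == "null" and (self.true_af_tumor != 0.0 or self.true_af_normal != 0.0):
            raise ValueError("null sites must have zero true AF in tumor and normal")


@dataclass
class SampleTruth:
    """Per-sample ground truth: site -> :class:`TruthRecord`."""

    sample_id: str
    records: dict[VariantSite, TruthRecord] = field(default_factory=dict)

    def sites(self, label: str | None = None) -> list[VariantSite]:
        if label is None:
            return list(self.records)
        return [s for s, r in self.records.items() if r.label == label]


@dataclass(frozen=True)
class PoolSpec:
    """Pool membership and nominal mixing proportions (N = number of members)."""

    member_ids: tuple[str, ...]
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.member_ids) < 1:
            raise ValueError("a pool needs at least one member")
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ValueError("pool member ids must be unique")
        if self.weights is not None:
            if len(self.weights) != len(self.member_ids):
                raise ValueError("weights must align with member_ids")
            if any(w < 0 for w in self.weights):
                raise ValueError("weights must be non-negative")
            if abs(sum(self.weights) - 1.0) > 1e-9:
                raise ValueError("weights must sum to 1")

    @property
    def n(self) -> int:
        return len(self.member_ids)

    @property
    def resolved_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.full(self.n, 1.0 / self.n)
        return np.asarray(self.weights, dtype=float)

    @staticmethod
    def single(sample_id: str) -> "PoolSpec":
        return PoolSpec((sample_id,))


@dataclass(frozen=True)
class DepthModel:
    """Negative-binomial per-site depth model.

    ``dispersion`` d parameterises the variance as mu * (1 + d * mu)
    (gamma-mixed Poisson with gamma shape 1/d); higher d means more uneven
    coverage.  d == 0 is the degenerate perfectly-even limit with constant
    depth round(mean_depth).
    """

    mean_depth: float
    dispersion: float
    material: str = "gDNA"

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


#: Coverage presets: amplified material is modelled with the same machinery
#: but a markedly larger dispersion, so its depth Gini exceeds genomic DNA's.
GDNA_DEPTH_MODEL = DepthModel(mean_depth=1400.0, dispersion=0.25, material="gDNA")
WGA_DEPTH_MODEL = DepthModel(mean_depth=1550.0, dispersion=0.80, material="wgaDNA")


# ---------------------------------------------------------------------------
# Ground truth generation
# ---------------------------------------------------------------------------

def _random_site(chrom: str, pos: int, rng: np.random.Generator) -> VariantSite:
    ref, alt = rng.choice(4, size=2, replace=False)
    return VariantSite(chrom=chrom, pos=pos, ref=_BASES[ref], alt=_BASES[alt])


def _draw_subclonal_af(config: CohortConfig, rng: np.random.Generator) -> float:
    component = rng.choice(len(config.subclone_af_means), p=np.asarray(config.subclone_weights))
    af = rng.normal(config.subclone_af_means[component], config.subclone_af_sd)
    return float(np.clip(af, 0.01, 1.0))


def generate_cohort(config: CohortConfig) -> list[SampleTruth]:
    """Generate per-sample ground truth for a cohort.

    Somatic sites are private to one sample (unless ``recurrent_fraction``
    is set, in which case that fraction of a sample's somatic sites is also
    planted in the next sample, for stress tests).  Germline SNP sites are
    shared: the first two samples are always heterozygous carriers — they
    play the role of the reference patients — and every other sample is a
    het carrier with probability ``germline_het_prob``.  A ``loh_fraction``
    of each sample's carried germline sites is placed in a simulated LOH
    region (tumor AF ``loh_tumor_af``, normal AF 0.5).

    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    sample_ids = config.resolved_sample_ids
    n_somatic = _broadcast(config.n_somatic, config.n_samples, "n_somatic")
    n_null = _broadcast(config.n_null, config.n_samples, "n_null")

    total_sites = config.n_germline + sum(n_somatic) + sum(n_null)
    if total_sites > config.region_length:
        raise ValueError(
            f"cannot place {total_sites} distinct sites in a {config.region_length} bp region"
        )
    positions = rng.choice(config.region_length, size=total_sites, replace=False) + 1
    positions_iter = iter(sorted(int(p) for p in positions))

    truths = [SampleTruth(sample_id=sid) for sid in sample_ids]

    # Shared germline SNP sites.
    germline_sites = [_random_site(config.chrom, next(positions_iter), rng) for _ in range(config.n_germline)]
    carriers: dict[VariantSite, list[int]] = {}
    for site in germline_sites:
        carrier_idx = [i for i in range(min(2, config.n_samples))]
        for i in range(2, config.n_samples):
            if rng.random() < config.germline_het_prob:
                carrier_idx.append(i)
        carriers[site] = carrier_idx
    for i, truth in enumerate(truths):
        carried = [s for s in germline_sites if i in carriers[s]]
        n_loh = int(round(config.loh_fraction * len(carried)))
        loh_sites = set(
            carried[j] for j in rng.permutation(len(carried))[:n_loh]
        )
        for site in carried:
            tumor_af = config.loh_tumor_af if site in loh_sites else 0.5
            truth.records[site] = TruthRecord("germline", tumor_af, 0.5)

    # Private somatic SNVs with subclonal AF structure.
    for i, truth in enumerate(truths):
        somatic_sites: list[VariantSite] = []
        for _ in range(n_somatic[i]):
            site = _random_site(config.chrom, next(positions_iter), rng)
            af = _draw_subclonal_af(config, rng)
            truth.records[site] = TruthRecord("somatic", af, 0.0)
            somatic_sites.append(site)
        if config.recurrent_fraction > 0 and config.n_samples > 1:
            n_recurrent = int(round(config.recurrent_fraction * len(somatic_sites)))
            neighbor = truths[(i + 1) % config.n_samples]
            for site in somatic_sites[:n_recurrent]:
                neighbor.records[site] = TruthRecord("somatic", _draw_subclonal_af(config, rng), 0.0)
        # Anchor flag: somatic sites with mid-range AF, mirroring variants
        # already confirmed by an orthogonal assay.
        eligible = [s for s in somatic_sites if 0.2 <= truth.records[s].true_af_tumor <= 0.8]
        for site in eligible[: config.n_anchors]:
            rec = truth.records[site]
            truth.records[site] = replace(rec, anchor=True)

    # Null sites: false-positive candidates, no variant in tumor or normal.
    for i, truth in enumerate(truths):
        for _ in range(n_null[i]):
            site = _random_site(config.chrom, next(positions_iter), rng)
            truth.records[site] = TruthRecord("null", 0.0, 0.0)

    return truths


def true_pool_af(pool: PoolSpec, member_afs: Sequence[float]) -> float:
    """Weighted-mixture pooled allele fraction: sum_i weight_i * af_i.

    For a single-sample ``pool`` this is the sample's own fraction; for an
    equal-weight pool of N it reduces to the individual fraction divided
    by N when one member carries the variant.
    """
    if len(member_afs) != pool.n:
        raise ValueError(f"expected {pool.n} member AFs, got {len(member_afs)}")
    return float(np.dot(pool.resolved_weights, np.asarray(member_afs, dtype=float)))


# ---------------------------------------------------------------------------
# Read-count simulation
# ---------------------------------------------------------------------------

def simulate_depths(
    model: DepthModel,
    n_sites: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw integer per-site depths from the model's negative-binomial family."""
    if n_sites <= 0:
        raise ValueError("n_sites must be > 0")
    rng = _as_rng(seed)
    if model.dispersion == 0:
        return np.full(n_sites, int(round(model.mean_depth)), dtype=np.int64)
    r = 1.0 / model.dispersion
    p = r / (r + model.mean_depth)
    return rng.negative_binomial(r, p, size=n_sites).astype(np.int64)


def simulate_site_counts(
    site: VariantSite,
    true_af: float,
    depth: int,
    seq_error: float,
    seed: int | np.random.Generator | None = None,
) -> SiteCounts:
    """Simulate read counts at one site.

    Alt reads are Binomial(depth, p) with
    ``p = true_af * (1 - seq_error) + (1 - true_af) * seq_error / 3``
    (a miscall lands on each of the three wrong bases with equal
    probability); reads on the remaining two bases are Binomial over the
    non-alt reads at rate ``2 * seq_error / 3``; ref reads are the
    remainder, so counts always sum to ``depth``.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not 0.0 <= true_af <= 1.0:
        raise ValueError("true_af must lie in [0, 1]")
    if not 0.0 <= seq_error <= 0.1:
        raise ValueError("seq_error must lie in [0, 0.1]")
    rng = _as_rng(seed)
    p_alt = true_af * (1.0 - seq_error) + (1.0 - true_af) * seq_error / 3.0
    alt = int(rng.binomial(depth, p_alt)) if depth > 0 else 0
    remaining = depth - alt
    other = int(rng.binomial(remaining, 2.0 * seq_error / 3.0)) if remaining > 0 else 0
    return SiteCounts(site=site, ref_count=depth - alt - other, alt_count=alt, other_count=other)


def simulate_experiment(
    truths: Mapping[str, SampleTruth] | Sequence[SampleTruth],
    pool: PoolSpec,
    model: DepthModel,
    config: CohortConfig,
    *,
    experiment_id: str,
    kind: str = "pool",
    replicate_of: str | None = None,
    weight_concentration: float | None = None,
    sites: Sequence[VariantSite] | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[Experiment, list[SiteCounts]]:
    """Simulate one capture experiment (an individual sample or a pool).

    Counts are produced at every site in ``sites`` (default: the union of
    sites across *all* provided truths, so that an experiment also reports
    reference-allele-only coverage at sites that are variant elsewhere in
    the cohort — as a real capture panel would).

    ``kind="normal"`` uses each member's normal-tissue true AF; tumor and
    pool experiments use the tumor AF.  If ``weight_concentration`` is
    given, the nominal pool weights are perturbed by a Dirichlet draw with
    concentration ``weight_concentration * N * weight`` per member,
    emulating DNA quantification / pipetting error; replicate experiments
    should simply be simulated with an independent seed.
    """
    if isinstance(truths, Mapping):
        truth_map = dict(truths)
    else:
        truth_map = {t.sample_id: t for t in truths}
    missing = [m for m in pool.member_ids if m not in truth_map]
    if missing:
        raise KeyError(f"pool members absent from cohort truth: {missing}")
    rng = _as_rng(seed)

    if sites is None:
        universe: set[VariantSite] = set()
        for truth in truth_map.values():
            universe.update(truth.records)
        sites = sorted(universe)

    weights = pool.resolved_weights
    if weight_concentration is not None:
        if weight_concentration <= 0:
            raise ValueError("weight_concentration must be > 0")
        weights = rng.dirichlet(weight_concentration * pool.n * weights)

    members = [truth_map[m] for m in pool.member_ids]
    depths = simulate_depths(model, len(sites), rng)
    records: list[SiteCounts] = []
    for site, depth in zip(sites, depths):
        afs = []
        for member in members:
            rec = member.records.get(site)
            if rec is None:
                afs.append(0.0)
            else:
                afs.append(rec.true_af_normal if kind == "normal" else rec.true_af_tumor)
        pooled = float(np.dot(weights, afs))
        records.append(simulate_site_counts(site, pooled, int(depth), config.seq_error, rng))

    experiment = Experiment(
        id=experiment_id,
        material=model.material,
        kind=kind,
        pool_size=pool.n,
        replicate_of=replicate_of,
    )
    return experiment, records


# ---------------------------------------------------------------------------
# Truth table I/O
# ---------------------------------------------------------------------------

_TRUTH_COLUMNS = ("chrom", "pos", "ref", "alt", "sample", "label", "true_af_tumor", "true_af_normal", "anchor")


def write_truth_table(truths: Iterable[SampleTruth], path: str | Path) -> None:
    """Write cohort ground truth as a TSV for downstream evaluation."""
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_TRUTH_COLUMNS)
        for truth in truths:
            for site in sorted(truth.records):
                rec = truth.records[site]
                writer.writerow(
                    [
                        site.chrom,
                        site.pos,
                        site.ref,
                        site.alt,
                        truth.sample_id,
                        rec.label,
                        f"{rec.true_af_tumor:.6g}",
                        f"{rec.true_af_normal:.6g}",
                        int(rec.anchor),
                    ]
                )


def load_truth_table(path: str | Path) -> list[SampleTruth]:
    """Read a truth TSV back into :class:`SampleTruth` objects."""
    truths: dict[str, SampleTruth] = {}
    with Path(path).open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if tuple(reader.fieldnames or ()) != _TRUTH_COLUMNS:
            raise ValueError(f"bad truth-table header in {path}")
        for row in reader:
            site = VariantSite(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            truth = truths.setdefault(row["sample"], SampleTruth(sample_id=row["sample"]))
            truth.records[site] = TruthRecord(
                label=row["label"],
                true_af_tumor=float(row["true_af_tumor"]),
                true_af_normal=float(row["true_af_normal"]),
                anchor=bool(int(row["anchor"])),
            )
    return list(truths.values())
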