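"""Configuration-driven end-to-end runner.

``simulate`` mode generates a synthetic cohort and a roster of capture
experiments (tumor/normal genomic-DNA pairs, whole-genome-amplified
duplicates, non-indexed pools of 2/5/10 with replicates), writes their
count tables, and analyzes them; ``analyze`` mode runs the same analysis on
count tables loaded from disk.  The analysis chain is:

1. somatic validation of each tumor/normal pair,
2. gDNA vs. wgaDNA allele-fraction concordance and per-experiment
   coverage-evenness metrics,
3. detection of the validated somatic SNVs in each pool (confusion matrix,
   FDR, median-ratio skew estimate, rescaled re-detection),
4. de novo calling across the target region of each pool with replicate
   concordance.

Every run writes per-site TSV artifacts, a consolidated ``report.json``, a
human-readable summary and the resolved configuration with its seed, so
all report numbers can be recomputed from the emitted tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from .concordance_metrics import (
    coefficient_of_variation,
    gini_index,
    pearson_correlation,
    rmse,
)
from .counts_io import (
    Experiment,
    SiteCounts,
    VariantSite,
    allele_fraction,
    group_by_experiment,
    load_count_table,
    load_site_list,
    write_count_table,
)
from .denovo_calling import DeNovoConfig, denovo_scan, replicate_intersect
from .pool_detection import (
    DetectionThreshold,
    confusion_matrix,
    false_discovery_rate,
    median_ratio,
    scale_allele_fractions,
)
from .somatic_validation import SomaticStatus, ValidationThresholds, validate_cohort
from .synthetic_cohort import (
    CohortConfig,
    DepthModel,
    PoolSpec,
    SampleTruth,
    generate_cohort,
    simulate_experiment,
    write_truth_table,
)

__all__ = [
    "ConfigurationError",
    "ExperimentDef",
    "PatientDef",
    "WgaPairDef",
    "PoolEvalDef",
    "RunConfig",
    "RunReport",
    "default_config",
    "load_config",
    "dump_config",
    "run_pipeline",
    "summarize",
]

logger = logging.getLogger("snvpool")


class ConfigurationError(ValueError):
    """Invalid or unresolvable run configuration (raised before any computation)."""


# ---------------------------------------------------------------------------
# Configuration schema
# ---------------------------------------------------------------------------

@dataclass
class ExperimentDef:
    """Roster entry: one capture experiment to simulate or analyze."""

    id: str
    kind: str  # tumor | normal | pool
    material: str = "gDNA"
    members: tuple[str, ...] = ()
    weights: tuple[float, ...] | None = None
    mean_depth: float = 1400.0
    dispersion: float = 0.25
    replicate_of: str | None = None

    def pool_spec(self) -> PoolSpec:
        return PoolSpec(tuple(self.members), None if self.weights is None else tuple(self.weights))

    def depth_model(self) -> DepthModel:
        return DepthModel(self.mean_depth, self.dispersion, self.material)


@dataclass
class PatientDef:
    """A tumor/normal experiment pair used for somatic validation."""

    label: str
    sample: str
    tumor_experiment: str
    normal_experiment: str


@dataclass
class WgaPairDef:
    """A genomic-DNA / amplified-DNA pair used for concordance metrics."""

    label: str
    gdna_experiment: str
    wga_experiment: str


@dataclass
class PoolEvalDef:
    """Evaluation of one pool against validated somatic SNV sets."""

    pool_experiment: str
    focal_patient: str  # provides known positives and expected AFs
    negative_patient: str  # provides known negatives (out-of-pool somatic SNVs)


@dataclass
class PathsConfig:
    count_table: str | None = None
    truth_table: str | None = None
    blacklist: str | None = None
    blacklist_format: str = "tsv"
    germline_sites: str | None = None


@dataclass
class RunConfig:
    mode: str = "simulate"
    master_seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    experiments: list[ExperimentDef] = field(default_factory=list)
    patients: list[PatientDef] = field(default_factory=list)
    wga_pairs: list[WgaPairDef] = field(default_factory=list)
    pool_evals: list[PoolEvalDef] = field(default_factory=list)
    validation: ValidationThresholds = field(default_factory=ValidationThresholds)
    detection_numerator: float = 0.05
    denovo: DeNovoConfig = field(default_factory=DeNovoConfig)
    blacklist_coverage: float = 0.9  # fraction of germline SNP loci on the dbSNP-proxy blacklist
    weight_concentration: float | None = None  # Dirichlet pool-mixing noise; None = exact weights
    paths: PathsConfig = field(default_factory=PathsConfig)


def default_config(master_seed: int = 0) -> RunConfig:
    """The package's reference study design.

    Two deeply characterized leukemia patients (227 and 305 true somatic
    SNVs, subclone AF clusters at 0.2/0.45), 14 uncharacterized samples
    with a few private somatic SNVs each, 19 shared heterozygous SNPs, and
    twelve capture experiments: tumor+normal gDNA per patient, wgaDNA
    tumor duplicates, and replicated non-indexed pools of 2, 5 and 10.
    The 5- and 10-sample pools carry the focal sample at 1.2x its nominal
    proportion (0.24 vs 0.20 and 0.12 vs 0.10), representing DNA
    quantification skew.
    """
    sample_ids = ["tumor1", "tumor2"] + [f"u{i:02d}" for i in range(1, 15)]
    cohort = CohortConfig(
        n_samples=16,
        n_somatic=(227, 305, 3),
        n_null=(250, 250, 0),
        n_germline=19,
        n_anchors=15,
        seed=master_seed,
        sample_ids=tuple(sample_ids),
    )
    pool5_members = ("tumor2", "u02", "u03", "u04", "u05")
    pool5_weights = (0.24, 0.19, 0.19, 0.19, 0.19)
    pool10_members = ("tumor1",) + tuple(f"u{i:02d}" for i in range(6, 15))
    pool10_weights = (0.12,) + (0.88 / 9,) * 9

    def pool(id_, members, weights, depth, replicate_of=None):
        return ExperimentDef(
            id=id_, kind="pool", material="gDNA", members=members, weights=weights,
            mean_depth=depth, dispersion=0.25, replicate_of=replicate_of,
        )

    experiments = [
        ExperimentDef("tumor1_gdna", "tumor", "gDNA", ("tumor1",), mean_depth=1385, dispersion=0.25),
        ExperimentDef("normal1_gdna", "normal", "gDNA", ("tumor1",), mean_depth=1280, dispersion=0.25),
        ExperimentDef("tumor2_gdna", "tumor", "gDNA", ("tumor2",), mean_depth=1466, dispersion=0.25),
        ExperimentDef("normal2_gdna", "normal", "gDNA", ("tumor2",), mean_depth=792, dispersion=0.25),
        ExperimentDef("tumor1_wga", "tumor", "wgaDNA", ("tumor1",), mean_depth=1564, dispersion=0.80),
        ExperimentDef("tumor2_wga", "tumor", "wgaDNA", ("tumor2",), mean_depth=1569, dispersion=0.80),
        pool("pool2", ("tumor1", "u01"), (0.5, 0.5), 1752),
        pool("pool5", pool5_members, pool5_weights, 1502),
        pool("pool10", pool10_members, pool10_weights, 1044),
        pool("pool2_rep", ("tumor1", "u01"), (0.5, 0.5), 1150, replicate_of="pool2"),
        pool("pool5_rep", pool5_members, pool5_weights, 1021, replicate_of="pool5"),
        pool("pool10_rep", pool10_members, pool10_weights, 1386, replicate_of="pool10"),
    ]
    patients = [
        PatientDef("patient1", "tumor1", "tumor1_gdna", "normal1_gdna"),
        PatientDef("patient2", "tumor2", "tumor2_gdna", "normal2_gdna"),
    ]
    wga_pairs = [
        WgaPairDef("patient1", "tumor1_gdna", "tumor1_wga"),
        WgaPairDef("patient2", "tumor2_gdna", "tumor2_wga"),
    ]
    pool_evals = [
        PoolEvalDef("pool2", "patient1", "patient2"),
        PoolEvalDef("pool5", "patient2", "patient1"),
        PoolEvalDef("pool10", "patient1", "patient2"),
        PoolEvalDef("pool2_rep", "patient1", "patient2"),
        PoolEvalDef("pool5_rep", "patient2", "patient1"),
        PoolEvalDef("pool10_rep", "patient1", "patient2"),
    ]
    return RunConfig(
        mode="simulate",
        master_seed=master_seed,
        cohort=cohort,
        experiments=experiments,
        patients=patients,
        wga_pairs=wga_pairs,
        pool_evals=pool_evals,
    )


# ---------------------------------------------------------------------------
# Config (de)serialization
# ---------------------------------------------------------------------------

def _tupled(value: Any) -> Any:
    if isinstance(value, list):
        return tuple(value)
    return value


def _build(cls, data: Mapping[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            kwargs[f.name] = _tupled(data[f.name])
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid {cls.__name__}: {exc}") from exc


def config_from_dict(data: Mapping[str, Any]) -> RunConfig:
    data = dict(data)
    cfg = RunConfig(
        mode=data.pop("mode", "simulate"),
        master_seed=int(data.pop("master_seed", 0)),
        cohort=_build(CohortConfig, data.pop("cohort", {})),
        experiments=[_build(ExperimentDef, e) for e in data.pop("experiments", [])],
        patients=[_build(PatientDef, p) for p in data.pop("patients", [])],
        wga_pairs=[_build(WgaPairDef, p) for p in data.pop("wga_pairs", [])],
        pool_evals=[_build(PoolEvalDef, p) for p in data.pop("pool_evals", [])],
        validation=_build(ValidationThresholds, data.pop("validation", {})),
        detection_numerator=float(data.pop("detection_numerator", 0.05)),
        denovo=_build(DeNovoConfig, data.pop("denovo", {})),
        blacklist_coverage=float(data.pop("blacklist_coverage", 0.9)),
        weight_concentration=data.pop("weight_concentration", None),
        paths=_build(PathsConfig, data.pop("paths", {})),
    )
    if data:
        raise ConfigurationError(f"unknown RunConfig keys: {sorted(data)}")
    if not isinstance(cfg.denovo.blacklist, frozenset):
        cfg.denovo = dataclasses.replace(
            cfg.denovo,
            blacklist=frozenset((str(c), int(p)) for c, p in cfg.denovo.blacklist),
        )
    return cfg


def config_to_dict(cfg: RunConfig) -> dict[str, Any]:
    def clean(obj: Any) -> Any:
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: clean(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, Mapping):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, frozenset):
            return sorted(clean(v) for v in obj)
        if isinstance(obj, (tuple, list)):
            return [clean(v) for v in obj]
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        return obj

    return clean(cfg)


def load_config(path: str | Path) -> RunConfig:
    with Path(path).open(encoding="utf-8") as handle:
        data = yaml.safe_load(handle) or {}
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return config_from_dict(data)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        yaml.safe_dump(config_to_dict(cfg), handle, sort_keys=True)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    """Consolidated results of one pipeline run."""

    mode: str
    master_seed: int
    patients: dict[str, dict[str, Any]] = field(default_factory=dict)
    wga: dict[str, dict[str, Any]] = field(default_factory=dict)
    experiments: dict[str, dict[str, Any]] = field(default_factory=dict)
    pools: dict[str, dict[str, Any]] = field(default_factory=dict)
    denovo: dict[str, dict[str, Any]] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _validate_config(cfg: RunConfig) -> None:
    exp_ids = [e.id for e in cfg.experiments]
    if len(set(exp_ids)) != len(exp_ids):
        raise ConfigurationError("duplicate experiment ids in roster")
    known = set(exp_ids)
    if cfg.mode not in ("simulate", "analyze"):
        raise ConfigurationError(f"mode must be 'simulate' or 'analyze', got {cfg.mode!r}")
    if cfg.mode == "simulate":
        samples = set(cfg.cohort.resolved_sample_ids)
        for e in cfg.experiments:
            unknown = set(e.members) - samples
            if unknown:
                raise ConfigurationError(
                    f"experiment {e.id!r} references unknown samples: {sorted(unknown)}"
                )
            if not e.members:
                raise ConfigurationError(f"experiment {e.id!r} has no members")
    else:
        if not cfg.paths.count_table:
            raise ConfigurationError("analyze mode requires paths.count_table")
    for e in cfg.experiments:
        if e.replicate_of is not None and e.replicate_of not in known:
            raise ConfigurationError(f"experiment {e.id!r}: unknown replicate_of {e.replicate_of!r}")
    for p in cfg.patients:
        for ref in (p.tumor_experiment, p.normal_experiment):
            if ref not in known:
                raise ConfigurationError(f"patient {p.label!r} references unknown experiment {ref!r}")
    patient_labels = {p.label for p in cfg.patients}
    for w in cfg.wga_pairs:
        for ref in (w.gdna_experiment, w.wga_experiment):
            if ref not in known:
                raise ConfigurationError(f"wga pair {w.label!r} references unknown experiment {ref!r}")
    for pe in cfg.pool_evals:
        if pe.pool_experiment not in known:
            raise ConfigurationError(f"pool eval references unknown experiment {pe.pool_experiment!r}")
        for pat in (pe.focal_patient, pe.negative_patient):
            if pat not in patient_labels:
                raise ConfigurationError(f"pool eval references unknown patient {pat!r}")


def _simulate_roster(
    cfg: RunConfig, outdir: Path
) -> tuple[dict[str, tuple[Experiment, dict[VariantSite, SiteCounts]]], frozenset, frozenset]:
    """Generate truth + counts for every experiment; write all simulate-mode artifacts."""
    cohort_cfg = dataclasses.replace(cfg.cohort, seed=cfg.master_seed)
    truths = generate_cohort(cohort_cfg)
    truth_map = {t.sample_id: t for t in truths}

    master = np.random.SeedSequence(cfg.master_seed)
    children = master.spawn(len(cfg.experiments) + 1)
    aux_rng = np.random.default_rng(children[-1])

    records: list[tuple[Experiment, SiteCounts]] = []
    for child, edef in zip(children, cfg.experiments):
        experiment, counts = simulate_experiment(
            truth_map,
            edef.pool_spec(),
            edef.depth_model(),
            cohort_cfg,
            experiment_id=edef.id,
            kind=edef.kind,
            replicate_of=edef.replicate_of,
            weight_concentration=cfg.weight_concentration if edef.kind == "pool" else None,
            seed=np.random.default_rng(child),
        )
        logger.info("simulated %s: %d sites", edef.id, len(counts))
        records.extend((experiment, c) for c in counts)

    # Shared germline loci: the dbSNP-proxy blacklist covers a fraction of
    # them; the het-SNP precision statistic uses loci that are plain
    # heterozygous (no LOH) in both reference patients.
    ref_samples = cohort_cfg.resolved_sample_ids[: min(2, cohort_cfg.n_samples)]
    germline_sites = sorted(
        {s for t in truths for s, r in t.records.items() if r.label == "germline"}
    )
    het_sites = [
        s
        for s in germline_sites
        if all(
            truth_map[sid].records.get(s) is not None
            and truth_map[sid].records[s].true_af_tumor == 0.5
            for sid in ref_samples
        )
    ]
    n_black = int(round(cfg.blacklist_coverage * len(germline_sites)))
    black_idx = sorted(aux_rng.permutation(len(germline_sites))[:n_black])
    blacklist = frozenset(germline_sites[i].key for i in black_idx)

    write_count_table(records, outdir / "counts.tsv")
    write_truth_table(truths, outdir / "truth.tsv")
    with (outdir / "blacklist.tsv").open("w", encoding="utf-8") as fh:
        for chrom, pos in sorted(blacklist):
            fh.write(f"{chrom}\t{pos}\n")
    with (outdir / "germline_sites.tsv").open("w", encoding="utf-8") as fh:
        for site in het_sites:
            fh.write(f"{site.chrom}\t{site.pos}\n")
    with (outdir / "target.bed").open("w", encoding="utf-8") as fh:
        fh.write(f"{cohort_cfg.chrom}\t0\t{cohort_cfg.region_length}\n")

    return group_by_experiment(records), blacklist, frozenset(s.key for s in het_sites)


def _load_roster(cfg: RunConfig) -> tuple[dict, frozenset, frozenset]:
    records = load_count_table(cfg.paths.count_table)
    blacklist: frozenset = frozenset()
    if cfg.paths.blacklist:
        blacklist = load_site_list(cfg.paths.blacklist, cfg.paths.blacklist_format)
    het_keys: frozenset = frozenset()
    if cfg.paths.germline_sites:
        het_keys = load_site_list(cfg.paths.germline_sites, "tsv")
    return group_by_experiment(records), blacklist, het_keys


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> RunReport:
    """Run the full pipeline; returns the report and writes all artifacts.

    Deterministic given ``cfg.master_seed`` in simulate mode.  Configuration
    errors are raised before any output file is created.
    """
    _validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg.mode == "simulate":
        tables, blacklist, het_keys = _simulate_roster(cfg, outdir)
    else:
        tables, blacklist, het_keys = _load_roster(cfg)

    denovo_cfg = dataclasses.replace(cfg.denovo, blacklist=cfg.denovo.blacklist | blacklist)
    report = RunReport(mode=cfg.mode, master_seed=cfg.master_seed)

    # --- 1. somatic validation per patient --------------------------------
    somatic_sets: dict[str, set[VariantSite]] = {}
    for patient in cfg.patients:
        _, tumor_table = tables[patient.tumor_experiment]
        _, normal_table = tables[patient.normal_experiment]
        status_df, summary = validate_cohort(tumor_table, normal_table, cfg.validation)
        somatic = set(
            VariantSite(r.chrom, r.pos, r.ref, r.alt)
            for r in status_df.itertuples()
            if r.status == SomaticStatus.SOMATIC.value
        )
        somatic_sets[patient.label] = somatic
        status_df.to_csv(outdir / f"status_{patient.label}.tsv", sep="\t", index=False, float_format="%.6g")
        report.patients[patient.label] = {
            "tumor_experiment": patient.tumor_experiment,
            "normal_experiment": patient.normal_experiment,
            "n_sites": int(len(status_df)),
            "n_somatic": summary[SomaticStatus.SOMATIC],
            "n_non_validated": summary[SomaticStatus.NON_VALIDATED],
            "n_insufficient_depth": summary[SomaticStatus.INSUFFICIENT_DEPTH],
        }
        logger.info("%s: %d somatic of %d sites", patient.label, len(somatic), len(status_df))

    # --- 2. evenness + het-SNP precision per experiment; wga concordance --
    for edef in cfg.experiments:
        experiment, table = tables[edef.id]
        depths = [c.depth for c in table.values()]
        entry: dict[str, Any] = {
            "kind": experiment.kind,
            "material": experiment.material,
            "pool_size": experiment.pool_size,
            "n_sites": len(depths),
            "mean_depth": float(np.mean(depths)) if depths else 0.0,
            "depth_cv": coefficient_of_variation(depths) if depths else float("nan"),
            "depth_gini": gini_index(depths) if depths else float("nan"),
        }
        if experiment.pool_size == 1 and het_keys:
            afs = [
                allele_fraction(c)
                for c in table.values()
                if c.site.key in het_keys and c.depth >= cfg.validation.min_depth
            ]
            if afs:
                entry["het_snp_mad"] = float(np.mean(np.abs(np.asarray(afs) - 0.5)))
                entry["n_het_snps"] = len(afs)
        report.experiments[edef.id] = entry

    for pair in cfg.wga_pairs:
        _, gdna = tables[pair.gdna_experiment]
        _, wga = tables[pair.wga_experiment]
        shared = [
            s
            for s in gdna
            if s in wga
            and gdna[s].depth >= cfg.validation.min_depth
            and wga[s].depth >= cfg.validation.min_depth
        ]
        x = [allele_fraction(gdna[s]) for s in shared]
        y = [allele_fraction(wga[s]) for s in shared]
        report.wga[pair.label] = {
            "gdna_experiment": pair.gdna_experiment,
            "wga_experiment": pair.wga_experiment,
            "n_sites": len(shared),
            "pearson_r": pearson_correlation(x, y),
            "rmse": rmse(x, y),
        }

    # --- 3. known-SNV detection in pools ----------------------------------
    for pe in cfg.pool_evals:
        experiment, pool_table = tables[pe.pool_experiment]
        n = experiment.pool_size
        threshold = DetectionThreshold(pool_size=n, numerator=cfg.detection_numerator)
        positives = somatic_sets[pe.focal_patient]
        negatives = somatic_sets[pe.negative_patient] - positives
        result = confusion_matrix(pool_table, positives, negatives, threshold)
        cm = result.cm

        focal = next(p for p in cfg.patients if p.label == pe.focal_patient)
        _, focal_gdna = tables[focal.tumor_experiment]
        mr_obs, mr_exp = [], []
        for site in sorted(positives):
            pool_counts = pool_table.get(site)
            gdna_counts = focal_gdna.get(site)
            if pool_counts is None or gdna_counts is None:
                continue
            if pool_counts.depth == 0 or gdna_counts.depth == 0:
                continue
            mr_obs.append(allele_fraction(pool_counts))
            mr_exp.append(allele_fraction(gdna_counts) / n)
        mr = median_ratio(mr_obs, mr_exp) if mr_obs else float("nan")

        # Re-detection after rescaling by the skew estimate: how many sites
        # detected in the original analysis are lost?
        n_lost = 0
        if mr_obs and np.isfinite(mr) and mr > 0:
            scaled = scale_allele_fractions(mr_obs, mr)
            for orig, adj in zip(mr_obs, scaled):
                if orig >= threshold.value and adj < threshold.value:
                    n_lost += 1

        rows = []
        for site in sorted(set(positives) | set(negatives)):
            cls = result.site_class[site]
            counts = pool_table.get(site)
            covered = counts is not None and counts.depth > 0
            rows.append(
                "\t".join(
                    [
                        site.chrom,
                        str(site.pos),
                        site.ref,
                        site.alt,
                        f"{allele_fraction(counts):.6g}" if covered else "NA",
                        f"{allele_fraction(focal_gdna[site]) / n:.6g}"
                        if site in positives and site in focal_gdna and focal_gdna[site].depth > 0
                        else "NA",
                        str(int(cls == "TP" or cls == "FP")),
                        cls,
                    ]
                )
            )
        with (outdir / f"pool_{pe.pool_experiment}.tsv").open("w", encoding="utf-8") as fh:
            fh.write("chrom\tpos\tref\talt\tobserved_af\texpected_af\tdetected\tclass\n")
            fh.write("\n".join(rows) + ("\n" if rows else ""))

        entry = {
            "pool_size": n,
            "threshold": threshold.value,
            "focal_patient": pe.focal_patient,
            "tp": cm.tp,
            "tn": cm.tn,
            "fp": cm.fp,
            "fn": cm.fn,
            "n_excluded": len(result.excluded),
            "median_ratio": mr,
            "n_lost_after_scaling": n_lost,
        }
        if cm.tp + cm.fp > 0:
            entry["fdr_percent"] = false_discovery_rate(cm)
            entry["fdr_fraction"] = false_discovery_rate(cm, percent=False)
        else:
            entry["fdr_percent"] = float("nan")
            entry["fdr_fraction"] = float("nan")
        report.pools[pe.pool_experiment] = entry
        logger.info(
            "%s: tp=%d tn=%d fp=%d fn=%d fdr=%.2f%% mr=%.3f",
            pe.pool_experiment, cm.tp, cm.tn, cm.fp, cm.fn, entry["fdr_percent"], mr,
        )

    # --- 4. de novo calling with replicate concordance --------------------
    all_tables = {eid: table for eid, (_, table) in tables.items()}
    replicate_partner: dict[str, str] = {}
    for edef in cfg.experiments:
        if edef.replicate_of is not None:
            replicate_partner[edef.id] = edef.replicate_of
            replicate_partner[edef.replicate_of] = edef.id

    calls_by_pool: dict[str, list] = {}
    for edef in cfg.experiments:
        if edef.kind != "pool":
            continue
        experiment, pool_table = tables[edef.id]
        stats: dict[str, int] = {}
        calls = denovo_scan(
            pool_table,
            experiment.pool_size,
            denovo_cfg,
            all_tables,
            pool_id=edef.id,
            replicate_id=replicate_partner.get(edef.id),
            stats=stats,
        )
        calls_by_pool[edef.id] = calls
        report.pools.setdefault(edef.id, {})["denovo"] = {
            "n_called": stats["n_called"],
            "attrition": {k: v for k, v in stats.items() if k.startswith("fail_")},
        }
        logger.info("%s de novo: %d calls (%s)", edef.id, stats["n_called"], stats)

    all_calls = []
    seen_pairs = set()
    for edef in cfg.experiments:
        if edef.kind != "pool" or edef.replicate_of is None:
            continue
        base, rep = edef.replicate_of, edef.id
        if (base, rep) in seen_pairs:
            continue
        seen_pairs.add((base, rep))
        merged = replicate_intersect(calls_by_pool.get(base, []), calls_by_pool.get(rep, []))
        all_calls.extend(merged)
        hc_sites = sorted({c.site for c in merged if c.high_confidence})
        lc = [c for c in merged if not c.high_confidence]
        report.denovo[base] = {
            "replicate": rep,
            "n_high_confidence": len(hc_sites),
            "n_discordant": len(lc),
        }
    # pools without a replicate partner: keep their raw calls
    for pool_id, calls in calls_by_pool.items():
        if pool_id not in replicate_partner:
            all_calls.extend(calls)

    with (outdir / "denovo_calls.tsv").open("w", encoding="utf-8") as fh:
        fh.write(
            "chrom\tpos\tref\talt\tpool_id\tobserved_af\tdepth\texpected_af\tfilters_passed\thigh_confidence\n"
        )
        for c in sorted(all_calls, key=lambda c: (c.site, c.pool_id)):
            fh.write(
                f"{c.site.chrom}\t{c.site.pos}\t{c.site.ref}\t{c.site.alt}\t{c.pool_id}\t"
                f"{c.observed_af:.6g}\t{c.depth}\t{c.expected_af:.6g}\t"
                f"{';'.join(c.filters_passed)}\t{int(c.high_confidence)}\n"
            )

    (outdir / "report.json").write_text(report.to_json() + "\n", encoding="utf-8")
    (outdir / "summary.txt").write_text(summarize(report) + "\n", encoding="utf-8")
    dump_config(cfg, outdir / "resolved_config.yaml")
    return report


# ---------------------------------------------------------------------------
# Human-readable summary
# ---------------------------------------------------------------------------

def _fmt_fdr(value: float) -> str:
    if value != value:  # NaN
        return "NA"
    return f"{value:.1f}"


def summarize(report: RunReport | Mapping[str, Any]) -> str:
    """Render the report as fixed-width tables (FDR at one decimal)."""
    data = report.to_dict() if isinstance(report, RunReport) else dict(report)
    lines: list[str] = []

    patients = data.get("patients", {})
    if patients:
        lines.append("Somatic validation")
        lines.append(f"{'patient':<12}{'sites':>8}{'somatic':>9}{'non_val':>9}{'low_dp':>8}")
        for label, entry in patients.items():
            lines.append(
                f"{label:<12}{entry['n_sites']:>8}{entry['n_somatic']:>9}"
                f"{entry['n_non_validated']:>9}{entry['n_insufficient_depth']:>8}"
            )
        lines.append("")

    pools = data.get("pools", {})
    if pools:
        denovo = data.get("denovo", {})
        lines.append("Pool detection")
        lines.append(
            f"{'pool':<14}{'TP':>6}{'TN':>6}{'FP':>6}{'FN':>6}{'FDR (%)':>9}{'MR':>7}{'novel':>7}"
        )
        for pool_id, entry in pools.items():
            if "tp" not in entry:
                continue
            novel = entry.get("denovo", {}).get("n_called", 0)
            mr = entry.get("median_ratio", float("nan"))
            mr_s = f"{mr:.2f}" if mr == mr else "NA"
            lines.append(
                f"{pool_id:<14}{entry['tp']:>6}{entry['tn']:>6}{entry['fp']:>6}{entry['fn']:>6}"
                f"{_fmt_fdr(entry['fdr_percent']):>9}{mr_s:>7}{novel:>7}"
            )
        for base, entry in denovo.items():
            lines.append(
                f"  {base} + {entry['replicate']}: "
                f"{entry['n_high_confidence']} high-confidence de novo calls, "
                f"{entry['n_discordant']} discordant"
            )
        lines.append("")

    wga = data.get("wga", {})
    if wga:
        lines.append("gDNA vs wgaDNA concordance")
        for label, entry in wga.items():
            lines.append(
                f"{label:<12} r={entry['pearson_r']:.3f}  rmse={entry['rmse']:.3f}  n={entry['n_sites']}"
            )
    return "\n".join(lines).rstrip()
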