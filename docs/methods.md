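# Methods

## Problem and scope

`snvpool` implements the count-level analysis of a deep targeted-sequencing
study design for cancer cohorts: candidate somatic single-nucleotide
variants (SNVs), previously nominated by whole-genome sequencing, are
re-sequenced at high depth (hundreds to thousands of reads per site) in
individual tumor/normal pairs and in **non-indexed pools** of tumor
samples — pools mixed at the genomic-DNA level without per-sample barcodes,
so a read cannot be attributed to a member sample. The package starts at
per-site read counts (ref / alt / other); alignment, pileup generation and
upstream variant calling are outside its contract.

## Model and procedures

### Allele fractions

At a site with counts $(r, a, o)$ the allele fraction is $\mathrm{AF} =
a / (r + a + o)$. Whether the denominator should include reads matching
neither allele is genuinely open; the package defaults to the total depth
and exposes `denominator="ref_alt"` as an alternative. At deep coverage the
two differ by at most the sequencing-error rate. A site with zero
denominator has an *undefined* fraction, kept distinct from a fraction of
zero throughout.

### Somatic validation

A candidate SNV is classified **somatic** when

* tumor AF ≥ 0.1 (inclusive),
* matched-normal AF < 0.01 (exclusive),
* depth ≥ 30 (inclusive) in both samples;

otherwise **non-validated**, or **insufficient_depth** when either depth
fails (sites missing from one table count as insufficient depth rather
than raising, mirroring capture dropout). The boundary conventions are
implemented exactly as stated and are pinned by tests. The heterozygous-SNP
deviation statistic — the mean of $|\mathrm{AF} - 0.5|$ over known
germline het SNPs — summarises allele-fraction precision per experiment.

### Detection of known SNVs in pools

A variant private to one member of an $N$-pool with individual AF $f$ has
expected pooled AF $f / N$ (generalised internally to a weighted mixture
$\sum_i w_i f_i$). Since validation requires $f \ge 0.1$, the lowest
expected pooled AF is $0.1/N$; a known SNV is **detected** when its
observed pooled AF is at least half that, i.e. $\ge 0.05 / N$
(inclusive). Evaluation exploits the non-recurrence of somatic SNVs:
variants validated in a sample *outside* the pool serve as known
negatives. The false discovery rate is $\mathrm{FDR} = FP / (TP + FP)$,
reported as a percentage at one decimal (raw fraction also emitted).

Sites uncovered in the pool are excluded from the confusion matrix and
tallied separately — the default separates capture failure from detection
failure — with `low_depth_policy="undetected"` available to score them as
misses instead.

### Pool-skew estimation (median ratio)

Pool composition is imperfect (DNA quantification and pipetting error).
The **median ratio** MR = median over sites of observed/expected pooled AF
estimates the effective proportion of the focal sample relative to
nominal: MR > 1 means over-representation. Observed fractions can be
rescaled by dividing by MR (capped at 1.0) and detection re-run; the
number of originally detected sites lost after rescaling measures how
sensitive the accuracy estimate is to skew.

### De novo calling in pools

Every covered target-region site is scanned for variants present in a
single (uncharacterised) member. The expected pooled AF of a heterozygous
single carrier is $0.5 / N$, and a site is called only if it passes all
of:

1. **depth** — total pool depth ≥ 30 × N (per-sample depth is
   unobservable in a non-indexed pool, so the total stands in);
2. **af_window** — observed AF within $[0.5, 2] \times 0.5/N$, both ends
   inclusive;
3. **majority_alt** — the row's alt base dominates the other
   non-reference reads (the scan calls the maximal non-reference allele);
4. **blacklist** — the locus is not a known polymorphism
   (dbSNP-proxy list; matching is positional);
5. **cross_experiment** — AF ≤ 1% in every other experiment with
   informative data (depth ≥ 30) at the site, the pool's own replicate
   exempted.

Calls made in both independently prepared replicates of a pool are marked
**high-confidence**; discordant calls are retained as low-confidence with
provenance. Per-filter attrition counts are recorded so the cascade is
auditable.

A note on multi-carrier germline suppression: a variant heterozygous in
exactly two equal-weight members has expected pooled AF exactly at the
upper window edge, where sampling noise decides the window outcome either
way. The window alone therefore reliably rejects only ≥ 3 carriers
(pooled AF ≥ $3 \times 0.5/N$). In a realistic cohort, two-carrier
variants are common polymorphisms and are removed deterministically by the
blacklist or by the cross-experiment filter; the tests exercise exactly
that division of labour.

### Concordance and evenness metrics

Material and replicate comparisons use Pearson correlation and RMSE over
paired allele-fraction vectors (sites with depth ≥ 30 in both
experiments). Coverage evenness per experiment uses the coefficient of
variation (population SD over mean by default; `ddof=1` optional) and the
Gini index in its mean-absolute-difference form
$G = \sum_{ij} |x_i - x_j| / (2 n^2 \mu)$, computed via the sorted-rank
identity, without the $n/(n-1)$ small-sample factor by default
(`corrected=True` applies it). Both are scale-invariant, so ordinal
comparisons between materials are insensitive to the variant chosen.

## Synthetic cohort generator

The generator emulates the data structure the analysis is designed for;
its defaults are the package's reference study conditions:

* **Sites** — placed uniformly without replacement on a 147 kb target
  region; ~1,100 candidate sites in the default two-patient design
  (somatic + null + shared germline), matching the scale of a
  ~1,500-variant capture panel split across two patients.
* **Somatic SNVs** — private to one sample; 227 and 305 in the two
  reference tumors; true AFs drawn from an equal-weight Gaussian mixture
  with means 0.2 and 0.45 (SD 0.03, clipped to (0, 1]) representing two
  leukemic subclones. A `recurrent_fraction` option plants shared somatic
  sites for stress tests. `n_anchors` flags mid-range-AF somatic sites as
  an orthogonally validated anchor set, which must classify somatic on
  clean data.
* **Germline SNPs** — 19 shared het sites (AF 0.5/0.5); the two reference
  samples are always carriers, other samples with probability 0.5. A
  fraction (default 0.1) of each sample's carried sites sits in a
  simulated LOH region (tumor AF 0.95, normal 0.5).
* **Null sites** — 250 per reference patient, no variant reads beyond
  error, representing false-positive candidates from upstream calling.
* **Depths** — negative binomial (gamma-mixed Poisson) with variance
  $\mu(1 + d\mu)$. Presets: genomic DNA $\mu = 1400, d = 0.25$ (CV ≈ 0.5);
  whole-genome-amplified DNA $\mu = 1550, d = 0.80$ (CV ≈ 0.9). Only the
  ordinal claim — amplified material is less even — is calibrated;
  absolute evenness of real captures varies with protocol. $d = 0$ is a
  degenerate constant-depth limit used by tests.
* **Read noise** — alt reads are Binomial(depth, $p$) with
  $p = f(1-e) + (1-f)\,e/3$ at per-base miscall rate $e$ (default 1e-3,
  typical post-filter Illumina scale), miscalls uniform over the three
  wrong bases; "other" reads are Binomial over the remainder at rate
  $2e/3$. Counts always sum to depth.
* **Pools** — default roster mirrors a twelve-experiment design:
  tumor+normal genomic-DNA pairs, amplified-DNA tumor duplicates, and
  replicated pools of 2, 5 and 10. The 5-pool carries its focal sample at
  weight 0.24 (nominal 0.20) and the 10-pool at 0.12 (nominal 0.10) —
  a 1.2× over-representation encoded as exact weights, so the MR statistic
  has a known target of 1.2. Symmetric-Dirichlet weight noise
  (`weight_concentration`, suggested value ≈ 60, which keeps a 1.2×
  excursion within ~2 SD in a 5-pool) is available but off by default so
  the skew mechanism stays deterministic. Replicates re-draw depths and
  read noise from independent seeds over the same truth.
* **Blacklist** — 90% of germline SNP loci by default (dbSNP-proxy
  coverage); the rest emulate novel germline variation that only the
  cross-experiment filter can remove.

All randomness flows from one master seed through per-experiment
`SeedSequence` substreams, so full runs are reproducible byte-for-byte.

### What the generator does not emulate

Alignment artifacts, mappability/segmental-duplication effects,
capture-probe and restriction-fragment structure, strand bias, and
position-correlated error — the dominant sources of false positives and
discordance in real captures. Consequently, clean-simulation results are
*upper bounds*: simulated FDR is near zero and simulated gDNA/wgaDNA
concordance (r ≈ 0.997, RMSE ≈ 0.012) and het-SNP deviation (≈ 0.01 at
depth ~1400) are tighter than real experiments, where artifact processes
dominate binomial noise. Passing tests demonstrate correctness of the
decision rules and statistics and internal consistency of the power
analysis, not real-data error rates.

## Numerical and design choices

* Threshold comparisons are plain float comparisons; tests that check
  boundary behaviour construct counts whose fractions are exactly
  representable at the boundary, and the power oracle derives its minimal
  alt-read count with the same comparison the detector uses.
* Ties/degenerate inputs: empty inputs raise (`het_snp_deviation`,
  `median_ratio`, FDR with no detections, Gini of all-zero depths) rather
  than returning a sentinel; depth-0 sites are "undetermined" and tallied
  separately in pool evaluation.
* `median_ratio` excludes sites with expected AF 0 with a warning; if all
  are excluded it raises.
* Coordinates are 1-based inclusive in count tables and site lists; BED
  is 0-based half-open and converted on load.
* Multi-allelic positions are represented as one row per alt allele.
* Pipeline problem sizes (two patients, ~1,100 sites, twelve experiments)
  keep a full default run under a second while preserving the panel-scale
  statistics; all stochastic tests use fixed seeds and tolerances derived
  from the relevant binomial/Monte-Carlo standard errors, never tuned
  constants.

## Known limitations

* No read-level simulation (FASTQ) or BAM/pileup ingestion; an adapter
  producing the count-table dialect is the intended integration point.
* De novo calls are reported per pool without member attribution —
  impossible without indexing; resolving the carrier requires follow-up
  genotyping of members, or overlapping-pool designs, which are out of
  scope.
* The de novo scan evaluates the single alt allele carried by each count
  row (the dominant non-reference base); sites with two genuine non-ref
  alleles at comparable fractions are not separable in this representation.
* Absolute CV/Gini values depend on the estimator variant (population vs
  sample, correction factor); only ordinal material comparisons are
  calibration-free.
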