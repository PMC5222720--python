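# Methods

## The bi-allelic position score

At a heterozygous position in one cell, RNA-seq reads supporting both
alleles indicate transcription from both chromosome copies. The score used
throughout is a per-(cell, chromosome) proportion: the number of covered
positions whose minor-allele fraction `min(ref, alt)/(ref + alt)` reaches
the ratio threshold, divided by the number of covered positions. Dividing
by the covered-position count makes the statistic scale-free in sequencing
depth and comparable across cells; an alternative normalization by total
read depth at covered positions is available (`CallParams(normalization=
"depth")`) for users who prefer a per-read rate. Defaults:
`ratio_threshold = 0.2`, `min_total_reads = 5`, `min_positions = 5`. The
ratio boundary is inclusive (a 2/10 position at threshold 0.2 is
bi-allelic): some fixed convention is required for reproducibility, and
the inclusive choice keeps the sweep operation's boundary example exact.
Because the call rate is sensitive to the ratio cutoff, the cutoff is a
first-class swept parameter (`threshold_sweep`) rather than a constant.

Cells with fewer than `min_positions` covered positions on a chromosome
get a flagged missing score (`NaN`, `defined = False`), never a silent 0:
a sparsely covered cell carries no evidence of silencing.

## Hypothesis-testing conventions

* **Wilcoxon rank-sum (Mann-Whitney), two-sided.** For combined n ≤ 20 the
  p-value is exact: all C(n_a+n_b, n_a) assignments of the pooled midranks
  are enumerated and the two-sided p is the fraction of assignments whose
  U deviates from n_a·n_b/2 at least as much as observed. Midranks make
  the enumeration well defined under ties (fully tied groups give p = 1).
  Above n = 20, scipy's tie-corrected normal approximation is used. No
  multiple-testing correction is applied to the pairwise stage tests; the
  raw adjacent-stage p-values are reported.
* **Fisher's exact test** (2×2) is the standard two-sided hypergeometric
  test (scipy). For r×c pattern tables the Freeman-Halton extension is
  computed by full enumeration of margin-compatible tables when the grand
  total is ≤ 30 (verified against R `fisher.test` in the suite), with a
  chi-square fallback and warning above that. Zero-margin tables return
  p = 1 with a warning rather than erroring.
* **Spearman correlation** uses average ranks; it is undefined (NaN,
  flagged) for < 3 observations or a constant argument.

## The correlation null

The association between the two focal lncRNAs is judged against an
empirical null rather than a parametric p-value: the Spearman correlation
of the target gene (*XIST*-like) with the focal partner (*XACT*-like) is
ranked within the distribution of the target's correlations with every
gene of a partner panel (all X-linked genes in the pipeline). The reported
`focal_quantile` is the fraction of scored partners with correlation ≤ the
focal one, focal included, so it lies on the lattice {1/m, …, 1}; under
independence it is uniform on that lattice (checked by KS calibration in
the acceptance suite). Partners with zero variance across the selected
cells cannot be ranked and are excluded but counted.

## Gene-level allelic calls

Per condition, read counts are pooled across cells position by position;
a pooled position is informative if it passes the depth filter, bi-allelic
if its pooled ratio reaches the threshold. A gene is bi-allelic with ≥ 1
bi-allelic position among ≥ 2 informative ones (both configurable),
mono-allelic with enough informative but too few bi-allelic positions, and
uninformative otherwise (excluded from the 2×2 mono/bi comparison).
Pooling across cells is only meaningful when the expressed allele is
consistent within the condition — a clonal cell line, or consistently
skewed silencing. The simulator therefore fixes the expressed allele per
position by default (`mono_allele_mode = "clonal"`); the per-cell random
alternative (`"random_cell"`) models random choice per cell, under which
pooled calls are expected to wash out. The demo pipeline pools female
cells only, since male X counts are structurally mono-allelic and would
dilute the condition's signal.

## The single-cell simulator

Study design: per stage (default 2-cell → blastocyst), a fixed number of
embryos, each contributing a fixed number of cells. `sex_ratio` is treated
as a composition, not a sampling probability — per stage the first
`round(ratio · n_embryos)` embryos are female — so stage-level analyses of
female cells never lose a stage to sampling noise.

* **Expression.** Background genes are i.i.d. log-normal (natural-log
  mean 1.5, sd 1.0, an FPKM-like scale with median ≈ 4.5). The two focal
  genes are zero (or an optional maternal trace, default 0; the observable
  maternal signal of the XACT-like transcript is of order 0.005 FPKM)
  strictly before the ZGA stage (default the 8-cell stage, matching the
  4→8-cell onset of embryonic transcription), and log-normal afterwards
  with a Gaussian copula: the latent normals have Pearson correlation
  2·sin(π·ρ_s/6) so the focal Spearman correlation targets `focal_rho`
  (default 0.8, a strong early-stage coupling) exactly in the population
  limit; monotone marginal transforms preserve it. Trophectoderm cells
  silence the XACT-like gene with probability `te_silencing_prob` while
  the XIST-like gene stays on. Lineages (TE/EPI/PE at 0.5/0.25/0.25) are
  assigned from the blastocyst stage onward, with designated marker genes
  boosted 4× in their lineage so generic marker-panel assignment has
  signal to work with.
* **Allele counts.** Per cell × position, total depth is negative binomial
  with mean 15 and size 2 (variance m + m²/r — the strong overdispersion
  of single-cell coverage); zero-depth draws yield no record. The latent
  bi-allelic indicator is Bernoulli with the per-stage schedule on the
  female X (default 0.5 → 0.2 across stages, i.e. progressive silencing),
  0 on the male X, and a flat 0.5 on autosomes. Bi-allelic positions split
  reads Binomial(depth, 1/2); mono-allelic positions put all reads on the
  position's expressed allele apart from an optional symmetric per-read
  error (default 0, used by the threshold-sweep tests to inject false
  calls). The latent indicator is retained (`true_biallelic`) for recovery
  scoring.

What the generator does **not** emulate: transcriptional burst kinetics
and zero inflation beyond the log-normal/NB sampling, embryo genealogy and
shared genotypes across embryos, linkage/phasing structure along the
chromosome (positions are exchangeable), reference-mapping bias, and
cell-type-specific expression programs beyond the marker boosts. Passing
recovery tests therefore show that the statistics detect the programmed
allelic structure at realistic depth and sample sizes — not that they are
robust to every artifact of real scRNA-seq.

## The FISH simulator

One nucleus is a two-channel (z, y, x) stack, default 16×64×64 voxels at
0.3×0.1×0.1 µm — anisotropic voxels, isotropic µm-space geometry — with a
spherical nucleus of radius 2 µm centered in the stack. A cloud is the sum
of `n_puncta` = 150 isotropic Gaussian puncta (σ = 0.25 µm, peak 100
counts) whose centers scatter normally with sd `cloud_spread` (default
0.5 µm) about the cloud center; the dense particulate texture mimics a
lncRNA accumulation of hundreds of transcripts and leaves `cloud_spread`
as the single dispersion ground-truth knob. Cloud centers are uniform in
the nucleus, kept away from the surface by about one cloud extent
(min(σ + spread, 0.45 R)). Channel-1 clouds paired with channel-0
counterparts sit at the counterpart's center displaced by
`inter_channel_offset` µm in a random feasible direction, so channel
overlap runs from complete (offset 0) to none (offset ≫ σ + spread);
infeasible offsets fail loudly after bounded placement attempts. Gaussian
background (mean 10, sd 2) is added and the image clipped at zero.
Determinism is per-seed exact. Output is multi-page TIFF (z-planes
interleaved by channel) plus a JSON sidecar carrying voxel size, channel
order and ground truth; the round trip is bit-exact.

Not modeled: a realistic optical PSF (puncta are isotropic Gaussians),
chromatic aberration and registration error, autofluorescence structure,
nucleus segmentation (one nucleus per stack), and photon-counting noise
(background is Gaussian, not Poisson).

## FISH quantification conventions

* **Threshold**: Otsu's criterion on a 256-bin histogram between the
  image minimum and maximum; the threshold is the bin *edge* maximizing
  between-class variance, ties (flat plateaus across empty bins) broken
  toward the lowest edge; constant images raise. The suite checks
  equality with a naive per-split maximization.
* **Segmentation**: above-threshold (≥, inclusive) voxels, 26-connected
  components, components under `min_voxels` = 27 (≈ a 3³ speck) dropped,
  remainder ordered by integrated intensity. Volume is voxel count ×
  voxel volume, so component volumes sum exactly to the thresholded-set
  volume when `min_voxels` = 1.
* **Dispersion**: D = intensity-weighted mean µm distance of mask voxels
  from the intensity-weighted centroid, divided by the equal-volume
  sphere radius. Calibration: single voxel → 0; uniform ball → 3/4
  (analytic mean distance 3R/4; the digital radius-20 ball measures
  0.7500); exactly translation invariant; invariant within discretization
  under isotropic voxel rescaling. This is a concrete, scale-free
  dispersion definition with an analytic anchor; published dispersion
  values computed by other definitions are not comparable in absolute
  terms, only in ordering (compact coating of a silenced X vs dispersed
  signal over an active X).
* **Co-localization**: Spearman over the *union* of the two channels'
  above-threshold voxel sets. The union keeps voxels that are signal in
  either channel, preserving the anti-correlated regime in which each
  channel is bright over the other's background — an intersection would
  delete exactly those voxels. Intersection and 2D max-projection
  variants are switchable. Fewer than 3 usable voxels or zero variance
  flag the correlation undefined rather than erroring.
* **Patterns**: per-channel cloud counts clipped to {0, 1, 2+} (two X
  chromosomes bound the biologically expected count), group-level
  category counts and positive fractions, rank trend across ordered
  groups, exact contingency comparisons between groups.

## Pipelines and determinism

Both end-to-end pipelines resolve a YAML/dict config, derive all
randomness from its single seed, and stamp every table and the JSON
summary with the seed and a SHA-256 hash of the resolved config.
Re-running an identical config reproduces every bundle file byte for byte
except `run.log`, whose lines carry wall-clock ISO timestamps by design;
the log duplicates no analytic content. Any stage failure aborts with the
stage name and config hash.

In the FISH pipeline, pattern counting and measurement use fixed reference
thresholds computed once from a dedicated calibration nucleus rendered
with clouds: per-nucleus Otsu on a *pure-background* nucleus would simply
split the noise distribution and hallucinate signal, so automatic
thresholding is reserved for nuclei known to contain signal.

## Problem sizes in the test and acceptance runs

Simulation-backed checks run at sizes chosen to keep the full suite fast
while leaving comfortable statistical margins: 60–200 seed replicates for
rate estimates, 4 stages × 40 female cells and 80 X + 80 autosomal
positions for trend recovery, 30 cells per group for the group
comparison, 100 cells × 100 partner genes for the correlation-null
calibration, and 20 nuclei per condition for co-localization medians. The
acceptance script reports each quantity together with the problem size
used.

## Known limitations

* The exact-enumeration rank-sum test is O(C(n, k)) and intentionally
  capped at combined n = 20; beyond that the normal approximation's tie
  correction is scipy's.
* The Freeman-Halton enumeration is exponential in table size and capped
  at a grand total of 30.
* Gene-level calls assume within-condition allelic consistency (see
  above); they are not meaningful for populations with random per-cell
  choice of the silenced chromosome.
* The dispersion and volume measurements depend on the threshold
  convention; comparisons are only valid within a fixed thresholding
  scheme.
* The exact power of the two-sided Fisher test for a (0.8, 0.2) vs
  (0.5, 0.5) category bias at 100 observations per group is 0.69 at
  α = 10⁻⁴ (by enumeration over the binomial outcome distributions), so
  studies of that design detect such a bias at that stringency in about
  two-thirds of replicates, not almost always.
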