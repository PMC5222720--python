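# xaquant

Quantitative machinery for studying X-chromosome activity in early human
development: an allele-specific single-cell RNA-seq statistic of X
inactivation, and 3D RNA-FISH cloud quantification for the two lncRNAs that
coat X chromosomes — *XIST* (the silencer) and *XACT* (which marks active
Xs in human pluripotent cells). It is written for computational biologists
who want to score chromosome-wide allelic imbalance in single cells, or to
measure lncRNA cloud number, volume, dispersion and channel co-localization
in nucleus image stacks — and for anyone who needs ground-truth simulators
to validate such analyses.

## What it computes

**Bi-allelic position score.** For a cell *c* and chromosome *k*, given
read counts (ref, alt) at heterozygous positions, define the allelic ratio
at a position as the minor-allele fraction

    ar = min(ref, alt) / (ref + alt)

A position is *covered* if `ref + alt >= min_total_reads` (default 5) and
*bi-allelic* if additionally `ar >= ratio_threshold` (default 0.2,
inclusive). The coverage-normalized score

    S(c, k) = n_biallelic(c, k) / n_covered(c, k)

is near its autosomal baseline when both X copies are transcribed and falls
toward 0 as one X is silenced. Around the score: threshold sweeps (the call
rate is sensitive to the ratio cutoff, so it is an explicit swept
parameter), Wilcoxon rank-sum group and stage comparisons (exact by
enumeration for combined n ≤ 20), Spearman stage trends, an empirical
correlation null (the *XIST*–*XACT* correlation ranked within *XIST*'s
correlations with every X-linked gene), and per-gene mono/bi-allelic calls
compared between conditions by Fisher's exact test.

**FISH measurements.** Per nucleus and channel: an Otsu threshold (256-bin
between-class-variance maximization), 26-connected components of the
above-threshold voxel set as clouds, per-cloud volume (voxels × voxel
volume), intensity-weighted centroid, and a unitless dispersion

    D = <weighted distance to centroid> / r_eq,   r_eq = (3V / 4π)^(1/3)

which is 3/4 for a uniform ball and grows as signal scatters. Channel
co-localization is the Spearman correlation of the two channels over the
union of their above-threshold voxel sets; populations are summarized by
cloud-count patterns (0/1/2+), positive fractions with rank trends, and
exact contingency comparisons.

**Simulators.** `synth_scrna` generates expression matrices (ZGA burst of
the two focal genes, Gaussian-copula Spearman correlation between them,
trophectoderm-specific *XACT* silencing) and allele count tables (negative
binomial depth, stage-scheduled bi-allelic fractions on the female X, flat
autosomes, purely mono-allelic male X). `synth_fish` renders two-channel 3D
nuclei as sums of Gaussian puncta with controllable cloud spread and
inter-channel offset. Both retain full ground truth for recovery tests.

## Worked example

```
xaquant run scrna --seed 7 --out demo_scrna/
```

simulates 200 cells across five stages (2-cell → blastocyst) with the X
bi-allelic fraction scheduled to fall from 0.5 to 0.2, scores every cell,
and prints (abridged):

```json
{
 "trend_direction": "decreasing",
 "trend_spearman": -0.7150804281504946,
 "terminal_stage_p": 6.786038616738627e-08,
 "correlation_null": {"focal_r": 0.616, "focal_quantile": 1.0,
                      "median_r": -0.017, "n_cells": 120},
 "gene_calls": {"table_mono_bi": [[0, 62], [25, 37]],
                "p_value": 2.83352668027987e-09}
}
```

The female X score declines with stage (Spearman −0.72 across cells; the
morula-vs-blastocyst Wilcoxon p ≈ 7e−8 recovers the programmed silencing),
the *XIST*–*XACT* correlation ranks above all 30 X-linked null partners
(focal quantile 1.0 against a median null correlation of ≈ 0), and pooled
gene-level calls shift from 62/62 bi-allelic genes at the 2-cell stage to
37/62 at blastocyst (Fisher p ≈ 3e−9).

```
xaquant run fish --seed 7 --out demo_fish/
```

renders a compact population (cloud spread 0.3 µm, zero inter-channel
offset) against a dispersed one (0.9 µm, offset 1.2 µm) and reports median
dispersions 0.62 vs 0.80 (Wilcoxon p ≈ 2e−5), with per-nucleus channel
correlations of median +0.92 when the clouds coincide and −0.54 when they
are displaced — the anti-correlated regime seen when two lncRNAs occupy
distinct nuclear territories.

Library use mirrors the CLI: `simulate_expression` / `simulate_allele_counts`
→ `call_biallelic` → `stage_trend` / `compare_score_groups` /
`correlation_null`, and `simulate_nucleus` → `compute_threshold` →
`segment_clouds` / `colocalize`. See `docs/methods.md` for models,
parameters and caveats.

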