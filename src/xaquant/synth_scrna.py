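"""Synthetic single-cell RNA-seq with known X-activity ground truth.

The generator emulates the structure of early-human-embryo single-cell
datasets that X-inactivation analyses rely on:

* a zygotic-genome-activation (ZGA) burst — two focal X-linked lncRNA genes
  (an XIST-like and an XACT-like gene) are off (or at a trace maternal
  level) strictly before ``zga_stage`` and log-normally expressed from it on;
* correlated focal expression — post-ZGA the two focal genes reach a target
  Spearman correlation, induced with a Gaussian copula on log expression so
  the rank correlation is exact in the population limit;
* lineage-specific silencing — trophectoderm (TE) cells silence the
  XACT-like gene with a configurable probability while the XIST-like gene
  stays on;
* progressive X silencing — the expected fraction of bi-allelic heterozygous
  X positions in female cells follows a per-stage schedule, while autosomes
  keep a flat fraction; male cells are purely mono-allelic on X;
* coverage-dependent allele sampling — per-position read depth is negative
  binomial, bi-allelic positions split reads by a balanced binomial.

Every record of latent ground truth (which positions are truly bi-allelic,
which TE cells silenced the XACT-like gene) is retained so recovery tests
can score the downstream statistics against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from xaquant.datasets import AlleleCountTable, ExpressionDataset

LINEAGES = ("TE", "EPI", "PE")


def _spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation of the Gaussian copula achieving Spearman rho_s."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


@dataclass
class ScrnaSimConfig:
    """Parameters of the single-cell simulator.

    Stage labels are ordered from earliest to latest; ``zga_stage`` marks
    the first stage at which the focal genes are transcribed.  Depth is
    negative binomial with mean ``coverage_mean`` and size (inverse
    dispersion) ``coverage_dispersion``; background expression is
    log-normal with parameters ``expr_logmean`` / ``expr_logsd`` on the
    natural-log scale.
    """

    stages: tuple[str, ...] = ("2cell", "4cell", "8cell", "morula", "blastocyst")
    n_embryos_per_stage: int = 2
    cells_per_embryo: int | Mapping[str, int] = 8
    sex_ratio: float = 0.5
    zga_stage: str = "8cell"
    focal_rho: float = 0.8
    te_silencing_prob: float = 0.3
    maternal_trace: float = 0.0
    lineage_onset_stage: str | None = "blastocyst"
    lineage_probs: Mapping[str, float] = field(
        default_factory=lambda: {"TE": 0.5, "EPI": 0.25, "PE": 0.25}
    )
    marker_genes_per_lineage: int = 2
    marker_boost: float = 4.0
    biallelic_fraction_by_stage: Mapping[str, float] = field(
        default_factory=lambda: {
            "2cell": 0.5,
            "4cell": 0.5,
            "8cell": 0.5,
            "morula": 0.4,
            "blastocyst": 0.2,
        }
    )
    autosomal_biallelic_fraction: float = 0.5
    mono_allele_mode: str = "clonal"  # "clonal": major allele fixed per position
    n_positions_per_chrom: Mapping[str, int] = field(
        default_factory=lambda: {"X": 120, "7": 120}
    )
    n_genes_per_chrom: Mapping[str, int] = field(default_factory=lambda: {"X": 30, "7": 30})
    coverage_mean: float = 15.0
    coverage_dispersion: float = 2.0
    expr_logmean: float = 1.5
    expr_logsd: float = 1.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("stage list must be nonempty")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("stage labels must be unique")
        if self.zga_stage not in self.stages:
            raise ValueError(f"zga_stage {self.zga_stage!r} not in stages")
        if not -1.0 <= self.focal_rho <= 1.0:
            raise ValueError("focal_rho must be in [-1, 1]")
        for name in ("sex_ratio", "te_silencing_prob", "autosomal_biallelic_fraction",
                     "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        extra = set(self.biallelic_fraction_by_stage) - set(self.stages)
        if extra:
            raise ValueError(f"biallelic_fraction_by_stage has unknown stages: {sorted(extra)}")
        for s, f in self.biallelic_fraction_by_stage.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"biallelic fraction for stage {s!r} must be in [0, 1]")
        if self.lineage_onset_stage is not None and self.lineage_onset_stage not in self.stages:
            raise ValueError(f"lineage_onset_stage {self.lineage_onset_stage!r} not in stages")
        if "X" not in self.n_positions_per_chrom:
            raise ValueError("n_positions_per_chrom must include chromosome 'X'")
        if self.mono_allele_mode not in ("clonal", "random_cell"):
            raise ValueError("mono_allele_mode must be 'clonal' or 'random_cell'")

    def cells_at(self, stage: str) -> int:
        if isinstance(self.cells_per_embryo, Mapping):
            return int(self.cells_per_embryo[stage])
        return int(self.cells_per_embryo)

    def stage_index(self, stage: str) -> int:
        return self.stages.index(stage)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScrnaSimConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(config: ScrnaSimConfig) -> ExpressionDataset:
    """Draw a cells × genes FPKM-scale matrix with the configured structure.

    Focal gene 1 (XIST-like) and focal gene 2 (XACT-like) are zero — or at
    ``maternal_trace`` — strictly before ``zga_stage``; from ``zga_stage``
    on they are log-normal with a Gaussian copula targeting Spearman
    ``focal_rho``.  TE cells silence focal gene 2 with probability
    ``te_silencing_prob``.  Background genes are independent log-normal.
    """
    rng = np.random.default_rng(config.seed)

    # --- cells -------------------------------------------------------------
    cell_ids, embryo_ids, stages_col, sexes, lineages = [], [], [], [], []
    onset = (
        config.stage_index(config.lineage_onset_stage)
        if config.lineage_onset_stage is not None
        else len(config.stages)
    )
    lineage_names = list(config.lineage_probs)
    lineage_p = np.asarray([config.lineage_probs[k] for k in lineage_names], dtype=float)
    lineage_p = lineage_p / lineage_p.sum()
    embryo_counter = 0
    # sex_ratio is a composition, not a sampling probability: per stage the
    # first round(ratio * n) embryos are female, so every stage carries
    # female cells whenever the ratio and embryo count allow it
    n_female = int(round(config.sex_ratio * config.n_embryos_per_stage))
    for si, stage in enumerate(config.stages):
        for ei in range(config.n_embryos_per_stage):
            embryo = f"embryo{embryo_counter:03d}"
            embryo_counter += 1
            sex = "F" if ei < n_female else "M"
            for ci in range(config.cells_at(stage)):
                cell_ids.append(f"{embryo}_c{ci:03d}")
                embryo_ids.append(embryo)
                stages_col.append(stage)
                sexes.append(sex)
                if si >= onset:
                    lineages.append(str(rng.choice(lineage_names, p=lineage_p)))
                else:
                    lineages.append("none")
    cell_meta = pd.DataFrame(
        {"embryo_id": embryo_ids, "stage": stages_col, "sex": sexes, "lineage": lineages},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    n_cells = len(cell_meta)

    # --- genes -------------------------------------------------------------
    genes, chroms, markers = ["XIST", "XACT"], ["X", "X"], ["", ""]
    for chrom, n_genes in config.n_genes_per_chrom.items():
        for gi in range(n_genes):
            genes.append(f"g{chrom}_{gi:03d}")
            chroms.append(str(chrom))
            markers.append("")
    # designate the first background genes as lineage markers
    bg_index = 2
    for lineage in lineage_names:
        for _ in range(config.marker_genes_per_lineage):
            if bg_index < len(genes):
                markers[bg_index] = lineage
                bg_index += 1
    gene_meta = pd.DataFrame(
        {
            "chrom": chroms,
            "is_focal1": [g == "XIST" for g in genes],
            "is_focal2": [g == "XACT" for g in genes],
            "marker": markers,
        },
        index=pd.Index(genes, name="gene"),
    )

    # --- expression --------------------------------------------------------
    values = np.exp(
        rng.normal(config.expr_logmean, config.expr_logsd, size=(n_cells, len(genes)))
    )

    stage_idx = np.asarray([config.stage_index(s) for s in cell_meta["stage"]])
    pre_zga = stage_idx < config.stage_index(config.zga_stage)
    post_zga = ~pre_zga

    rho_p = _spearman_to_pearson(config.focal_rho)
    cov = np.array([[1.0, rho_p], [rho_p, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=int(post_zga.sum()), method="cholesky")
    focal = np.exp(config.expr_logmean + config.expr_logsd * z)
    values[post_zga, 0] = focal[:, 0]
    values[post_zga, 1] = focal[:, 1]
    values[pre_zga, 0] = config.maternal_trace
    values[pre_zga, 1] = config.maternal_trace

    is_te = (cell_meta["lineage"] == "TE").to_numpy()
    silenced = is_te & (rng.random(n_cells) < config.te_silencing_prob)
    values[silenced, 1] = 0.0

    # boost lineage marker genes in their lineage
    for gi, lineage in enumerate(markers):
        if lineage:
            in_lineage = (cell_meta["lineage"] == lineage).to_numpy()
            values[in_lineage, gi] *= config.marker_boost

    vdf = pd.DataFrame(values, index=cell_meta.index, columns=gene_meta.index)
    return ExpressionDataset(vdf, gene_meta, cell_meta)


# ---------------------------------------------------------------------------
# allele counts
# ---------------------------------------------------------------------------

def simulate_allele_counts(
    dataset: ExpressionDataset, config: ScrnaSimConfig
) -> AlleleCountTable:
    """Draw per-cell ref/alt read counts at heterozygous positions.

    Per cell × position, total depth is negative binomial
    (``coverage_mean``, ``coverage_dispersion``).  A latent bi-allelic
    indicator is Bernoulli with the stage schedule on female X, zero on
    male X, and ``autosomal_biallelic_fraction`` elsewhere.  Bi-allelic
    positions split reads Binomial(depth, 1/2); mono-allelic positions put
    all reads on one (random) allele, apart from per-read errors at
    ``error_rate``.  Zero-depth draws produce no record.  The latent
    indicator is kept in a ``true_biallelic`` column.
    """
    rng = np.random.default_rng(config.seed + 1)

    for stage in dataset.cell_meta["stage"].unique():
        if stage not in config.biallelic_fraction_by_stage:
            raise ValueError(
                f"biallelic_fraction_by_stage has no entry for stage {stage!r}"
            )

    # positions per chromosome, assigned round-robin to that chromosome's genes
    pos_chrom, pos_coord, pos_gene = [], [], []
    for chrom, n_pos in config.n_positions_per_chrom.items():
        chrom = str(chrom)
        chrom_genes = list(dataset.gene_meta.index[dataset.gene_meta["chrom"] == chrom])
        if not chrom_genes:
            raise ValueError(f"no genes on chromosome {chrom!r} to host positions")
        for i in range(int(n_pos)):
            pos_chrom.append(chrom)
            pos_coord.append((i + 1) * 1000)  # 1-based coordinates
            pos_gene.append(chrom_genes[i % len(chrom_genes)])
    n_pos = len(pos_chrom)
    pos_chrom_arr = np.asarray(pos_chrom)
    is_x_pos = pos_chrom_arr == "X"

    cells = dataset.cell_meta.index.to_numpy()
    stages = dataset.cell_meta["stage"].to_numpy()
    is_female = (dataset.cell_meta["sex"] == "F").to_numpy()
    stage_frac = np.asarray(
        [config.biallelic_fraction_by_stage[s] for s in stages], dtype=float
    )
    n_cells = len(cells)

    # cell-major flat grid
    depth = _negative_binomial(
        rng, config.coverage_mean, config.coverage_dispersion, size=(n_cells, n_pos)
    )
    p_bi = np.where(
        is_x_pos[None, :],
        np.where(is_female[:, None], stage_frac[:, None], 0.0),
        config.autosomal_biallelic_fraction,
    )
    true_bi = rng.random((n_cells, n_pos)) < p_bi

    ref = np.zeros((n_cells, n_pos), dtype=np.int64)
    alt = np.zeros((n_cells, n_pos), dtype=np.int64)
    # bi-allelic: balanced binomial split
    ref[true_bi] = rng.binomial(depth[true_bi], 0.5)
    alt[true_bi] = depth[true_bi] - ref[true_bi]
    # mono-allelic: all reads on one random allele, minus per-read errors
    mono = ~true_bi
    minor = (
        rng.binomial(depth[mono], config.error_rate)
        if config.error_rate > 0
        else np.zeros(int(mono.sum()), dtype=np.int64)
    )
    if config.mono_allele_mode == "clonal":
        # the expressed allele is a fixed property of the position, as in a
        # clonal line (or consistently skewed silencing), so condition-level
        # pooling across cells preserves mono-allelic signal
        major_is_ref_pos = rng.random(n_pos) < 0.5
        major_is_ref = np.broadcast_to(major_is_ref_pos[None, :], (n_cells, n_pos))[mono]
    else:
        major_is_ref = rng.random(int(mono.sum())) < 0.5
    mono_ref = np.where(major_is_ref, depth[mono] - minor, minor)
    ref[mono] = mono_ref
    alt[mono] = depth[mono] - mono_ref

    keep = depth > 0
    cell_idx, pos_idx = np.nonzero(keep)
    records = pd.DataFrame(
        {
            "cell_id": cells[cell_idx],
            "chrom": pos_chrom_arr[pos_idx],
            "pos": np.asarray(pos_coord)[pos_idx],
            "gene": np.asarray(pos_gene)[pos_idx],
            "ref_count": ref[keep],
            "alt_count": alt[keep],
            "true_biallelic": true_bi[keep],
        }
    )
    return AlleleCountTable(records)


def _negative_binomial(
    rng: np.random.Generator, mean: float, size_param: float, size: tuple[int, ...]
) -> np.ndarray:
    """NB draws parameterised by mean and size r (variance = m + m^2/r)."""
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=size).astype(np.int64)
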