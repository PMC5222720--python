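"""X-chromosome activity from allele-specific single-cell counts.

The central statistic is the *coverage-normalized bi-allelic-position
score*: per cell and chromosome, the number of heterozygous positions whose
minor-allele read fraction reaches a threshold, divided by the number of
positions passing the depth filter.  In a female cell, two active X
chromosomes produce many bi-allelic X positions; X inactivation (or
erosion-free silencing) drives the X score down while autosomal scores stay
put.  Around the score this module provides:

* a threshold sweep (the call rate is sensitive to the allelic-ratio
  cutoff, so the cutoff is an explicit, swept parameter);
* rank-based group and stage comparisons (Wilcoxon rank-sum, Spearman
  trend across ordered stages);
* per-cell classification of a marker gene as expressed/silent, used to
  split cells into e.g. XACT-positive and XACT-negative groups;
* an empirical correlation null: the Spearman correlation of a target gene
  (XIST-like) with a focal partner (XACT-like), ranked within the
  distribution of its correlations with every gene of a partner panel;
* per-gene mono-/bi-allelic classification pooled over the cells of a
  condition, with a Fisher's exact comparison of mono/bi gene counts
  between two conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from xaquant.datasets import AlleleCountTable, ExpressionDataset
from xaquant.stats import RankSumResult, compare_contingency, rank_sum_test, spearman

SUMMARY_COLUMNS = ["cell_id", "chrom", "n_covered", "n_biallelic", "score", "defined"]


@dataclass
class CallParams:
    """Filters of the bi-allelic-position caller.

    ratio_threshold
        Minimum minor-allele fraction for a covered position to be called
        bi-allelic; inclusive boundary; in (0, 0.5].
    min_total_reads
        Minimum ref+alt depth for a position to count as covered.
    min_positions
        Minimum covered positions per (cell, chromosome) for the score to
        be defined; sparser combinations are flagged missing, never 0.
    normalization
        ``"covered"`` (default): score = n_biallelic / n_covered.
        ``"depth"``: score = n_biallelic / total reads at covered positions.
    """

    ratio_threshold: float = 0.2
    min_total_reads: int = 5
    min_positions: int = 5
    normalization: str = "covered"

    def __post_init__(self) -> None:
        if not 0.0 < self.ratio_threshold <= 0.5:
            raise ValueError("ratio_threshold must be in (0, 0.5]")
        if self.min_total_reads < 1 or self.min_positions < 1:
            raise ValueError("min_total_reads and min_positions must be positive")
        if self.normalization not in ("covered", "depth"):
            raise ValueError("normalization must be 'covered' or 'depth'")


def call_biallelic(table: AlleleCountTable, params: CallParams | None = None) -> pd.DataFrame:
    """Per (cell, chromosome) bi-allelic position counts and score.

    A position is covered iff ``ref + alt >= min_total_reads``; a covered
    position is bi-allelic iff its allelic ratio is ``>= ratio_threshold``
    (inclusive).  Rows with ``n_covered < min_positions`` keep their counts
    but have ``score = NaN`` and ``defined = False``.

    Returns a DataFrame with columns ``cell_id, chrom, n_covered,
    n_biallelic, score, defined``.
    """
    params = params or CallParams()
    if len(table) == 0:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    rec = table.records
    depth = (rec["ref_count"] + rec["alt_count"]).to_numpy()
    covered = depth >= params.min_total_reads
    ratio = table.allelic_ratio.to_numpy()
    biallelic = covered & (ratio >= params.ratio_threshold - 1e-12)

    df = pd.DataFrame(
        {
            "cell_id": rec["cell_id"].to_numpy(),
            "chrom": rec["chrom"].to_numpy(),
            "covered": covered,
            "biallelic": biallelic,
            "covered_depth": np.where(covered, depth, 0),
        }
    )
    grouped = df.groupby(["cell_id", "chrom"], sort=True).agg(
        n_covered=("covered", "sum"),
        n_biallelic=("biallelic", "sum"),
        covered_depth=("covered_depth", "sum"),
    )
    grouped = grouped.reset_index()
    defined = grouped["n_covered"] >= params.min_positions
    denom = (
        grouped["n_covered"]
        if params.normalization == "covered"
        else grouped["covered_depth"]
    ).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(denom > 0, grouped["n_biallelic"] / denom, np.nan)
    grouped["score"] = np.where(defined, score, np.nan)
    grouped["defined"] = defined
    return grouped[SUMMARY_COLUMNS]


def threshold_sweep(
    table: AlleleCountTable,
    thresholds: Sequence[float],
    params: CallParams | None = None,
) -> pd.DataFrame:
    """Bi-allelic summaries at each allelic-ratio threshold.

    Returns the long concatenation of :func:`call_biallelic` outputs with a
    leading ``ratio_threshold`` column.  ``n_covered`` does not depend on
    the threshold; ``n_biallelic`` is non-increasing in it.
    """
    params = params or CallParams()
    out = []
    for thr in thresholds:
        p = CallParams(
            ratio_threshold=float(thr),
            min_total_reads=params.min_total_reads,
            min_positions=params.min_positions,
            normalization=params.normalization,
        )
        summary = call_biallelic(table, p)
        summary.insert(0, "ratio_threshold", float(thr))
        out.append(summary)
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame()


def compare_score_groups(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum comparison of two score groups.

    Exact for combined n <= 20, tie-corrected normal approximation
    otherwise; reports group medians.  Raises if either group has fewer
    than two defined (non-NaN) scores.
    """
    return rank_sum_test(scores_a, scores_b)


def stage_trend(
    summary: pd.DataFrame,
    stage_by_cell: Mapping[str, str] | pd.Series,
    stage_order: Sequence[str],
    chrom: str = "X",
) -> dict:
    """Per-stage score summaries, adjacent-stage tests, and the stage trend.

    Parameters
    ----------
    summary
        Output of :func:`call_biallelic`.
    stage_by_cell
        Mapping cell id → stage label.
    stage_order
        Stage labels from earliest to latest; stages with no defined score
        are skipped with a warning and listed in ``skipped_stages``.
    chrom
        Chromosome whose scores are analysed.

    Returns a dict with ``per_stage`` (DataFrame: stage, n, median, q25,
    q75), ``adjacent_tests`` (DataFrame: stage_a, stage_b, p_value),
    ``trend_spearman`` (score vs stage rank over cells), and
    ``skipped_stages``.
    """
    stage_by_cell = pd.Series(dict(stage_by_cell)) if not isinstance(
        stage_by_cell, pd.Series
    ) else stage_by_cell
    sub = summary[(summary["chrom"] == chrom) & summary["defined"]].copy()
    sub["stage"] = sub["cell_id"].map(stage_by_cell)

    per_stage_rows, scores_by_stage, skipped = [], {}, []
    for stage in stage_order:
        vals = sub.loc[sub["stage"] == stage, "score"].dropna().to_numpy()
        if len(vals) == 0:
            warnings.warn(f"stage {stage!r} has no defined scores; skipped", stacklevel=2)
            skipped.append(stage)
            continue
        scores_by_stage[stage] = vals
        per_stage_rows.append(
            {
                "stage": stage,
                "n": len(vals),
                "median": float(np.median(vals)),
                "q25": float(np.percentile(vals, 25)),
                "q75": float(np.percentile(vals, 75)),
            }
        )
    used = [s for s in stage_order if s in scores_by_stage]
    if len(used) < 2:
        raise ValueError("need defined scores in at least 2 stages")

    adj = []
    for s_a, s_b in zip(used[:-1], used[1:]):
        res = rank_sum_test(scores_by_stage[s_a], scores_by_stage[s_b])
        adj.append({"stage_a": s_a, "stage_b": s_b, "p_value": res.p_value})

    rank_of = {s: i for i, s in enumerate(stage_order)}
    cell_scores = sub["score"].to_numpy()
    cell_ranks = sub["stage"].map(rank_of).to_numpy(dtype=float)
    trend = spearman(cell_ranks, cell_scores)

    return {
        "per_stage": pd.DataFrame(per_stage_rows),
        "adjacent_tests": pd.DataFrame(adj),
        "trend_spearman": trend,
        "skipped_stages": skipped,
    }


def classify_focal_status(
    dataset: ExpressionDataset, gene: str, expr_threshold: float = 0.0
) -> pd.Series:
    """Per-cell ``"positive"``/``"negative"`` status of a marker gene.

    Positive iff expression is strictly greater than ``expr_threshold``
    (so a cell at exactly the threshold — e.g. 0 with the default — is
    negative).
    """
    if gene not in dataset.values.columns:
        raise KeyError(f"gene {gene!r} not present in dataset")
    expr = dataset.values[gene]
    return pd.Series(
        np.where(expr > expr_threshold, "positive", "negative"),
        index=dataset.values.index,
        name=f"{gene}_status",
    )


@dataclass
class CorrelationNull:
    """A focal gene-gene correlation ranked within an empirical null.

    ``r_values`` maps each partner gene to its Spearman correlation with
    the target over the filtered cells; ``focal_quantile`` is the fraction
    of scored partners whose correlation is <= the focal partner's.
    """

    target_gene: str
    focal_partner: str
    r_values: pd.Series
    focal_r: float
    focal_quantile: float
    median_r: float
    n_cells: int
    excluded_partners: list = field(default_factory=list)


def correlation_null(
    dataset: ExpressionDataset,
    target_gene: str,
    partner_set: Sequence[str],
    focal_partner: str,
    cell_filter: Callable[[pd.DataFrame], pd.Series] | pd.Series | None = None,
) -> CorrelationNull:
    """Rank a focal partner's correlation within a panel-wide null.

    Computes the Spearman correlation (average ranks) of ``target_gene``
    with every gene of ``partner_set`` over the filtered cells, and places
    the focal partner's correlation within that empirical distribution.
    Partners with zero variance across the cells are excluded and listed.

    ``cell_filter`` may be a boolean Series over cells or a callable
    applied to ``cell_meta``.
    """
    partner_set = list(partner_set)
    if not partner_set:
        raise ValueError("partner_set must be nonempty")
    if focal_partner not in partner_set:
        raise ValueError(f"focal partner {focal_partner!r} not in partner_set")
    for g in [target_gene] + partner_set:
        if g not in dataset.values.columns:
            raise KeyError(f"gene {g!r} not present in dataset")

    if cell_filter is None:
        mask = pd.Series(True, index=dataset.values.index)
    elif callable(cell_filter):
        mask = cell_filter(dataset.cell_meta).astype(bool)
    else:
        mask = pd.Series(cell_filter, index=dataset.values.index).astype(bool)
    cells = dataset.values.index[mask]
    if len(cells) < 3:
        raise ValueError(f"need >= 3 cells after filtering, got {len(cells)}")

    target = dataset.values.loc[cells, target_gene].to_numpy()
    r_values, excluded = {}, []
    # rank once, correlate as Pearson on ranks (equivalent, one pass per gene)
    target_ranks = pd.Series(target).rank().to_numpy()
    for g in partner_set:
        partner = dataset.values.loc[cells, g].to_numpy()
        if np.all(partner == partner[0]) or np.all(target == target[0]):
            excluded.append(g)
            continue
        partner_ranks = pd.Series(partner).rank().to_numpy()
        r_values[g] = float(np.corrcoef(target_ranks, partner_ranks)[0, 1])
    if focal_partner in excluded:
        raise ValueError(f"focal partner {focal_partner!r} has zero variance")
    if not r_values:
        raise ValueError("no partner with nonzero variance")
    r_series = pd.Series(r_values, name="spearman_r")
    focal_r = r_series[focal_partner]
    return CorrelationNull(
        target_gene=target_gene,
        focal_partner=focal_partner,
        r_values=r_series,
        focal_r=float(focal_r),
        focal_quantile=float((r_series <= focal_r).mean()),
        median_r=float(r_series.median()),
        n_cells=int(len(cells)),
        excluded_partners=excluded,
    )


def gene_allelic_calls(
    table: AlleleCountTable,
    params: CallParams | None = None,
    per_gene_min_positions: int = 2,
    min_biallelic_positions: int = 1,
) -> pd.DataFrame:
    """Classify each gene as mono-/bi-allelic from cell-pooled positions.

    Read counts are pooled over all cells of the table (one condition) per
    position; a pooled position is informative if it passes the depth
    filter and bi-allelic if additionally its pooled allelic ratio reaches
    the threshold.  A gene is ``biallelic`` with at least
    ``min_biallelic_positions`` bi-allelic positions among at least
    ``per_gene_min_positions`` informative ones, ``monoallelic`` with
    enough informative but too few bi-allelic positions, and
    ``uninformative`` otherwise.

    Returns a DataFrame indexed by gene with columns
    ``n_informative_positions``, ``n_biallelic_positions``, ``call``.
    """
    params = params or CallParams()
    if len(table) == 0:
        return pd.DataFrame(
            columns=["n_informative_positions", "n_biallelic_positions", "call"]
        )
    pooled = (
        table.records.groupby(["gene", "chrom", "pos"], sort=True)[["ref_count", "alt_count"]]
        .sum()
        .reset_index()
    )
    depth = pooled["ref_count"] + pooled["alt_count"]
    informative = depth >= params.min_total_reads
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.minimum(pooled["ref_count"], pooled["alt_count"]) / depth
    biallelic = informative & (ratio >= params.ratio_threshold - 1e-12)
    per_gene = pd.DataFrame(
        {
            "n_informative_positions": informative.groupby(pooled["gene"]).sum(),
            "n_biallelic_positions": biallelic.groupby(pooled["gene"]).sum(),
        }
    )
    call = np.where(
        per_gene["n_informative_positions"] < per_gene_min_positions,
        "uninformative",
        np.where(
            per_gene["n_biallelic_positions"] >= min_biallelic_positions,
            "biallelic",
            "monoallelic",
        ),
    )
    per_gene["call"] = call
    per_gene.index.name = "gene"
    return per_gene


def compare_gene_calls(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> dict:
    """Fisher's exact comparison of mono/bi gene counts between conditions.

    Uninformative genes are excluded from the 2×2 table
    ``[[mono_a, bi_a], [mono_b, bi_b]]``.
    """
    def counts(calls: pd.DataFrame, label: str) -> tuple[int, int]:
        informative = calls[calls["call"] != "uninformative"]
        if len(informative) == 0:
            raise ValueError(f"condition {label} has zero informative genes")
        return (
            int((informative["call"] == "monoallelic").sum()),
            int((informative["call"] == "biallelic").sum()),
        )

    mono_a, bi_a = counts(calls_a, "a")
    mono_b, bi_b = counts(calls_b, "b")
    table = [[mono_a, bi_a], [mono_b, bi_b]]
    res = compare_contingency(table)
    return {
        "table": table,
        "p_value": res["p_value"],
        "method": res["method"],
        "biallelic_fraction_a": bi_a / (mono_a + bi_a),
        "biallelic_fraction_b": bi_b / (mono_b + bi_b),
    }


def assign_lineages(
    dataset: ExpressionDataset, panel: Mapping[str, Sequence[str]]
) -> pd.Series:
    """Assign each cell the lineage whose marker panel is most expressed.

    ``panel`` maps lineage label → marker gene list; the score is the mean
    log1p expression of the panel, and each cell takes the argmax lineage.
    """
    scores = {}
    for lineage, genes in panel.items():
        genes = [g for g in genes if g in dataset.values.columns]
        if not genes:
            raise KeyError(f"no panel genes for lineage {lineage!r} present in dataset")
        scores[lineage] = np.log1p(dataset.values[genes]).mean(axis=1)
    score_df = pd.DataFrame(scores)
    return score_df.idxmax(axis=1).rename("lineage")
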