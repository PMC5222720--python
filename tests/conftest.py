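import numpy as np
import pandas as pd
import pytest

from xaquant.datasets import AlleleCountTable, ExpressionDataset
from xaquant.synth_fish import ChannelConfig, FishSimConfig
from xaquant.synth_scrna import ScrnaSimConfig


@pytest.fixture
def small_scrna_config():
    """Small, fast simulator config exercising all stages."""
    return ScrnaSimConfig(
        n_embryos_per_stage=2,
        cells_per_embryo=6,
        n_positions_per_chrom={"X": 40, "7": 40},
        n_genes_per_chrom={"X": 10, "7": 10},
        seed=11,
    )


@pytest.fixture
def small_fish_config():
    return FishSimConfig(seed=11)


def random_allele_table(rng: np.random.Generator, n_cells=3, n_pos=20) -> AlleleCountTable:
    """Random table over two chromosomes, depths 0-30."""
    rows = []
    for c in range(n_cells):
        for chrom in ("X", "7"):
            for p in range(n_pos):
                depth = int(rng.integers(0, 30))
                ref = int(rng.integers(0, depth + 1))
                if depth == 0:
                    continue
                rows.append((f"cell{c}", chrom, (p + 1) * 10, f"g{p % 5}", ref, depth - ref))
    return AlleleCountTable(
        pd.DataFrame(
            rows, columns=["cell_id", "chrom", "pos", "gene", "ref_count", "alt_count"]
        )
    )


def tiny_expression_dataset(values: np.ndarray, genes=None, chroms=None) -> ExpressionDataset:
    """Hand-built dataset: rows are cells, columns genes (first two focal)."""
    n_cells, n_genes = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    chroms = chroms or ["X"] * n_genes
    cells = [f"c{i}" for i in range(n_cells)]
    gene_meta = pd.DataFrame(
        {
            "chrom": chroms,
            "is_focal1": [i == 0 for i in range(n_genes)],
            "is_focal2": [i == 1 for i in range(n_genes)],
            "marker": [""] * n_genes,
        },
        index=pd.Index(genes, name="gene"),
    )
    cell_meta = pd.DataFrame(
        {
            "embryo_id": ["e0"] * n_cells,
            "stage": ["blastocyst"] * n_cells,
            "sex": ["F"] * n_cells,
            "lineage": ["none"] * n_cells,
        },
        index=pd.Index(cells, name="cell_id"),
    )
    vdf = pd.DataFrame(values, index=cell_meta.index, columns=gene_meta.index)
    return ExpressionDataset(vdf, gene_meta, cell_meta)
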