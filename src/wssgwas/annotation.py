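"""Candidate-gene lookup and gene-set over-representation.

Maps QTL regions to overlapping genes (any overlap, 1-based inclusive
intervals, strand ignored) and runs a one-sided hypergeometric test per
user-supplied gene set with Benjamini–Hochberg adjustment. Gene sets
arrive as a two-column (set_id, gene_id) table; no ontology database is
consulted, keeping results deterministic.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data import require_columns


def genes_in_regions(regions: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Genes whose [start, end] interval intersects each region.

    ``regions`` needs columns chrom, region_start_bp (or start_bp) and
    region_end_bp (or end_bp); intervals are 1-based inclusive on both
    sides, so a gene ending one bp before a region start does not
    overlap.
    """
    require_columns(genes, ["gene_id", "chrom", "start_bp", "end_bp"], "gene table")
    start_col = "region_start_bp" if "region_start_bp" in regions else "start_bp"
    end_col = "region_end_bp" if "region_end_bp" in regions else "end_bp"
    rows = []
    gchrom = genes["chrom"].astype(str).to_numpy()
    gstart = genes["start_bp"].to_numpy()
    gend = genes["end_bp"].to_numpy()
    for _, region in regions.iterrows():
        hit = (
            (gchrom == str(region["chrom"]))
            & (gstart <= region[end_col])
            & (gend >= region[start_col])
        )
        for _, gene in genes[hit].iterrows():
            rows.append(
                {
                    "chrom": region["chrom"],
                    "region_start_bp": region[start_col],
                    "region_end_bp": region[end_col],
                    "gene_id": gene["gene_id"],
                    "symbol": gene.get("symbol", ""),
                    "gene_start_bp": gene["start_bp"],
                    "gene_end_bp": gene["end_bp"],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "region_start_bp",
            "region_end_bp",
            "gene_id",
            "symbol",
            "gene_start_bp",
            "gene_end_bp",
        ],
    )


def hypergeometric_enrichment(
    candidates: set[str] | list[str],
    gene_sets: pd.DataFrame,
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per gene set.

    p = P(X ≥ k) for k overlapping genes out of n candidates, a set of
    size K within a universe of N genes; sets and candidates are
    intersected with the universe first. Benjamini–Hochberg adjustment
    across sets.
    """
    require_columns(gene_sets, ["set_id", "gene_id"], "gene-set table")
    universe = set(map(str, universe))
    cand = set(map(str, candidates)) & universe
    N, n = len(universe), len(cand)
    rows = []
    for set_id, sub in gene_sets.groupby("set_id"):
        members = set(map(str, sub["gene_id"])) & universe
        K = len(members)
        k = len(members & cand)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {"set_id": set_id, "overlap": k, "set_size": K,
             "n_candidates": n, "universe": N, "p_value": min(p, 1.0)}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    return out
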