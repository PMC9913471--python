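"""Core in-memory containers shared across the pipeline.

Phenotypes are held as a pandas DataFrame in "wide" layout — one row
per (boar, collection date) with the four semen traits as columns —
since the quality-control rules act on whole records, not single trait
cells. Genotypes are a dense individuals × SNPs matrix of allele counts
{0,1,2} (−1 for missing before imputation) plus a SNP map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: semen trait columns: motility, progressive motility, abnormality rate (%)
#: and total sperm count (×10⁸)
TRAITS = ("spmot", "sppmot", "spabr", "spcount")

#: required phenotype columns besides the traits
PHENO_COLUMNS = (
    "boar_id",
    "collection_date",
    "parity",
    "age_months",
    "interval_days",
    "volume_ml",
)

MISSING_CODE = -1

_SEASONS = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
    12: "winter", 1: "winter", 2: "winter",
}


def season_of(month: int) -> str:
    """Season level from calendar month (Mar–May spring, …, Dec–Feb winter)."""
    return _SEASONS[int(month)]


def year_season(dates: pd.Series) -> pd.Series:
    """Year × season fixed-effect level, e.g. ``2021_summer``."""
    d = pd.to_datetime(dates)
    return d.dt.year.astype(str) + "_" + d.dt.month.map(season_of)


class FormatError(ValueError):
    """Malformed or incomplete input data."""


def require_columns(frame: pd.DataFrame, columns, what: str = "table") -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise FormatError(f"{what} is missing required column(s): {', '.join(missing)}")


@dataclass
class GenotypeMatrix:
    """Individuals × SNPs allele-count matrix with its SNP map.

    ``codes[i, j]`` counts copies of SNP j's counted (A1) allele in
    individual i: 0, 1, 2, or −1 for missing. ``snp_map`` has columns
    ``snp_id, chrom, pos`` (bp, 1-based) and optionally ``a1, a2``.
    """

    individual_ids: list[str]
    codes: np.ndarray  # int8/float, shape (n_ind, n_snp)
    snp_map: pd.DataFrame
    _freq: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.shape != (len(self.individual_ids), len(self.snp_map)):
            raise FormatError(
                f"genotype codes shape {self.codes.shape} does not match "
                f"{len(self.individual_ids)} individuals × {len(self.snp_map)} SNPs"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    def allele_frequencies(self) -> np.ndarray:
        """Counted-allele frequency per SNP, ignoring missing codes.

        Computed once from this (post-QC) sample and cached, so that Z
        centering, λ and weight updates all use the same frequencies.
        """
        if self._freq is None:
            codes = np.ma.masked_equal(self.codes, MISSING_CODE)
            self._freq = np.asarray(codes.mean(axis=0) / 2.0)
        return self._freq

    def subset(self, individuals=None, snps=None) -> "GenotypeMatrix":
        ind_idx = (
            np.arange(self.n_individuals)
            if individuals is None
            else np.asarray(individuals)
        )
        snp_idx = np.arange(self.n_snps) if snps is None else np.asarray(snps)
        return GenotypeMatrix(
            individual_ids=[self.individual_ids[i] for i in ind_idx],
            codes=self.codes[np.ix_(ind_idx, snp_idx)],
            snp_map=self.snp_map.iloc[snp_idx].reset_index(drop=True),
        )

    def sorted_by_position(self) -> "GenotypeMatrix":
        order = self.snp_map.sort_values(
            ["chrom", "pos"], kind="stable"
        ).index.to_numpy()
        return self.subset(snps=order)
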