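"""Phenotype and genotype quality control.

Phenotype rules (semen records):
  (b) ejaculate volume ≤ 50 mL removed;
  (c) sperm motility < 10 % removed;
  (d) inter-collection interval > 60 days removed, and a 0-day interval
      (two collections on the same date) removes the later duplicate;
  (a) after (b)–(d), boars left with fewer than 5 records are dropped
      entirely, so the count reflects usable records.

Genotype rules: unmapped / sex-chromosome / position-less SNPs out
first, then individual call rate < 0.9, SNP call rate < 0.9,
MAF < 0.01, Hardy–Weinberg exact-test p < 1e-6; remaining missing
codes are imputed to the per-SNP mean rounded to the nearest of
{0, 1, 2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    MISSING_CODE,
    FormatError,
    GenotypeMatrix,
    require_columns,
)

SEX_CHROMOSOMES = {"X", "Y", "XY", "MT", "M", "0"}


@dataclass
class QCReport:
    """Per-rule removal counts; removed + retained = input for each entity."""

    entity: str
    n_input: int
    removed: dict[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"entity": self.entity, "rule": rule, "removed": n}
            for rule, n in self.removed.items()
        ]
        rows.append(
            {"entity": self.entity, "rule": "retained", "removed": self.n_retained}
        )
        return pd.DataFrame(rows)


def filter_phenotypes(
    records: pd.DataFrame,
    min_records: int = 5,
    min_volume_ml: float = 50.0,
    min_motility: float = 10.0,
    max_interval_days: int = 60,
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the record-level semen QC rules; see module docstring.

    Volume exactly 50 mL is removed (rule is ≤); interval exactly 60
    days is retained (rule is >).
    """
    require_columns(
        records,
        ["boar_id", "collection_date", "volume_ml", "spmot", "interval_days"],
        "phenotype table",
    )
    rep = QCReport("records", len(records))
    df = records.copy()
    df["collection_date"] = pd.to_datetime(df["collection_date"])
    df = df.sort_values(["boar_id", "collection_date"], kind="stable")

    dup = df.duplicated(["boar_id", "collection_date"], keep="first")
    rep.removed["interval_0_days"] = int(dup.sum())
    df = df[~dup]

    low_vol = df["volume_ml"] <= min_volume_ml
    rep.removed[f"volume_le_{min_volume_ml:g}ml"] = int(low_vol.sum())
    df = df[~low_vol]

    low_mot = df["spmot"] < min_motility
    rep.removed[f"motility_lt_{min_motility:g}pct"] = int(low_mot.sum())
    df = df[~low_mot]

    long_gap = df["interval_days"] > max_interval_days
    rep.removed[f"interval_gt_{max_interval_days}d"] = int(long_gap.sum())
    df = df[~long_gap]

    counts = df.groupby("boar_id")["collection_date"].transform("size")
    few = counts < min_records
    rep.removed[f"boar_lt_{min_records}_records"] = int(few.sum())
    df = df[~few]

    return df.reset_index(drop=True), rep


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Two-sided exact Hardy–Weinberg test p-value on genotype counts.

    Conditional on the observed allele counts, sums the probabilities of
    all heterozygote counts no more likely than the observed one
    (the standard SNP exact test). Returns 1.0 when fewer than one copy
    of the rare allele is present.
    """
    n_het, n_hom1, n_hom2 = int(n_het), int(n_hom1), int(n_hom2)
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom1 + n_hom2
    rare = 2 * min(n_hom1, n_hom2) + n_het
    if n == 0 or rare == 0:
        return 1.0
    # probabilities over all het counts with the same parity as `rare`
    mid = rare * (2 * n - rare) // (2 * n)
    if (mid % 2) != (rare % 2):
        mid += 1
    probs = np.zeros(rare + 1)
    probs[mid] = 1.0
    # downward recurrence: P(h-2)/P(h) = h(h-1) / (4 (hom_r+1)(hom_c+1))
    h = mid
    hom_r = (rare - mid) // 2
    hom_c = n - (mid + hom_r)
    while h > 1:
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
        hom_r += 1
        hom_c += 1
    # upward recurrence: P(h+2)/P(h) = 4 hom_r hom_c / ((h+2)(h+1))
    h = mid
    hom_r = (rare - mid) // 2
    hom_c = n - (mid + hom_r)
    while h + 2 <= rare:
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        h += 2
        hom_r -= 1
        hom_c -= 1
    probs /= probs.sum()
    p_obs = probs[n_het]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_pvalues(codes: np.ndarray) -> np.ndarray:
    """Exact HWE p per SNP column of a {0,1,2,missing} code matrix."""
    out = np.ones(codes.shape[1])
    for j in range(codes.shape[1]):
        col = codes[:, j]
        col = col[col != MISSING_CODE]
        out[j] = hwe_exact_p(
            int(np.sum(col == 1)), int(np.sum(col == 0)), int(np.sum(col == 2))
        )
    return out


@dataclass
class GenotypeQCReport:
    """SNP-level and individual-level removals from genotype QC."""

    snps: QCReport
    individuals: QCReport

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [self.snps.to_frame(), self.individuals.to_frame()], ignore_index=True
        )


def filter_genotypes(
    geno: GenotypeMatrix,
    min_call_rate: float = 0.9,
    min_maf: float = 0.01,
    hwe_threshold: float = 1e-6,
) -> tuple[GenotypeMatrix, GenotypeQCReport]:
    """Apply marker and individual QC; impute residual missing codes.

    Order follows standard practice: map-based SNP removal, individual
    call rate, SNP call rate, MAF, HWE; allele frequencies for the MAF
    rule are computed on the call-rate-passing sample.
    """
    rep = QCReport("snps", geno.n_snps)
    chrom = geno.snp_map["chrom"].astype(str).str.upper()
    pos = pd.to_numeric(geno.snp_map["pos"], errors="coerce")
    bad_map = chrom.isin(SEX_CHROMOSOMES) | pos.isna() | (pos <= 0)
    rep.removed["unmapped_or_sex_chromosome"] = int(bad_map.sum())
    keep_snp = ~bad_map.to_numpy()
    codes = geno.codes[:, keep_snp]

    missing = codes == MISSING_CODE
    ind_call = 1.0 - missing.mean(axis=1) if codes.shape[1] else np.ones(len(missing))
    keep_ind = ind_call >= min_call_rate
    n_ind_removed = int((~keep_ind).sum())
    codes = codes[keep_ind]

    missing = codes == MISSING_CODE
    snp_call = 1.0 - missing.mean(axis=0)
    low_call = snp_call < min_call_rate
    rep.removed["snp_call_rate"] = int(low_call.sum())

    with np.errstate(invalid="ignore"):
        freq = np.ma.masked_equal(codes, MISSING_CODE).mean(axis=0).filled(np.nan) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    low_maf = ~low_call & (np.isnan(maf) | (maf < min_maf))
    rep.removed["maf"] = int(low_maf.sum())

    testable = ~(low_call | low_maf)
    hwe_fail = np.zeros(codes.shape[1], dtype=bool)
    if testable.any():
        pvals = hwe_pvalues(codes[:, testable])
        hwe_fail[np.flatnonzero(testable)[pvals < hwe_threshold]] = True
    rep.removed["hwe"] = int(hwe_fail.sum())

    keep_cols = ~(low_call | low_maf | hwe_fail)
    if not keep_cols.any():
        raise FormatError("genotype QC removed every SNP")

    codes = codes[:, keep_cols].astype(np.int8)
    snp_map = geno.snp_map.loc[keep_snp].loc[keep_cols].reset_index(drop=True)
    # only autosomes remain, so the chromosome label can be numeric
    snp_map = snp_map.assign(chrom=pd.to_numeric(snp_map["chrom"]))
    ids = [i for i, k in zip(geno.individual_ids, keep_ind) if k]
    codes = impute_mean(codes)
    out = GenotypeMatrix(ids, codes, snp_map).sorted_by_position()
    ind_rep = QCReport("individuals", geno.n_individuals)
    ind_rep.removed["individual_call_rate"] = n_ind_removed
    return out, GenotypeQCReport(snps=rep, individuals=ind_rep)


def impute_mean(codes: np.ndarray) -> np.ndarray:
    """Replace missing codes by the per-SNP mean rounded to {0,1,2}."""
    codes = np.asarray(codes)
    out = codes.copy()
    masked = np.ma.masked_equal(codes, MISSING_CODE)
    fill = np.clip(np.rint(masked.mean(axis=0).filled(0)), 0, 2).astype(codes.dtype)
    miss_i, miss_j = np.nonzero(codes == MISSING_CODE)
    out[miss_i, miss_j] = fill[miss_j]
    return out
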