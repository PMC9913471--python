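"""Readers and writers for the standard file formats.

PLINK text (.ped/.map) and binary (.bed/.bim/.fam) genotype layouts,
pedigree CSV (animal,sire,dam with 0 = unknown), phenotype CSV, gene
annotation as BED or GFF3, and TSV result writers.

Genotype codes count copies of the .bim A1 allele, so a .bed byte's
2-bit fields map as 00→2, 10→1, 11→0, 01→missing. BED intervals are
0-based half-open on disk and converted to the internal 1-based
inclusive convention on read.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MISSING_CODE, FormatError, GenotypeMatrix, require_columns
from .pedigree import Pedigree

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major

# 2-bit field value -> allele-count code (count of A1)
_BED_DECODE = np.array([2, MISSING_CODE, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING_CODE: 0b01, 1: 0b10, 0: 0b11}


# ---------------------------------------------------------------------------
# PLINK
# ---------------------------------------------------------------------------

def read_plink(prefix: str | os.PathLike) -> GenotypeMatrix:
    """Read a PLINK fileset, binary (.bed/.bim/.fam) or text (.ped/.map)."""
    prefix = Path(prefix)
    if prefix.with_suffix(".bed").exists():
        return _read_bed(prefix)
    if prefix.with_suffix(".ped").exists():
        return _read_ped(prefix)
    raise FileNotFoundError(f"no {prefix}.bed or {prefix}.ped found")


def _read_bim(path: Path) -> pd.DataFrame:
    bim = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    return bim[["snp_id", "chrom", "pos", "a1", "a2"]]


def _read_fam(path: Path) -> list[str]:
    fam = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if fam.shape[1] < 2:
        raise FormatError(f"{path}: expected at least 2 columns (FID IID)")
    return fam[1].tolist()


def _read_bed(prefix: Path) -> GenotypeMatrix:
    snp_map = _read_bim(prefix.with_suffix(".bim"))
    ids = _read_fam(prefix.with_suffix(".fam"))
    n_ind, n_snp = len(ids), len(snp_map)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK bed)")
    bytes_per_snp = (n_ind + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * n_snp:
        raise FormatError(
            f"{prefix}.bed: size {body.size} != {bytes_per_snp} bytes × {n_snp} SNPs"
        )
    mat = body.reshape(n_snp, bytes_per_snp)
    # unpack 2-bit fields, individual-fastest within a byte (LSB first)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    fields = (mat[:, :, None] >> shifts) & 0b11  # (n_snp, bytes, 4)
    codes = _BED_DECODE[fields.reshape(n_snp, -1)[:, :n_ind]]
    return GenotypeMatrix(ids, codes.T.copy(), snp_map)


def _read_ped(prefix: Path) -> GenotypeMatrix:
    snp_map = pd.read_csv(
        prefix.with_suffix(".map"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos"],
        dtype={"chrom": str, "snp_id": str},
    )[["snp_id", "chrom", "pos"]]
    n_snp = len(snp_map)
    ids: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snp:
                raise FormatError(
                    f"{prefix}.ped line {lineno}: expected {6 + 2 * n_snp} fields, "
                    f"got {len(parts)}"
                )
            ids.append(parts[1])
            allele_rows.append(np.array(parts[6:], dtype="U2"))
    alleles = (
        np.stack(allele_rows) if allele_rows else np.empty((0, 2 * n_snp), dtype="U2")
    )
    a1_col, a2_col, codes = _codes_from_alleles(alleles, n_snp)
    snp_map = snp_map.assign(a1=a1_col, a2=a2_col)
    return GenotypeMatrix(ids, codes, snp_map)


def _codes_from_alleles(alleles: np.ndarray, n_snp: int):
    """Allele-pair text columns → {0,1,2,missing} counts of A1.

    A1 is the lexicographically first non-missing allele observed at the
    SNP (deterministic; 2p(1−p) and Z centering are symmetric in the
    choice).
    """
    n_ind = alleles.shape[0]
    codes = np.full((n_ind, n_snp), MISSING_CODE, dtype=np.int8)
    a1_col, a2_col = [], []
    for j in range(n_snp):
        pair = alleles[:, 2 * j : 2 * j + 2]
        obs = np.unique(pair[pair != "0"])
        if obs.size > 2:
            raise FormatError(f"SNP column {j}: more than two alleles {obs.tolist()}")
        a1 = obs[0] if obs.size else "A"
        a2 = obs[1] if obs.size > 1 else ("B" if obs.size else "B")
        a1_col.append(a1)
        a2_col.append(a2)
        valid = (pair != "0").all(axis=1)
        codes[valid, j] = (pair[valid] == a1).sum(axis=1).astype(np.int8)
    return a1_col, a2_col, codes


def write_plink(geno: GenotypeMatrix, prefix: str | os.PathLike, binary: bool = True) -> None:
    """Write a GenotypeMatrix as .bed/.bim/.fam (or .ped/.map)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    sm = geno.snp_map
    a1 = sm["a1"] if "a1" in sm else pd.Series(["A"] * len(sm))
    a2 = sm["a2"] if "a2" in sm else pd.Series(["B"] * len(sm))
    if binary:
        bim = pd.DataFrame(
            {
                "chrom": sm["chrom"],
                "snp_id": sm["snp_id"],
                "cm": 0,
                "pos": sm["pos"],
                "a1": a1,
                "a2": a2,
            }
        )
        bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
        fam = pd.DataFrame(
            {
                "fid": geno.individual_ids,
                "iid": geno.individual_ids,
                "pat": 0,
                "mat": 0,
                "sex": 0,
                "pheno": -9,
            }
        )
        fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
        n_ind = geno.n_individuals
        bytes_per_snp = (n_ind + 3) // 4
        lut = np.zeros(256, dtype=np.uint8)
        for code, bits in _BED_ENCODE.items():
            lut[int(np.array(code, dtype=np.int8).view(np.uint8))] = bits
        fields = lut[geno.codes.T.astype(np.int8).view(np.uint8)]  # (n_snp, n_ind)
        pad = np.full(
            (geno.n_snps, bytes_per_snp * 4 - n_ind), _BED_ENCODE[0], dtype=np.uint8
        )
        fields = np.concatenate([fields, pad], axis=1).reshape(geno.n_snps, -1, 4)
        shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
        packed = (fields << shifts).sum(axis=2).astype(np.uint8)
        with open(prefix.with_suffix(".bed"), "wb") as fh:
            fh.write(_BED_MAGIC)
            fh.write(packed.tobytes())
    else:
        pd.DataFrame(
            {"chrom": sm["chrom"], "snp_id": sm["snp_id"], "cm": 0, "pos": sm["pos"]}
        ).to_csv(prefix.with_suffix(".map"), sep="\t", header=False, index=False)
        a1v, a2v = a1.to_numpy(), a2.to_numpy()
        with open(prefix.with_suffix(".ped"), "w") as fh:
            for i, iid in enumerate(geno.individual_ids):
                row = geno.codes[i]
                first = np.where(row >= 1, a1v, np.where(row == 0, a2v, "0"))
                second = np.where(row == 2, a1v, np.where(row >= 0, a2v, "0"))
                pairs = np.empty(2 * len(row), dtype=object)
                pairs[0::2] = first
                pairs[1::2] = second
                fh.write(" ".join([iid, iid, "0", "0", "0", "-9", *pairs]) + "\n")


# ---------------------------------------------------------------------------
# pedigree / phenotypes
# ---------------------------------------------------------------------------

def read_pedigree(path: str | os.PathLike) -> Pedigree:
    """Pedigree CSV with columns animal,sire,dam (0 or empty = unknown)."""
    df = pd.read_csv(path, dtype=str)
    require_columns(df, ["animal", "sire", "dam"], "pedigree file")
    return Pedigree.from_frame(df[["animal", "sire", "dam"]])


def write_pedigree(ped: Pedigree, path: str | os.PathLike) -> None:
    ped.to_frame().to_csv(path, index=False)


def read_phenotypes(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"boar_id": str})
    require_columns(df, ["boar_id", "collection_date"], "phenotype file")
    df["collection_date"] = pd.to_datetime(df["collection_date"])
    return df


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def read_annotation(path: str | os.PathLike) -> pd.DataFrame:
    """Gene table with columns gene_id, symbol, chrom, start_bp, end_bp, strand.

    BED input (0-based half-open) is converted to 1-based inclusive;
    GFF3 rows of type ``gene`` are taken as-is (already 1-based
    inclusive).
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3", ".gtf"}:
        return _read_gff3(path)
    return _read_bed_genes(path)


def _read_bed_genes(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED needs at least chrom/start/end columns")
    out = pd.DataFrame(
        {
            "gene_id": df[3] if df.shape[1] > 3 else [f"gene{i}" for i in range(len(df))],
            "symbol": df[3] if df.shape[1] > 3 else "",
            "chrom": df[0].astype(str).str.replace("^chr", "", regex=True),
            "start_bp": df[1].astype(int) + 1,  # half-open 0-based → 1-based inclusive
            "end_bp": df[2].astype(int),
            "strand": df[5] if df.shape[1] > 5 else ".",
        }
    )
    if (out["start_bp"] > out["end_bp"]).any():
        bad = int((out["start_bp"] > out["end_bp"]).sum())
        raise FormatError(f"{path}: {bad} interval(s) with start > end")
    return out


def _read_gff3(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path} line {lineno}: expected 9 tab fields")
            if parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", attrs.get("gene_id", f"line{lineno}"))
            rows.append(
                {
                    "gene_id": gene_id.removeprefix("gene:"),
                    "symbol": attrs.get("Name", attrs.get("gene_name", "")),
                    "chrom": parts[0].removeprefix("chr"),
                    "start_bp": int(parts[3]),
                    "end_bp": int(parts[4]),
                    "strand": parts[6],
                }
            )
    return pd.DataFrame(rows)


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a result table as TSV (the package's uniform output format)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
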