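"""Genomic relationship matrices and the single-step H inverse.

Implements the VanRaden genomic relationship G = Z D Z' / Σ 2p(1-p)
with a diagonal SNP-weight matrix D, the stabilising blend
Gw = 0.9 G + 0.1 A22, and the single-step inverse

    H⁻¹ = A⁻¹ + [0 0; 0 Gw⁻¹ − A22⁻¹]

where the correction acts only on the genotyped block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, sparse

#: blend weights for Gw = BLEND_G·G + BLEND_A·A22, chosen for compatibility
#: between genomic and pedigree information and bias control
BLEND_G = 0.9
BLEND_A = 0.1

_JITTER = 1e-8


class SingularRelationshipError(np.linalg.LinAlgError):
    """Gw (or A22) could not be factorised; advise blending or a ridge."""


def center_genotypes(codes: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Center allele counts: column j of Z is codes_j − 2 p_j."""
    codes = np.asarray(codes, dtype=float)
    return codes - 2.0 * np.asarray(freqs, dtype=float)


def scaling_constant(freqs: np.ndarray) -> float:
    """λ = 1 / Σ 2 p_i (1 − p_i), the reciprocal of the expected marker
    heterozygosity sum that normalises G (and scales back-solved SNP
    effects)."""
    p = np.asarray(freqs, dtype=float)
    s = float(np.sum(2.0 * p * (1.0 - p)))
    if s <= 0:
        raise ValueError("sum of 2p(1-p) is zero: all SNPs monomorphic")
    return 1.0 / s


def build_G(Z: np.ndarray, weights: np.ndarray | None, freqs: np.ndarray) -> np.ndarray:
    """G = Z D Z' / Σ 2p(1−p) with D = diag(weights) (None ⇒ identity)."""
    Z = np.asarray(Z, dtype=float)
    if weights is None:
        ZD = Z
    else:
        w = np.asarray(weights, dtype=float)
        if w.ndim != 1 or w.shape[0] != Z.shape[1]:
            raise ValueError("weights must be a vector of length n_snps")
        if np.any(w < 0):
            raise ValueError("SNP weights must be non-negative")
        ZD = Z * w
    return scaling_constant(freqs) * (ZD @ Z.T)


def blend_Gw(G: np.ndarray, A22: np.ndarray,
             blend_g: float = BLEND_G, blend_a: float = BLEND_A) -> np.ndarray:
    """Gw = 0.9·G + 0.1·A22 (elementwise)."""
    return blend_g * np.asarray(G) + blend_a * np.asarray(A22)


def _chol_inverse(M: np.ndarray, what: str) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant via Cholesky, with one jitter retry."""
    M = np.asarray(M, dtype=float)
    for jitter in (0.0, _JITTER * np.mean(np.diag(M)) * M.shape[0]):
        try:
            c, low = linalg.cho_factor(M + jitter * np.eye(M.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            continue
        logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
        return linalg.cho_solve((c, low), np.eye(M.shape[0])), logdet
    raise SingularRelationshipError(
        f"{what} is not positive definite; blend with A22 or add a ridge"
    )


@dataclass
class HInverse:
    """H⁻¹ as a matrix contract for mixed-model assembly.

    ``matrix`` is H⁻¹ over all pedigree animals (genotyped correction
    embedded); ``logdet`` is log|H| = log|A| + log|Gw| − log|A22|,
    needed by the REML likelihood.
    """

    ids: list[str]
    matrix: sparse.csr_matrix
    logdet: float
    genotyped_index: np.ndarray


def build_Hinv(
    Ainv: sparse.spmatrix,
    A22: np.ndarray,
    Gw: np.ndarray,
    genotyped_index: np.ndarray,
    ids: list[str],
    logdet_A: float = 0.0,
) -> HInverse:
    """Assemble H⁻¹ = A⁻¹ + embed(Gw⁻¹ − A22⁻¹) on the genotyped indices."""
    genotyped_index = np.asarray(genotyped_index, dtype=np.int64)
    n = Ainv.shape[0]
    if genotyped_index.size == 0:
        return HInverse(ids, sparse.csr_matrix(Ainv), logdet_A, genotyped_index)
    Gw_inv, logdet_Gw = _chol_inverse(Gw, "Gw")
    A22_inv, logdet_A22 = _chol_inverse(A22, "A22")
    corr = sparse.coo_matrix(
        (
            (Gw_inv - A22_inv).ravel(),
            (
                np.repeat(genotyped_index, genotyped_index.size),
                np.tile(genotyped_index, genotyped_index.size),
            ),
        ),
        shape=(n, n),
    )
    H = sparse.csr_matrix(Ainv) + corr.tocsr()
    return HInverse(ids, H, logdet_A + logdet_Gw - logdet_A22, genotyped_index)
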