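"""Iterative SNP weighting: the weighted single-step GWAS loop.

Starting from unit SNP weights, each iteration (i) predicts GEBV for
every animal by ssGBLUP under the current weighted genomic relationship,
(ii) back-solves SNP effects from the genotyped animals' GEBV,

    ĝ = λ D Z' Gw⁻¹ â,      λ = 1 / Σ 2 p_i (1 − p_i),

(iii) sets the next weights to d_i = ĝ_i² · 2 p_i (1 − p_i), and
(iv) rescales them so tr(D) stays equal to the SNP count, stabilising
the total genetic variance. Three iterations are the default, after
which window variances are computed from the final effects. The loop is
deterministic given its inputs; iteration 1 (D = I) is classic ssGBLUP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from . import grm
from .data import GenotypeMatrix
from .mixed_model import (
    ModelSpec,
    RelationshipOperator,
    VarianceComponents,
    aireml,
    predict_gebv,
)
from .pedigree import Pedigree


class DegenerateWeightsError(ZeroDivisionError):
    """All SNP effects were zero, so weights cannot be renormalised."""


@dataclass
class SNPWeightState:
    """Weights used and effects obtained at one iteration."""

    iteration: int
    weights: np.ndarray  # D(t), used to build G(t)
    effects: np.ndarray  # ĝ(t)
    trace0: float  # tr(D(1)) = n SNPs

    def to_frame(self, snp_map: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": snp_map["snp_id"],
                "chrom": snp_map["chrom"],
                "pos": snp_map["pos"],
                "effect": self.effects,
                "weight": self.weights,
            }
        )


def backsolve_snp_effects(
    weights: np.ndarray,
    Z: np.ndarray,
    Gw: np.ndarray,
    gebv_genotyped: np.ndarray,
    lam: float,
) -> np.ndarray:
    """ĝ = λ D Z' Gw⁻¹ â for the genotyped animals' GEBV â."""
    a_hat = np.asarray(gebv_genotyped, dtype=float)
    if Z.shape[0] != a_hat.shape[0]:
        raise ValueError(
            f"Z has {Z.shape[0]} individuals but GEBV vector has {a_hat.shape[0]}"
        )
    if Z.shape[1] != len(weights):
        raise ValueError("weights length does not match SNP count")
    ginv_a = linalg.solve(Gw, a_hat, assume_a="pos")
    return lam * np.asarray(weights, dtype=float) * (Z.T @ ginv_a)


def update_weights(g_hat: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """d_i = ĝ_i² · 2 p_i (1 − p_i): a SNP's variance contribution."""
    p = np.asarray(freqs, dtype=float)
    return np.asarray(g_hat, dtype=float) ** 2 * 2.0 * p * (1.0 - p)


def normalize_weights(d_next: np.ndarray, trace0: float) -> np.ndarray:
    """Rescale so tr(D) returns to its initial value (the SNP count)."""
    total = float(np.sum(d_next))
    if total <= 0:
        raise DegenerateWeightsError(
            "total SNP weight is zero (all back-solved effects zero)"
        )
    return np.asarray(d_next, dtype=float) * (trace0 / total)


def run_wssgwas(
    pheno: pd.DataFrame,
    ped: Pedigree,
    geno: GenotypeMatrix,
    spec: ModelSpec,
    vc: VarianceComponents | None = None,
    n_iter: int = 3,
    reestimate_vc: bool = False,
) -> tuple[list[SNPWeightState], list[pd.DataFrame], VarianceComponents]:
    """Run the full weighted single-step GWAS loop.

    Returns one :class:`SNPWeightState` and one GEBV table per
    iteration, plus the variance components used. If ``vc`` is None the
    components are estimated by AI-REML under the unweighted H (and, if
    ``reestimate_vc``, refreshed each iteration).
    """
    ped = ped.with_founders(geno.individual_ids)
    Ainv = ped.relationship_inverse()
    logdet_A = ped.relationship_logdet()
    A22 = ped.submatrix(geno.individual_ids)
    gen_index = np.array([ped.position(a) for a in geno.individual_ids])

    p = geno.allele_frequencies()
    Z = grm.center_genotypes(geno.codes, p)
    lam = grm.scaling_constant(p)
    het = 2.0 * p * (1.0 - p)

    n_snps = geno.n_snps
    trace0 = float(n_snps)
    weights = np.ones(n_snps)

    states: list[SNPWeightState] = []
    gebv_tables: list[pd.DataFrame] = []

    for t in range(1, n_iter + 1):
        G = grm.build_G(Z, weights if t > 1 else None, p)
        Gw = grm.blend_Gw(G, A22)
        hinv = grm.build_Hinv(Ainv, A22, Gw, gen_index, list(ped.ids), logdet_A)
        rel = RelationshipOperator.from_hinv(hinv)

        if vc is None or (reestimate_vc and t > 1):
            vc = aireml(spec, pheno, rel)

        gebv = predict_gebv(spec, pheno, rel, vc)
        gebv_tables.append(gebv)
        a_hat = (
            gebv.set_index("animal_id")
            .loc[geno.individual_ids, "gebv"]
            .to_numpy()
        )

        g_hat = backsolve_snp_effects(weights, Z, Gw, a_hat, lam)
        states.append(SNPWeightState(t, weights.copy(), g_hat, trace0))

        weights = normalize_weights(update_weights(g_hat, p), trace0)

    return states, gebv_tables, vc
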