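"""Repeatability-model mixed-model equations and AI-REML.

The single-trait repeatability model for repeated semen records is

    y = X b + Z a + W p + e,
    a ~ N(0, K σa²),  p ~ N(0, I σp²),  e ~ N(0, I σe²),

with fixed effects year–season and parity, linear covariates age (months)
and collection interval (days), additive genetic effects ``a`` with
relationship K (pedigree A, or single-step H when genomic information is
blended in), and a permanent-environment effect per boar capturing
non-genetic animal-level covariance between repeated records.

Variance components are estimated by average-information REML on
Henderson's mixed-model equations; the BLUP (A) and ssGBLUP (H) paths
share all code except the relationship operator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, sparse

from .data import require_columns, year_season
from .grm import HInverse
from .pedigree import Pedigree


class RankError(ValueError):
    """Fixed-effect design is rank deficient (unestimable effect)."""


class ConvergenceError(RuntimeError):
    """AI-REML failed to converge; carries the parameter trajectory."""

    def __init__(self, message: str, trajectory: list | None = None):
        super().__init__(message)
        self.trajectory = trajectory or []


@dataclass
class ModelSpec:
    """Trait and effect structure of the repeatability model."""

    trait: str
    fixed_factors: tuple[str, ...] = ("year_season", "parity")
    covariates: tuple[str, ...] = ("age_months", "interval_days")


@dataclass
class RelationshipOperator:
    """Relationship inverse plus the log-determinant REML needs.

    ``ids`` fixes the animal order of the additive-effect block.
    """

    ids: list[str]
    inv: sparse.csr_matrix
    logdet: float

    @classmethod
    def from_pedigree(cls, ped: Pedigree) -> "RelationshipOperator":
        return cls(list(ped.ids), ped.relationship_inverse(), ped.relationship_logdet())

    @classmethod
    def from_hinv(cls, h: HInverse) -> "RelationshipOperator":
        return cls(list(h.ids), h.matrix, h.logdet)


@dataclass
class VarianceComponents:
    """REML variance components with standard errors and derived ratios."""

    sigma_a2: float
    sigma_p2: float
    sigma_e2: float
    se_a: float = float("nan")
    se_p: float = float("nan")
    se_e: float = float("nan")
    se_h2: float = float("nan")
    se_re: float = float("nan")
    converged: bool = True
    n_iterations: int = 0
    loglik: float = float("nan")
    boundary: bool = False
    #: (iteration, components, REML log-likelihood) per accepted step
    trajectory: list = field(default_factory=list, repr=False)

    @property
    def total(self) -> float:
        return self.sigma_a2 + self.sigma_p2 + self.sigma_e2

    @property
    def h2(self) -> float:
        return self.sigma_a2 / self.total

    @property
    def repeatability(self) -> float:
        return (self.sigma_a2 + self.sigma_p2) / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sigma_a2": self.sigma_a2,
                    "se_a": self.se_a,
                    "sigma_p2": self.sigma_p2,
                    "se_p": self.se_p,
                    "sigma_e2": self.sigma_e2,
                    "se_e": self.se_e,
                    "h2": self.h2,
                    "se_h2": self.se_h2,
                    "re": self.repeatability,
                    "se_re": self.se_re,
                }
            ]
        )


def heritability(sigma_a2: float, sigma_p2: float, sigma_e2: float) -> tuple[float, float]:
    """(h², repeatability) from the three variance components.

    h² = σa²/(σa²+σp²+σe²); repeatability = (σa²+σp²)/(σa²+σp²+σe²).
    """
    total = sigma_a2 + sigma_p2 + sigma_e2
    if total <= 0:
        raise ValueError("total variance must be positive")
    return sigma_a2 / total, (sigma_a2 + sigma_p2) / total


# ---------------------------------------------------------------------------
# design / MME assembly
# ---------------------------------------------------------------------------

def build_design(spec: ModelSpec, pheno: pd.DataFrame, rel: RelationshipOperator):
    """Design matrices (y, X, Z, W) for one trait.

    X carries an intercept, drop-first dummies for each fixed factor and
    the linear covariates; Z maps records to the animals of ``rel``; W
    maps records to the boars that have records.
    """
    require_columns(pheno, ["boar_id", spec.trait], "phenotype table")
    df = pheno.copy()
    if "year_season" in spec.fixed_factors and "year_season" not in df.columns:
        df["year_season"] = year_season(df["collection_date"])
    df = df[np.isfinite(pd.to_numeric(df[spec.trait], errors="coerce"))]
    n = len(df)
    if n == 0:
        raise ValueError(f"no records with a finite value for trait {spec.trait!r}")

    y = df[spec.trait].to_numpy(dtype=float)

    cols = [np.ones(n)]
    labels = ["intercept"]
    for factor in spec.fixed_factors:
        require_columns(df, [factor], "phenotype table")
        dummies = pd.get_dummies(df[factor].astype(str), prefix=factor, drop_first=True)
        dummies = dummies[sorted(dummies.columns)]
        cols.append(dummies.to_numpy(dtype=float))
        labels.extend(dummies.columns)
    for cov in spec.covariates:
        require_columns(df, [cov], "phenotype table")
        cols.append(df[cov].to_numpy(dtype=float)[:, None])
        labels.append(cov)
    X = np.column_stack(cols)

    rank = np.linalg.matrix_rank(X.T @ X)
    if rank < X.shape[1]:
        _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
        bad = [labels[j] for j in piv[rank:]]
        raise RankError(
            "fixed-effect design is rank deficient; unestimable column(s): "
            + ", ".join(bad)
        )

    animal_pos = {a: i for i, a in enumerate(rel.ids)}
    try:
        z_idx = np.array([animal_pos[str(b)] for b in df["boar_id"]])
    except KeyError as exc:
        raise KeyError(f"phenotyped boar {exc.args[0]!r} missing from pedigree") from None
    q_a = len(rel.ids)
    Z = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), z_idx)), shape=(n, q_a)
    )

    rec_boars = sorted(set(df["boar_id"].astype(str)))
    boar_pos = {b: i for i, b in enumerate(rec_boars)}
    w_idx = np.array([boar_pos[str(b)] for b in df["boar_id"]])
    W = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), w_idx)), shape=(n, len(rec_boars))
    )
    return df, y, X, labels, Z, W, rec_boars


@dataclass
class MixedModelEquations:
    """Assembled Henderson system, reusable across variance-ratio values."""

    spec: ModelSpec
    rel: RelationshipOperator
    y: np.ndarray
    X: np.ndarray
    fixed_labels: list[str]
    Z: sparse.csr_matrix
    W: sparse.csr_matrix
    pe_ids: list[str]
    _MtM: np.ndarray = field(repr=False, default=None)
    _rhs: np.ndarray = field(repr=False, default=None)
    _Kinv: sparse.csr_matrix = field(repr=False, default=None)

    def __post_init__(self) -> None:
        M = sparse.hstack(
            [sparse.csr_matrix(self.X), self.Z, self.W], format="csr"
        )
        self._M = M
        self._MtM = np.asarray((M.T @ M).todense())
        self._rhs = M.T @ self.y
        self._yty = float(self.y @ self.y)
        self._Kinv = sparse.csr_matrix(self.rel.inv)

    # block slices ------------------------------------------------------
    @property
    def nf(self) -> int:
        return self.X.shape[1]

    @property
    def q_a(self) -> int:
        return self.Z.shape[1]

    @property
    def q_p(self) -> int:
        return self.W.shape[1]

    @property
    def n_records(self) -> int:
        return len(self.y)

    def _slices(self):
        nf, qa = self.nf, self.q_a
        return slice(0, nf), slice(nf, nf + qa), slice(nf + qa, nf + qa + self.q_p)

    def coefficient_matrix(self, alpha_a: float, alpha_p: float) -> np.ndarray:
        """Dense C = M'M + diag(0, K⁻¹·αa, I·αp)."""
        if not (np.isfinite(alpha_a) and np.isfinite(alpha_p)) or min(alpha_a, alpha_p) <= 0:
            raise ValueError("variance ratios must be positive and finite")
        C = self._MtM.copy()
        sf, sa, sp = self._slices()
        C[sa, sa] += alpha_a * np.asarray(self._Kinv.todense())
        C[sp, sp] += alpha_p * np.eye(self.q_p)
        return C

    def solve(self, vc: VarianceComponents, return_inverse: bool = False):
        """Solutions (b̂, â, p̂) at fixed variance components."""
        alpha_a = vc.sigma_e2 / vc.sigma_a2
        alpha_p = vc.sigma_e2 / vc.sigma_p2
        C = self.coefficient_matrix(alpha_a, alpha_p)
        cf = linalg.cho_factor(C, lower=True)
        sol = linalg.cho_solve(cf, self._rhs)
        out = _Solutions(self, sol, cf)
        if return_inverse:
            out.C_inverse = linalg.cho_solve(cf, np.eye(C.shape[0]))
        return out


@dataclass
class _Solutions:
    mme: MixedModelEquations
    vector: np.ndarray
    factor: tuple = field(repr=False, default=None)
    C_inverse: np.ndarray | None = field(repr=False, default=None)

    @property
    def fixed(self) -> np.ndarray:
        return self.vector[self.mme._slices()[0]]

    @property
    def additive(self) -> np.ndarray:
        return self.vector[self.mme._slices()[1]]

    @property
    def permanent(self) -> np.ndarray:
        return self.vector[self.mme._slices()[2]]

    @property
    def residuals(self) -> np.ndarray:
        return self.mme.y - self.mme._M @ self.vector


def assemble_mme(
    spec: ModelSpec,
    pheno: pd.DataFrame,
    rel: RelationshipOperator,
    ratios: tuple[float, float] | None = None,
) -> MixedModelEquations:
    """Build the MME for ``spec`` over ``pheno`` with relationship ``rel``.

    ``ratios`` = (αa, αp) = (σe²/σa², σe²/σp²) may be passed to validate
    solvability eagerly; the system itself is ratio-free and reusable.
    """
    _, y, X, labels, Z, W, pe_ids = build_design(spec, pheno, rel)
    mme = MixedModelEquations(spec, rel, y, X, labels, Z, W, pe_ids)
    if ratios is not None:
        mme.coefficient_matrix(*ratios)
    return mme


# ---------------------------------------------------------------------------
# AI-REML
# ---------------------------------------------------------------------------

def aireml(
    spec: ModelSpec,
    pheno: pd.DataFrame,
    rel: RelationshipOperator,
    start: VarianceComponents | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    verbose: bool = False,
) -> VarianceComponents:
    """Average-information REML for (σa², σp², σe²).

    Newton steps use the average-information matrix with step-halving on
    likelihood decrease (an EM step is the fallback); standard errors
    come from the inverse AI matrix at convergence and h²/repeatability
    SEs from the delta method. Components are floored at 1e-8 × the
    phenotypic variance; an estimate pinned there raises a boundary
    warning and its SE is unreliable.
    """
    mme = assemble_mme(spec, pheno, rel)
    n, nf, q_a, q_p = mme.n_records, mme.nf, mme.q_a, mme.q_p

    rec_per_boar = np.asarray(mme.W.sum(axis=0)).ravel()
    if rec_per_boar.max() <= 1:
        warnings.warn(
            "every boar has a single record: permanent-environment variance "
            "is not separable from the residual",
            stacklevel=2,
        )

    var_y = float(np.var(mme.y, ddof=1))
    floor = 1e-8 * var_y
    pin_level = 1e-4 * var_y  # below this a shrinking component is pinned
    if start is None:
        theta = np.array([0.25 * var_y, 0.25 * var_y, 0.5 * var_y])
    else:
        theta = np.array([start.sigma_a2, start.sigma_p2, start.sigma_e2], dtype=float)
    theta = np.maximum(theta, floor)

    Kinv = mme._Kinv
    trajectory = []
    n_warmup = 3  # EM iterations before switching to AI steps
    AI = np.eye(3)
    converged = False

    def evaluate(th):
        sa2, sp2, se2 = th
        alpha_a, alpha_p = se2 / sa2, se2 / sp2
        C = mme.coefficient_matrix(alpha_a, alpha_p)
        cf = linalg.cho_factor(C, lower=True)
        logdet_C = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        sol = linalg.cho_solve(cf, mme._rhs)
        m = C.shape[0]
        m2ll = (
            (n - m) * np.log(se2)
            + mme.rel.logdet
            + q_a * np.log(sa2)
            + q_p * np.log(sp2)
            + logdet_C
            + (mme._yty - float(mme._rhs @ sol)) / se2
        )
        return m2ll, C, cf, sol

    for it in range(1, max_iter + 1):
        sa2, sp2, se2 = theta
        m2ll, C, cf, sol = evaluate(theta)
        Cinv = linalg.cho_solve(cf, np.eye(C.shape[0]))
        sf, sa_sl, sp_sl = mme._slices()
        Caa = Cinv[sa_sl, sa_sl]
        tr_Kinv_Caa = float(np.sum(Kinv.multiply(Caa)))
        tr_Cpp = float(np.trace(Cinv[sp_sl, sp_sl]))

        a_hat = sol[sa_sl]
        p_hat = sol[sp_sl]
        e_hat = mme.y - mme._M @ sol
        aKa = float(a_hat @ (Kinv @ a_hat))
        pp = float(p_hat @ p_hat)
        ee = float(e_hat @ e_hat)

        score = np.array(
            [
                -0.5 * (q_a / sa2 - tr_Kinv_Caa * se2 / sa2**2 - aKa / sa2**2),
                -0.5 * (q_p / sp2 - tr_Cpp * se2 / sp2**2 - pp / sp2**2),
                -0.5 * (
                    (n - nf - q_a - q_p
                     + (se2 / sa2) * tr_Kinv_Caa + (se2 / sp2) * tr_Cpp) / se2
                    - ee / se2**2
                ),
            ]
        )

        F = np.column_stack(
            [
                mme.Z @ a_hat / sa2,
                mme.W @ p_hat / sp2,
                e_hat / se2,
            ]
        )
        PF = np.empty_like(F)
        for j in range(3):
            rhs_j = mme._M.T @ F[:, j]
            sol_j = linalg.cho_solve(cf, rhs_j)
            PF[:, j] = (F[:, j] - mme._M @ sol_j) / se2
        AI = 0.5 * (F.T @ PF)
        AI = 0.5 * (AI + AI.T)

        trajectory.append((it, theta.copy(), -0.5 * m2ll))
        if verbose:
            print(f"iter {it}: theta={theta}, logL={-0.5 * m2ll:.6f}")

        em_theta = np.maximum(
            np.array(
                [
                    (aKa + tr_Kinv_Caa * se2) / q_a,
                    (pp + tr_Cpp * se2) / q_p,
                    (mme._yty - float(mme._rhs @ sol)) / (n - nf),
                ]
            ),
            floor,
        )

        # active-set handling: a component driven to the boundary is
        # pinned at the floor and left out of the AI update until its
        # score turns positive again
        pinned = (theta <= pin_level) & (score <= 0)
        active = ~pinned

        # a few EM warm-up rounds stabilise the trajectory far from the
        # optimum; afterwards Newton steps on the AI matrix, kept inside
        # a trust region (no component shrinks below 5% of its value per
        # step) with step-halving, and EM as the fallback
        new_theta = None
        if it > n_warmup and active.any():
            try:
                delta = np.zeros(3)
                delta[active] = linalg.solve(
                    AI[np.ix_(active, active)], score[active], assume_a="pos"
                )
            except np.linalg.LinAlgError:
                delta = None
            if delta is not None:
                step = 1.0
                for _ in range(12):
                    cand = np.maximum.reduce(
                        [theta + step * delta, 0.05 * theta, np.full(3, floor)]
                    )
                    cand[pinned] = floor
                    try:
                        cand_m2ll = evaluate(cand)[0]
                    except np.linalg.LinAlgError:
                        cand_m2ll = np.inf
                    if cand_m2ll <= m2ll + 1e-10:
                        new_theta = cand
                        break
                    step *= 0.5
        if new_theta is None:
            new_theta = em_theta  # EM: guaranteed ascent, slow but safe
            new_theta[pinned] = floor

        rel_change = np.max(np.abs(new_theta - theta) / (np.abs(theta) + 1e-12))
        theta = new_theta
        if rel_change < tol:
            converged = True
            break

    if not converged:
        raise ConvergenceError(
            f"AI-REML did not converge in {max_iter} iterations "
            f"(last relative change {rel_change:.3e})",
            trajectory,
        )

    m2ll = evaluate(theta)[0]
    boundary = bool(np.any(theta <= floor * (1 + 1e-6)))
    if boundary:
        warnings.warn(
            "variance component pinned at its lower boundary; standard errors "
            "are unreliable",
            stacklevel=2,
        )

    # SEs from the inverse AI matrix (active components only when a
    # component sits on the boundary); delta method for the ratios
    free = theta > pin_level
    cov = np.zeros((3, 3))
    ses = np.full(3, np.nan)
    try:
        cov[np.ix_(free, free)] = linalg.inv(AI[np.ix_(free, free)])
        ses[free] = np.sqrt(np.maximum(np.diag(cov)[free], 0.0))
    except np.linalg.LinAlgError:
        cov = np.full((3, 3), np.nan)
    sa2, sp2, se2 = theta
    T = theta.sum()
    g_h2 = np.array([(T - sa2) / T**2, -sa2 / T**2, -sa2 / T**2])
    s_ap = sa2 + sp2
    g_re = np.array([(T - s_ap) / T**2, (T - s_ap) / T**2, -s_ap / T**2])
    se_h2 = float(np.sqrt(max(g_h2 @ cov @ g_h2, 0.0)))
    se_re = float(np.sqrt(max(g_re @ cov @ g_re, 0.0)))

    return VarianceComponents(
        sigma_a2=float(sa2),
        sigma_p2=float(sp2),
        sigma_e2=float(se2),
        se_a=float(ses[0]),
        se_p=float(ses[1]),
        se_e=float(ses[2]),
        se_h2=se_h2,
        se_re=se_re,
        converged=converged,
        n_iterations=it,
        loglik=float(-0.5 * m2ll),
        boundary=boundary,
        trajectory=trajectory,
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_gebv(
    spec: ModelSpec,
    pheno: pd.DataFrame,
    rel: RelationshipOperator,
    vc: VarianceComponents,
) -> pd.DataFrame:
    """Breeding values for every animal in ``rel`` at fixed components.

    Returns a GEBV table with one row per animal: estimated breeding
    value ``gebv`` and the permanent-environment solution ``pe`` (NaN
    for animals without records). With K = A this is pedigree BLUP; with
    K = H it is ssGBLUP.
    """
    mme = assemble_mme(spec, pheno, rel)
    sol = mme.solve(vc)
    pe = pd.Series(sol.permanent, index=mme.pe_ids)
    return pd.DataFrame(
        {
            "animal_id": rel.ids,
            "gebv": sol.additive,
            "pe": [pe.get(a, np.nan) for a in rel.ids],
        }
    )


def fixed_effect_table(mme: MixedModelEquations, sol: _Solutions) -> pd.DataFrame:
    return pd.DataFrame({"effect": mme.fixed_labels, "estimate": sol.fixed})
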