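"""Latent-factor genotype–environment association.

The model is the ridge latent factor mixed model: for a centered
(mean-imputed) dosage matrix Y (n × L) and scaled environment E (n × d),

    Y ≈ E·B + U·Vᵀ,

minimizing ‖Y − E·B − U·Vᵀ‖² + λ‖B‖². Factors are taken from the top-K
SVD of the ridge-regression residual, then the environmental effect
sizes B are re-estimated given the factors. Association testing regresses
each locus on [1, E, U], converts per-variable t statistics to z-scores
and recalibrates them with the genomic inflation factor
GIF = median(z²) / median(χ²₁) before Benjamini–Hochberg selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.utils.extmath import randomized_svd
from statsmodels.stats.multitest import multipletests

from .genotypes import GenotypeMatrix

__all__ = [
    "LatentModel",
    "AssociationResult",
    "CandidateSet",
    "fit_latent_model",
    "association_test",
    "bh_fdr",
    "merge_candidates",
    "select_K",
]

CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, df=1))  # ≈ 0.4549


def _as_matrix(G) -> np.ndarray:
    if isinstance(G, GenotypeMatrix):
        return G.imputed_dosages()
    return np.asarray(G, dtype=float)


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic SVD sign convention: per factor, the largest-magnitude
    loading is positive."""
    for k in range(V.shape[1]):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] *= -1
            U[:, k] *= -1
    return U, V


@dataclass
class LatentModel:
    """Fitted latent factor regression: scores U, loadings V, effects B."""

    K: int
    U: np.ndarray                  # n × K factor scores
    V: np.ndarray                  # L × K loadings
    B: np.ndarray                  # d × L environmental effect sizes
    lam: float
    variables: list[str]
    locus_ids: list[str] = field(default_factory=list)

    def effects_frame(self) -> pd.DataFrame:
        cols = self.locus_ids or list(range(self.B.shape[1]))
        return pd.DataFrame(self.B, index=self.variables, columns=cols)


def _env_matrix(E) -> tuple[np.ndarray, list[str]]:
    if isinstance(E, pd.DataFrame):
        return E.to_numpy(dtype=float), list(E.columns)
    E = np.asarray(E, dtype=float)
    return E, [f"v{i}" for i in range(E.shape[1])]


def fit_latent_model(G, E, K: int, lam: float = 1e-5) -> LatentModel:
    """Fit the ridge latent factor model (SVD-based two-step solution).

    ``G`` may be a :class:`GenotypeMatrix` (mean-imputed internally) or a
    numeric matrix; it is column-centered before fitting. ``E`` must be
    the training-scaled climate table. ``K = 0`` degrades to plain
    multivariate ridge regression.
    """
    Y = _as_matrix(G)
    Y = Y - Y.mean(axis=0, keepdims=True)
    X, variables = _env_matrix(E)
    n, L = Y.shape
    if K < 0 or K >= min(n, L):
        raise ValueError(f"K must be in [0, min(n, L)); got {K}")
    d = X.shape[1]
    A = X.T @ X + lam * np.eye(d)
    B0 = np.linalg.solve(A, X.T @ Y)
    R = Y - X @ B0
    if K > 0:
        Uk, Sk, Vtk = randomized_svd(R, n_components=K, random_state=0)
        U = Uk * Sk
        V = Vtk.T
        U, V = _fix_signs(U, V)
        B = np.linalg.solve(A, X.T @ (Y - U @ V.T))
    else:
        U = np.zeros((n, 0))
        V = np.zeros((L, 0))
        B = B0
    locus_ids = G.locus_ids if isinstance(G, GenotypeMatrix) else []
    return LatentModel(K=K, U=U, V=V, B=B, lam=lam, variables=variables,
                       locus_ids=list(locus_ids))


@dataclass
class AssociationResult:
    """Per locus × variable association statistics with GIF calibration."""

    z: pd.DataFrame               # loci × variables
    p_raw: pd.DataFrame
    p_calibrated: pd.DataFrame
    gif: pd.Series                # per variable
    joint_p: pd.Series | None = None

    def min_calibrated_p(self) -> pd.Series:
        return self.p_calibrated.min(axis=1)


def association_test(G, E, U: np.ndarray, joint: bool = False
                     ) -> AssociationResult:
    """Test each locus against each climate variable, adjusting for U.

    Per-locus OLS of the dosage on [1, E, U]; z-scores for the d climate
    coefficients; per-variable genomic inflation factors recalibrate the
    squared z-scores against χ²₁. With ``joint=True`` a d-df joint test of
    all climate variables per locus is added.
    """
    Y = _as_matrix(G)
    X, variables = _env_matrix(E)
    n, L = Y.shape
    d = X.shape[1]
    Z = np.column_stack([np.ones(n), X, U])
    p_cols = Z.shape[1]
    # rank check with column attribution
    _, Rq = np.linalg.qr(Z)
    diag = np.abs(np.diag(Rq))
    tol = diag.max() * max(Z.shape) * np.finfo(float).eps
    bad = np.nonzero(diag < tol)[0]
    if bad.size:
        names = ["intercept"] + variables + [f"U{k+1}" for k in range(U.shape[1])]
        raise ValueError(
            f"design matrix rank-deficient; collinear columns: "
            f"{[names[i] for i in bad]}")

    ZtZinv = np.linalg.inv(Z.T @ Z)
    coefs = ZtZinv @ (Z.T @ Y)                    # p_cols × L
    resid = Y - Z @ coefs
    dof = n - p_cols
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(ZtZinv), sigma2))
    tstat = coefs / se
    env_t = tstat[1:1 + d, :].T                  # loci × d
    # map t quantiles onto the normal scale so the χ² calibration is exact
    z = stats.norm.isf(stats.t.sf(env_t, dof))
    z = np.where(np.isfinite(z), z, np.sign(env_t) * 40.0)
    p_raw = 2.0 * stats.norm.sf(np.abs(z))
    gif = np.median(z ** 2, axis=0) / CHI2_MEDIAN_1DF
    p_cal = stats.chi2.sf(z ** 2 / gif[None, :], df=1)

    loci = G.locus_ids if isinstance(G, GenotypeMatrix) else list(range(L))
    zf = pd.DataFrame(z, index=loci, columns=variables)
    joint_p = None
    if joint:
        # d-df joint Wald test on GIF-calibrated per-variable z-scores
        chi = (z ** 2 / gif[None, :]).sum(axis=1)
        joint_p = pd.Series(stats.chi2.sf(chi, df=d), index=loci)
    return AssociationResult(
        z=zf,
        p_raw=pd.DataFrame(p_raw, index=loci, columns=variables),
        p_calibrated=pd.DataFrame(p_cal, index=loci, columns=variables),
        gif=pd.Series(gif, index=variables, name="gif"),
        joint_p=joint_p,
    )


def bh_fdr(p, q: float = 0.01) -> np.ndarray:
    """Benjamini–Hochberg step-up selection at FDR level ``q``.

    Returns a boolean mask over the input order. Ties at the boundary
    p-value are all included (step-up treats equal p-values identically).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


@dataclass
class CandidateSet:
    """Candidate loci with provenance (prior-list | supplemental)."""

    table: pd.DataFrame            # columns: locus_id, provenance

    def __post_init__(self) -> None:
        if self.table["locus_id"].duplicated().any():
            raise ValueError("candidate set contains duplicate loci")

    @classmethod
    def from_ids(cls, ids, provenance: str) -> "CandidateSet":
        return cls(pd.DataFrame({"locus_id": list(ids),
                                 "provenance": provenance}))

    @property
    def locus_ids(self) -> list[str]:
        return list(self.table["locus_id"])

    def __len__(self) -> int:
        return len(self.table)


def merge_candidates(prior: CandidateSet, supplemental: CandidateSet,
                     universe=None) -> CandidateSet:
    """Union of candidate sets; loci present in both keep the prior tag."""
    if universe is not None:
        known = set(universe)
        unknown = [l for l in prior.locus_ids + supplemental.locus_ids
                   if l not in known]
        if unknown:
            raise ValueError(f"unknown locus ids: {unknown[:5]}")
    prior_ids = set(prior.locus_ids)
    extra = supplemental.table[~supplemental.table["locus_id"].isin(prior_ids)]
    merged = pd.concat([prior.table, extra], ignore_index=True)
    return CandidateSet(merged)


def select_K(G, K_grid=range(1, 9), mask_fraction: float = 0.05,
             seed: int = 0, n_iter: int = 5) -> int:
    """Choose the factor count by held-out masking cross-validation.

    Masks a fraction of observed dosage entries, fits a rank-K truncated
    SVD of the (uncentered) matrix with iterative imputation of the
    masked cells, and returns the K minimizing held-out RMSE; ties break
    toward the smallest K. The matrix is left uncentered so K discrete
    ancestral pools induce a rank-K mean structure.
    """
    K_grid = list(K_grid)
    if not K_grid:
        raise ValueError("K_grid must be nonempty")
    M = _as_matrix(G)
    rng = np.random.default_rng(seed)
    observed = np.isfinite(M)
    mask = observed & (rng.random(M.shape) < mask_fraction)
    col_means = np.nanmean(M, axis=0)
    rmse = {}
    truth = M[mask]
    base = np.where(observed & ~mask, M, np.broadcast_to(col_means, M.shape))
    for K in K_grid:
        X = base.copy()
        for _ in range(n_iter):
            Uk, Sk, Vtk = randomized_svd(X, n_components=K, random_state=0)
            recon = (Uk * Sk) @ Vtk
            X[mask] = recon[mask]
        rmse[K] = float(np.sqrt(np.mean((X[mask] - truth) ** 2)))
    best = min(rmse, key=lambda k: (round(rmse[k], 12), k))
    return int(best)
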