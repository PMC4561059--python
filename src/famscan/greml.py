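"""SNP heritability: GRM construction, relatedness pruning, and REML.

The genetic relationship matrix (GRM) uses the standard standardized-dosage
estimator A_jk = (1/m) sum_i (x_ij - 2p_i)(x_ik - 2p_i) / (2 p_i (1-p_i))
with allele frequencies recomputed in the analyzed sample.  Variance
components attached to one or more GRMs are estimated by restricted
maximum likelihood with average-information (AI) updates and an EM
fallback; estimates are constrained to be non-negative, and the test of a
component on its zero boundary uses the 50:50 mixture of a point mass and
chi-square(1).

A binary phenotype is analyzed on the observed 0/1 scale; the liability
transformation h2_liab = h2_obs * K(1-K) / phi(Phi^-1(1-K))^2 (K the
population prevalence) is a reporting step.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import GenotypeDataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

@dataclass
class GRM:
    """Genetic relationship matrix with the individual ids it is indexed by."""

    ids: list[str]
    values: np.ndarray
    n_snps_used: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM shape does not match id list")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")

    def subset(self, keep_ids: list[str]) -> "GRM":
        index = {iid: k for k, iid in enumerate(self.ids)}
        idx = np.array([index[i] for i in keep_ids])
        return GRM(list(keep_ids), self.values[np.ix_(idx, idx)], self.n_snps_used)


def compute_grm(genotypes: GenotypeDataset, snp_mask=None) -> GRM:
    """Standardized-dosage GRM; monomorphic SNPs are skipped."""
    dos = genotypes.dosages
    if snp_mask is not None:
        dos = dos[:, np.asarray(snp_mask)]
    dos = dos.astype(float)
    p = dos.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    n_skipped = int((~poly).sum())
    if n_skipped:
        logger.info("skipped %d monomorphic SNPs in GRM", n_skipped)
    dos = dos[:, poly]
    p = p[poly]
    m = dos.shape[1]
    if m == 0:
        raise ValueError("no polymorphic SNPs available for the GRM")
    Z = (dos - 2 * p) / np.sqrt(2 * p * (1 - p))
    A = (Z @ Z.T) / m
    return GRM(ids=list(genotypes.individuals), values=A, n_snps_used=m)


def write_grm(grm: GRM, prefix: str) -> None:
    """GCTA-compatible gzipped triplet text plus an id file."""
    with open(f"{prefix}.grm.id", "w") as fh:
        for iid in grm.ids:
            fh.write(f"{iid}\t{iid}\n")
    with gzip.open(f"{prefix}.grm.gz", "wt") as fh:
        n = len(grm.ids)
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i+1}\t{j+1}\t{grm.n_snps_used}\t{grm.values[i, j]:.8g}\n")


def read_grm(prefix: str) -> GRM:
    ids = [line.split()[1] for line in open(f"{prefix}.grm.id")]
    n = len(ids)
    values = np.zeros((n, n))
    n_snps = 0
    with gzip.open(f"{prefix}.grm.gz", "rt") as fh:
        for line in fh:
            i, j, m, v = line.split()
            i, j = int(i) - 1, int(j) - 1
            values[i, j] = values[j, i] = float(v)
            n_snps = int(m)
    return GRM(ids=ids, values=values, n_snps_used=n_snps)


def prune_related(grm: GRM, cutoff: float = 0.025) -> list[str]:
    """Greedy relatedness pruning: repeatedly drop the individual with the
    most remaining over-cutoff partners (ties broken by id order) until no
    off-diagonal relatedness exceeds the cutoff.  Returns retained ids."""
    A = grm.values.copy()
    np.fill_diagonal(A, 0.0)
    over = A > cutoff
    active = np.ones(len(grm.ids), dtype=bool)
    while True:
        deg = (over & active[None, :] & active[:, None]).sum(axis=1)
        deg[~active] = 0
        if deg.max() == 0:
            break
        active[int(np.argmax(deg))] = False  # argmax takes the first = id order
    return [iid for iid, a in zip(grm.ids, active) if a]


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def _restricted_loglik(theta, y, X, mats):
    """Restricted log-likelihood (constant terms dropped) and P matrix."""
    n = len(y)
    V = theta[-1] * np.eye(n)
    for t, A in zip(theta[:-1], mats):
        V += t * A
    L = np.linalg.cholesky(V)
    logdetV = 2.0 * np.log(np.diag(L)).sum()
    Vinv = np.linalg.inv(V)
    XtVinv = X.T @ Vinv
    XtVinvX = XtVinv @ X
    sign, logdetX = np.linalg.slogdet(XtVinvX)
    P = Vinv - XtVinv.T @ np.linalg.solve(XtVinvX, XtVinv)
    Py = P @ y
    ll = -0.5 * (logdetV + logdetX + float(y @ Py))
    return ll, P, Py


class REML(BaseEstimator):
    """Variance-component estimation (GREML) by AI-REML with EM fallback.

    The model is y = Xb + sum_c g_c + e with cov(g_c) = A_c * sigma2_c and
    cov(e) = I * sigma2_e; estimates are constrained non-negative (boundary
    hits are logged and reported as zero).

    Attributes
    ----------
    sigma2_ : component variances, residual last.
    se_ : standard errors from the inverse AI matrix.
    h2_obs_, h2_se_ : fraction(s) of phenotypic variance per genetic
        component, with delta-method SE.
    lrt_, lrt_p_ : likelihood-ratio test of the (single or first) genetic
        component against zero, p from the 50:50 boundary mixture.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-6, compute_lrt: bool = True):
        self.max_iter = max_iter
        self.tol = tol
        self.compute_lrt = compute_lrt

    def fit(self, y, X=None, grms: list[GRM] | list[np.ndarray] | None = None):
        y = np.asarray(y, dtype=float)
        n = len(y)
        if X is None:
            X = np.ones((n, 1))
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if not np.allclose(X[:, 0], 1.0):
            X = np.column_stack([np.ones(n), X])
        if grms is None or len(grms) == 0:
            raise ValueError("at least one GRM component is required")
        mats = [g.values if isinstance(g, GRM) else np.asarray(g, dtype=float)
                for g in grms]
        for A in mats:
            if A.shape != (n, n):
                raise ValueError("GRM dimension does not match phenotype length")
        if n <= X.shape[1]:
            raise ValueError("more fixed effects than observations")

        vp = float(np.var(y, ddof=1))
        floor = 1e-8 * vp
        c = len(mats)
        theta = np.array([vp / 2.0 / c] * c + [vp / 2.0])
        ll, P, Py = _restricted_loglik(theta, y, X, mats)
        converged = False
        trajectory = [ll]
        for it in range(1, self.max_iter + 1):
            score = np.empty(c + 1)
            PA = [P @ A for A in mats] + [P]
            APy = [A @ Py for A in mats] + [Py]
            for i in range(c + 1):
                score[i] = -0.5 * (np.trace(PA[i]) - float(Py @ APy[i]))
            AI = np.empty((c + 1, c + 1))
            PAPy = [P @ v for v in APy]
            for i in range(c + 1):
                for j in range(i, c + 1):
                    AI[i, j] = AI[j, i] = 0.5 * float(APy[i] @ PAPy[j])
            if it <= 1:
                # EM step for stability far from the optimum
                new = theta + theta**2 * np.array(
                    [float(Py @ APy[i]) - np.trace(PA[i]) for i in range(c + 1)]) / n
            else:
                try:
                    new = theta + np.linalg.solve(AI, score)
                except np.linalg.LinAlgError:
                    new = theta + theta**2 * np.array(
                        [float(Py @ APy[i]) - np.trace(PA[i]) for i in range(c + 1)]) / n
            new = np.maximum(new, floor)
            ll_new, P_new, Py_new = _restricted_loglik(new, y, X, mats)
            halvings = 0
            while ll_new < ll - 1e-10 and halvings < 10:
                new = np.maximum(theta + 0.5 * (new - theta), floor)
                ll_new, P_new, Py_new = _restricted_loglik(new, y, X, mats)
                halvings += 1
            delta = np.abs(new - theta).max()
            theta, ll, P, Py = new, ll_new, P_new, Py_new
            trajectory.append(ll)
            if delta < self.tol * vp:
                converged = True
                break
        if not converged:
            logger.warning("REML did not converge in %d iterations", self.max_iter)

        boundary = theta <= floor * 1.001
        if boundary[:-1].any():
            logger.info("variance component(s) %s at the zero boundary",
                        list(np.flatnonzero(boundary[:-1])))
        # SEs from the inverse AI at the solution
        APy = [A @ Py for A in mats] + [Py]
        PAPy = [P @ v for v in APy]
        AI = np.empty((c + 1, c + 1))
        for i in range(c + 1):
            for j in range(i, c + 1):
                AI[i, j] = AI[j, i] = 0.5 * float(APy[i] @ PAPy[j])
        try:
            cov = np.linalg.inv(AI)
        except np.linalg.LinAlgError:
            cov = np.full((c + 1, c + 1), np.nan)

        total = theta.sum()
        h2 = theta[:-1] / total
        # delta method: d h_i / d theta_j = (delta_ij * total - theta_i)/total^2
        J = np.zeros((c, c + 1))
        for i in range(c):
            J[i] = -theta[i] / total**2
            J[i, i] += 1.0 / total
        h2_cov = J @ cov @ J.T

        self.sigma2_ = np.where(boundary, 0.0, theta)
        self.se_ = np.sqrt(np.clip(np.diag(cov), 0, None))
        self.h2_obs_ = h2 if c > 1 else float(h2[0])
        self.h2_se_ = (np.sqrt(np.clip(np.diag(h2_cov), 0, None)) if c > 1
                       else float(np.sqrt(max(h2_cov[0, 0], 0.0))))
        self.loglik_ = ll
        self.converged_ = converged
        self.n_iter_ = it
        self.trajectory_ = trajectory
        self.boundary_ = boundary

        if self.compute_lrt:
            if c == 1:
                ll0 = _null_restricted_loglik(y, X)
            else:
                sub = REML(max_iter=self.max_iter, tol=self.tol, compute_lrt=False)
                sub.fit(y, X, grms=mats[1:])
                ll0 = sub.loglik_
            self.lrt_ = max(0.0, 2.0 * (ll - ll0))
            self.lrt_p_ = lrt_mixture_pvalue(self.lrt_)
        return self


def _null_restricted_loglik(y, X) -> float:
    """Restricted log-likelihood of the no-GRM model V = sigma2 * I."""
    n, p = X.shape
    Q, _ = np.linalg.qr(X)
    resid = y - Q @ (Q.T @ y)
    rss = float(resid @ resid)
    s2 = rss / (n - p)
    sign, logdetX = np.linalg.slogdet(X.T @ X / s2)
    return -0.5 * (n * np.log(s2) + logdetX + rss / s2)


@dataclass
class VarianceComponents:
    """REML result on the observed scale, with optional liability rescaling."""

    sigma2_g: np.ndarray
    sigma2_e: float
    h2_obs: float | np.ndarray
    h2_se: float | np.ndarray
    lrt: float
    p: float
    h2_liability: float | None = None
    prevalence_K: float | None = None
    converged: bool = True


def reml_fit(y, X=None, grms=None, prevalence: float | None = None,
             **kwargs) -> VarianceComponents:
    """Thin functional wrapper over :class:`REML`."""
    model = REML(**kwargs).fit(y, X=X, grms=grms)
    h2_liab = None
    if prevalence is not None:
        h2_total = float(np.sum(model.h2_obs_))
        h2_liab = observed_to_liability(h2_total, prevalence)
    return VarianceComponents(
        sigma2_g=model.sigma2_[:-1],
        sigma2_e=float(model.sigma2_[-1]),
        h2_obs=model.h2_obs_,
        h2_se=model.h2_se_,
        lrt=model.lrt_,
        p=model.lrt_p_,
        h2_liability=h2_liab,
        prevalence_K=prevalence,
        converged=model.converged_,
    )


def lrt_mixture_pvalue(lrt: float) -> float:
    """P-value of a variance component tested on its zero boundary.

    The null reference is the 50:50 mixture of a point mass at zero and
    chi-square with 1 df, so p = 0.5 * P(chi2_1 > LRT).
    """
    if lrt < 0:
        raise ValueError("LRT statistic must be non-negative")
    return float(0.5 * stats.chi2.sf(lrt, df=1))


def observed_to_liability(h2_obs: float, K: float) -> float:
    """Convert observed-scale (0/1) heritability to the liability scale.

    h2_liab = h2_obs * K(1-K) / phi(z)^2 with z the threshold Phi^-1(1-K).
    """
    if not 0 < K < 1:
        raise ValueError("prevalence K must be strictly inside (0, 1)")
    if not 0 <= h2_obs <= 1:
        raise ValueError("h2_obs must be in [0, 1]")
    z = stats.norm.ppf(1 - K)
    return float(h2_obs * K * (1 - K) / stats.norm.pdf(z) ** 2)


def chromosome_length_regression(per_chr_variance, lengths):
    """Regress per-chromosome variance fractions on chromosome length.

    Returns (slope, one-tailed t statistic, one-tailed p) for slope > 0 on
    n - 2 degrees of freedom.
    """
    v = np.asarray(per_chr_variance, dtype=float)
    L = np.asarray(lengths, dtype=float)
    if len(v) != len(L) or len(v) < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if np.ptp(L) == 0:
        raise ValueError("chromosome lengths are constant")
    res = stats.linregress(L, v)
    df = len(v) - 2
    if res.stderr == 0:
        t = np.inf if res.slope > 0 else -np.inf
    else:
        t = res.slope / res.stderr
    p_one = float(stats.t.sf(t, df))
    return float(res.slope), float(t), p_one
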