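"""Bayesian kernel (RKHS) regression by Gibbs sampling.

Fits y = mu + sum_k u_k + e with u_k ~ N(0, sigma2_k K_k) for the named
kernels of a :class:`~phenogp.kernels.KernelSet`.  Each kernel is handled
through its eigendecomposition K = V L V': the term becomes a ridge
regression on the columns of B = V L^{1/2}, whose coefficients have iid
N(0, sigma2_k) priors -- the classical eigen-representation of kernel
regression, which makes the within-term Gibbs update a set of independent
univariate draws because B'B is diagonal.  Variances carry scaled-inverse
chi-square priors whose scales split R2 = 0.5 of the response variance
equally across non-residual terms; missing responses are imputed by data
augmentation, which is what produces predictions for unobserved records.

The multitrait variant (model M6) fits a bivariate response (primary
trait, which may be partially missing, plus an always-observed secondary
trait) with unstructured 2x2 covariance matrices on the genetic terms and
the residual (inverse-Wishart priors); the environment term stays
trait-specific.  Missing primary values are imputed from their
conditional normal given the secondary trait, which is how secondary
information sharpens predictions for untested material.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kernels import KernelSet

logger = logging.getLogger(__name__)

#: kernel terms that share the 2x2 genetic covariance in the multitrait model
GENETIC_TERMS = ("g", "gxE")


@dataclass(frozen=True)
class GibbsConfig:
    """Chain settings and priors for the Gibbs samplers."""

    n_iter: int = 12000
    burn_in: int = 2000
    thin: int = 5
    df0: float = 5.0          # prior degrees of freedom per variance term
    r2: float = 0.5           # prior share of variance given to the kernels
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_kept(self) -> int:
        return len(range(self.burn_in, self.n_iter, self.thin))


@dataclass
class PosteriorFit:
    """Posterior summaries of one fitted prediction model."""

    model_id: str
    variance_components: dict          # term -> posterior-mean variance
    variance_sd: dict                  # term -> posterior sd
    mu: float
    effects: dict                      # term -> posterior-mean record effects
    fitted: np.ndarray                 # posterior mean of mu + sum_k u_k
    records: pd.DataFrame
    ess: dict                          # term -> effective sample size
    config: GibbsConfig
    missing_mask: np.ndarray | None = None
    # multitrait extras
    genetic_cov: np.ndarray | None = None    # 2x2 posterior-mean genetic cov
    residual_cov: np.ndarray | None = None   # 2x2 posterior-mean residual cov
    fitted_secondary: np.ndarray | None = None
    mu_secondary: float | None = None

    @property
    def genetic_correlation(self) -> float | None:
        if self.genetic_cov is None:
            return None
        g = self.genetic_cov
        return float(g[0, 1] / np.sqrt(g[0, 0] * g[1, 1]))


def effective_sample_size(x: np.ndarray) -> float:
    """Initial-positive-sequence ESS estimate for one scalar chain."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for k in range(1, n // 2):
        pair = acf[2 * k - 1] + acf[2 * k] if 2 * k < n else acf[2 * k - 1]
        if pair < 0:
            break
        s += pair
    return float(n / max(1.0, 1.0 + 2.0 * s))


def _eigen_basis(K: np.ndarray, rtol: float = 1e-8):
    """B = V sqrt(L) for the eigenpairs with L > rtol * max(L)."""
    K = 0.5 * (K + K.T)
    evals, evecs = np.linalg.eigh(K)
    if evals[-1] <= 0:
        raise ValueError("kernel has no positive eigenvalue")
    if evals[0] < -1e-8 * max(1.0, evals[-1]):
        raise ValueError("kernel is not positive semidefinite")
    keep = evals > rtol * evals[-1]
    lam = np.clip(evals[keep], 0.0, None)
    return evecs[:, keep] * np.sqrt(lam), lam


def _chi2_scale_draw(rng, ss: float, df: float) -> float:
    return ss / rng.chisquare(df)


def fit_rkhs(
    y,
    kernels: KernelSet,
    config: GibbsConfig = GibbsConfig(),
) -> PosteriorFit:
    """Gibbs-sampled kernel regression of one response on a KernelSet.

    ``y`` is record-indexed (aligned with ``kernels.records``); NaN marks
    unobserved records, whose predictions come from data augmentation.
    """
    y = np.asarray(y, dtype=float)
    n = kernels.n_records
    if len(y) != n:
        raise ValueError("response length does not match kernel records")
    miss = ~np.isfinite(y)
    n_obs = int((~miss).sum())
    if n_obs == 0:
        raise ValueError("all responses missing")
    if n_obs < 10:
        raise ValueError("need at least 10 observed responses")

    terms = list(kernels.kernels)
    bases = {}
    for t in terms:
        try:
            bases[t] = _eigen_basis(kernels.kernels[t])
        except ValueError as exc:
            raise ValueError(f"kernel {t!r}: {exc}") from exc

    rng = np.random.default_rng(config.seed)
    vy = float(np.var(y[~miss]))
    if vy == 0:
        vy = 1.0
    df0 = config.df0
    s0 = {t: vy * config.r2 / len(terms) * (df0 + 2.0) for t in terms}
    s0e = vy * (1.0 - config.r2) * (df0 + 2.0)

    mu = float(np.mean(y[~miss]))
    sig = {t: vy * config.r2 / len(terms) for t in terms}
    sig_e = vy * (1.0 - config.r2)
    alpha = {t: np.zeros(bases[t][0].shape[1]) for t in terms}
    u = {t: np.zeros(n) for t in terms}
    y_aug = np.where(miss, mu, y)
    fitted_total = np.zeros(n)

    keep_iter = set(range(config.burn_in, config.n_iter, config.thin))
    n_kept = len(keep_iter)
    mean_fitted = np.zeros(n)
    mean_u = {t: np.zeros(n) for t in terms}
    sum_mu = 0.0
    chains = {t: np.empty(n_kept) for t in terms}
    chains["residual"] = np.empty(n_kept)
    kept = 0

    for it in range(config.n_iter):
        for t in terms:
            B, lam = bases[t]
            r = y_aug - mu - fitted_total + u[t]
            prec = lam / sig_e + 1.0 / sig[t]
            mean = (B.T @ r / sig_e) / prec
            alpha[t] = mean + rng.standard_normal(len(lam)) / np.sqrt(prec)
            new_u = B @ alpha[t]
            fitted_total += new_u - u[t]
            u[t] = new_u
            ss = float(alpha[t] @ alpha[t]) + s0[t]
            sig[t] = _chi2_scale_draw(rng, ss, df0 + len(lam))
        resid = y_aug - fitted_total
        mu = float(np.mean(resid)) + rng.standard_normal() * np.sqrt(sig_e / n)
        e = resid - mu
        sig_e = _chi2_scale_draw(rng, float(e @ e) + s0e, df0 + n)
        if miss.any():
            y_aug[miss] = (
                mu + fitted_total[miss]
                + rng.standard_normal(int(miss.sum())) * np.sqrt(sig_e)
            )
        if it in keep_iter:
            mean_fitted += mu + fitted_total
            for t in terms:
                mean_u[t] += u[t]
                chains[t][kept] = sig[t]
            chains["residual"][kept] = sig_e
            sum_mu += mu
            kept += 1

    mean_fitted /= n_kept
    post_var = {t: float(np.mean(chains[t])) for t in terms}
    post_var["residual"] = float(np.mean(chains["residual"]))
    post_sd = {t: float(np.std(c, ddof=1)) for t, c in chains.items()}
    ess = {t: effective_sample_size(c) for t, c in chains.items()}
    return PosteriorFit(
        model_id=kernels.model_id,
        variance_components=post_var,
        variance_sd=post_sd,
        mu=sum_mu / n_kept,
        effects={t: mean_u[t] / n_kept for t in terms},
        fitted=mean_fitted,
        records=kernels.records,
        ess=ess,
        config=config,
        missing_mask=miss,
    )


def fit_multitrait(
    Y,
    kernels: KernelSet,
    config: GibbsConfig = GibbsConfig(),
) -> PosteriorFit:
    """Bivariate Gibbs sampler for the multitrait model (M6).

    ``Y`` is an (n_records, 2) array/DataFrame: column 0 the primary trait
    (NaN allowed), column 1 the always-observed secondary trait.  The
    genetic terms (g, gxE) share an unstructured 2x2 covariance, as does
    the residual; the environment term is trait-specific.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != 2:
        raise ValueError("Y must have exactly 2 trait columns")
    n = kernels.n_records
    if Y.shape[0] != n:
        raise ValueError("response length does not match kernel records")
    if np.isnan(Y[:, 1]).any():
        raise ValueError("secondary trait must be fully observed")
    miss = ~np.isfinite(Y[:, 0])
    if int((~miss).sum()) < 2:
        raise ValueError("need at least 2 records with both traits")

    terms = list(kernels.kernels)
    cov_terms = [t for t in terms if t in GENETIC_TERMS]
    ind_terms = [t for t in terms if t not in GENETIC_TERMS]
    bases = {t: _eigen_basis(kernels.kernels[t]) for t in terms}

    rng = np.random.default_rng(config.seed)
    vy = np.array([np.nanvar(Y[:, 0]), np.var(Y[:, 1])])
    vy[vy == 0] = 1.0
    df0 = config.df0
    nu0 = 5.0                                  # inverse-Wishart prior df (> p + 1)
    n_terms = len(terms)
    # prior scale matrices chosen so the prior mean matches the univariate split
    psi0 = {
        t: np.diag(vy * config.r2 / n_terms) * (nu0 - 3.0) for t in cov_terms
    }
    psi0e = np.diag(vy * (1.0 - config.r2)) * (nu0 - 3.0)
    s0_ind = {t: vy * config.r2 / n_terms * (df0 + 2.0) for t in ind_terms}

    mu = np.array([float(np.nanmean(Y[:, 0])), float(np.mean(Y[:, 1]))])
    Sig = {t: np.diag(vy * config.r2 / n_terms) for t in cov_terms}
    sig_ind = {t: vy * config.r2 / n_terms for t in ind_terms}
    R = np.diag(vy * (1.0 - config.r2))
    A = {t: np.zeros((bases[t][0].shape[1], 2)) for t in terms}
    U = {t: np.zeros((n, 2)) for t in terms}
    Y_aug = Y.copy()
    Y_aug[miss, 0] = mu[0]
    fitted = np.zeros((n, 2))

    keep_iter = set(range(config.burn_in, config.n_iter, config.thin))
    n_kept = len(keep_iter)
    mean_fitted = np.zeros((n, 2))
    sum_mu = np.zeros(2)
    mean_u = {t: np.zeros((n, 2)) for t in terms}
    chain_gcov = np.empty((n_kept, 2, 2))
    chain_rcov = np.empty((n_kept, 2, 2))
    kept = 0

    def _inv2(M):
        det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
        return np.array([[M[1, 1], -M[0, 1]], [-M[1, 0], M[0, 0]]]) / det

    for it in range(config.n_iter):
        Rinv = _inv2(R)
        # -- covariance-coupled terms: rows of A are independent 2-vectors
        for t in cov_terms:
            B, lam = bases[t]
            Res = Y_aug - mu - fitted + U[t]
            BtR = B.T @ Res                             # m x 2
            Sinv = _inv2(Sig[t])
            # per-row precision: lam_j * Rinv + Sinv  (2x2 each)
            P = lam[:, None, None] * Rinv[None] + Sinv[None]
            det = P[:, 0, 0] * P[:, 1, 1] - P[:, 0, 1] * P[:, 1, 0]
            Pinv = np.empty_like(P)
            Pinv[:, 0, 0] = P[:, 1, 1] / det
            Pinv[:, 1, 1] = P[:, 0, 0] / det
            Pinv[:, 0, 1] = -P[:, 0, 1] / det
            Pinv[:, 1, 0] = -P[:, 1, 0] / det
            rhs = BtR @ Rinv.T                          # m x 2
            mean = np.einsum("mij,mj->mi", Pinv, rhs)
            # sample: mean + chol(Pinv) z
            L11 = np.sqrt(Pinv[:, 0, 0])
            L21 = Pinv[:, 1, 0] / L11
            L22 = np.sqrt(np.maximum(Pinv[:, 1, 1] - L21**2, 1e-300))
            z = rng.standard_normal((len(lam), 2))
            A[t] = mean + np.column_stack(
                (L11 * z[:, 0], L21 * z[:, 0] + L22 * z[:, 1])
            )
            new_u = B @ A[t]
            fitted += new_u - U[t]
            U[t] = new_u
            Sig[t] = stats.invwishart.rvs(
                df=nu0 + len(lam), scale=psi0[t] + A[t].T @ A[t], random_state=rng
            )
        # -- trait-independent terms (environment): univariate updates
        for t in ind_terms:
            B, lam = bases[t]
            Res = Y_aug - mu - fitted + U[t]
            for trait in (0, 1):
                r = Res[:, trait]
                prec = lam / R[trait, trait] + 1.0 / sig_ind[t][trait]
                mean = (B.T @ r / R[trait, trait]) / prec
                A[t][:, trait] = mean + rng.standard_normal(len(lam)) / np.sqrt(prec)
                ss = float(A[t][:, trait] @ A[t][:, trait]) + s0_ind[t][trait]
                sig_ind[t][trait] = _chi2_scale_draw(rng, ss, df0 + len(lam))
            new_u = B @ A[t]
            fitted += new_u - U[t]
            U[t] = new_u
        # -- means, residual covariance, missing primaries
        Res = Y_aug - fitted
        mu = Res.mean(axis=0) + rng.multivariate_normal(np.zeros(2), R / n)
        E = Res - mu
        R = stats.invwishart.rvs(df=nu0 + n, scale=psi0e + E.T @ E, random_state=rng)
        if miss.any():
            cond_mean = (
                mu[0] + fitted[miss, 0]
                + R[0, 1] / R[1, 1] * (Y_aug[miss, 1] - mu[1] - fitted[miss, 1])
            )
            cond_var = max(R[0, 0] - R[0, 1] ** 2 / R[1, 1], 1e-300)
            Y_aug[miss, 0] = cond_mean + rng.standard_normal(int(miss.sum())) * np.sqrt(cond_var)
        if it in keep_iter:
            mean_fitted += mu + fitted
            sum_mu += mu
            for t in terms:
                mean_u[t] += U[t]
            if "g" in Sig:
                chain_gcov[kept] = Sig["g"]
            elif cov_terms:
                chain_gcov[kept] = sum(Sig[t] for t in cov_terms)
            else:
                chain_gcov[kept] = np.zeros((2, 2))
            chain_rcov[kept] = R
            kept += 1

    mean_fitted /= n_kept
    gcov = chain_gcov.mean(axis=0)
    rcov = chain_rcov.mean(axis=0)
    ess = {
        "genetic_cov01": effective_sample_size(chain_gcov[:, 0, 1]),
        "residual_var0": effective_sample_size(chain_rcov[:, 0, 0]),
    }
    gcorr_chain = chain_gcov[:, 0, 1] / np.sqrt(
        chain_gcov[:, 0, 0] * chain_gcov[:, 1, 1]
    )
    return PosteriorFit(
        model_id=kernels.model_id,
        variance_components={"residual": float(rcov[0, 0]),
                             "genetic": float(gcov[0, 0])},
        variance_sd={"residual": float(np.std(chain_rcov[:, 0, 0], ddof=1)),
                     "genetic": float(np.std(chain_gcov[:, 0, 0], ddof=1)),
                     "genetic_corr": float(np.std(gcorr_chain, ddof=1))},
        mu=float(sum_mu[0] / n_kept),
        effects={t: mean_u[t][:, 0] / n_kept for t in terms},
        fitted=mean_fitted[:, 0],
        records=kernels.records,
        ess=ess,
        config=config,
        missing_mask=miss,
        genetic_cov=gcov,
        residual_cov=rcov,
        fitted_secondary=mean_fitted[:, 1],
        mu_secondary=float(sum_mu[1] / n_kept) if n_kept else None,
    )


def predict_records(fit: PosteriorFit, target_idx) -> np.ndarray:
    """Posterior-mean predictions for a subset of record positions."""
    idx = np.asarray(target_idx, dtype=int)
    if idx.size == 0:
        return np.empty(0)
    if idx.min() < 0 or idx.max() >= len(fit.fitted):
        raise IndexError("target record outside the fit's record index")
    return fit.fitted[idx]
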