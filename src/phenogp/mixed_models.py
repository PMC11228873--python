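"""REML mixed-model engine for per-environment trial analysis.

Two models drive the pipeline's first stage, fitted separately per
population and environment:

* end-of-season model: trait = mu + Hybrid + Range + Row + Rep + e, with
  the hybrid fixed to produce BLUEs (and refitted fully random for the
  entry-mean heritability sigma2_H / (sigma2_H + sigma2_e / n_reps));
* temporal model: VI value = mu + Hybrid + Flight + Hybrid:Flight +
  Range + Row + Rep + e, fully random, whose Hybrid:Flight BLUPs are the
  per-hybrid temporal values passed on to FPCA.

The engine is EM-REML on Henderson's mixed-model equations (MME).  All
random terms here are categorical factors, so every diagonal block of the
MME coefficient matrix is diagonal; the largest factor block (the
hybrid-by-flight interaction, with thousands of levels) is absorbed by a
Schur complement, leaving a small dense system per iteration.  The traces
of the inverse-MME blocks needed by the EM updates come from the same
factorization, so a full-scale temporal fit costs a small dense Cholesky
per iteration rather than a sparse-inverse computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

logger = logging.getLogger(__name__)

_TWO_PI = 2.0 * np.pi


class RankDeficiencyError(ValueError):
    """The fixed-effect design is singular after reference coding."""


class EmptyInputError(ValueError):
    """No usable observations for the requested fit."""


class UnknownViError(KeyError):
    """Requested vegetation index absent from the data."""


@dataclass
class VarianceComponents:
    """REML variance-component estimates for one fit."""

    components: dict            # term name -> variance
    residual: float
    converged: bool
    n_iterations: int

    def __getitem__(self, term: str) -> float:
        if term == "residual":
            return self.residual
        return self.components[term]


@dataclass
class RemlResult:
    """Converged solutions of one REML fit."""

    variance_components: VarianceComponents
    fixed_effects: pd.Series            # reference-coded solutions, incl. intercept
    random_effects: dict                # term -> Series of BLUPs by level
    fitted: np.ndarray
    loglik: float                       # restricted log-likelihood at the optimum
    n_obs: int


def _term_name(term) -> str:
    return ":".join(term) if isinstance(term, (tuple, list)) else str(term)


def _factor_codes(df: pd.DataFrame, term, levels=None):
    """Integer codes and level labels for a factor or interaction term."""
    if isinstance(term, (tuple, list)):
        key = df[list(term)].astype(str).agg("\x1f".join, axis=1)
    else:
        key = df[term]
    if levels is None:
        cat = pd.Categorical(key)
    else:
        cat = pd.Categorical(key, categories=levels)
        if (cat.codes < 0).any():
            raise ValueError(f"term {_term_name(term)} has values outside its levels")
    return cat.codes.astype(np.int64), list(cat.categories)


def _incidence(codes: np.ndarray, n_levels: int) -> sp.csr_matrix:
    n = len(codes)
    return sp.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels)
    )


class MixedDesign:
    """Precomputed design for a sequence of REML fits sharing one layout.

    The temporal model is fitted once per vegetation index with identical
    design matrices (same plots and flights), so the cross-products W'W are
    built once and each fit only supplies a new response vector.
    """

    def __init__(self, df: pd.DataFrame, fixed, random, random_levels=None):
        df = df.reset_index(drop=True)
        self.n = len(df)
        if self.n == 0:
            raise EmptyInputError("no observations")
        random_levels = random_levels or {}

        # fixed design: intercept + reference-coded dummies
        X_cols = [np.ones(self.n)]
        self.fixed_labels = ["(Intercept)"]
        for term in fixed:
            codes, levels = _factor_codes(df, term)
            name = _term_name(term)
            for j, lev in enumerate(levels[1:], start=1):
                X_cols.append((codes == j).astype(float))
                self.fixed_labels.append(f"{name}[{lev}]")
        X = np.column_stack(X_cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise RankDeficiencyError("fixed-effect design is rank deficient")
        self.X = X
        self.p = X.shape[1]

        self.random_names = [_term_name(t) for t in random]
        self.Z = []
        self.random_level_labels = {}
        self.q = []
        for term in random:
            name = _term_name(term)
            codes, levels = _factor_codes(df, term, random_levels.get(name))
            self.Z.append(_incidence(codes, len(levels)))
            self.random_level_labels[name] = levels
            self.q.append(len(levels))
        self.q = np.asarray(self.q, dtype=int)

        W = sp.hstack([sp.csr_matrix(X)] + self.Z, format="csr")
        self.W = W
        self.WtW = (W.T @ W).tocsc()
        # block index ranges within the MME
        offs = np.cumsum([self.p] + list(self.q))
        self.block_slices = [slice(0, self.p)] + [
            slice(a, b) for a, b in zip(offs[:-1], offs[1:])
        ]
        self.dim = offs[-1]
        # absorb the largest random block when it dominates the system
        big = int(np.argmax(self.q)) if len(self.q) else -1
        self.absorb = big if (len(self.q) and self.q[big] > 500) else None
        if self.absorb is not None:
            bs = self.block_slices[1 + self.absorb]
            mask = np.zeros(self.dim, dtype=bool)
            mask[bs] = True
            self.small_idx = np.flatnonzero(~mask)
            self.big_idx = np.flatnonzero(mask)
            A = self.WtW[np.ix_(self.small_idx, self.small_idx)]
            self.A_small = np.asarray(A.todense())
            self.B = self.WtW[np.ix_(self.small_idx, self.big_idx)].tocsr()
            self.D0 = np.asarray(
                self.WtW[np.ix_(self.big_idx, self.big_idx)].diagonal()
            ).ravel()
            # small-system positions of each non-absorbed block
            self.small_block_pos = []
            pos_of = np.full(self.dim, -1)
            pos_of[self.small_idx] = np.arange(len(self.small_idx))
            for bs2 in self.block_slices:
                self.small_block_pos.append(pos_of[np.arange(bs2.start, bs2.stop)])
        else:
            self.M0 = np.asarray(self.WtW.todense())

    def rhs(self, y: np.ndarray) -> np.ndarray:
        return self.W.T @ y

    # -- one linear solve of the MME at given lambdas, plus EM traces ------
    def solve(self, Wty, lambdas, need_traces=True):
        """Solve (W'W + Lambda) s = W'y; return s, per-block inverse traces
        and log|M| (None when traces are not requested)."""
        lam = np.zeros(self.dim)
        for k, bs in enumerate(self.block_slices[1:]):
            lam[bs] = lambdas[k]
        if self.absorb is None:
            M = self.M0 + np.diag(lam)
            cf = sla.cho_factor(M, lower=True)
            sol = sla.cho_solve(cf, Wty)
            if not need_traces:
                return sol, None, 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            Minv = sla.cho_solve(cf, np.eye(self.dim))
            traces = [
                float(np.trace(Minv[bs, bs])) for bs in self.block_slices[1:]
            ]
            logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            return sol, traces, logdet

        D = self.D0 + lam[self.big_idx]
        Dinv = 1.0 / D
        BDi = self.B.multiply(Dinv[None, :]).tocsr()       # B D^-1
        S = self.A_small + np.diag(lam[self.small_idx]) - np.asarray(
            (BDi @ self.B.T).todense()
        )
        cf = sla.cho_factor(S, lower=True)
        rhs_small = Wty[self.small_idx] - BDi @ Wty[self.big_idx]
        sol_small = sla.cho_solve(cf, rhs_small)
        sol_big = Dinv * (Wty[self.big_idx] - self.B.T @ sol_small)
        sol = np.empty(self.dim)
        sol[self.small_idx] = sol_small
        sol[self.big_idx] = sol_big
        if not need_traces:
            logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0])))) + float(
                np.sum(np.log(D))
            )
            return sol, None, logdet
        Sinv = sla.cho_solve(cf, np.eye(S.shape[0]))
        G2 = np.asarray((BDi @ BDi.T).todense())           # B D^-2 B'
        traces = []
        for k, bs in enumerate(self.block_slices[1:]):
            if k == self.absorb:
                traces.append(float(np.sum(Dinv) + np.sum(Sinv * G2)))
            else:
                pos = self.small_block_pos[1 + k]
                traces.append(float(np.trace(Sinv[np.ix_(pos, pos)])))
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0])))) + float(
            np.sum(np.log(D))
        )
        return sol, traces, logdet

    def reml(
        self,
        y: np.ndarray,
        tol: float = 1e-6,
        max_iter: int = 500,
        start=None,
    ) -> RemlResult:
        """EM-REML fit for one response on this design."""
        y = np.asarray(y, dtype=float)
        if len(y) != self.n:
            raise ValueError("response length does not match design")
        n, p = self.n, self.p
        K = len(self.q)
        Wty = self.rhs(y)
        yty = float(y @ y)
        vary = float(np.var(y))
        if vary == 0.0:
            # constant response: exact degenerate solution
            sol = np.zeros(self.dim)
            sol[0] = y[0]
            vc = VarianceComponents(
                {nm: 0.0 for nm in self.random_names}, 0.0, True, 0
            )
            return self._package(vc, sol, y, float("nan"))

        floor = max(vary, 1e-12) * 1e-8
        if start is not None:
            sig = np.array([max(start[nm], floor) for nm in self.random_names])
            sig_e = max(start["residual"], floor)
        else:
            sig = np.full(K, vary / (K + 1.0))
            sig_e = vary / (K + 1.0)

        converged = False
        it = 0
        hist: list = []
        for it in range(1, max_iter + 1):
            lambdas = sig_e / sig
            sol, traces, _ = self.solve(Wty, lambdas, need_traces=True)
            new_sig = np.empty(K)
            for k, bs in enumerate(self.block_slices[1:]):
                u = sol[bs]
                new_sig[k] = (u @ u + sig_e * traces[k]) / self.q[k]
            e_dot = yty - float(sol @ Wty)
            new_sig_e = e_dot / (n - p)
            new_sig = np.maximum(new_sig, floor)
            new_sig_e = max(new_sig_e, floor)
            scale = max(vary, 1e-12)
            # a component at the zero boundary decays only harmonically
            # under EM; once negligible and still shrinking, pin it there
            if it > 10:
                snap = (new_sig < sig) & (new_sig < 3e-4 * scale)
                new_sig[snap] = floor
            # components collapsing to the boundary change multiplicatively
            # slowly under EM; once negligible they are treated as converged
            active = new_sig > 1e-5 * scale
            rel = np.abs(new_sig - sig) / np.maximum(sig, 1e-3 * scale)
            delta = max(
                float(np.max(rel[active])) if active.any() else 0.0,
                abs(new_sig_e - sig_e) / max(sig_e, 1e-3 * scale),
            )
            sig, sig_e = new_sig, new_sig_e
            if delta < tol:
                converged = True
                break
            # EM converges geometrically; every few sweeps, extrapolate each
            # component along its own geometric trajectory (Aitken step)
            hist.append(np.append(sig, sig_e))
            if len(hist) >= 3 and it % 8 == 0:
                s0, s1, s2 = hist[-3], hist[-2], hist[-1]
                d1, d0 = s2 - s1, s1 - s0
                with np.errstate(divide="ignore", invalid="ignore"):
                    r = np.where(np.abs(d0) > 0, d1 / d0, 0.0)
                ok = (r > 0.0) & (r < 0.995)
                ext = np.where(ok, s2 + d1 * r / (1.0 - r), s2)
                # an extrapolation through zero means the component is
                # heading for the boundary: snap small ones, reject others
                neg = ext < floor
                ext[neg] = np.where(s2[neg] < 0.01 * scale, floor, s2[neg])
                sig, sig_e = ext[:-1], float(ext[-1])

        if not converged:
            # EM stalls when a component crawls along the zero boundary;
            # finish by maximizing the restricted likelihood directly
            sig, sig_e, polished = self._polish(Wty, yty, sig, sig_e, floor)
            converged = polished

        lambdas = sig_e / sig
        sol, _, logdetM = self.solve(Wty, lambdas, need_traces=True)
        yPy = (yty - float(sol @ Wty)) / sig_e
        loglik = -0.5 * (
            (n - p - self.dim + p) * np.log(sig_e)
            + float(np.sum(self.q * np.log(sig)))
            + logdetM
            + yPy
            + (n - p) * np.log(_TWO_PI)
        )
        vc = VarianceComponents(
            dict(zip(self.random_names, sig.tolist())), float(sig_e), converged, it
        )
        if not converged:
            logger.warning(
                "REML did not converge in %d iterations (last rel. change %.2e)",
                max_iter, delta,
            )
        return self._package(vc, sol, y, loglik)

    def _neg2_restricted_ll(self, Wty, yty, sig, sig_e):
        """-2 x restricted log-likelihood (up to the constant term)."""
        sol, _, logdetM = self.solve(Wty, sig_e / sig, need_traces=False)
        yPy = (yty - float(sol @ Wty)) / sig_e
        n, p = self.n, self.p
        return (
            (n - self.dim) * np.log(sig_e)
            + float(np.sum(self.q * np.log(sig)))
            + logdetM
            + yPy
        )

    def _polish(self, Wty, yty, sig, sig_e, floor):
        """Direct Nelder-Mead maximization of the restricted likelihood,
        started from the EM iterate (used when EM stalls at a boundary)."""
        from scipy.optimize import minimize

        x0 = np.log(np.maximum(np.append(sig, sig_e), floor))

        def nll(x):
            theta = np.exp(np.clip(x, -60.0, 60.0))
            return self._neg2_restricted_ll(Wty, yty, theta[:-1], float(theta[-1]))

        res = minimize(nll, x0, method="Nelder-Mead",
                       options=dict(maxiter=400 * len(x0), fatol=1e-10, xatol=1e-7))
        theta = np.exp(np.clip(res.x, -60.0, 60.0))
        if nll(res.x) <= nll(x0):
            return np.maximum(theta[:-1], floor), max(float(theta[-1]), floor), bool(res.success)
        return sig, sig_e, False

    def _package(self, vc, sol, y, loglik) -> RemlResult:
        fixed = pd.Series(sol[: self.p], index=self.fixed_labels)
        random_effects = {}
        for k, bs in enumerate(self.block_slices[1:]):
            name = self.random_names[k]
            random_effects[name] = pd.Series(
                sol[bs], index=self.random_level_labels[name]
            )
        fitted = self.W @ sol
        return RemlResult(
            variance_components=vc,
            fixed_effects=fixed,
            random_effects=random_effects,
            fitted=fitted,
            loglik=loglik,
            n_obs=self.n,
        )


def solve_reml(
    df: pd.DataFrame,
    response: str,
    fixed,
    random,
    tol: float = 1e-6,
    max_iter: int = 500,
    random_levels=None,
    start=None,
) -> RemlResult:
    """EM-REML fit of a crossed-factor mixed model.

    Parameters
    ----------
    df : DataFrame with the response and all factor columns.
    response : name of the response column; rows with missing response
        are dropped.
    fixed, random : lists of factor terms; a term is a column name or a
        tuple of column names (interaction).  An intercept is always
        included; fixed factors are reference coded.
    random_levels : optional dict term-name -> explicit level list, used
        to carry a complete grid (levels without data get BLUP 0).
    start : optional dict of starting variances (term name / "residual").
    """
    df = df.loc[df[response].notna()].reset_index(drop=True)
    if df.empty:
        raise EmptyInputError(f"no non-missing values of {response!r}")
    design = MixedDesign(df, fixed, random, random_levels)
    return design.reml(df[response].to_numpy(float), tol=tol, max_iter=max_iter, start=start)


def reml_loglik_dense(df, response, fixed, random, components, residual):
    """Restricted log-likelihood via the dense covariance matrix.

    Independent of the MME path (used as a numerical cross-check); only
    sensible for small data sets.
    """
    df = df.loc[df[response].notna()].reset_index(drop=True)
    design = MixedDesign(df, fixed, random)
    y = df[response].to_numpy(float)
    n = design.n
    V = residual * np.eye(n)
    for k, Z in enumerate(design.Z):
        Zd = np.asarray(Z.todense())
        V += components[design.random_names[k]] * (Zd @ Zd.T)
    X = design.X
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    _, ld_V = np.linalg.slogdet(V)
    _, ld_X = np.linalg.slogdet(XtViX)
    return -0.5 * (
        ld_V + ld_X + float(r @ Vi @ r) + (n - X.shape[1]) * np.log(_TWO_PI)
    )


# ---------------------------------------------------------------------------
# Stage-1 fits
# ---------------------------------------------------------------------------

_EQ1_RANDOM = ["range", "row", "rep"]


def _env_plots(plots: pd.DataFrame, environment: str) -> pd.DataFrame:
    sub = plots.loc[plots["environment"] == environment]
    if sub.empty:
        raise EmptyInputError(f"no plots for environment {environment!r}")
    return sub


def fit_blues(plots: pd.DataFrame, trait: str, environment: str,
              tol: float = 1e-6, max_iter: int = 500) -> pd.DataFrame:
    """Per-environment hybrid BLUEs: hybrid fixed, range/row/rep random.

    Returns a tidy table (hybrid, environment, trait, blue), with the BLUE
    reported on the trait scale (intercept + hybrid effect).
    """
    if trait not in ("gy", "pht"):
        raise ValueError("trait must be 'gy' or 'pht'")
    sub = _env_plots(plots, environment)
    sub = sub.loc[sub[trait].notna()]
    if sub.empty:
        raise EmptyInputError(f"all values of {trait!r} missing in {environment!r}")
    if sub["hybrid"].nunique() < 2:
        raise EmptyInputError("need at least 2 hybrids with data")
    res = solve_reml(sub, trait, fixed=["hybrid"], random=_EQ1_RANDOM,
                     tol=tol, max_iter=max_iter)
    mu = res.fixed_effects["(Intercept)"]
    hybrids = sorted(sub["hybrid"].astype(str).unique())
    eff = {h: 0.0 for h in hybrids}
    for label, val in res.fixed_effects.items():
        if label.startswith("hybrid["):
            eff[label[len("hybrid["):-1]] = val
    return pd.DataFrame(
        {
            "hybrid": hybrids,
            "environment": environment,
            "trait": trait,
            "blue": [mu + eff[h] for h in hybrids],
        }
    )


def estimate_heritability(plots: pd.DataFrame, trait: str, environment: str,
                          tol: float = 1e-6, max_iter: int = 500) -> float:
    """Entry-mean heritability from the fully random end-of-season model.

    h2 = sigma2_H / (sigma2_H + sigma2_e / n_reps), with n_reps the number
    of replications present; range/row/rep variances are estimated but do
    not enter the denominator.
    """
    sub = _env_plots(plots, environment)
    sub = sub.loc[sub[trait].notna()]
    n_reps = sub["rep"].nunique()
    if n_reps < 2:
        raise ValueError("heritability needs at least 2 replications")
    res = solve_reml(sub, trait, fixed=[], random=["hybrid"] + _EQ1_RANDOM,
                     tol=tol, max_iter=max_iter)
    vh = res.variance_components["hybrid"]
    ve = res.variance_components.residual
    if vh + ve / n_reps == 0:
        return 0.0
    return float(vh / (vh + ve / n_reps))


def _temporal_design(sub: pd.DataFrame):
    """Design for the fully random temporal model on one environment."""
    hybrids = sorted(sub["hybrid"].astype(str).unique())
    daps = sorted(sub["flight_dap"].unique())
    hf_levels = [f"{h}\x1f{d}" for h in hybrids for d in daps]
    levels = {
        "hybrid": hybrids,
        "flight_dap": [str(d) for d in daps],
        "hybrid:flight_dap": hf_levels,
    }
    sub = sub.copy()
    sub["flight_dap"] = sub["flight_dap"].astype(str)
    design = MixedDesign(
        sub,
        fixed=[],
        random=["hybrid", "flight_dap", ("hybrid", "flight_dap"),
                "range", "row", "rep"],
        random_levels=levels,
    )
    return design, hybrids, daps


def fit_temporal_blups(
    vi_obs: pd.DataFrame,
    vi_name: str,
    environment: str,
    tol: float = 1e-6,
    max_iter: int = 200,
    start=None,
) -> pd.DataFrame:
    """Per-hybrid temporal values of one VI in one environment.

    Fits the fully random temporal model and returns, on the complete
    hybrid x flight grid, each hybrid's predicted temporal deviation
    BLUP(hybrid) + BLUP(hybrid:flight).  The flight main effect is
    excluded, so values are centered across hybrids at every flight;
    cells without data shrink toward the hybrid's main effect.  Output
    columns: hybrid, environment, vi_name, flight_dap, blup.
    """
    table, _ = fit_temporal_blups_all(
        vi_obs, [vi_name], environment, tol=tol, max_iter=max_iter, start=start
    )
    return table


def fit_temporal_blups_all(
    vi_obs: pd.DataFrame,
    vi_names,
    environment: str,
    tol: float = 1e-6,
    max_iter: int = 200,
    start=None,
):
    """Temporal BLUPs for several VIs sharing one environment's design.

    The design matrices depend only on the plot/flight layout, so they are
    built once; each VI supplies a new response and warm-starts from the
    previous VI's variance components.  Returns (blup_table, variance
    components per VI).
    """
    sub_env = vi_obs.loc[vi_obs["environment"] == environment]
    if sub_env.empty:
        raise EmptyInputError(f"no VI observations for environment {environment!r}")
    present = set(sub_env["vi_name"].unique())
    missing = [v for v in vi_names if v not in present]
    if missing:
        raise UnknownViError(f"VIs absent from data: {missing}")
    if sub_env["flight_dap"].nunique() < 2 or sub_env["hybrid"].nunique() < 2:
        raise EmptyInputError("need at least 2 flights and 2 hybrids")

    key_cols = ["hybrid", "flight_dap", "range", "row", "rep"]
    design = None
    key_ref = None
    tables = []
    vcs = {}
    warm = dict(start) if start else None
    for vi in vi_names:
        sub = (
            sub_env.loc[sub_env["vi_name"] == vi]
            .dropna(subset=["value"])
            .sort_values(key_cols, kind="stable")
            .reset_index(drop=True)
        )
        key = sub[key_cols]
        if design is None or not key.equals(key_ref):
            design, hybrids, daps = _temporal_design(sub)
            key_ref = key
        res = design.reml(sub["value"].to_numpy(float), tol=tol,
                          max_iter=max_iter, start=warm)
        vcs[vi] = res.variance_components
        warm = dict(res.variance_components.components,
                    residual=res.variance_components.residual)
        # temporal value of hybrid i at flight j: its predicted deviation
        # BLUP(H_i) + BLUP(HF_ij).  The flight main effect and intercept are
        # left out, so values are centered across hybrids at every flight.
        hf = res.random_effects["hybrid:flight_dap"].to_numpy()
        h_main = res.random_effects["hybrid"].to_numpy()
        n_d = len(daps)
        hf = hf + np.repeat(h_main, n_d)
        tables.append(
            pd.DataFrame(
                {
                    "hybrid": np.repeat(hybrids, n_d),
                    "environment": environment,
                    "vi_name": vi,
                    "flight_dap": np.tile(daps, len(hybrids)),
                    "blup": hf,
                }
            )
        )
        logger.info(
            "temporal BLUPs %s/%s: %d rows, %d REML iterations%s",
            environment, vi, len(tables[-1]), res.variance_components.n_iterations,
            "" if res.variance_components.converged else " (not converged)",
        )
    return pd.concat(tables, ignore_index=True), vcs
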