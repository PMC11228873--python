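"""Functional PCA of temporal vegetation-index curves.

Each hybrid's temporal BLUP curve V_i(t) on an environment's flight grid
is decomposed as V_i(t) = mu(t) + sum_k xi_ik phi_k(t): mean curve,
orthonormal eigenfunctions and per-hybrid scores.  Because the curves live
on a common, dense per-environment grid, the estimator is a
quadrature-weighted PCA of the discretized sample covariance (trapezoidal
weights over DAP) -- exact at the observed design, with no smoothing.

Two flight windows are supported: "until_flowering" (flights with
DAP <= flowering start, inclusive) and "full" (all flights).  The first
two scores per VI form the phenomic score matrix; because score columns
are named by VI and component only, score matrices from environments with
different flight calendars can be merged row-wise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WINDOWS = ("until_flowering", "full")


class InsufficientGridError(ValueError):
    """Fewer than two flight dates inside the requested window."""


class AlignmentError(ValueError):
    """Hybrid sets differ across the VIs of one environment."""


class SchemaError(ValueError):
    """Score-matrix columns do not match across environments."""


@dataclass
class FpcaModel:
    """Fitted functional PCA for one VI x environment x window."""

    vi_name: str
    environment: str
    window: str
    dap_grid: np.ndarray          # ascending DAPs used
    mean_curve: np.ndarray        # mu(t) on the grid
    eigenfunctions: np.ndarray    # grid x n_components, quadrature-orthonormal
    eigenvalues: np.ndarray       # non-increasing, >= 0
    scores: pd.DataFrame          # hybrid x FPCA1..m

    @property
    def explained_fractions(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        if tot <= 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / tot

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    """Composite trapezoidal quadrature weights on an ascending grid."""
    grid = np.asarray(grid, dtype=float)
    if len(grid) < 2:
        raise InsufficientGridError("need at least 2 grid points")
    w = np.zeros_like(grid)
    d = np.diff(grid)
    w[:-1] += d / 2.0
    w[1:] += d / 2.0
    return w


def fit_fpca(
    curves: pd.DataFrame,
    dap_grid=None,
    window_daps=None,
    vi_name: str = "",
    environment: str = "",
    window: str = "full",
) -> FpcaModel:
    """Quadrature-weighted functional PCA of per-hybrid curves.

    Parameters
    ----------
    curves : DataFrame, hybrids x DAP columns (ascending integers).
    dap_grid : optional explicit grid; defaults to the column labels.
    window_daps : optional subset of DAPs to restrict to (the flight
        window); must select at least 2 grid points.
    """
    if curves.shape[0] < 2:
        raise ValueError("need at least 2 hybrids")
    grid = np.asarray(dap_grid if dap_grid is not None else curves.columns, dtype=float)
    Y = curves.to_numpy(dtype=float)
    if window_daps is not None:
        keep = np.isin(grid, np.asarray(window_daps, dtype=float))
        grid, Y = grid[keep], Y[:, keep]
    if len(grid) < 2:
        raise InsufficientGridError(
            f"only {len(grid)} flights inside the window; need >= 2"
        )
    order = np.argsort(grid)
    grid, Y = grid[order], Y[:, order]

    w = trapezoid_weights(grid)
    mu = Y.mean(axis=0)
    Yc = Y - mu
    n = Y.shape[0]
    C = (Yc.T @ Yc) / (n - 1)                 # pointwise sample covariance
    sw = np.sqrt(w)
    Cw = sw[:, None] * C * sw[None, :]
    evals, evecs = np.linalg.eigh(0.5 * (Cw + Cw.T))
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    phi = evecs[:, order] / sw[:, None]       # quadrature-orthonormal
    # sign convention: largest-magnitude grid value positive
    for k in range(phi.shape[1]):
        j = int(np.argmax(np.abs(phi[:, k])))
        if phi[j, k] < 0:
            phi[:, k] = -phi[:, k]
    xi = (Yc * w[None, :]) @ phi              # weighted inner products
    scores = pd.DataFrame(
        xi,
        index=curves.index,
        columns=[f"FPCA{k + 1}" for k in range(phi.shape[1])],
    )
    return FpcaModel(
        vi_name=vi_name,
        environment=environment,
        window=window,
        dap_grid=grid,
        mean_curve=mu,
        eigenfunctions=phi,
        eigenvalues=evals,
        scores=scores,
    )


def curves_from_blups(blups: pd.DataFrame, vi_name: str, environment: str) -> pd.DataFrame:
    """Pivot a temporal BLUP table into a hybrid x DAP curve matrix."""
    sub = blups.loc[
        (blups["vi_name"] == vi_name) & (blups["environment"] == environment)
    ]
    if sub.empty:
        raise KeyError(f"no BLUPs for {vi_name!r} in {environment!r}")
    mat = sub.pivot(index="hybrid", columns="flight_dap", values="blup")
    return mat.sort_index(axis=0).sort_index(axis=1)


def fit_fpca_environment(
    blups: pd.DataFrame,
    environment: str,
    flowering_start_dap: int,
    vi_names=None,
    window: str = "full",
) -> dict:
    """Fit FPCA for every VI of one environment under one flight window."""
    if window not in WINDOWS:
        raise ValueError(f"window must be one of {WINDOWS}")
    sub = blups.loc[blups["environment"] == environment]
    vi_names = list(vi_names) if vi_names is not None else sorted(sub["vi_name"].unique())
    models = {}
    for vi in vi_names:
        curves = curves_from_blups(sub, vi, environment)
        daps = curves.columns.to_numpy(dtype=float)
        win = daps[daps <= flowering_start_dap] if window == "until_flowering" else None
        models[vi] = fit_fpca(
            curves, window_daps=win, vi_name=vi, environment=environment, window=window
        )
    return models


def explained_variance_summary(models, k: int = 2):
    """Cumulative explained-variance fraction of the first k components.

    Returns (per-model Series of cumulative fractions, mean, sd) across
    the supplied models (typically all VIs of one or more environments).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    models = list(models.values()) if isinstance(models, dict) else list(models)
    rows = {}
    for m in models:
        frac = m.explained_fractions
        rows[(m.vi_name, m.environment, m.window)] = float(frac[:k].sum())
    per_model = pd.Series(rows)
    return per_model, float(per_model.mean()), float(per_model.std(ddof=1)) if len(per_model) > 1 else 0.0


def build_score_matrix(models: dict, n_scores: int = 2) -> pd.DataFrame:
    """Assemble the per-environment phenomic score matrix.

    Rows are (hybrid, environment); columns are ``<vi>_FPCA1``,
    ``<vi>_FPCA2`` for every VI in canonical (sorted) order, so the
    column labels are identical across environments regardless of each
    environment's flight calendar.
    """
    if not models:
        raise ValueError("no FPCA models supplied")
    vis = sorted(models)
    envs = {models[v].environment for v in vis}
    if len(envs) != 1:
        raise AlignmentError(f"models span several environments: {sorted(envs)}")
    environment = envs.pop()
    ref = models[vis[0]].scores.index
    cols = {}
    for vi in vis:
        sc = models[vi].scores
        if not sc.index.equals(ref):
            raise AlignmentError(
                f"hybrid set of VI {vi!r} differs from {vis[0]!r}"
            )
        for k in range(n_scores):
            cols[f"{vi}_FPCA{k + 1}"] = sc.iloc[:, k].to_numpy()
    out = pd.DataFrame(cols, index=ref)
    out.index = pd.MultiIndex.from_arrays(
        [ref.to_numpy(), np.repeat(environment, len(ref))],
        names=["hybrid", "environment"],
    )
    return out[sorted(out.columns, key=lambda c: (c.rsplit("_FPCA", 1)[0], c))]


def merge_environments(matrices) -> pd.DataFrame:
    """Row-wise merge of per-environment score matrices.

    Identical column labels are required (they are, by construction, when
    every environment used the same VI panel): mismatched flight dates do
    not prevent merging because scores are indexed by component, not DAP.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no score matrices supplied")
    ref_cols = sorted(matrices[0].columns)
    for m in matrices[1:]:
        if sorted(m.columns) != ref_cols:
            raise SchemaError("score-matrix columns differ across environments")
    out = pd.concat([m[ref_cols] for m in matrices], axis=0)
    return out
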