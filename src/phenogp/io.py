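"""Readers and writers for the pipeline's tabular file layouts.

File layouts mirror the study-style deposited CSVs:

* ``GAPIT.Genotype.Numerical <pop>.txt`` -- numeric genotypes: first
  column ``taxa``, one column per marker, dosage codes 0/1/2 (tab- or
  comma-delimited; missing cells imputed to the column mean code);
* ``Yield.csv`` / ``PHT.csv`` -- trait BLUEs: hybrid, environment, trait,
  blue;
* ``FP.<environment>.csv`` -- temporal hybrid-by-flight BLUPs of every
  VI: hybrid, flight_dap, then one column per VI;
* ``FP.<environment>.FPCA.until_flowering.csv`` /
  ``FP.<environment>.FPCA.full_flights.csv`` -- phenomic score matrices:
  hybrid, environment, then ``<vi>_FPCA1``/``<vi>_FPCA2`` per VI;
* ``<trait>.for.multitrait.csv`` -- primary-trait BLUEs plus the single
  secondary-trait column ``VARI_FPCA1``;
* plot tables and a simulator-only ground-truth table.

All CSVs are comma-separated UTF-8 with a mandatory header; missing
values are empty cells or ``NA``.  Schema violations raise
:class:`SchemaError` naming the offending column rather than coercing.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .kernels import MarkerMatrix

logger = logging.getLogger(__name__)

_NA = ["", "NA"]


class SchemaError(ValueError):
    """A file's header does not match its expected schema."""


class ParseError(ValueError):
    """A cell could not be parsed (message carries the line number)."""


def _require_columns(df: pd.DataFrame, needed, path) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


# -- genotypes ---------------------------------------------------------------

def write_genotypes_numeric(markers: MarkerMatrix, path, sep: str = "\t") -> None:
    df = markers.to_frame()
    df.insert(0, "taxa", df.index)
    df.to_csv(path, sep=sep, index=False)


def read_genotypes_numeric(path) -> MarkerMatrix:
    """Read a numeric genotype table (first column taxa, cells 0/1/2).

    Tab- and comma-delimited files are both accepted.  Missing cells are
    imputed to the rounded column mean code, with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", na_values=_NA,
                     keep_default_na=False)
    if df.columns[0].lower() != "taxa":
        raise SchemaError(f"{path}: first column must be 'taxa', got {df.columns[0]!r}")
    taxa = df.iloc[:, 0].astype(str).tolist()
    body = df.iloc[:, 1:]
    X = np.empty(body.shape, dtype=float)
    for j, col in enumerate(body.columns):
        vals = pd.to_numeric(body[col], errors="coerce")
        bad = vals.isna() & body[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ParseError(
                f"{path}: non-numeric cell in column {col!r} at line {line}"
            )
        if vals.isna().any():
            fill = float(np.round(vals.mean()))
            logger.warning(
                "%s: %d missing cells in marker %s imputed to %g",
                path, int(vals.isna().sum()), col, fill,
            )
            vals = vals.fillna(fill)
        if not vals.isin([0, 1, 2]).all():
            raise ParseError(f"{path}: column {col!r} has codes outside {{0,1,2}}")
        X[:, j] = vals.to_numpy()
    return MarkerMatrix(hybrids=taxa, markers=list(body.columns), X=X.astype(int))


# -- stage tables ------------------------------------------------------------

def write_plot_table(plots: pd.DataFrame, path) -> None:
    _require_columns(plots, ["hybrid", "environment", "range", "row", "rep"], path)
    plots.to_csv(path, index=False)


def read_plot_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=_NA, keep_default_na=False)
    _require_columns(df, ["hybrid", "environment", "range", "row", "rep"], path)
    for c in ("gy", "pht"):
        if c in df.columns:
            df[c] = pd.to_numeric(df[c], errors="coerce")
    df["hybrid"] = df["hybrid"].astype(str)
    return df


def write_vi_table(vi_obs: pd.DataFrame, path) -> None:
    cols = ["hybrid", "environment", "flight_dap", "vi_name",
            "range", "row", "rep", "value"]
    _require_columns(vi_obs, cols, path)
    vi_obs[cols].to_csv(path, index=False)


def read_vi_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=_NA, keep_default_na=False)
    _require_columns(
        df,
        ["hybrid", "environment", "flight_dap", "vi_name",
         "range", "row", "rep", "value"],
        path,
    )
    df["hybrid"] = df["hybrid"].astype(str)
    return df


def write_blue_table(blues: pd.DataFrame, path) -> None:
    """Yield.csv / PHT.csv layout: hybrid, environment, trait, blue."""
    _require_columns(blues, ["hybrid", "environment", "trait", "blue"], path)
    blues.to_csv(path, index=False)


def read_blue_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=_NA, keep_default_na=False)
    _require_columns(df, ["hybrid", "environment", "trait", "blue"], path)
    df["hybrid"] = df["hybrid"].astype(str)
    return df


def write_temporal_blups(blups: pd.DataFrame, path, vi_names=None) -> None:
    """FP.<environment>.csv layout: hybrid, flight_dap, one column per VI."""
    _require_columns(
        blups, ["hybrid", "environment", "vi_name", "flight_dap", "blup"], path
    )
    envs = blups["environment"].unique()
    if len(envs) != 1:
        raise SchemaError(f"{path}: one FP file holds exactly one environment")
    wide = blups.pivot_table(
        index=["hybrid", "flight_dap"], columns="vi_name", values="blup"
    ).reset_index()
    wide.columns.name = None
    if vi_names is not None:
        wide = wide[["hybrid", "flight_dap"] + list(vi_names)]
    wide.insert(1, "environment", envs[0])
    wide.to_csv(path, index=False)


def read_temporal_blups(path, vi_names=None) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=_NA, keep_default_na=False)
    _require_columns(df, ["hybrid", "environment", "flight_dap"], path)
    vi_cols = [c for c in df.columns
               if c not in ("hybrid", "environment", "flight_dap")]
    if vi_names is not None:
        unknown = [c for c in vi_cols if c not in vi_names]
        if unknown:
            raise SchemaError(f"{path}: unknown VI column(s) {unknown}")
    long = df.melt(
        id_vars=["hybrid", "environment", "flight_dap"],
        value_vars=vi_cols,
        var_name="vi_name",
        value_name="blup",
    )
    long["hybrid"] = long["hybrid"].astype(str)
    return long


def write_score_matrix(scores: pd.DataFrame, path) -> None:
    """FP.<env>.FPCA.<window>.csv layout: hybrid, environment, score cols."""
    out = scores.reset_index()
    _require_columns(out, ["hybrid", "environment"], path)
    out.to_csv(path, index=False)


def read_score_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=_NA, keep_default_na=False)
    _require_columns(df, ["hybrid", "environment"], path)
    bad = [c for c in df.columns
           if c not in ("hybrid", "environment") and "_FPCA" not in c]
    if bad:
        raise SchemaError(f"{path}: unexpected non-score column(s) {bad}")
    df["hybrid"] = df["hybrid"].astype(str)
    return df.set_index(["hybrid", "environment"])


def write_multitrait_table(blues: pd.DataFrame, secondary: pd.Series, trait: str, path) -> None:
    """<trait>.for.multitrait.csv: BLUEs plus the VARI_FPCA1 secondary column."""
    _require_columns(blues, ["hybrid", "environment", "trait", "blue"], path)
    sub = blues.loc[blues["trait"] == trait].copy()
    key = pd.MultiIndex.from_frame(sub[["hybrid", "environment"]])
    sub["VARI_FPCA1"] = secondary.reindex(key).to_numpy()
    sub.to_csv(path, index=False)


def read_multitrait_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=_NA, keep_default_na=False)
    _require_columns(df, ["hybrid", "environment", "trait", "blue", "VARI_FPCA1"], path)
    df["hybrid"] = df["hybrid"].astype(str)
    return df


def write_kernel(K: np.ndarray, records: pd.DataFrame, path) -> None:
    """Square kernel CSV with '<hybrid>@<environment>' record labels."""
    labels = records["hybrid"].astype(str) + "@" + records["environment"].astype(str)
    pd.DataFrame(K, index=labels, columns=labels).to_csv(path)


def write_truth_tables(truth, out_dir) -> None:
    """Simulator-only ground-truth tables (synthetic provenance)."""
    out_dir = Path(out_dir)
    truth.genetic.to_csv(out_dir / "truth.genetic.csv")
    truth.gxe.to_csv(out_dir / "truth.gxe.csv")
    truth.vi_genetic.to_csv(out_dir / "truth.vi_genetic.csv")
    truth.vi_loadings.to_frame().to_csv(out_dir / "truth.vi_loadings.csv")


def write_manifest(path, config: dict, seed: int) -> None:
    """Run manifest: config, seed and package version, as JSON."""
    from . import __version__

    payload = {"seed": seed, "version": __version__, "config": config}
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
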