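"""Relationship kernels for multi-environment phenomic/genomic prediction.

Builds the covariance structures used by the Bayesian prediction models:
the genomic relationship matrix ``G = Xc Xc' / p`` from centered,
column-standardized marker codes, the phenomic relationship matrix
``P = Rc Rc' / (2 * n_vi)`` from functional principal component scores,
the environment block kernel ``Z_E Z_E' / n_env``, and Hadamard-product
genotype-by-environment (reaction-norm) interaction kernels.  Kernels are
assembled per model (M1-M6) at the record level, where a record is one
(hybrid, environment) combination.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODEL_IDS = ("M1", "M2", "M3", "M4", "M5", "M6")

#: kernel names required by each prediction model
MODEL_KERNELS = {
    "M1": ("E", "g", "gxE"),
    "M2": ("E", "P1", "P1xE"),
    "M3": ("E", "P2", "P2xE"),
    "M4": ("E", "g", "P1", "gxE", "P1xE"),
    "M5": ("E", "g", "P2", "gxE", "P2xE"),
    # M6 is the multitrait model; its kernel structure is identical to M1,
    # the second (secondary-trait) response is what distinguishes it.
    "M6": ("E", "g", "gxE"),
}


class DegenerateMarkerError(ValueError):
    """All markers monomorphic: no genomic relationship can be formed."""


class KernelConfigurationError(ValueError):
    """A model requests a kernel that was not supplied."""


@dataclass
class MarkerMatrix:
    """Biallelic genotypes coded as minor-allele dosage 0/1/2.

    Parameters
    ----------
    hybrids : list of str
        Row labels (hybrid identifiers), in matrix order.
    markers : list of str
        Column labels (marker identifiers).
    X : ndarray of shape (n_hybrids, n_markers)
        Integer dosage codes in {0, 1, 2}.
    """

    hybrids: list
    markers: list
    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        if self.X.shape != (len(self.hybrids), len(self.markers)):
            raise ValueError("genotype matrix shape does not match labels")
        vals = np.unique(self.X[~np.isnan(self.X.astype(float))])
        if not np.all(np.isin(vals, [0, 1, 2])):
            raise ValueError("genotype codes must be in {0, 1, 2}")

    @property
    def n_hybrids(self) -> int:
        return len(self.hybrids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.hybrids, columns=self.markers)


@dataclass
class KernelSet:
    """Named record-level relationship matrices for one prediction model.

    ``records`` fixes the (hybrid, environment) ordering shared by every
    kernel; each kernel is a symmetric n_records x n_records array.
    """

    records: pd.DataFrame  # columns: hybrid, environment
    kernels: dict = field(default_factory=dict)
    model_id: str = "M1"
    multitrait: bool = False

    @property
    def n_records(self) -> int:
        return len(self.records)

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise KernelConfigurationError(f"unknown model id {self.model_id!r}")
        n = self.n_records
        for name, K in self.kernels.items():
            if K.shape != (n, n):
                raise KernelConfigurationError(
                    f"kernel {name!r} has shape {K.shape}, expected {(n, n)}"
                )


def _standardize_columns(M: np.ndarray) -> np.ndarray:
    """Center and scale columns to unit (population) variance."""
    Mc = M - M.mean(axis=0)
    sd = M.std(axis=0)  # population denominator: trace identity exact
    return Mc / sd


def genomic_relationship(markers: MarkerMatrix) -> pd.DataFrame:
    """Genomic relationship matrix G = Xc Xc' / p (VanRaden-style, scaled).

    Columns of the dosage matrix are centered and standardized before the
    cross-product, so ``trace(G) / n == 1`` exactly.  Monomorphic markers
    carry no relationship information and are dropped with a warning.

    Returns a hybrid-labelled DataFrame.
    """
    X = markers.X.astype(float)
    if markers.n_hybrids < 2:
        raise ValueError("need at least 2 hybrids")
    poly = X.std(axis=0) > 0
    if not poly.any():
        raise DegenerateMarkerError("all markers are monomorphic")
    if not poly.all():
        n_dropped = int((~poly).sum())
        warnings.warn(f"dropped {n_dropped} monomorphic markers", stacklevel=2)
        X = X[:, poly]
    Xc = _standardize_columns(X)
    p = Xc.shape[1]
    G = Xc @ Xc.T / p
    G = 0.5 * (G + G.T)
    return pd.DataFrame(G, index=markers.hybrids, columns=markers.hybrids)


def phenomic_relationship(scores: pd.DataFrame) -> np.ndarray:
    """Phenomic relationship kernel P = Rc Rc' / n_cols from FPCA scores.

    ``scores`` is a record-level score matrix (rows = hybrid x environment,
    columns = 2 FPCA scores per vegetation index; 72 columns for the full
    36-VI panel, hence the divisor 2 x 36).  Columns are centered and
    standardized first, so raw score scale differences across VIs do not
    dominate; constant columns are dropped with a warning and the divisor
    reduced accordingly.
    """
    R = np.asarray(scores, dtype=float)
    if R.shape[0] < 2:
        raise ValueError("need at least 2 rows of scores")
    keep = R.std(axis=0) > 0
    if not keep.any():
        raise ValueError("all score columns are constant")
    if not keep.all():
        warnings.warn(
            f"dropped {int((~keep).sum())} constant score columns; "
            f"divisor reduced to {int(keep.sum())}",
            stacklevel=2,
        )
        R = R[:, keep]
    Rc = _standardize_columns(R)
    P = Rc @ Rc.T / Rc.shape[1]
    return 0.5 * (P + P.T)


def environment_indicator(records: pd.DataFrame) -> np.ndarray:
    """Unscaled Z_E Z_E': 1 if two records share an environment, else 0."""
    env = np.asarray(records["environment"])
    return (env[:, None] == env[None, :]).astype(float)


def environment_kernel(records: pd.DataFrame) -> np.ndarray:
    """Environment kernel Z_E Z_E' / n_env (block constant 1/n_env)."""
    n_env = records["environment"].nunique()
    if n_env < 1:
        raise ValueError("need at least one environment")
    return environment_indicator(records) / n_env


def expand_to_records(G: pd.DataFrame, records: pd.DataFrame) -> np.ndarray:
    """Expand a hybrid-level kernel to record level: Zg G Zg'."""
    idx = G.index.get_indexer(records["hybrid"])
    if (idx < 0).any():
        missing = records.loc[idx < 0, "hybrid"].unique()
        raise KeyError(f"hybrids missing from kernel: {list(missing)[:5]}")
    Gv = G.to_numpy()
    return Gv[np.ix_(idx, idx)]


def interaction_kernel(
    main: np.ndarray, env_indicator: np.ndarray, divisor: float
) -> np.ndarray:
    """Hadamard (reaction-norm) interaction: (indicator o main) / divisor.

    ``main`` is the record-level main-effect kernel, ``env_indicator`` the
    unscaled same-environment 0/1 matrix.  Cross-environment record pairs
    are annihilated by the indicator.
    """
    main = np.asarray(main, dtype=float)
    env_indicator = np.asarray(env_indicator, dtype=float)
    if main.shape != env_indicator.shape:
        raise ValueError(
            f"shape mismatch: main {main.shape} vs indicator {env_indicator.shape}"
        )
    return main * env_indicator / divisor


def assemble_model(
    model_id: str,
    records: pd.DataFrame,
    G: pd.DataFrame | None = None,
    P1: np.ndarray | None = None,
    P2: np.ndarray | None = None,
) -> KernelSet:
    """Assemble the KernelSet for one of the six prediction models.

    M1/M6: E + g + gxE;  M2: E + P1 + P1xE;  M3: E + P2 + P2xE;
    M4: E + g + P1 + gxE + P1xE;  M5: E + g + P2 + gxE + P2xE.
    The g x E kernel divides the Hadamard product by n_env, the P x E
    kernel by n_env on top of the P kernel's own 2 x n_vi divisor.
    """
    if model_id not in MODEL_IDS:
        raise KernelConfigurationError(f"unknown model id {model_id!r}")
    records = records.reset_index(drop=True)
    n_env = records["environment"].nunique()
    ind = environment_indicator(records)
    available: dict[str, np.ndarray] = {"E": environment_kernel(records)}
    if G is not None:
        g_rec = expand_to_records(G, records)
        available["g"] = g_rec
        available["gxE"] = interaction_kernel(g_rec, ind, n_env)
    if P1 is not None:
        available["P1"] = np.asarray(P1, dtype=float)
        available["P1xE"] = interaction_kernel(P1, ind, n_env)
    if P2 is not None:
        available["P2"] = np.asarray(P2, dtype=float)
        available["P2xE"] = interaction_kernel(P2, ind, n_env)

    wanted = MODEL_KERNELS[model_id]
    missing = [k for k in wanted if k not in available]
    if missing:
        raise KernelConfigurationError(
            f"model {model_id} requires kernels {missing} which were not supplied"
        )
    kernels = {k: available[k] for k in wanted}
    return KernelSet(
        records=records,
        kernels=kernels,
        model_id=model_id,
        multitrait=(model_id == "M6"),
    )
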