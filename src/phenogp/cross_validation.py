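"""Prediction scenarios CV2 / CV1 / CV0 / CV00 with hybrid-level folds.

Folds partition hybrids (not records), so a hybrid's tested/untested
status is identical across environments within a repeat, and the same
fold plan serves all four scenarios:

* CV2 -- tested hybrids in observed environments (in-sample records);
* CV1 -- untested hybrids in observed environments;
* CV0 -- tested hybrids in an unobserved (left-out) environment;
* CV00 -- untested hybrids in an unobserved environment.

Training always uses only tested hybrids' records (untested hybrids'
responses are masked everywhere, so no genotype information leaks); in
the leave-one-environment scenarios the held-out environment's responses
are masked as well.  For the multitrait model the secondary trait stays
observed for every record in every scenario.  Prediction ability is the
Pearson correlation between predicted and observed (BLUE) values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kernels import KernelSet, MODEL_KERNELS, assemble_model
from .prediction import GibbsConfig, fit_multitrait, fit_rkhs

logger = logging.getLogger(__name__)

SCENARIOS = ("CV2", "CV1", "CV0", "CV00")


class UndefinedAbilityError(ValueError):
    """Prediction ability undefined (zero variance in one input)."""


@dataclass
class FoldPlan:
    """Hybrid-level k-fold assignments for a number of repeats."""

    k: int
    repeats: int
    seed: int
    assignment: pd.DataFrame   # hybrids x repeats, integer fold index

    @property
    def hybrids(self) -> list:
        return list(self.assignment.index)

    def fold_hybrids(self, repeat: int, fold: int) -> list:
        col = self.assignment.iloc[:, repeat]
        return list(col.index[col == fold])


def make_folds(hybrids, k: int = 5, repeats: int = 20, seed: int = 0) -> FoldPlan:
    """Uniform random hybrid partition into k folds, per repeat.

    Fold sizes differ by at most one (415 hybrids -> 4 x 83 training
    folds + 83 test; 220 -> 176/44).  Deterministic for a fixed seed.
    """
    hybrids = list(hybrids)
    n = len(hybrids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} hybrids, got {n}")
    rng = np.random.default_rng(seed)
    base = np.repeat(np.arange(k), np.diff(np.linspace(0, n, k + 1).astype(int)))
    cols = {}
    for r in range(repeats):
        perm = rng.permutation(n)
        assign = np.empty(n, dtype=int)
        assign[perm] = base
        cols[r] = assign
    return FoldPlan(
        k=k,
        repeats=repeats,
        seed=seed,
        assignment=pd.DataFrame(cols, index=pd.Index(hybrids, name="hybrid")),
    )


def prediction_ability(predicted, observed) -> float:
    """Pearson correlation between predicted and observed values."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if len(p) != len(o) or len(p) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if not (np.isfinite(p).all() and np.isfinite(o).all()):
        raise ValueError("inputs must be finite")
    if np.std(p) == 0 or np.std(o) == 0:
        raise UndefinedAbilityError("zero variance in predicted or observed values")
    return float(np.corrcoef(p, o)[0, 1])


@dataclass
class PredictionDataset:
    """Everything the CV scenarios need, at the record level.

    ``records`` fixes the (hybrid, environment) ordering; ``y`` holds the
    trait BLUEs aligned to it; kernel ingredients are supplied once and
    assembled per model.  ``secondary`` is the always-observed secondary
    trait (VARI FPCA1) for the multitrait model.
    """

    records: pd.DataFrame               # columns hybrid, environment
    y: np.ndarray
    trait: str
    G: pd.DataFrame | None = None       # hybrid-level genomic kernel
    P1: np.ndarray | None = None        # record-level phenomic kernels
    P2: np.ndarray | None = None
    secondary: np.ndarray | None = None

    def __post_init__(self):
        self.records = self.records.reset_index(drop=True)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.y) != len(self.records):
            raise ValueError("y length does not match records")

    @property
    def hybrids(self) -> list:
        return sorted(self.records["hybrid"].unique())

    @property
    def environments(self) -> list:
        return sorted(self.records["environment"].unique())

    def kernel_set(self, model_id: str) -> KernelSet:
        return assemble_model(
            model_id, self.records, G=self.G, P1=self.P1, P2=self.P2
        )


@dataclass
class CvResult:
    """Long-format prediction abilities plus Table-2-style summaries."""

    table: pd.DataFrame   # model_id, scenario, environment, repeat, fold, r

    def summary(self) -> pd.DataFrame:
        """Mean +/- sd of ability per model x scenario, pooled over
        repeats, folds and environments."""
        g = self.table.groupby(["model_id", "scenario"])["r"]
        out = g.agg(["mean", "std", "count"]).reset_index()
        return out.rename(columns={"std": "sd", "count": "n"})

    def pivot(self) -> pd.DataFrame:
        s = self.summary()
        s["cell"] = s.apply(lambda r: f"{r['mean']:.2f} ± {r['sd']:.2f}", axis=1)
        return s.pivot(index="model_id", columns="scenario", values="cell")


def _fit_and_predict(data, kernel_sets, model_id, y_masked, config):
    """One model fit on a masked response; returns record-level predictions."""
    ks = kernel_sets[model_id]
    if model_id == "M6":
        if data.secondary is None:
            raise ValueError("multitrait model needs a secondary trait")
        Y = np.column_stack([y_masked, data.secondary])
        fit = fit_multitrait(Y, ks, config)
    else:
        fit = fit_rkhs(y_masked, ks, config)
    return fit.fitted


def _ability_rows(data, preds, hybrid_sets, scenario, environments, model_id,
                  repeat, fold):
    env = data.records["environment"].to_numpy()
    hyb = data.records["hybrid"].to_numpy()
    rows = []
    for e in environments:
        mask = (env == e) & np.isin(hyb, hybrid_sets[scenario])
        if mask.sum() < 3:
            continue
        try:
            r = prediction_ability(preds[mask], data.y[mask])
        except UndefinedAbilityError:
            continue
        rows.append(
            dict(model_id=model_id, scenario=scenario, environment=e,
                 repeat=repeat, fold=fold, r=r)
        )
    return rows


def _check_models(models):
    unknown = [m for m in models if m not in MODEL_KERNELS]
    if unknown:
        raise ValueError(f"unknown models requested: {unknown}")


def run_within_env(
    data: PredictionDataset,
    models,
    foldplan: FoldPlan,
    config: GibbsConfig = GibbsConfig(),
) -> CvResult:
    """CV2/CV1: train on tested hybrids in all environments; score tested
    (CV2) and untested (CV1) hybrids per environment."""
    _check_models(models)
    kernel_sets = {m: data.kernel_set(m) for m in models}
    hyb = data.records["hybrid"].to_numpy()
    rows = []
    for rep in range(foldplan.repeats):
        for fold in range(foldplan.k):
            untested = set(foldplan.fold_hybrids(rep, fold))
            tested = [h for h in foldplan.hybrids if h not in untested]
            y_masked = np.where(np.isin(hyb, list(untested)), np.nan, data.y)
            for m_idx, model_id in enumerate(models):
                cfg = _reseed(config, rep, fold, m_idx, 0)
                preds = _fit_and_predict(data, kernel_sets, model_id, y_masked, cfg)
                sets = {"CV2": np.asarray(tested), "CV1": np.asarray(list(untested))}
                for scen in ("CV2", "CV1"):
                    rows.extend(
                        _ability_rows(data, preds, sets, scen,
                                      data.environments, model_id, rep, fold)
                    )
    return CvResult(table=pd.DataFrame(rows))


def run_leave_one_env(
    data: PredictionDataset,
    models,
    foldplan: FoldPlan,
    config: GibbsConfig = GibbsConfig(),
) -> CvResult:
    """CV0/CV00: leave one environment out; train on tested hybrids of the
    remaining environments; score tested (CV0) and untested (CV00)
    hybrids in the held-out environment."""
    _check_models(models)
    environments = data.environments
    if len(environments) < 2:
        raise ValueError("leave-one-environment-out needs >= 2 environments")
    kernel_sets = {m: data.kernel_set(m) for m in models}
    hyb = data.records["hybrid"].to_numpy()
    env = data.records["environment"].to_numpy()
    rows = []
    for rep in range(foldplan.repeats):
        for fold in range(foldplan.k):
            untested = set(foldplan.fold_hybrids(rep, fold))
            for e_idx, held in enumerate(environments):
                y_masked = np.where(
                    np.isin(hyb, list(untested)) | (env == held), np.nan, data.y
                )
                for m_idx, model_id in enumerate(models):
                    cfg = _reseed(config, rep, fold, m_idx, 1 + e_idx)
                    preds = _fit_and_predict(
                        data, kernel_sets, model_id, y_masked, cfg
                    )
                    tested = [h for h in foldplan.hybrids if h not in untested]
                    sets = {"CV0": np.asarray(tested),
                            "CV00": np.asarray(list(untested))}
                    for scen in ("CV0", "CV00"):
                        rows.extend(
                            _ability_rows(data, preds, sets, scen, [held],
                                          model_id, rep, fold)
                        )
    return CvResult(table=pd.DataFrame(rows))


def _reseed(config: GibbsConfig, rep: int, fold: int, m_idx: int, extra: int) -> GibbsConfig:
    """Distinct, reproducible chain seed per (repeat, fold, model, env)."""
    mix = np.random.SeedSequence(
        [config.seed, rep, fold, m_idx, extra]
    ).generate_state(1)[0] % (2**31)
    from dataclasses import replace

    return replace(config, seed=int(mix))
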