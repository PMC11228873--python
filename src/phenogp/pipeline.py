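"""End-to-end pipeline driver: simulate -> stage-1 mixed models ->
temporal correlations -> FPCA -> kernels -> cross-validated prediction.

Each stage reads and writes the file layouts in :mod:`phenogp.io`, so the
stages can be run separately (as the CLI does) or chained in memory.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fpca as fpca_mod
from . import io as io_mod
from . import kernels as kernels_mod
from . import mixed_models as mm
from . import temporal as temporal_mod
from .cross_validation import (
    CvResult,
    FoldPlan,
    PredictionDataset,
    make_folds,
    run_leave_one_env,
    run_within_env,
)
from .prediction import GibbsConfig
from .simulate import SyntheticTrial, preset_config, simulate_trial

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    preset: str = "demo"
    seed: int = 0
    n_markers: int = 1000
    trait: str = "gy"
    window: str = "until_flowering"
    models: tuple = ("M1", "M2", "M3", "M4", "M5", "M6")
    cv_k: int = 5
    cv_repeats: int = 5        # fast profile; the full design uses 20
    gibbs_iter: int = 2000
    gibbs_burn_in: int = 500
    gibbs_thin: int = 2
    reml_tol: float = 1e-6
    reml_max_iter: int = 200
    out_dir: str = "phenogp-out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def gibbs(self) -> GibbsConfig:
        return GibbsConfig(
            n_iter=self.gibbs_iter,
            burn_in=self.gibbs_burn_in,
            thin=self.gibbs_thin,
            seed=self.seed,
        )


def _timed(stage):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            logger.info("stage %s finished in %.1f s", stage, time.perf_counter() - t0)
            return out
        return inner
    return wrap


@_timed("simulate")
def stage_simulate(config: PipelineConfig, out_dir: Path) -> SyntheticTrial:
    trial = simulate_trial(
        preset_config(config.preset, n_markers=config.n_markers, seed=config.seed)
    )
    out_dir.mkdir(parents=True, exist_ok=True)
    io_mod.write_plot_table(trial.plots, out_dir / "plots.csv")
    io_mod.write_vi_table(trial.vi_obs, out_dir / "vi_observations.csv")
    io_mod.write_genotypes_numeric(
        trial.markers, out_dir / "GAPIT.Genotype.Numerical.txt"
    )
    io_mod.write_truth_tables(trial.truth, out_dir)
    logger.info(
        "simulated %d plots, %d VI records, %d hybrids",
        len(trial.plots), len(trial.vi_obs), trial.config.n_hybrids,
    )
    return trial


@_timed("stage1")
def stage_stage1(config: PipelineConfig, plots, vi_obs, out_dir: Path):
    """Per-environment BLUEs, heritabilities and temporal BLUPs."""
    out_dir.mkdir(parents=True, exist_ok=True)
    environments = sorted(plots["environment"].unique())
    vi_names = sorted(vi_obs["vi_name"].unique())
    blues, herit, blup_frames = [], [], []
    for env in environments:
        for trait in ("gy", "pht"):
            blues.append(
                mm.fit_blues(plots, trait, env,
                             tol=config.reml_tol, max_iter=config.reml_max_iter)
            )
            herit.append(
                dict(environment=env, trait=trait,
                     heritability=mm.estimate_heritability(
                         plots, trait, env,
                         tol=config.reml_tol, max_iter=config.reml_max_iter))
            )
        table, _ = mm.fit_temporal_blups_all(
            vi_obs, vi_names, env,
            tol=config.reml_tol, max_iter=config.reml_max_iter,
        )
        blup_frames.append(table)
        io_mod.write_temporal_blups(table, out_dir / f"FP.{env}.csv", vi_names)
    blue_table = pd.concat(blues, ignore_index=True)
    blups = pd.concat(blup_frames, ignore_index=True)
    for trait, fname in (("gy", "Yield.csv"), ("pht", "PHT.csv")):
        io_mod.write_blue_table(
            blue_table.loc[blue_table["trait"] == trait], out_dir / fname
        )
    pd.DataFrame(herit).to_csv(out_dir / "heritability.csv", index=False)
    return blue_table, blups, pd.DataFrame(herit)


@_timed("correlate")
def stage_correlate(blups, blues, out_dir: Path):
    """Temporal correlations of every VI with each trait per environment."""
    out_dir.mkdir(parents=True, exist_ok=True)
    correlations = []
    for env in sorted(blups["environment"].unique()):
        for trait in sorted(blues["trait"].unique()):
            for vi in sorted(blups["vi_name"].unique()):
                correlations.append(
                    temporal_mod.temporal_correlation(blups, blues, vi, trait, env)
                )
    tidy = pd.concat([c.to_frame() for c in correlations], ignore_index=True)
    tidy.to_csv(out_dir / "temporal_correlations.csv", index=False)
    summary = temporal_mod.correlation_summary(correlations)
    summary.to_csv(out_dir / "temporal_correlations.summary.csv", index=False)
    return correlations, summary


@_timed("fpca")
def stage_fpca(blups, flowering_daps: dict, out_dir: Path):
    """FPCA per VI x environment x window; writes merged score matrices."""
    out_dir.mkdir(parents=True, exist_ok=True)
    environments = sorted(blups["environment"].unique())
    models = {}
    scores = {}
    for window, suffix in (("until_flowering", "until_flowering"),
                           ("full", "full_flights")):
        per_env = []
        for env in environments:
            env_models = fpca_mod.fit_fpca_environment(
                blups, env, flowering_daps[env], window=window
            )
            models[(env, window)] = env_models
            sm = fpca_mod.build_score_matrix(env_models)
            io_mod.write_score_matrix(sm, out_dir / f"FP.{env}.FPCA.{suffix}.csv")
            per_env.append(sm)
        scores[window] = fpca_mod.merge_environments(per_env)
    return models, scores


@_timed("kernels")
def stage_kernels(markers, scores: dict, blues, trait: str, out_dir: Path | None = None):
    """Build the prediction dataset: records, y, G, P1, P2, secondary."""
    sub = blues.loc[blues["trait"] == trait]
    records = (
        scores["until_flowering"].index.to_frame(index=False)
        .sort_values(["environment", "hybrid"], kind="stable")
        .reset_index(drop=True)
    )
    key = pd.MultiIndex.from_frame(records[["hybrid", "environment"]])
    y = (
        sub.set_index(["hybrid", "environment"])["blue"]
        .reindex(key)
        .to_numpy(float)
    )
    G = kernels_mod.genomic_relationship(markers)
    P1 = kernels_mod.phenomic_relationship(scores["until_flowering"].loc[key])
    P2 = kernels_mod.phenomic_relationship(scores["full"].loc[key])
    secondary = scores["until_flowering"].loc[key, "VARI_FPCA1"].to_numpy(float) \
        if "VARI_FPCA1" in scores["until_flowering"].columns else None
    data = PredictionDataset(
        records=records, y=y, trait=trait, G=G, P1=P1, P2=P2, secondary=secondary
    )
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        io_mod.write_kernel(P1, records, out_dir / "kernel.P1.csv")
        G_rec = kernels_mod.expand_to_records(G, records)
        io_mod.write_kernel(G_rec, records, out_dir / "kernel.g.csv")
    return data


@_timed("fit")
def stage_fit(config: PipelineConfig, data: PredictionDataset, out_dir: Path) -> dict:
    """Fit the configured models on the full data; write posterior
    summaries (term, posterior mean, sd, effective n) and predictions."""
    from .prediction import fit_multitrait, fit_rkhs

    out_dir.mkdir(parents=True, exist_ok=True)
    gibbs = config.gibbs()
    fits = {}
    for model_id in config.models:
        ks = data.kernel_set(model_id)
        if model_id == "M6":
            if data.secondary is None:
                raise ValueError("multitrait model needs a secondary trait")
            Y = np.column_stack([data.y, data.secondary])
            fit = fit_multitrait(Y, ks, gibbs)
        else:
            fit = fit_rkhs(data.y, ks, gibbs)
        fits[model_id] = fit
        summary = pd.DataFrame(
            {
                "term": list(fit.variance_components),
                "posterior_mean": list(fit.variance_components.values()),
                "posterior_sd": [fit.variance_sd.get(t, np.nan)
                                 for t in fit.variance_components],
                "effective_n": [fit.ess.get(t, np.nan)
                                for t in fit.variance_components],
            }
        )
        summary.to_csv(out_dir / f"fit.{model_id}.summary.csv", index=False)
        preds = data.records.assign(observed=data.y, predicted=fit.fitted)
        preds.to_csv(out_dir / f"fit.{model_id}.predictions.csv", index=False)
    return fits


@_timed("cv")
def stage_cv(config: PipelineConfig, data: PredictionDataset, out_dir: Path) -> CvResult:
    out_dir.mkdir(parents=True, exist_ok=True)
    plan = make_folds(data.hybrids, k=config.cv_k, repeats=config.cv_repeats,
                      seed=config.seed)
    gibbs = config.gibbs()
    within = run_within_env(data, list(config.models), plan, gibbs)
    loo = run_leave_one_env(data, list(config.models), plan, gibbs)
    result = CvResult(table=pd.concat([within.table, loo.table], ignore_index=True))
    result.table.to_csv(out_dir / "cv_results.csv", index=False)
    result.summary().to_csv(out_dir / "cv_summary.csv", index=False)
    return result


def run_all(config: PipelineConfig) -> CvResult:
    """Run the whole pipeline from a preset simulation; returns CV results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io_mod.write_manifest(out / "manifest.json", config.to_dict(), config.seed)
    trial = stage_simulate(config, out)
    blues, blups, _ = stage_stage1(config, trial.plots, trial.vi_obs, out)
    stage_correlate(blups, blues, out)
    flowering = {e.name: e.flowering_start_dap for e in trial.config.environments}
    _, scores = stage_fpca(blups, flowering, out)
    data = stage_kernels(trial.markers, scores, blues, config.trait, out)
    # write the multitrait input table alongside the kernels
    sec = scores["until_flowering"]["VARI_FPCA1"] \
        if "VARI_FPCA1" in scores["until_flowering"].columns else None
    if sec is not None:
        fname = "Yield.for.multitrait.csv" if config.trait == "gy" else "PHT.for.multitrait.csv"
        io_mod.write_multitrait_table(blues, sec, config.trait, out / fname)
    return stage_cv(config, data, out)
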