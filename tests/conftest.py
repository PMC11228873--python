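"""Shared fixtures: small synthetic trials and kernel inputs.

Everything is generated programmatically with fixed seeds; no data files.
"""

import numpy as np
import pandas as pd
import pytest

import phenogp as pg


@pytest.fixture(scope="session")
def small_trial():
    """A 60-hybrid, 2-environment trial with 4 VIs (fast, reused widely)."""
    cfg = pg.preset_config(
        "demo",
        seed=11,
        n_hybrids=60,
        n_markers=300,
        vi_names=("VARI", "RCC", "GCC", "ExG"),
        environments=(
            pg.EnvironmentSpec("envA", (20, 30, 40, 55, 70, 85), 55, 12, 10),
            pg.EnvironmentSpec("envB", (25, 35, 45, 60, 75), 60, 12, 10),
        ),
    )
    return pg.simulate_trial(cfg)


@pytest.fixture(scope="session")
def small_stage1(small_trial):
    """BLUEs and temporal BLUPs of the small trial, both environments."""
    from phenogp import mixed_models as mm

    blues = pd.concat(
        [
            mm.fit_blues(small_trial.plots, trait, env)
            for env in ("envA", "envB")
            for trait in ("gy", "pht")
        ],
        ignore_index=True,
    )
    blups = pd.concat(
        [
            mm.fit_temporal_blups_all(
                small_trial.vi_obs, list(small_trial.config.vi_names), env
            )[0]
            for env in ("envA", "envB")
        ],
        ignore_index=True,
    )
    return blues, blups


@pytest.fixture(scope="session")
def small_scores(small_trial, small_stage1):
    """Merged FPCA score matrices (both windows) for the small trial."""
    from phenogp import fpca as fp

    _, blups = small_stage1
    flowering = {e.name: e.flowering_start_dap for e in small_trial.config.environments}
    out = {}
    for window in ("until_flowering", "full"):
        mats = []
        for env in ("envA", "envB"):
            models = fp.fit_fpca_environment(blups, env, flowering[env], window=window)
            mats.append(fp.build_score_matrix(models))
        out[window] = fp.merge_environments(mats)
    return out


@pytest.fixture(scope="session")
def small_dataset(small_trial, small_stage1, small_scores):
    """PredictionDataset for the small trial (grain yield)."""
    from phenogp.kernels import genomic_relationship, phenomic_relationship
    from phenogp.cross_validation import PredictionDataset

    blues, _ = small_stage1
    sub = blues.loc[blues["trait"] == "gy"]
    records = (
        small_scores["until_flowering"].index.to_frame(index=False)
        .sort_values(["environment", "hybrid"], kind="stable")
        .reset_index(drop=True)
    )
    key = pd.MultiIndex.from_frame(records[["hybrid", "environment"]])
    y = sub.set_index(["hybrid", "environment"])["blue"].reindex(key).to_numpy(float)
    return PredictionDataset(
        records=records,
        y=y,
        trait="gy",
        G=genomic_relationship(small_trial.markers),
        P1=phenomic_relationship(small_scores["until_flowering"].loc[key]),
        P2=phenomic_relationship(small_scores["full"].loc[key]),
        secondary=small_scores["until_flowering"].loc[key, "VARI_FPCA1"].to_numpy(float),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
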