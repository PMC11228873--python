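"""Mixed-model engine: oracle equivalence, BLUEs, heritability, BLUPs."""

import numpy as np
import pandas as pd
import pytest

import phenogp as pg
from phenogp import mixed_models as mm


def dense_mme_oracle(df, response, fixed, random, components, residual):
    """Independent dense Henderson-MME solve at given variances.

    Builds X and Z with pandas dummies and solves the full mixed-model
    equations directly -- no shared code with the package's absorbed path.
    """
    df = df.loc[df[response].notna()].reset_index(drop=True)
    y = df[response].to_numpy(float)
    X = [np.ones(len(df))]
    for term in fixed:
        d = pd.get_dummies(df[term].astype(str), drop_first=True, dtype=float)
        X.extend(d[c].to_numpy() for c in d.columns)
    X = np.column_stack(X)
    Zs, lams = [], []
    for term in random:
        col = (
            df[list(term)].astype(str).agg("\x1f".join, axis=1)
            if isinstance(term, tuple) else df[term].astype(str)
        )
        Z = pd.get_dummies(col, dtype=float).to_numpy()
        Zs.append(Z)
        lams.append(residual / components[term if isinstance(term, str) else ":".join(term)])
    W = np.hstack([X] + Zs)
    M = W.T @ W
    off = X.shape[1]
    for Z, lam in zip(Zs, lams):
        q = Z.shape[1]
        M[off:off + q, off:off + q] += lam * np.eye(q)
        off += q
    sol = np.linalg.solve(M, W.T @ y)
    return sol[: X.shape[1]], sol[X.shape[1]:]


def explicit_reml_loglik(y, X, Z, sig_u, sig_e):
    """Textbook REML log-likelihood via the dense covariance matrix."""
    n = len(y)
    V = sig_e * np.eye(n) + sig_u * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return -0.5 * (
        np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtViX)[1]
        + r @ Vi @ r
        + (n - X.shape[1]) * np.log(2 * np.pi)
    )


@pytest.fixture()
def crossed_data(rng):
    n = 48
    df = pd.DataFrame(
        {
            "a": rng.choice([f"a{i}" for i in range(6)], n),
            "b": rng.choice([f"b{i}" for i in range(4)], n),
            "f": rng.choice(["u", "v", "w"], n),
        }
    )
    eff_a = dict(zip([f"a{i}" for i in range(6)], rng.normal(0, 1, 6)))
    eff_b = dict(zip([f"b{i}" for i in range(4)], rng.normal(0, 0.8, 4)))
    eff_f = {"u": 0.0, "v": 1.0, "w": -0.5}
    df["y"] = (
        3.0 + df.a.map(eff_a) + df.b.map(eff_b) + df.f.map(eff_f)
        + rng.normal(0, 0.5, n)
    )
    return df


class TestSolveReml:
    def test_constant_response_degenerates_cleanly(self, crossed_data):
        df = crossed_data.assign(y=4.2)
        res = mm.solve_reml(df, "y", fixed=[], random=["a", "b"])
        vc = res.variance_components
        assert vc.residual == 0.0
        assert all(v == 0.0 for v in vc.components.values())
        assert res.fixed_effects["(Intercept)"] == pytest.approx(4.2)
        assert all((s == 0).all() for s in res.random_effects.values())

    def test_solutions_match_dense_henderson_oracle(self, crossed_data):
        res = mm.solve_reml(crossed_data, "y", fixed=["f"], random=["a", "b"],
                            tol=1e-10)
        vc = res.variance_components
        beta, u = dense_mme_oracle(
            crossed_data, "y", ["f"], ["a", "b"], vc.components, vc.residual
        )
        assert np.allclose(res.fixed_effects.to_numpy(), beta, atol=1e-6)
        got_u = np.concatenate(
            [res.random_effects["a"].to_numpy(), res.random_effects["b"].to_numpy()]
        )
        assert np.allclose(got_u, u, atol=1e-6)

    def test_reml_criterion_beats_grid_oracle(self, rng):
        # 12-observation, one random factor: the returned variances must
        # score at least as well as an exhaustive grid on the explicit
        # restricted likelihood
        df = pd.DataFrame({"g": list("AABBCCDDEEFF")})
        eff = dict(zip("ABCDEF", rng.normal(0, 1, 6)))
        df["y"] = df.g.map(eff) + rng.normal(0, 0.7, 12)
        res = mm.solve_reml(df, "y", fixed=[], random=["g"], tol=1e-10)
        X = np.ones((12, 1))
        Z = pd.get_dummies(df["g"], dtype=float).to_numpy()
        y = df["y"].to_numpy()
        vc = res.variance_components
        ours = explicit_reml_loglik(y, X, Z, vc.components["g"], vc.residual)
        assert ours == pytest.approx(res.loglik, abs=1e-8)
        grid = np.linspace(0.01, 5.0, 60)
        best = max(
            explicit_reml_loglik(y, X, Z, su, se) for su in grid for se in grid
        )
        assert ours >= best - 1e-6

    def test_huge_shrinkage_recovers_ols(self, crossed_data):
        # random variances pinned at ~0 (lambda -> inf): fixed solutions
        # collapse onto ordinary least squares
        design = mm.MixedDesign(crossed_data, ["f"], ["a", "b"])
        y = crossed_data["y"].to_numpy(float)
        sol, _, _ = design.solve(design.rhs(y), np.array([1e12, 1e12]),
                                 need_traces=False)
        beta_ols, *_ = np.linalg.lstsq(design.X, y, rcond=None)
        assert np.allclose(sol[: design.p], beta_ols, atol=1e-6)

    def test_rank_deficient_fixed_design_raises(self, crossed_data):
        df = crossed_data.assign(f2=crossed_data["f"])
        with pytest.raises(mm.RankDeficiencyError):
            mm.solve_reml(df, "y", fixed=["f", "f2"], random=["a"])

    def test_variances_never_negative(self, small_trial):
        for env in ("envA", "envB"):
            sub = small_trial.plots[small_trial.plots.environment == env]
            res = mm.solve_reml(sub, "gy", [], ["hybrid", "range", "row", "rep"])
            vc = res.variance_components
            assert vc.residual >= 0
            assert all(v >= 0 for v in vc.components.values())


class TestFitBlues:
    def test_noise_free_balanced_blue_is_hybrid_mean(self):
        hybrids = [f"H{i}" for i in range(6)]
        rows = []
        for rep in (1, 2):
            for i, h in enumerate(hybrids):
                rows.append(
                    dict(hybrid=h, environment="E", range=1 + i % 3,
                         row=1 + i // 3, rep=rep, gy=5.0 + i, pht=np.nan)
                )
        plots = pd.DataFrame(rows)
        blues = pg.fit_blues(plots, "gy", "E")
        means = plots.groupby("hybrid")["gy"].mean()
        assert np.allclose(
            blues.set_index("hybrid")["blue"].loc[means.index], means, atol=1e-8
        )

    def test_one_blue_per_hybrid(self, small_trial, small_stage1):
        blues, _ = small_stage1
        sub = blues.query("environment == 'envA' and trait == 'gy'")
        assert len(sub) == small_trial.config.n_hybrids
        assert sub["hybrid"].is_unique

    def test_high_heritability_blues_track_truth(self):
        cfg = pg.preset_config(
            "demo", seed=4, n_hybrids=150, n_markers=400,
            heritability_gy=0.9, gxe_fraction=0.0,
            environments=(pg.EnvironmentSpec("envA", (20, 40, 60), 40, 18, 17),),
        )
        trial = pg.simulate_trial(cfg)
        blues = pg.fit_blues(trial.plots, "gy", "envA").set_index("hybrid")["blue"]
        truth = trial.truth.genetic["gy"]
        r = np.corrcoef(blues.loc[truth.index], truth)[0, 1]
        assert r > 0.9

    def test_all_missing_raises(self, small_trial):
        plots = small_trial.plots.assign(gy=np.nan)
        with pytest.raises(mm.EmptyInputError):
            pg.fit_blues(plots, "gy", "envA")


class TestHeritability:
    def test_zero_residual_gives_one(self):
        cfg = pg.preset_config(
            "demo", seed=2, n_hybrids=30, n_markers=100,
            heritability_gy=1.0, spatial_fraction=0.0,
        )
        trial = pg.simulate_trial(cfg)
        assert pg.estimate_heritability(trial.plots, "gy", "envA") > 0.999

    def test_zero_genetic_variance_near_zero(self):
        vals = []
        for seed in range(10):
            cfg = pg.preset_config(
                "demo", seed=seed, n_hybrids=800, n_markers=100,
                heritability_gy=0.0,
                environments=(pg.EnvironmentSpec("envA", (20, 40), 30, 40, 40),),
            )
            trial = pg.simulate_trial(cfg)
            vals.append(pg.estimate_heritability(trial.plots, "gy", "envA"))
        assert np.mean(vals) <= 0.05

    def test_single_rep_rejected(self, small_trial):
        single = small_trial.plots[small_trial.plots["rep"] == 1]
        with pytest.raises(ValueError, match="replications"):
            pg.estimate_heritability(single, "gy", "envA")


class TestTemporalBlups:
    def test_complete_grid_and_flightwise_centering(self, small_trial, small_stage1):
        _, blups = small_stage1
        cfg = small_trial.config
        env = cfg.environments[0]
        sub = blups[blups.environment == "envA"]
        assert len(sub) == cfg.n_hybrids * env.n_flights * len(cfg.vi_names)
        # shrunken predictions are centered across hybrids at every
        # flight: the per-flight mean is negligible against their spread
        g = sub.groupby(["vi_name", "flight_dap"])["blup"]
        ratio = (g.mean().abs() / g.std()).max()
        assert ratio < 0.02

    def test_null_trajectory_variance_shrinks_to_zero(self):
        # no hybrid-level trajectory variation at all: every temporal
        # prediction must shrink to (near) zero relative to the noise
        cfg = pg.preset_config(
            "demo", seed=6, n_hybrids=40, n_markers=100,
            vi_amplitude_cv=0.0, vi_timing_sd=0.0, vi_names=("VARI", "GCC"),
            environments=(pg.EnvironmentSpec("envA", (20, 35, 50, 70), 50, 10, 8),),
        )
        trial = pg.simulate_trial(cfg)
        noise_sd = trial.vi_obs.groupby(["vi_name", "flight_dap"])["value"].std().max()
        table, _ = mm.fit_temporal_blups_all(trial.vi_obs, ["VARI", "GCC"], "envA")
        assert table["blup"].abs().max() < 0.1 * noise_sd

    def test_unknown_vi_raises(self, small_trial):
        with pytest.raises(mm.UnknownViError):
            pg.fit_temporal_blups(small_trial.vi_obs, "NOPE", "envA")

    def test_blup_shrinks_below_raw_cell_deviation(self, small_trial, small_stage1):
        _, blups = small_stage1
        vi, env = "VARI", "envA"
        obs = small_trial.vi_obs.query("vi_name == @vi and environment == @env")
        cell = obs.groupby(["hybrid", "flight_dap"])["value"].mean().unstack()
        raw_dev = cell.sub(cell.mean(axis=0), axis=1)   # centered across hybrids
        got = blups.query("vi_name == @vi and environment == @env").pivot(
            index="hybrid", columns="flight_dap", values="blup"
        )
        raw_sd = float(raw_dev.stack().std())
        got_sd = float(got.stack().std())
        assert got_sd <= raw_sd + 1e-12
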