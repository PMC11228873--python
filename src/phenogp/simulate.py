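"""Synthetic multi-environment maize trial generator.

Emulates the data structure of a two-population hybrid trial phenotyped by
repeated drone flights: an RCBD field layout with 2 replications per
environment, end-of-season grain yield (t/ha) and plant height (cm), and
per-plot vegetation-index (VI) values at every flight, on flight-date
(days-after-planting, DAP) grids that differ between environments.

The generative model, per population:

* marker dosages 0/1/2 with uniform minor-allele frequencies;
* additive genetic values built from the markers (so genomic kernels carry
  real signal), plus per-environment genetic deviations (G x E);
* plot phenotype = environment mean + genetic value + G x E deviation +
  independent range / row / rep effects + residual, with the residual
  variance back-solved so the entry-mean heritability
  sigma2_H / (sigma2_H + sigma2_e / n_reps) hits its target;
* VI trajectories follow a double-logistic curve in DAP (green-up rise,
  plateau near flowering, senescence decline); hybrid genetic variation
  enters the amplitude and the green-up inflection, and each VI's
  amplitude score is constructed with a programmed correlation to the
  yield genetic value (largest for VARI, largest negative for RCC).

Ground truth (genetic values, G x E deviations, per-VI trajectory scores
and programmed correlations) is recorded so that estimators downstream can
be checked by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kernels import MarkerMatrix

#: 33 visible-band vegetation indices plus the raw R, G, B bands.
DEFAULT_VI_NAMES: tuple = (
    "VARI", "RCC", "BCC", "BI", "BIM", "CIVE", "COM1", "COM2", "ExG",
    "ExGR", "ExR", "GCC", "GLAI", "GLI", "GRVI", "HI", "HUE", "IKAW",
    "INT", "MExG", "MGRVI", "NDI", "NGBDI", "NGRDI", "RGBVI", "SAT",
    "SCI", "SHP", "SI", "TGI", "VDVI", "VEG", "WI",
    "R", "G", "B",
)


@dataclass(frozen=True)
class EnvironmentSpec:
    """Design of one environment (year/trial): flights and field grid."""

    name: str
    flight_daps: tuple
    flowering_start_dap: int
    n_ranges: int
    n_rows: int

    def __post_init__(self):
        daps = tuple(int(d) for d in self.flight_daps)
        object.__setattr__(self, "flight_daps", daps)
        if any(b <= a for a, b in zip(daps, daps[1:])):
            raise ValueError("flight_daps must be strictly increasing")
        if not daps:
            raise ValueError("need at least one flight")
        if not (daps[0] <= self.flowering_start_dap <= daps[-1]):
            raise ValueError("flowering_start_dap must lie within the flight window")

    @property
    def n_flights(self) -> int:
        return len(self.flight_daps)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of one synthetic trial."""

    n_hybrids: int
    n_markers: int
    environments: tuple
    n_reps: int = 2
    vi_names: tuple = DEFAULT_VI_NAMES
    heritability_gy: float = 0.7
    heritability_pht: float = 0.8
    vi_genetic_corr: float = 0.6
    seed: int = 0
    # simulator-only knobs (no study-stated values exist for these)
    gxe_fraction: float = 0.3      # G x E variance / main genetic variance
    spatial_fraction: float = 0.25  # range/row/rep variance / residual variance
    genetic_sd_gy: float = 0.8      # t/ha
    genetic_sd_pht: float = 10.0    # cm
    mean_gy: float = 10.0           # t/ha
    mean_pht: float = 220.0         # cm
    vi_amplitude_cv: float = 0.12   # genetic CV of trajectory amplitude
    vi_timing_sd: float = 0.5       # hybrid sd of green-up inflection, days
    vi_noise_frac: float = 0.06     # VI plot residual sd / trajectory amplitude
    maf_range: tuple = (0.05, 0.5)

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        for h in (self.heritability_gy, self.heritability_pht):
            if not 0.0 <= h <= 1.0:
                raise ValueError("heritabilities must be in [0, 1]")
        if not -1.0 <= self.vi_genetic_corr <= 1.0:
            raise ValueError("vi_genetic_corr must be in [-1, 1]")
        object.__setattr__(self, "environments", tuple(self.environments))
        object.__setattr__(self, "vi_names", tuple(self.vi_names))
        for env in self.environments:
            if env.n_ranges * env.n_rows < self.n_hybrids * self.n_reps:
                raise ValueError(
                    f"grid of environment {env.name!r} too small for "
                    f"{self.n_hybrids} hybrids x {self.n_reps} reps"
                )


@dataclass(frozen=True)
class TrajectoryParams:
    """Double-logistic VI trajectory parameters.

    value(t) = baseline + amplitude * [ L(r_green (t - t_green))
                                        - drop * L(r_sen (t - t_sen)) ]
    with L the standard logistic; ``drop`` in [0, 1] is the fraction of the
    amplitude lost to senescence (0 disables the decline).
    """

    baseline: float
    amplitude: float
    t_green: float
    r_green: float
    t_sen: float
    r_sen: float
    drop: float = 0.6


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def vi_trajectory(params: TrajectoryParams, dap) -> np.ndarray:
    """Evaluate a double-logistic VI trajectory at DAP(s).

    Rises through vegetative growth, plateaus near flowering and declines
    during senescence; the maximum lies between the two inflection points
    when the senescence component is active.
    """
    t = np.asarray(dap, dtype=float)
    if np.any(t < 0):
        raise ValueError("dap must be non-negative")
    up = _logistic(params.r_green * (t - params.t_green))
    down = _logistic(params.r_sen * (t - params.t_sen))
    return params.baseline + params.amplitude * (up - params.drop * down)


def vi_trajectory_derivative(params: TrajectoryParams, dap) -> np.ndarray:
    """Closed-form d/dt of :func:`vi_trajectory` (used for shape checks)."""
    t = np.asarray(dap, dtype=float)
    up = _logistic(params.r_green * (t - params.t_green))
    down = _logistic(params.r_sen * (t - params.t_sen))
    return params.amplitude * (
        params.r_green * up * (1 - up)
        - params.drop * params.r_sen * down * (1 - down)
    )


@dataclass
class TrialTruth:
    """Ground truth of one synthetic trial (simulator-only output)."""

    genetic: pd.DataFrame          # hybrid x {gy, pht}: main genetic values
    gxe: pd.DataFrame              # (hybrid, environment) x {gy, pht}
    vi_genetic: pd.DataFrame       # hybrid x vi_name: amplitude scores
    vi_loadings: pd.Series         # vi_name -> programmed corr with gy value


@dataclass
class SyntheticTrial:
    """A complete simulated multi-environment trial."""

    config: SimulationConfig
    markers: MarkerMatrix
    plots: pd.DataFrame    # hybrid, environment, range, row, rep, gy, pht
    vi_obs: pd.DataFrame   # hybrid, environment, flight_dap, vi_name, range, row, rep, value
    truth: TrialTruth

    @property
    def hybrids(self) -> list:
        return list(self.markers.hybrids)


def simulate_markers(
    n_hybrids: int,
    n_markers: int,
    maf_range=(0.05, 0.5),
    seed=None,
) -> MarkerMatrix:
    """Simulate biallelic dosage genotypes with uniform allele frequencies.

    Each marker's allele frequency is drawn uniformly from ``maf_range``
    and dosages are Binomial(2, f) per hybrid.  Markers that come out
    monomorphic are redrawn (they carry no relationship information).
    """
    if n_hybrids < 2 or n_markers < 2:
        raise ValueError("n_hybrids and n_markers must both be >= 2")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be within (0, 0.5]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    freqs = rng.uniform(lo, hi, size=n_markers)
    X = rng.binomial(2, freqs, size=(n_hybrids, n_markers))
    for _ in range(100):
        mono = X.std(axis=0) == 0
        if not mono.any():
            break
        k = int(mono.sum())
        X[:, mono] = rng.binomial(2, freqs[mono], size=(n_hybrids, k))
    hybrids = [f"H{i + 1:04d}" for i in range(n_hybrids)]
    markers = [f"M{j + 1:06d}" for j in range(n_markers)]
    return MarkerMatrix(hybrids=hybrids, markers=markers, X=X)


def _genetic_scores(Xc: np.ndarray, rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """Standardized marker-driven genetic scores (columns ~ mean 0, var 1)."""
    beta = rng.normal(size=(Xc.shape[1], n))
    u = Xc @ beta
    u = u - u.mean(axis=0)
    sd = u.std(axis=0)
    sd[sd == 0] = 1.0
    return u / sd


def _rcbd_layout(
    env: EnvironmentSpec, hybrids: list, n_reps: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Assign hybrids to field cells, one contiguous block per replication."""
    n = len(hybrids)
    cells = [
        (r + 1, c + 1) for r in range(env.n_ranges) for c in range(env.n_rows)
    ]
    recs = []
    for rep in range(1, n_reps + 1):
        block = cells[(rep - 1) * n: rep * n]
        order = rng.permutation(n)
        for (rg, rw), h_idx in zip(block, order):
            recs.append((hybrids[h_idx], env.name, rg, rw, rep))
    return pd.DataFrame(recs, columns=["hybrid", "environment", "range", "row", "rep"])


def simulate_trial(config: SimulationConfig) -> SyntheticTrial:
    """Simulate a complete trial under ``config`` (seeded, reproducible)."""
    rng = np.random.default_rng(config.seed)
    markers = simulate_markers(
        config.n_hybrids, config.n_markers, config.maf_range, seed=rng
    )
    hybrids = markers.hybrids
    X = markers.X.astype(float)
    Xc = (X - X.mean(axis=0))
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xc = Xc / sd

    n_h = config.n_hybrids
    envs = config.environments
    gxe_sd = np.sqrt(config.gxe_fraction)

    # main genetic values (unit variance scores, scaled to trait units)
    u = _genetic_scores(Xc, rng, 2)
    u_gy = u[:, 0] * config.genetic_sd_gy
    u_pht = u[:, 1] * config.genetic_sd_pht
    genetic = pd.DataFrame({"gy": u_gy, "pht": u_pht}, index=pd.Index(hybrids, name="hybrid"))

    # per-environment genetic deviations (marker-driven, independent scores)
    gxe_rows = []
    gxe_scores = {}
    for env in envs:
        d = _genetic_scores(Xc, rng, 2)
        d_gy = d[:, 0] * gxe_sd * config.genetic_sd_gy
        d_pht = d[:, 1] * gxe_sd * config.genetic_sd_pht
        gxe_scores[env.name] = (d_gy, d_pht)
        gxe_rows.append(
            pd.DataFrame(
                {"hybrid": hybrids, "environment": env.name, "gy": d_gy, "pht": d_pht}
            )
        )
    gxe = pd.concat(gxe_rows, ignore_index=True).set_index(["hybrid", "environment"])

    # VI loadings: programmed correlation of each VI's amplitude score with
    # the yield genetic value.  VARI gets the maximum, RCC its negative,
    # raw bands a weak one, everything else a random intermediate value.
    rho_max = config.vi_genetic_corr
    loadings = {}
    for vi in config.vi_names:
        if vi == "VARI":
            loadings[vi] = rho_max
        elif vi == "RCC":
            loadings[vi] = -rho_max
        elif vi in ("R", "G", "B"):
            loadings[vi] = 0.2 * rho_max * rng.choice([-1.0, 1.0])
        else:
            loadings[vi] = rho_max * rng.uniform(-0.85, 0.85)
    vi_loadings = pd.Series(loadings, name="loading")
    vi_loadings.index.name = "vi_name"

    # amplitude genetic scores: rho * yield score + sqrt(1-rho^2) * own score
    u_gy_std = (u_gy - u_gy.mean()) / u_gy.std()
    eta = _genetic_scores(Xc, rng, len(config.vi_names))
    rho = vi_loadings.reindex(list(config.vi_names)).to_numpy()
    g_vi = rho * u_gy_std[:, None] + np.sqrt(1.0 - rho**2) * eta
    vi_genetic = pd.DataFrame(
        g_vi, index=pd.Index(hybrids, name="hybrid"), columns=list(config.vi_names)
    )
    # shared green-up timing genetic score (days)
    z_timing = _genetic_scores(Xc, rng, 1)[:, 0]

    # per-VI curve geometry (baseline / amplitude scale differ across VIs)
    vi_base = rng.uniform(0.10, 0.60, size=len(config.vi_names))
    vi_amp = rng.uniform(0.20, 0.60, size=len(config.vi_names))

    plots_list = []
    vi_frames = []
    truth_h_index = pd.Index(hybrids, name="hybrid")
    h_pos = {h: i for i, h in enumerate(hybrids)}

    for env in envs:
        layout = _rcbd_layout(env, hybrids, config.n_reps, rng)
        hi = layout["hybrid"].map(h_pos).to_numpy()
        n_plots = len(layout)

        d_gy, d_pht = gxe_scores[env.name]

        # residual variance back-solved from the entry-mean heritability
        for trait, u_main, d_env, h2, mu in (
            ("gy", u_gy, d_gy, config.heritability_gy, config.mean_gy),
            ("pht", u_pht, d_pht, config.heritability_pht, config.mean_pht),
        ):
            g_env = u_main + d_env
            var_g = float(np.var(g_env))
            if h2 >= 1.0:
                sig_e = 0.0
            elif h2 <= 0.0:
                g_env = np.zeros_like(g_env)
                sig_e = 1.0
            else:
                sig_e = np.sqrt(config.n_reps * var_g * (1.0 - h2) / h2)
            sp_sd = np.sqrt(config.spatial_fraction) * sig_e
            rng_eff = rng.normal(0, sp_sd, env.n_ranges)
            row_eff = rng.normal(0, sp_sd, env.n_rows)
            rep_eff = rng.normal(0, sp_sd, config.n_reps)
            y = (
                mu
                + g_env[hi]
                + rng_eff[layout["range"].to_numpy() - 1]
                + row_eff[layout["row"].to_numpy() - 1]
                + rep_eff[layout["rep"].to_numpy() - 1]
                + rng.normal(0, sig_e, n_plots)
            )
            layout[trait] = y
        plots_list.append(layout)

        # VI trajectories: plot x flight values per VI
        daps = np.asarray(env.flight_daps, dtype=float)
        t_green_env = env.flowering_start_dap - 20.0
        t_sen_env = env.flowering_start_dap + 25.0
        env_shift = rng.normal(0, 0.03)  # small environment-level level shift
        for v_idx, vi in enumerate(config.vi_names):
            amp0 = vi_amp[v_idx]
            g_amp = g_vi[:, v_idx] + gxe_sd * _genetic_scores(Xc, rng, 1)[:, 0]
            amp_h = amp0 * (1.0 + config.vi_amplitude_cv * g_amp)
            # timing variation kept small so amplitude carries the
            # programmed trait correlation rather than being swamped
            tg_h = t_green_env + config.vi_timing_sd * z_timing
            # plot x flight genetic trajectory
            up = _logistic(0.18 * (daps[None, :] - tg_h[hi, None]))
            down = _logistic(0.12 * (daps[None, :] - t_sen_env))
            vals = vi_base[v_idx] + env_shift + amp_h[hi, None] * (up - 0.6 * down)
            noise_sd = config.vi_noise_frac * amp0
            sp_sd = np.sqrt(config.spatial_fraction) * noise_sd
            rng_eff = rng.normal(0, sp_sd, env.n_ranges)
            row_eff = rng.normal(0, sp_sd, env.n_rows)
            rep_eff = rng.normal(0, sp_sd, config.n_reps)
            vals = (
                vals
                + rng_eff[layout["range"].to_numpy() - 1][:, None]
                + row_eff[layout["row"].to_numpy() - 1][:, None]
                + rep_eff[layout["rep"].to_numpy() - 1][:, None]
                + rng.normal(0, noise_sd, vals.shape)
            )
            frame = pd.DataFrame(vals, columns=env.flight_daps)
            frame["hybrid"] = layout["hybrid"].to_numpy()
            frame["range"] = layout["range"].to_numpy()
            frame["row"] = layout["row"].to_numpy()
            frame["rep"] = layout["rep"].to_numpy()
            long = frame.melt(
                id_vars=["hybrid", "range", "row", "rep"],
                var_name="flight_dap",
                value_name="value",
            )
            long["environment"] = env.name
            long["vi_name"] = vi
            vi_frames.append(long)

    plots = pd.concat(plots_list, ignore_index=True)
    vi_obs = pd.concat(vi_frames, ignore_index=True)
    vi_obs["flight_dap"] = vi_obs["flight_dap"].astype(int)
    vi_obs = vi_obs[
        ["hybrid", "environment", "flight_dap", "vi_name", "range", "row", "rep", "value"]
    ]

    truth = TrialTruth(
        genetic=genetic,
        gxe=gxe,
        vi_genetic=vi_genetic.set_axis(truth_h_index, axis=0),
        vi_loadings=vi_loadings,
    )
    return SyntheticTrial(
        config=config, markers=markers, plots=plots, vi_obs=vi_obs, truth=truth
    )


# ---------------------------------------------------------------------------
# Preset trial shapes
# ---------------------------------------------------------------------------

def _pop1_envs() -> tuple:
    return (
        EnvironmentSpec(
            name="2018",
            flight_daps=(29, 36, 43, 51, 65, 82, 99),
            flowering_start_dap=65,
            n_ranges=30,
            n_rows=28,
        ),
        EnvironmentSpec(
            name="2019",
            flight_daps=(22, 29, 35, 41, 47, 53, 59, 66, 73, 80, 87, 94, 101, 108),
            flowering_start_dap=66,
            n_ranges=30,
            n_rows=28,
        ),
    )


def _pop2_envs() -> tuple:
    daps17 = tuple(range(20, 20 + 17 * 5, 5))          # 17 flights, 20..100
    daps20 = tuple(range(18, 18 + 20 * 5, 5))          # 20 flights, 18..113
    return (
        EnvironmentSpec("2020.drought", daps17, 62, 22, 20),
        EnvironmentSpec("2020.optimal", daps17, 60, 22, 20),
        EnvironmentSpec("2021.drought", daps20, 63, 22, 20),
    )


PRESETS = {
    "pop1-like": dict(n_hybrids=415, environments=_pop1_envs),
    "pop2-like": dict(n_hybrids=220, environments=_pop2_envs),
    # small shape for demos and smoke tests (not a study condition)
    "demo": dict(
        n_hybrids=40,
        environments=lambda: (
            EnvironmentSpec("envA", (20, 30, 40, 55, 70, 85), 55, 10, 8),
            EnvironmentSpec("envB", (25, 35, 45, 60, 75), 60, 10, 8),
        ),
    ),
}


def preset_config(name: str, n_markers: int = 1000, seed: int = 0, **overrides) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a named preset shape.

    ``pop1-like`` is a 415-hybrid trial over two environments with 7 and 14
    flights; ``pop2-like`` a 220-hybrid trial over three environments with
    17, 17 and 20 flights; ``demo`` a small shape for quick runs.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    shape = PRESETS[name]
    cfg = SimulationConfig(
        n_hybrids=shape["n_hybrids"],
        n_markers=n_markers,
        environments=shape["environments"](),
        seed=seed,
    )
    if "demo" == name:
        cfg = replace(cfg, vi_names=cfg.vi_names[:6])
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg
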