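"""Synthetic understory-community generator.

Emulates the sampling design of a fern trait survey on a regular grid of
10 m x 10 m quadrats in a forest plot: a deterministic elevation gradient,
spatially autocorrelated soil fields, overstory structure/composition
variables, species communities assembled by Gaussian niche filtering along
an environmental gradient, and individual-level trait measurements with
controllable intraspecific plasticity.  Every draw is a pure function of
the scenario seed, so downstream stages can be tested against known ground
truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("cwmitv.synthetic")

__all__ = [
    "TRAITS",
    "TRAIT_MEANS",
    "TRAIT_SDS",
    "TRAIT_BOUNDS",
    "TOPO_VARS",
    "SOIL_VARS",
    "BIOTIC_VARS",
    "ENV_GROUPS",
    "Scenario",
    "ScenarioError",
    "ConfigurationError",
    "generate_environment",
    "generate_community",
    "generate_traits",
    "generate_overstory",
    "scenario_truth",
    "write_tables",
]

# The six measured leaf/plant traits: fern height (cm), leaf area (cm^2),
# specific leaf area (cm^2/g), leaf dry matter content (g/g), SPAD
# chlorophyll reading (unitless), PSII actual quantum yield (unitless).
TRAITS = ("FH", "LA", "SLA", "LDMC", "SPAD", "PhiPSII")

# Community-level means and between-species SDs used to seed baselines.
TRAIT_MEANS = {
    "FH": 42.7,
    "LA": 437.0,
    "SLA": 197.0,
    "LDMC": 0.37,
    "SPAD": 44.0,
    "PhiPSII": 0.32,
}
TRAIT_SDS = {
    "FH": 12.0,
    "LA": 180.0,
    "SLA": 40.0,
    "LDMC": 0.06,
    "SPAD": 4.0,
    "PhiPSII": 0.03,
}
# Hard physical ranges; generated values are clipped into them (with a log
# message) because additive noise can stray outside.
TRAIT_BOUNDS = {"LDMC": (1e-6, 1.0), "PhiPSII": (0.0, 1.0)}

TOPO_VARS = ("elevation", "slope", "aspect", "convexity")
SOIL_VARS = ("pH", "moisture", "SOC", "TN", "TP", "K", "Ca", "Mg", "Mn")
BIOTIC_VARS = ("density", "basal_area", "comp1", "comp2")

ENV_GROUPS = {
    **{v: "topographic" for v in TOPO_VARS},
    **{v: "soil" for v in SOIL_VARS},
    **{v: "biotic" for v in BIOTIC_VARS},
}


class ScenarioError(ValueError):
    """Raised when a Scenario violates its invariants."""


class ConfigurationError(ValueError):
    """Raised when a generator is asked for a column or field that does not exist."""


@dataclass
class Scenario:
    """Parameters of one synthetic study.

    The defaults mirror the field design being emulated: an 11 x 11 grid of
    10 m quadrats (121 plots), 45 understory species, five measured
    individuals per species per plot, and soil fields with a ~30 m
    correlation length.

    Parameters
    ----------
    niche_optima
        Per-species optimum on the standardized turnover gradient.  ``None``
        spreads the optima evenly over [-2, 2] with seeded jitter.
    niche_breadth
        Gaussian niche SD on the standardized gradient (scalar or
        per-species).  ``np.inf`` removes turnover entirely.
    trait_baselines
        Species x trait DataFrame of fixed trait means.  ``None`` draws
        baselines whose correlation with the niche optima is set by
        ``turnover_coupling``, so that species replacement along the
        gradient moves community trait means.
    plasticity_slopes
        Array of shape (n_species, 6, len(plasticity_gradients)): trait-unit
        change per SD of each plastic gradient.  All zeros (the default)
        disables environmentally structured ITV.
    individual_sd
        Within-plot individual noise, expressed as a multiple of each
        trait's between-species SD.
    plot_itv_sd
        Plot-level species trait deviation, independent of the environment
        (idiosyncratic ITV), in the same between-species-SD units.
    cover_noise_cv
        Coefficient of variation of the multiplicative lognormal noise on
        expected covers.
    """

    n_plots_x: int = 11
    n_plots_y: int = 11
    plot_size: float = 10.0
    n_species: int = 45
    niche_optima: np.ndarray | None = None
    niche_breadth: float | np.ndarray = 0.5
    max_cover: float = 30.0
    trait_baselines: pd.DataFrame | None = None
    turnover_coupling: float = 0.6
    plasticity_slopes: np.ndarray | None = None
    plasticity_gradients: tuple[str, ...] = ("elevation",)
    individual_sd: float = 0.25
    plot_itv_sd: float = 1.2
    env_spatial_range: float = 30.0
    cover_noise_cv: float = 1.0
    n_individuals: int = 5
    turnover_gradient: str = "TP"
    seed: int = 0
    # fraction of max_cover below which a species is recorded as absent
    detection_floor: float = 0.01

    def __post_init__(self) -> None:
        if self.n_plots_x <= 0 or self.n_plots_y <= 0:
            raise ScenarioError("grid dimensions must be positive")
        if self.n_plots_x * self.n_plots_y < 4:
            raise ScenarioError("grid must contain at least 4 plots")
        if np.any(np.asarray(self.niche_breadth) <= 0):
            raise ScenarioError("niche_breadth must be positive")
        if self.individual_sd < 0 or self.plot_itv_sd < 0:
            raise ScenarioError("trait noise SDs must be nonnegative")
        if self.cover_noise_cv < 0:
            raise ScenarioError("cover_noise_cv must be nonnegative")
        if self.n_species < 1 or self.n_individuals < 1:
            raise ScenarioError("n_species and n_individuals must be >= 1")
        if self.max_cover <= 0:
            raise ScenarioError("max_cover must be positive")

    @property
    def n_plots(self) -> int:
        return self.n_plots_x * self.n_plots_y

    @property
    def species_ids(self) -> list[str]:
        return [f"sp{i + 1:02d}" for i in range(self.n_species)]

    @property
    def plot_ids(self) -> list[str]:
        return [f"p{i + 1:03d}" for i in range(self.n_plots)]

    def with_seed(self, seed: int) -> "Scenario":
        return replace(self, seed=seed)

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-specific generator so each stage is independently reproducible."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stage]))

    def optima(self) -> np.ndarray:
        if self.niche_optima is not None:
            out = np.asarray(self.niche_optima, dtype=float)
            if out.shape != (self.n_species,):
                raise ScenarioError("niche_optima must have one entry per species")
            return out
        rng = self.rng(10)
        base = np.linspace(-2.0, 2.0, self.n_species)
        return base + rng.normal(0.0, 0.25, self.n_species)

    def breadths(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.niche_breadth, dtype=float),
                               (self.n_species,)).copy()

    def baselines(self) -> pd.DataFrame:
        """Species x trait fixed means (generated unless supplied)."""
        if self.trait_baselines is not None:
            tb = self.trait_baselines
            missing = [t for t in TRAITS if t not in tb.columns]
            if missing:
                raise ScenarioError(f"trait_baselines missing columns: {missing}")
            return tb.loc[self.species_ids, list(TRAITS)].astype(float)
        rng = self.rng(11)
        mu = self.optima()
        muz = (mu - mu.mean()) / (mu.std() if mu.std() > 0 else 1.0)
        rho = self.turnover_coupling
        resid = np.sqrt(max(1.0 - rho**2, 0.0))
        # alternate the sign of the coupling across traits so the leaf-economics
        # style trade-off (e.g. SLA up while LDMC down) appears along the gradient
        signs = {"FH": 1, "LA": 1, "SLA": -1, "LDMC": 1, "SPAD": 1, "PhiPSII": -1}
        data = {}
        for t in TRAITS:
            z = signs[t] * rho * muz + resid * rng.normal(0.0, 1.0, self.n_species)
            data[t] = TRAIT_MEANS[t] + TRAIT_SDS[t] * z
        tb = pd.DataFrame(data, index=self.species_ids)
        return _clip_bounded(tb, where="trait_baselines")

    def slopes(self) -> np.ndarray:
        if self.plasticity_slopes is None:
            return np.zeros((self.n_species, len(TRAITS), len(self.plasticity_gradients)))
        sl = np.asarray(self.plasticity_slopes, dtype=float)
        want = (self.n_species, len(TRAITS), len(self.plasticity_gradients))
        if sl.shape != want:
            raise ScenarioError(f"plasticity_slopes must have shape {want}, got {sl.shape}")
        return sl


def uniform_plasticity(scenario: Scenario, trait: str, slope: float) -> np.ndarray:
    """Slope array giving every species the same plastic response of one trait
    to the first plasticity gradient (trait units per gradient SD)."""
    sl = np.zeros((scenario.n_species, len(TRAITS), len(scenario.plasticity_gradients)))
    sl[:, TRAITS.index(trait), 0] = slope
    return sl


# ---------------------------------------------------------------------------
# Gaussian random fields

def _distance_matrix(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(-1))


def gaussian_random_field(coords: np.ndarray, range_m: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance field with exponential covariance exp(-d/range).

    Realized by dense Cholesky factorization of the covariance over plot
    centers; fine for the few hundred plots of a grid design.  ``range_m <= 0``
    degenerates to i.i.d. standard normals.
    """
    n = coords.shape[0]
    z = rng.standard_normal(n)
    if range_m <= 0:
        return z
    cov = np.exp(-_distance_matrix(coords) / range_m)
    cov[np.diag_indices(n)] += 1e-10
    return np.linalg.cholesky(cov) @ z


# ---------------------------------------------------------------------------
# Environment

def generate_environment(scenario: Scenario) -> pd.DataFrame:
    """Per-plot coordinates plus topographic / soil / biotic predictors.

    Elevation is a deterministic plane over the grid; soil variables are
    built from two latent spatially autocorrelated fields (a fertility axis
    carrying moisture/SOC/TN and, with opposite sign, pH; and a
    phosphorus-richness axis carrying TP/Ca) plus variable-specific fields;
    biotic variables are overstory stand density, basal area and two
    composition axes.  The ``group`` tag of each predictor is available via
    :data:`ENV_GROUPS` and is also attached as ``df.attrs["groups"]``.
    """
    ns = scenario
    rng = ns.rng(0)
    ix, iy = np.meshgrid(np.arange(ns.n_plots_x), np.arange(ns.n_plots_y), indexing="ij")
    x = (ix.ravel() + 0.5) * ns.plot_size
    y = (iy.ravel() + 0.5) * ns.plot_size
    coords = np.column_stack([x, y])
    n = ns.n_plots

    def grf() -> np.ndarray:
        return gaussian_random_field(coords, ns.env_spatial_range, rng)

    # deterministic elevation: tilted plane with a gentle ridge, ~400 +- 40 m
    xr = (x - x.mean()) / max(x.max() - x.min(), 1.0)
    yr = (y - y.mean()) / max(y.max() - y.min(), 1.0)
    elevation = 400.0 + 70.0 * xr + 40.0 * yr + 15.0 * (xr * yr)

    slope = np.clip(32.5 + 5.1 * grf(), 5.0, 60.0)
    aspect = 152.0 + 30.0 * grf()
    convexity = 0.02 + 0.85 * gaussian_random_field(coords, ns.plot_size, rng)

    fert = grf()     # latent fertility field
    phos = grf()     # latent phosphorus-richness field

    def soil(mean: float, sd: float, w_f: float, w_p: float,
             lo: float | None = None, hi: float | None = None) -> np.ndarray:
        w_e = np.sqrt(max(1.0 - w_f**2 - w_p**2, 0.0))
        v = mean + sd * (w_f * fert + w_p * phos + w_e * grf())
        return np.clip(v, lo, hi) if lo is not None or hi is not None else v

    env = pd.DataFrame({
        "plot_id": ns.plot_ids,
        "x": x,
        "y": y,
        "elevation": elevation,
        "slope": slope,
        "aspect": aspect,
        "convexity": convexity,
        "pH": soil(3.79, 0.21, -0.7, 0.0, lo=2.5, hi=6.0),
        "moisture": soil(35.4, 4.1, 0.7, 0.0, lo=5.0),
        "SOC": soil(7.9, 2.6, 0.8, 0.0, lo=0.5),
        "TN": soil(0.50, 0.12, 0.8, 0.0, lo=0.05),
        "TP": soil(0.03, 0.007, 0.0, 0.8, lo=0.003),
        "K": soil(22700.0, 3600.0, 0.0, 0.4, lo=1000.0),
        "Ca": soil(1900.0, 500.0, 0.0, 0.8, lo=100.0),
        "Mg": soil(4100.0, 600.0, 0.4, 0.0, lo=100.0),
        "Mn": soil(548.0, 271.0, 0.0, 0.3, lo=10.0),
        "density": np.clip(np.round(67.0 + 30.0 * grf()), 0, None),
        "basal_area": np.clip(35.5 + 18.0 * (0.5 * fert + 0.866 * grf()), 0.0, None),
        "comp1": 0.49 * grf(),
        "comp2": 0.32 * grf(),
    })
    env.attrs["groups"] = dict(ENV_GROUPS)
    return env


# ---------------------------------------------------------------------------
# Community

def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def generate_community(env: pd.DataFrame, scenario: Scenario) -> pd.DataFrame:
    """Plot x species cover matrix from Gaussian niches on the turnover gradient.

    Expected cover of species i in plot j is
    ``max_cover * exp(-(g_j - mu_i)^2 / (2 sigma_i^2))`` on the standardized
    gradient, times mean-one lognormal noise with CV ``cover_noise_cv``;
    covers below ``detection_floor * max_cover`` are recorded as 0.
    """
    ns = scenario
    if ns.turnover_gradient not in env.columns:
        raise ConfigurationError(
            f"turnover gradient column {ns.turnover_gradient!r} not in environment table")
    rng = ns.rng(1)
    g = _standardize(env[ns.turnover_gradient].to_numpy(float))
    mu = ns.optima()
    sig = ns.breadths()
    with np.errstate(over="ignore"):
        expected = ns.max_cover * np.exp(-((g[:, None] - mu[None, :]) ** 2)
                                         / (2.0 * sig[None, :] ** 2))
    if ns.cover_noise_cv > 0:
        s2 = np.log1p(ns.cover_noise_cv**2)
        noise = rng.lognormal(-s2 / 2.0, np.sqrt(s2), expected.shape)
    else:
        noise = 1.0
    cover = expected * noise
    cover[cover < ns.detection_floor * ns.max_cover] = 0.0
    return pd.DataFrame(cover, index=pd.Index(env["plot_id"], name="plot_id"),
                        columns=ns.species_ids)


def generate_overstory(env: pd.DataFrame, scenario: Scenario,
                       n_tree_species: int = 20) -> pd.DataFrame:
    """Plot x tree-species Importance-Value surrogate matrix.

    Tree species occupy 2-D Gaussian niches on the two latent composition
    axes (``comp1``, ``comp2``), so an NMDS of this matrix recovers gradients
    aligned with those axes.
    """
    rng = scenario.rng(3)
    a1 = _standardize(env["comp1"].to_numpy(float))
    a2 = _standardize(env["comp2"].to_numpy(float))
    mu1 = rng.uniform(-1.8, 1.8, n_tree_species)
    mu2 = rng.uniform(-1.8, 1.8, n_tree_species)
    sig = 1.0
    expected = np.exp(-(((a1[:, None] - mu1) ** 2) + ((a2[:, None] - mu2) ** 2))
                      / (2 * sig**2))
    s2 = np.log1p(0.3**2)
    iv = expected * rng.lognormal(-s2 / 2, np.sqrt(s2), expected.shape)
    iv[iv < 0.02] = 0.0
    return pd.DataFrame(iv, index=pd.Index(env["plot_id"], name="plot_id"),
                        columns=[f"tree{i + 1:02d}" for i in range(n_tree_species)])


# ---------------------------------------------------------------------------
# Traits

def _clip_bounded(df: pd.DataFrame, where: str) -> pd.DataFrame:
    out = df.copy()
    for t, (lo, hi) in TRAIT_BOUNDS.items():
        if t in out.columns:
            n_clip = int(((out[t] < lo) | (out[t] > hi)).sum())
            if n_clip:
                logger.info("clipped %d %s values to [%g, %g] in %s", n_clip, t, lo, hi, where)
            out[t] = out[t].clip(lo, hi)
    return out


def generate_traits(env: pd.DataFrame, community: pd.DataFrame,
                    scenario: Scenario) -> pd.DataFrame:
    """Individual-level trait records for every (plot, species) occurrence.

    Each present pair gets ``n_individuals`` records with value
    ``baseline + sum_k slope_k * envz_k + plot_deviation + N(0, individual_sd)``,
    noise SDs expressed in units of each trait's between-species SD.  LDMC and
    PSII yield are clipped to their physical ranges.
    """
    ns = scenario
    if community.to_numpy().sum() <= 0:
        raise ValueError("community matrix is empty: no occurrences to sample traits from")
    for gcol in ns.plasticity_gradients:
        if gcol not in env.columns:
            raise ConfigurationError(f"plasticity gradient {gcol!r} not in environment table")
    rng = ns.rng(2)
    baselines = ns.baselines()
    slopes = ns.slopes()
    envz = np.column_stack([_standardize(env[g].to_numpy(float))
                            for g in ns.plasticity_gradients])
    envz_by_plot = dict(zip(env["plot_id"], envz))
    scale = np.array([TRAIT_SDS[t] for t in TRAITS])

    records: list[dict] = []
    sp_index = {s: k for k, s in enumerate(community.columns)}
    for plot_id, row in community.iterrows():
        present = row.index[row.to_numpy() > 0]
        ez = envz_by_plot[plot_id]
        for sp in present:
            k = sp_index[sp]
            mean_vec = baselines.loc[sp].to_numpy() + slopes[k] @ ez
            if ns.plot_itv_sd > 0:
                mean_vec = mean_vec + rng.normal(0.0, ns.plot_itv_sd, len(TRAITS)) * scale
            vals = mean_vec + rng.normal(0.0, ns.individual_sd, (ns.n_individuals, len(TRAITS))) * scale
            for j in range(ns.n_individuals):
                rec = {"plot_id": plot_id, "species_id": sp,
                       "individual_id": f"{plot_id}-{sp}-{j + 1}"}
                rec.update(dict(zip(TRAITS, vals[j])))
                records.append(rec)
    traits = pd.DataFrame.from_records(records)
    return _clip_bounded(traits, where="trait records")


# ---------------------------------------------------------------------------
# Ground truth

def scenario_truth(scenario: Scenario) -> dict:
    """Qualitative decomposition ground truth implied by the scenario.

    Returns a label plus the shares that are determined a priori: zero
    plasticity and zero trait noise force the ITV share to 0; an infinitely
    broad niche with noiseless cover forces constant composition and hence a
    turnover share of 0.  Mixed scenarios make no numeric claim.
    """
    ns = scenario
    no_itv = (np.all(ns.slopes() == 0) and ns.individual_sd == 0
              and ns.plot_itv_sd == 0)
    breadths = ns.breadths()
    no_turnover = bool(np.all(np.isinf(breadths)) and ns.cover_noise_cv == 0)
    if no_itv and no_turnover:
        return {"label": "degenerate", "pct_itv": 0.0, "pct_turnover": 0.0}
    if no_itv:
        return {"label": "no_itv", "pct_itv": 0.0, "pct_turnover": None}
    if no_turnover:
        return {"label": "no_turnover", "pct_itv": None, "pct_turnover": 0.0}
    return {"label": "mixed", "pct_itv": None, "pct_turnover": None}


# ---------------------------------------------------------------------------
# I/O

def write_tables(outdir, env: pd.DataFrame, community: pd.DataFrame,
                 traits: pd.DataFrame, overstory: pd.DataFrame | None = None) -> None:
    """Write the standard delimited-text bundle consumed by the pipeline."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    env.to_csv(out / "environment.csv", index=False)
    community.to_csv(out / "community.csv")
    traits.to_csv(out / "traits.csv", index=False)
    if overstory is not None:
        overstory.to_csv(out / "overstory.csv")
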