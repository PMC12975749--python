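"""End-to-end orchestration: simulate/load -> validate -> species means ->
CWM -> decomposition -> ordination -> spatial GLS -> variance partitioning.

Every stage is a pure function of its inputs plus the seed, all interchange
is delimited text (CSV, UTF-8, header row, "." decimal, empty field for
missing), and the run manifest (config hash + seed + package versions)
suffices to re-run deterministic stages bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cwm import CwmTriple, compute_species_means, cwm_triple, decompose_cwm_variance
from .ordination import bray_curtis, nmds, pca, trait_pca_axes, wisconsin
from .partition import partition_three_groups
from .spatial import CorrelationModel, fit_gls_r2, vif
from .synthetic import (SOIL_VARS, TOPO_VARS, TRAIT_BOUNDS, TRAITS, Scenario,
                        generate_community, generate_environment,
                        generate_overstory, generate_traits, write_tables)

logger = logging.getLogger("cwmitv.pipeline")

__all__ = ["RunConfig", "ResultBundle", "ValidationError",
           "run_full_analysis", "validate_tables", "load_config"]


class ValidationError(ValueError):
    """Input tables violate the schema; message lists file/column/row."""


@dataclass
class RunConfig:
    """Flat run configuration (see docs/methods.md for the key set).

    Exactly one of ``scenario`` (generator parameters) or the three input
    paths must be given.  ``seed`` drives every stochastic stage.
    """

    outdir: str = "results"
    seed: int = 0
    scenario: dict | None = None
    community_csv: str | None = None
    traits_csv: str | None = None
    environment_csv: str | None = None
    overstory_csv: str | None = None
    trait_list: list[str] = field(default_factory=lambda: list(TRAITS))
    cwm_variants: list[str] = field(default_factory=lambda: ["fixed", "specific", "intravar"])
    n_trait_axes: int = 2
    corr_family: str = "exponential"
    estimate_nugget: bool = False
    nmds_starts: int = 20
    nmds_wisconsin: bool = False
    run_partition: bool = True
    verbosity: int = 1

    def __post_init__(self) -> None:
        has_paths = any([self.community_csv, self.traits_csv, self.environment_csv])
        if (self.scenario is None) == (not has_paths):
            raise ValueError("exactly one of scenario / input paths must be given")
        if has_paths and not all([self.community_csv, self.traits_csv,
                                  self.environment_csv]):
            raise ValueError("community, traits and environment paths are all required")

    def corr(self) -> CorrelationModel:
        return CorrelationModel(family=self.corr_family,
                                estimate_nugget=self.estimate_nugget)

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        return d

    def hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path, seed: int | None = None, outdir: str | None = None) -> RunConfig:
    """Read a YAML config file into a RunConfig; CLI flags override."""
    import yaml
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if seed is not None:
        raw["seed"] = seed
    if outdir is not None:
        raw["outdir"] = outdir
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


@dataclass
class ResultBundle:
    """All tables produced by one run, plus the manifest."""

    cwm: pd.DataFrame
    decomposition: pd.DataFrame
    pca_results: dict
    nmds_scores: pd.DataFrame | None
    predictors: pd.DataFrame
    vif: pd.Series
    coefficients: pd.DataFrame
    pseudo_r2: pd.DataFrame
    partitions: pd.DataFrame | None
    manifest: dict
    outdir: Path


# ---------------------------------------------------------------------------
# Validation

def validate_tables(community: pd.DataFrame, traits: pd.DataFrame,
                    env: pd.DataFrame) -> list[dict]:
    """Cross-referential and range checks; returns a list of issue records
    (table, column, row, code, message) — empty when the bundle is clean."""
    issues: list[dict] = []

    def issue(table, column, row, code, message):
        issues.append({"table": table, "column": column, "row": row,
                       "code": code, "message": message})

    # environment: one record per plot, unique coordinates
    if env["plot_id"].duplicated().any():
        for r in env.index[env["plot_id"].duplicated()]:
            issue("environment", "plot_id", int(r), "duplicate", "duplicate plot_id")
    for c in ("x", "y"):
        if c not in env.columns:
            issue("environment", c, None, "missing-column", f"no {c} coordinate column")
    if {"x", "y"} <= set(env.columns) and env.duplicated(["x", "y"]).any():
        for r in env.index[env.duplicated(["x", "y"])]:
            issue("environment", "x,y", int(r), "duplicate", "duplicate coordinates")

    # community: nonnegative covers, plots known to the environment table
    comm_vals = community.to_numpy(float)
    for i, j in zip(*np.nonzero(comm_vals < 0)):
        issue("community", str(community.columns[j]), str(community.index[i]),
              "range", "negative cover")
    unknown_plots = set(community.index) - set(env["plot_id"])
    for p in sorted(unknown_plots):
        issue("community", "plot_id", p, "referential", "plot missing from environment")

    # traits: referential integrity and physical ranges
    known_pairs = {(p, s) for p, row in community.iterrows()
                   for s, v in row.items() if v > 0}
    for r, rec in traits.iterrows():
        if rec["plot_id"] not in community.index:
            issue("traits", "plot_id", int(r), "referential", "unknown plot id")
        elif (rec["plot_id"], rec["species_id"]) not in known_pairs:
            issue("traits", "species_id", int(r), "referential",
                  "(plot, species) pair absent from community matrix")
    for t, (lo, hi) in TRAIT_BOUNDS.items():
        if t in traits.columns:
            bad = traits.index[(traits[t] < lo) | (traits[t] > hi)]
            for r in bad:
                issue("traits", t, int(r), "range", f"value outside [{lo}, {hi}]")
    num_cols = [c for c in traits.columns
                if c not in ("plot_id", "species_id", "individual_id")]
    nonfinite = ~np.isfinite(traits[num_cols].to_numpy(float))
    for i, j in zip(*np.nonzero(nonfinite)):
        issue("traits", num_cols[j], int(traits.index[i]), "range", "non-finite value")
    return issues


# ---------------------------------------------------------------------------
# Stages

def _simulate(config: RunConfig):
    sc = Scenario(**{**(config.scenario or {}), "seed": config.seed})
    env = generate_environment(sc)
    community = generate_community(env, sc)
    traits = generate_traits(env, community, sc)
    overstory = generate_overstory(env, sc)
    return env, community, traits, overstory


def _load(config: RunConfig):
    community = pd.read_csv(config.community_csv, index_col=0)
    community.index.name = "plot_id"
    traits = pd.read_csv(config.traits_csv)
    env = pd.read_csv(config.environment_csv)
    overstory = None
    if config.overstory_csv:
        overstory = pd.read_csv(config.overstory_csv, index_col=0)
    return env, community, traits, overstory


def build_predictors(env: pd.DataFrame, overstory: pd.DataFrame | None,
                     config: RunConfig):
    """Reduce the raw environment to the 8 standard model predictors.

    Topographic and soil blocks are each reduced to their first two
    principal components; the biotic block is stand density, basal area and
    the two NMDS axes of the overstory composition matrix (falling back to
    the provided composition axes when no overstory matrix is given).
    Returns (predictor table indexed by plot_id, group map, pca results,
    nmds scores or None).
    """
    e = env.set_index("plot_id")
    topo = pca(e[list(TOPO_VARS)], scale=True)
    soil = pca(e[list(SOIL_VARS)], scale=True)
    logger.info("topography PCA: first two PCs explain %.1f%%",
                topo.explained_pct.iloc[:2].sum())
    logger.info("soil PCA: first two PCs explain %.1f%%",
                soil.explained_pct.iloc[:2].sum())
    pred = pd.DataFrame(index=e.index)
    pred["PC_topo1"] = topo.scores["PC1"]
    pred["PC_topo2"] = topo.scores["PC2"]
    pred["PC_soil1"] = soil.scores["PC1"]
    pred["PC_soil2"] = soil.scores["PC2"]
    pred["density"] = e["density"]
    pred["basal_area"] = e["basal_area"]
    nmds_scores = None
    if overstory is not None:
        occupied = overstory.loc[overstory.sum(axis=1) > 0]
        mat = wisconsin(occupied) if config.nmds_wisconsin else occupied
        res = nmds(bray_curtis(mat), k=2, n_starts=config.nmds_starts,
                   seed=config.seed)
        logger.info("overstory NMDS stress-1 = %.4f", res.stress)
        nmds_scores = res.scores
        pred["NMDS1"] = nmds_scores["NMDS1"]
        pred["NMDS2"] = nmds_scores["NMDS2"]
    else:
        pred["NMDS1"] = e["comp1"]
        pred["NMDS2"] = e["comp2"]
    if pred.isna().any().any():
        n0 = len(pred)
        pred = pred.dropna()
        logger.warning("dropped %d plots lacking a predictor value", n0 - len(pred))
    groups = {"topographic": ["PC_topo1", "PC_topo2"],
              "soil": ["PC_soil1", "PC_soil2"],
              "biotic": ["density", "basal_area", "NMDS1", "NMDS2"]}
    return pred, groups, {"topographic": topo, "soil": soil}, nmds_scores


def _fit_all(triple: CwmTriple, pred: pd.DataFrame, groups: dict,
             coords: pd.DataFrame, config: RunConfig):
    """GLS fits (+ pseudo-R^2, + partition) for every response x CWM variant."""
    corr = config.corr()
    coef_rows, r2_rows, part_rows = [], [], []
    responses = [t for t in triple.traits]
    for variant in config.cwm_variants:
        table = getattr(triple, variant)
        for resp in responses:
            y = table[resp].dropna()
            plots = y.index.intersection(pred.index)
            yv = y.loc[plots]
            X = pred.loc[plots]
            xy = coords.loc[plots]
            fit, null, r2 = fit_gls_r2(yv, X, xy, corr, response=f"{resp}_{variant}")
            for name, row in fit.params.iterrows():
                coef_rows.append({"response": resp, "variant": variant,
                                  "predictor": name, **row.to_dict()})
            r2_rows.append({"response": resp, "variant": variant,
                            "pseudo_r2": r2, "loglik": fit.loglik,
                            "null_loglik": null.loglik, "aic": fit.aic,
                            "range_m": fit.range_, "n": fit.n,
                            "converged": fit.converged})
            if config.run_partition:
                part = partition_three_groups(yv, groups, X, xy, corr,
                                              response=f"{resp}_{variant}")
                for frac, val in part.fractions.items():
                    part_rows.append({"response": resp, "variant": variant,
                                      "fraction": frac, "value": val,
                                      "total_r2": part.total,
                                      "reliable": part.reliable})
    coefficients = pd.DataFrame(coef_rows)
    pseudo_r2 = pd.DataFrame(r2_rows)
    partitions = pd.DataFrame(part_rows) if part_rows else None
    # side-by-side summary of explanatory power per response
    wide = pseudo_r2.pivot(index="response", columns="variant", values="pseudo_r2")
    for resp, row in wide.iterrows():
        logger.info("pseudo-R2 %-8s  %s", resp,
                    "  ".join(f"{v}={row.get(v, float('nan')):.3f}"
                              for v in config.cwm_variants))
    return coefficients, pseudo_r2, partitions


def run_full_analysis(config: RunConfig) -> ResultBundle:
    """Execute all requested stages in dependency order and write every table."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if config.scenario is not None:
        env, community, traits, overstory = _simulate(config)
        write_tables(out / "inputs", env, community, traits, overstory)
    else:
        env, community, traits, overstory = _load(config)

    issues = validate_tables(community, traits, env)
    if issues:
        head = issues[0]
        raise ValidationError(
            f"{len(issues)} validation issue(s); first: table={head['table']} "
            f"column={head['column']} row={head['row']}: {head['message']}")

    # drop plots with no fern cover before CWM computation
    occupied = community.index[community.sum(axis=1) > 0]
    if len(occupied) < len(community):
        logger.warning("dropped %d plots with zero total cover",
                       len(community) - len(occupied))
    community = community.loc[occupied]

    means = compute_species_means(traits, [t for t in config.trait_list])
    trait_fit, means_aug = trait_pca_axes(means, n_axes=config.n_trait_axes)
    logger.info("trait PCA: first two PCs explain %.1f%%",
                trait_fit.explained_pct.iloc[:2].sum())
    triple = cwm_triple(community, means_aug)
    decomposition = decompose_cwm_variance(triple)

    pred, groups, pca_results, nmds_scores = build_predictors(env, overstory, config)
    pca_results["traits"] = trait_fit
    vif_report = vif(pred)
    logger.info("max VIF among the 8 predictors: %.2f", vif_report.max())

    coords = env.set_index("plot_id")[["x", "y"]]
    coefficients, pseudo_r2, partitions = _fit_all(triple, pred, groups,
                                                   coords, config)

    manifest = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "config": config.as_dict(),
        "versions": _versions(),
        "n_plots": int(len(community)),
        "n_species": int(community.shape[1]),
        "n_trait_records": int(len(traits)),
    }

    triple.to_frame().to_csv(out / "cwm.csv")
    decomposition.to_csv(out / "decomposition.csv")
    for block, res in pca_results.items():
        res.loadings.to_csv(out / f"pca_{block}_loadings.csv")
        res.explained_pct.to_csv(out / f"pca_{block}_explained.csv")
    if nmds_scores is not None:
        nmds_scores.to_csv(out / "nmds_scores.csv")
    pred.to_csv(out / "predictors.csv")
    vif_report.to_csv(out / "vif.csv")
    coefficients.to_csv(out / "coefficients.csv", index=False)
    pseudo_r2.to_csv(out / "pseudo_r2.csv", index=False)
    if partitions is not None:
        partitions.to_csv(out / "partition.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return ResultBundle(cwm=triple.to_frame(), decomposition=decomposition,
                        pca_results=pca_results, nmds_scores=nmds_scores,
                        predictors=pred, vif=vif_report,
                        coefficients=coefficients, pseudo_r2=pseudo_r2,
                        partitions=partitions, manifest=manifest, outdir=out)


def _versions() -> dict:
    import scipy
    import sklearn
    import statsmodels
    return {"cwmitv": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
            "statsmodels": statsmodels.__version__}
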