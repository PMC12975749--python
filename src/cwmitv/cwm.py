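"""Community-weighted means and the turnover / ITV variance decomposition.

Three CWM variants are computed per plot and trait, all weighted by relative
species cover p_i:

* ``CWM_fixed = sum_i p_i x_i`` — species-wide fixed trait means x_i; varies
  among plots only through species turnover.
* ``CWM_specific = sum_i p_i x_im`` — plot-specific species means x_im;
  varies through turnover plus intraspecific trait variation (ITV).
* ``CWM_intravar = CWM_specific - CWM_fixed`` — the per-plot trait shift
  attributable to ITV alone.

The across-plot sum of squares of CWM_specific then decomposes as
``SS_specific = SS_fixed + SS_intraspecific + SS_cov``, giving percentage
contributions of species turnover, ITV and their covariation to total
community-level trait variation.  A negative covariation lets turnover and
ITV contributions sum past 100%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("cwmitv.cwm")

__all__ = [
    "SpeciesMeans",
    "CwmTriple",
    "compute_species_means",
    "compute_cwm",
    "cwm_triple",
    "decompose_cwm_variance",
]

_ID_COLS = ("plot_id", "species_id", "individual_id")


@dataclass
class SpeciesMeans:
    """Fixed and plot-specific species trait means.

    ``specific`` is indexed by (plot_id, species_id); ``fixed`` by species_id.
    The fixed mean of a species is the *unweighted* average of its
    plot-specific means over the plots where it occurs, so heavily sampled
    plots do not dominate.
    """

    fixed: pd.DataFrame
    specific: pd.DataFrame
    n_individuals: pd.Series
    n_plots_present: pd.Series

    @property
    def traits(self) -> list[str]:
        return list(self.fixed.columns)

    def with_axes(self, fixed_axes: pd.DataFrame, specific_axes: pd.DataFrame) -> "SpeciesMeans":
        """Append extra derived 'traits' (e.g. trait-PCA axis scores)."""
        return SpeciesMeans(
            fixed=self.fixed.join(fixed_axes),
            specific=self.specific.join(specific_axes),
            n_individuals=self.n_individuals,
            n_plots_present=self.n_plots_present,
        )


def compute_species_means(traits: pd.DataFrame,
                          trait_cols: list[str] | None = None) -> SpeciesMeans:
    """Two-stage averaging of individual records.

    x_im is the arithmetic mean over the individuals of (plot, species);
    x_i is the unweighted arithmetic mean of x_im over occupied plots —
    plots, not individuals, are the averaging unit.
    """
    if traits.empty:
        raise ValueError("trait table is empty")
    if trait_cols is None:
        trait_cols = [c for c in traits.columns if c not in _ID_COLS]
    bad = traits[trait_cols].apply(lambda c: ~np.isfinite(c))
    if bad.to_numpy().any():
        raise ValueError("trait table contains non-finite values")
    def exact_mean(gb):
        # pairwise summation can be a ulp off even for identical values;
        # groups with a single distinct value get that value exactly, so a
        # no-ITV dataset yields CWM_intravar of exactly 0
        m, lo, hi = gb.mean(), gb.min(), gb.max()
        return m.where(lo != hi, lo)

    grouped = traits.groupby(["plot_id", "species_id"], sort=True)
    specific = exact_mean(grouped[trait_cols])
    n_individuals = grouped.size().rename("n_individuals")
    fixed = exact_mean(specific.groupby(level="species_id")[trait_cols])
    n_plots_present = (specific.groupby(level="species_id").size()
                       .rename("n_plots_present"))
    return SpeciesMeans(fixed=fixed, specific=specific,
                        n_individuals=n_individuals,
                        n_plots_present=n_plots_present)


@dataclass
class CwmTriple:
    """Plot x trait tables of the three CWM variants."""

    fixed: pd.DataFrame
    specific: pd.DataFrame
    intravar: pd.DataFrame

    @property
    def traits(self) -> list[str]:
        return list(self.fixed.columns)

    def to_frame(self) -> pd.DataFrame:
        """Wide table with ``<trait>_<variant>`` columns, for CSV export."""
        parts = []
        for variant, df in (("fixed", self.fixed), ("specific", self.specific),
                            ("intravar", self.intravar)):
            parts.append(df.add_suffix(f"_{variant}"))
        return pd.concat(parts, axis=1)


def _weighted_sums(community: pd.DataFrame, means: SpeciesMeans):
    """Per-plot renormalized weights joined to species means (long form).

    Weights are renormalized over the species that have a plot-specific mean
    in that plot, so the same p_i apply to all three CWM variants and the
    identity intravar = specific - fixed holds exactly per plot.
    """
    if (community.to_numpy() < 0).any():
        raise ValueError("negative cover in community matrix")
    long = community.stack()
    long = long[long > 0].rename("cover")
    long.index.names = ["plot_id", "species_id"]
    usable = long.to_frame().join(means.specific, how="inner")
    dropped = set(community.index) - set(usable.index.get_level_values("plot_id"))
    if dropped:
        logger.warning("%d plots have no species with trait data; CWMs set to missing",
                       len(dropped))
    totals = usable.groupby(level="plot_id")["cover"].transform("sum")
    usable["weight"] = usable["cover"] / totals
    return usable, sorted(dropped)


def cwm_triple(community: pd.DataFrame, means: SpeciesMeans) -> CwmTriple:
    """All three CWM variants on the shared renormalized weight set."""
    usable, dropped = _weighted_sums(community, means)
    traits = means.traits
    w = usable["weight"].to_numpy()[:, None]
    sp = usable.index.get_level_values("species_id")
    x_im = usable[traits].to_numpy()
    x_i = means.fixed.loc[sp, traits].to_numpy()
    contrib_fixed = pd.DataFrame(w * x_i, index=usable.index, columns=traits)
    contrib_spec = pd.DataFrame(w * x_im, index=usable.index, columns=traits)
    fixed = contrib_fixed.groupby(level="plot_id").sum()
    specific = contrib_spec.groupby(level="plot_id").sum()
    # re-attach plots with no usable species as missing rows
    all_plots = community.index
    fixed = fixed.reindex(all_plots)
    specific = specific.reindex(all_plots)
    return CwmTriple(fixed=fixed, specific=specific, intravar=specific - fixed)


def compute_cwm(community: pd.DataFrame, means: SpeciesMeans,
                mode: str = "fixed") -> pd.DataFrame:
    """One CWM variant (``fixed``, ``specific`` or ``intravar``) per plot x trait."""
    if mode not in ("fixed", "specific", "intravar"):
        raise ValueError(f"unknown CWM mode {mode!r}")
    triple = cwm_triple(community, means)
    return getattr(triple, mode)


def decompose_cwm_variance(triple: CwmTriple) -> pd.DataFrame:
    """Across-plot sum-of-squares decomposition, per trait.

    SS terms are centered sums of squares over plots of the fixed,
    intravar and specific CWM series; ``ss_cov`` is the remainder
    ``ss_specific - ss_fixed - ss_intra`` (algebraically twice the centered
    cross-product of the fixed and intravar series).  Percentages are
    relative to ``ss_specific``; plots with a missing value for a trait are
    dropped listwise for that trait.
    """
    rows = []
    for t in triple.traits:
        df = pd.DataFrame({
            "F": triple.fixed[t], "I": triple.intravar[t], "S": triple.specific[t],
        }).dropna()
        n = len(df)
        if n < 3:
            raise ValueError(f"trait {t!r}: need >= 3 plots with values, have {n}")
        f = df["F"].to_numpy() - df["F"].mean()
        i = df["I"].to_numpy() - df["I"].mean()
        s = df["S"].to_numpy() - df["S"].mean()
        ss_fixed = float(f @ f)
        ss_intra = float(i @ i)
        ss_specific = float(s @ s)
        ss_cov = ss_specific - ss_fixed - ss_intra
        if ss_specific > 0:
            pct = [100.0 * v / ss_specific for v in (ss_fixed, ss_intra, ss_cov)]
        else:
            logger.warning("trait %s: SS_specific is zero; percentage shares undefined", t)
            pct = [np.nan] * 3
        rows.append({"trait": t, "n_plots": n, "ss_specific": ss_specific,
                     "ss_fixed": ss_fixed, "ss_intra": ss_intra, "ss_cov": ss_cov,
                     "pct_turnover": pct[0], "pct_itv": pct[1], "pct_cov": pct[2]})
    return pd.DataFrame(rows).set_index("trait")
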