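"""Three-group variance partitioning of GLS explained variance.

For predictor groups T (topographic), S (soil) and B (biotic), the seven
subset models T, S, B, TS, TB, SB, TSB are fitted against a shared
intercept-only null, each Nagelkerke pseudo-R^2 is recorded, and the
inclusion-exclusion linear system is solved for the seven disjoint Venn
fractions (three unique, three pairwise-shared, one triple-shared):

    unique_T  = R2_TSB - R2_SB                       (cyclically for S, B)
    shared_TS = R2_TB + R2_SB - R2_B - R2_TSB        (cyclically)
    shared_TSB = R2_TSB - sum(unique) - sum(pairwise)

so the fractions sum to the full-model R^2 exactly by construction.
Because correlation parameters are re-estimated independently in every
subset model, small negative fractions are possible; they are reported as
computed, with an optional floor-at-zero display mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .spatial import CorrelationModel, fit_gls, nagelkerke_r2

logger = logging.getLogger("cwmitv.partition")

__all__ = ["PartitionResult", "partition_three_groups"]

GROUP_KEYS = ("topographic", "soil", "biotic")
SUBSETS = ("T", "S", "B", "TS", "TB", "SB", "TSB")
FRACTIONS = ("unique_T", "unique_S", "unique_B",
             "shared_TS", "shared_TB", "shared_SB", "shared_TSB")


@dataclass
class PartitionResult:
    """Pseudo-R^2 of the 7 subset models and the 7 disjoint Venn fractions."""

    r2: dict[str, float]          # subset label -> pseudo-R^2
    fractions: dict[str, float]   # disjoint fraction -> share of variance
    total: float                  # full-model pseudo-R^2 (= r2["TSB"])
    reliable: bool                # False if any subset fit failed to converge

    def to_frame(self, floor_at_zero: bool = False) -> pd.DataFrame:
        """One row per disjoint fraction (display may floor negatives at 0)."""
        vals = {k: (max(v, 0.0) if floor_at_zero else v)
                for k, v in self.fractions.items()}
        return pd.DataFrame({"fraction": list(vals), "value": list(vals.values())})


def _drop_duplicate_columns(env: pd.DataFrame, use: list[str]) -> list[str]:
    """Keep one representative of exactly duplicated predictor columns.

    Duplicates span the same space, so the subset R^2 is unchanged; dropping
    them keeps the design non-singular when two groups share a variable.
    """
    kept: list[str] = []
    for c in use:
        v = env[c].to_numpy(float)
        if any((env[k].to_numpy(float) == v).all() for k in kept):
            logger.info("dropping predictor %r (exact duplicate within subset)", c)
            continue
        kept.append(c)
    return kept


def partition_three_groups(y, groups: dict[str, list[str]], env: pd.DataFrame,
                           coords, corr: CorrelationModel | None = None,
                           response: str = "y") -> PartitionResult:
    """Partition explained variance among topographic / soil / biotic groups.

    ``groups`` maps the three group keys to non-empty lists of columns of
    ``env``; all 8 fits (7 subsets + shared null) use the identical plot set.
    """
    corr = corr or CorrelationModel()
    for key in GROUP_KEYS:
        if not groups.get(key):
            raise ValueError(f"predictor group {key!r} is empty or missing")
    cols = {"T": list(groups["topographic"]), "S": list(groups["soil"]),
            "B": list(groups["biotic"])}
    null = fit_gls(y, None, coords, corr, response=response)
    r2: dict[str, float] = {}
    reliable = null.converged
    for label in SUBSETS:
        use = sum((cols[g] for g in label), [])
        use = _drop_duplicate_columns(env, use)
        fit = fit_gls(y, env[use], coords, corr, response=f"{response}|{label}")
        reliable = reliable and fit.converged
        r2[label] = nagelkerke_r2(fit, null)
    if not reliable:
        logger.warning("partition for %s flagged unreliable: a subset fit "
                       "did not converge", response)
    fr = {
        "unique_T": r2["TSB"] - r2["SB"],
        "unique_S": r2["TSB"] - r2["TB"],
        "unique_B": r2["TSB"] - r2["TS"],
        "shared_TS": r2["TB"] + r2["SB"] - r2["B"] - r2["TSB"],
        "shared_TB": r2["TS"] + r2["SB"] - r2["S"] - r2["TSB"],
        "shared_SB": r2["TS"] + r2["TB"] - r2["T"] - r2["TSB"],
    }
    fr["shared_TSB"] = r2["TSB"] - sum(fr.values())
    return PartitionResult(r2=r2, fractions=fr, total=r2["TSB"], reliable=reliable)
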