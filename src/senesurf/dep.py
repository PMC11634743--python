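"""Differential-expression calling for senescent vs control comparisons.

A protein is a DEP (differentially expressed protein) for a comparison when
its fold change FC = mean(SEN)/mean(CTRL) satisfies FC >= 1.5 (up) or
FC <= 1/1.5 (down) AND the two-sided p-value is below 0.05. p-values come
from a Welch (unequal-variance) two-sample t-test on log2(PSM + pseudocount)
replicate values; no multiple-testing correction is applied by default,
mirroring the per-protein p < 0.05 rule, with Benjamini-Hochberg available
as an option.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .psm import PsmMatrix

DEP_COLUMNS = ["protein_id", "comparison_id", "fc", "log2fc", "p_value", "direction"]

__all__ = [
    "DEP_COLUMNS",
    "OverlapSummary",
    "test_protein",
    "call_deps",
    "intersect_deps",
    "percent",
    "comparison_id",
]


def comparison_id(cell_model: str, inducer: str) -> str:
    return f"{cell_model}|{inducer}"


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100*numerator/denominator, rounded half-away-from-zero.

    Python's built-in round() is banker's rounding; printed summary
    percentages use the conventional half-away-from-zero rule instead.
    """
    if decimals not in (0, 1):
        raise ValueError("decimals must be 0 or 1")
    if denominator == 0:
        raise ZeroDivisionError("percent() with zero denominator")
    x = 100.0 * numerator / denominator
    scale = 10.0**decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


def test_protein(
    sen_values, ctrl_values, pseudocount: float = 1.0
) -> tuple[float, float, float]:
    """Fold change and Welch-t p-value for one protein.

    FC is the ratio of group means on the PSM scale (after adding the
    pseudocount); the p-value is a two-sided Welch t-test on
    log2(value + pseudocount). Conventions for degenerate inputs: both
    groups constant and equal -> p = 1 (zero t statistic); both constant
    but different -> p is set to the machine floor with a warning (the t
    statistic is undefined at zero pooled variance).
    """
    sen = np.asarray(sen_values, dtype=float) + pseudocount
    ctrl = np.asarray(ctrl_values, dtype=float) + pseudocount
    if len(sen) < 2 or len(ctrl) < 2:
        raise ValueError("need >=2 replicates per group")
    if np.any(sen <= 0) or np.any(ctrl <= 0):
        raise ValueError("values must be positive after pseudocount")
    fc = sen.mean() / ctrl.mean()
    log2fc = float(np.log2(fc))
    ls, lc = np.log2(sen), np.log2(ctrl)
    if np.ptp(ls) == 0 and np.ptp(lc) == 0:  # both groups exactly constant
        if np.isclose(ls.mean(), lc.mean()):
            p = 1.0
        else:
            warnings.warn(
                "zero variance in both groups with different means; "
                "p set to the machine floor",
                stacklevel=2,
            )
            p = float(np.finfo(float).tiny)
    else:
        t, p = stats.ttest_ind(ls, lc, equal_var=False)
        p = 1.0 if np.isnan(p) else float(p)
    return float(fc), log2fc, p


def _direction(fc: np.ndarray, p: np.ndarray, fc_thr: float, p_thr: float) -> np.ndarray:
    direction = np.full(fc.shape, "none", dtype=object)
    direction[(fc >= fc_thr) & (p < p_thr)] = "up"
    direction[(fc <= 1.0 / fc_thr) & (p < p_thr)] = "down"
    return direction


def call_deps(
    matrix: PsmMatrix,
    comparison: tuple[str, str] | str,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    pseudocount: float = 1.0,
    adjust: str = "none",
) -> pd.DataFrame:
    """Call DEPs for one (cell_model, inducer) comparison.

    Returns a DepTable: one row per protein with fc, log2fc, p_value and
    direction in {up, down, none}. Thresholds are inclusive for FC
    (fc >= 1.5 counts as up) and strict for p (p < 0.05).
    """
    if isinstance(comparison, str):
        cell_model, inducer = comparison.split("|")
    else:
        cell_model, inducer = comparison
    if (cell_model, inducer) not in matrix.comparisons():
        raise KeyError(f"unknown comparison ({cell_model}, {inducer})")
    if matrix.n_missing:
        raise ValueError("call_deps requires a complete (imputed) matrix")

    sen_cols = matrix.samples_of(cell_model, inducer, "SEN")
    ctrl_cols = matrix.samples_of(cell_model, inducer, "CTRL")
    sen = matrix.values[sen_cols].to_numpy(dtype=float) + pseudocount
    ctrl = matrix.values[ctrl_cols].to_numpy(dtype=float) + pseudocount

    fc = sen.mean(axis=1) / ctrl.mean(axis=1)
    ls, lc = np.log2(sen), np.log2(ctrl)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(ls, lc, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    # zero-variance rows: equal means -> p=1; different means -> machine floor
    flat = np.isnan(p)
    if flat.any():
        same = np.isclose(ls[flat].mean(axis=1), lc[flat].mean(axis=1))
        fill = np.where(same, 1.0, np.finfo(float).tiny)
        p[flat] = fill

    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        p = multipletests(p, method="fdr_bh")[1]
    elif adjust != "none":
        raise ValueError("adjust must be 'none' or 'bh'")

    table = pd.DataFrame(
        {
            "protein_id": matrix.protein_ids,
            "comparison_id": comparison_id(cell_model, inducer),
            "fc": fc,
            "log2fc": np.log2(fc),
            "p_value": np.clip(p, np.finfo(float).tiny, 1.0),
            "direction": _direction(fc, p, fc_threshold, p_threshold),
        }
    ).reset_index(drop=True)
    return table


@dataclass
class OverlapSummary:
    """Intersection of DEP sets with directional concordance classes."""

    set_sizes: dict[str, int]
    intersection: set[str]
    concordance: dict[str, int]  # up / down / discordant, partitioning the intersection
    venn: dict[frozenset, int] = field(default_factory=dict)

    @property
    def n_intersection(self) -> int:
        return len(self.intersection)

    def percentages(self, decimals: int = 1) -> dict[str, float]:
        n = self.n_intersection
        if n == 0:
            return {k: 0.0 for k in self.concordance}
        return {k: percent(v, n, decimals) for k, v in self.concordance.items()}


def intersect_deps(
    dep_tables: list[pd.DataFrame], direction_filter: str | None = None
) -> OverlapSummary:
    """Intersect DEP sets across comparisons and classify concordance.

    A protein is in a table's DEP set when its direction is not 'none'
    (or matches ``direction_filter`` when given). Concordance over the
    intersection: up-in-all, down-in-all, or discordant. Venn region sizes
    are reported for up to 5 sets.
    """
    if len(dep_tables) < 2:
        raise ValueError("need >=2 DEP tables to intersect")
    sets: dict[str, set[str]] = {}
    directions: dict[str, dict[str, str]] = {}
    for t in dep_tables:
        cid = str(t["comparison_id"].iloc[0]) if len(t) else f"set{len(sets)}"
        dep = t[t["direction"] != "none"]
        if direction_filter is not None:
            dep = dep[dep["direction"] == direction_filter]
        sets[cid] = set(dep["protein_id"])
        directions[cid] = dict(zip(dep["protein_id"], dep["direction"]))

    inter = set.intersection(*sets.values()) if sets else set()
    conc = {"up": 0, "down": 0, "discordant": 0}
    for pid in inter:
        ds = {directions[cid][pid] for cid in sets}
        if ds == {"up"}:
            conc["up"] += 1
        elif ds == {"down"}:
            conc["down"] += 1
        else:
            conc["discordant"] += 1

    venn: dict[frozenset, int] = {}
    if len(sets) <= 5:
        names = list(sets)
        universe = set.union(*sets.values())
        for r in range(1, len(names) + 1):
            for combo in itertools.combinations(names, r):
                inside = set.intersection(*(sets[n] for n in combo))
                outside = set.union(
                    set(), *(sets[n] for n in names if n not in combo)
                )
                venn[frozenset(combo)] = len(inside - outside)
        assert sum(venn.values()) == len(universe)

    return OverlapSummary(
        set_sizes={k: len(v) for k, v in sets.items()},
        intersection=inter,
        concordance=conc,
        venn=venn,
    )
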