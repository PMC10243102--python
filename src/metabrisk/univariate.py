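"""Per-metabolite two-group screening and biomarker-panel construction.

Concentrations of plasma metabolites are not normally distributed, so each
metabolite is tested with the nonparametric Wilcoxon rank-sum (Mann-Whitney)
test; P-values are adjusted per comparison with the Benjamini-Hochberg
step-up procedure (the multiplicity family is the metabolite list of one
group pair). Fold changes (ratio of arithmetic group means, case over
control) describe the direction of each alteration. A biomarker panel is the
set of metabolites significant in *every* comparison of interest.

A descriptive stage-trend screen flags metabolites whose group means change
strictly monotonically across ordered disease stages; no test is attached
because stage-pair differences are typically too subtle for significance at
these sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profiles import ProfileMatrix

__all__ = [
    "UnivariateTable",
    "BiomarkerPanel",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "fold_change",
    "compare_groups",
    "panel_overlap",
    "stage_trend_screen",
]

#: Largest per-group size at which 'auto' mode uses exact enumeration.
EXACT_THRESHOLD = 20


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float], mode: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) P-value.

    ``exact`` enumerates the permutation distribution and refuses ties;
    ``approx`` uses the normal approximation with tie-corrected variance and
    continuity correction; ``auto`` picks exact when both groups have at most
    ``EXACT_THRESHOLD`` values and there are no ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if mode == "exact":
        if has_ties:
            raise ValueError("exact mode is undefined in the presence of ties")
        method = "exact"
    elif mode == "approx":
        method = "asymptotic"
    elif mode == "auto":
        small = a.size <= EXACT_THRESHOLD and b.size <= EXACT_THRESHOLD
        method = "exact" if (small and not has_ties) else "asymptotic"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(a: Sequence[float], b: Sequence[float]) -> float:
    """Ratio of arithmetic group means, oriented case (b) over control (a)."""
    ma = float(np.mean(np.asarray(a, dtype=float)))
    mb = float(np.mean(np.asarray(b, dtype=float)))
    if ma <= 0 or mb <= 0:
        raise ValueError("fold change requires strictly positive group means")
    return mb / ma


@dataclass
class UnivariateTable:
    """Per-metabolite statistics for one two-group comparison.

    Columns: metabolite, p_raw, p_adj, fold_change, direction
    (+1 if the case mean exceeds the control mean, -1 if lower, 0 if equal).
    """

    comparison: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"metabolite", "p_raw", "p_adj"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"table missing columns: {sorted(missing)}")

    @property
    def metabolites(self) -> list[str]:
        return [str(m) for m in self.table["metabolite"]]

    def significant(self, threshold: float = 0.05, adjusted: bool = True) -> set[str]:
        col = "p_adj" if adjusted else "p_raw"
        mask = self.table[col] < threshold
        return {str(m) for m in self.table.loc[mask, "metabolite"]}

    @classmethod
    def from_adjusted_pvalues(cls, comparison: str,
                              pvalues: Mapping[str, float]) -> "UnivariateTable":
        """Build a table from already-adjusted P-values (e.g. published values)."""
        df = pd.DataFrame(
            {
                "metabolite": list(pvalues),
                "p_raw": np.nan,
                "p_adj": [float(v) for v in pvalues.values()],
                "fold_change": np.nan,
                "direction": 0,
            }
        )
        return cls(comparison, df)

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "comparison", self.comparison)
        out.to_csv(path, index=False)


def compare_groups(m: ProfileMatrix, control: str, case: str,
                   mode: str = "auto") -> UnivariateTable:
    """Wilcoxon + BH + fold change for every metabolite, case vs control.

    The BH family is the full metabolite list of this one comparison.
    """
    sub = m.select_groups([control, case])
    va = sub.values[sub.groups == control].to_numpy(dtype=float)
    vb = sub.values[sub.groups == case].to_numpy(dtype=float)
    p_raw, fcs, direction = [], [], []
    for j in range(sub.n_metabolites):
        p_raw.append(wilcoxon_rank_sum(va[:, j], vb[:, j], mode=mode))
        fcs.append(fold_change(va[:, j], vb[:, j]))
        diff = vb[:, j].mean() - va[:, j].mean()
        direction.append(int(np.sign(diff)))
    df = pd.DataFrame(
        {
            "metabolite": sub.metabolite_names,
            "p_raw": p_raw,
            "p_adj": bh_adjust(p_raw),
            "fold_change": fcs,
            "direction": direction,
        }
    )
    return UnivariateTable(f"{control} vs {case}", df)


@dataclass(frozen=True)
class BiomarkerPanel:
    """Metabolites significant in every defining comparison."""

    metabolites: tuple[str, ...]
    comparisons: tuple[str, ...]
    threshold: float = 0.05

    def __len__(self) -> int:
        return len(self.metabolites)


def panel_overlap(tables: Sequence[UnivariateTable], threshold: float = 0.05,
                  adjusted: bool = True) -> BiomarkerPanel:
    """Intersection of the significant sets across comparisons.

    All tables must share the same metabolite universe.
    """
    if not tables:
        raise ValueError("need at least one comparison table")
    universe = set(tables[0].metabolites)
    for t in tables[1:]:
        if set(t.metabolites) != universe:
            raise ValueError(
                f"comparison {t.comparison!r} has a different metabolite universe"
            )
    common = universe
    for t in tables:
        common &= t.significant(threshold, adjusted=adjusted)
    # preserve the metabolite order of the first table
    ordered = tuple(m for m in tables[0].metabolites if m in common)
    return BiomarkerPanel(ordered, tuple(t.comparison for t in tables), threshold)


def stage_trend_screen(m: ProfileMatrix, stage_groups: Sequence[str]) -> pd.DataFrame:
    """Metabolites whose group means are strictly monotone across ordered stages.

    Purely descriptive: returns a DataFrame with columns ``metabolite`` and
    ``direction`` ("up" or "down" along the given stage order).
    """
    stage_groups = list(stage_groups)
    if len(stage_groups) < 3:
        raise ValueError("trend screening requires at least 3 stage groups")
    m.select_groups(stage_groups)  # validates the group names
    means = np.stack(
        [m.values[m.groups == g].to_numpy(dtype=float).mean(axis=0) for g in stage_groups]
    )
    rows = []
    for j, name in enumerate(m.metabolite_names):
        col = means[:, j]
        d = np.diff(col)
        if np.all(d > 0):
            rows.append((name, "up"))
        elif np.all(d < 0):
            rows.append((name, "down"))
    return pd.DataFrame(rows, columns=["metabolite", "direction"])
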