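"""Metabolite concentration tables: reading, validation, filtering, and scaling.

A :class:`ProfileMatrix` holds a samples x metabolites table of nonnegative
plasma metabolite concentrations with a group label per sample. The standard
preprocessing sequence is: drop contaminant metabolites, then normalise each
sample to total area (so every row sums to 1, removing plasma-dilution
differences), then centre/scale per metabolite before multivariate modelling.
The filter-then-normalise order matters and is fixed: normalising first would
let excluded contaminants distort every remaining fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProfileMatrix",
    "ScaledMatrix",
    "ProfileValidationError",
    "read_profiles",
    "exclude_metabolites",
    "normalize_total_area",
    "scale",
    "DEFAULT_EXCLUSIONS",
]

#: Contaminant metabolites removed before statistical analysis: glycerol
#: leaches from ultrafiltration membranes and propylene glycol is an
#: environmental contaminant.
DEFAULT_EXCLUSIONS = ("Glycerol", "Propylene glycol")

_ROW_SUM_TOL = 1e-9


class ProfileValidationError(ValueError):
    """Raised when a concentration table violates its invariants."""


@dataclass
class ProfileMatrix:
    """Samples x metabolites concentration table with per-sample group labels.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, one column per metabolite, all
        entries nonnegative finite reals.
    groups
        Series of group labels aligned with ``values.index``.
    normalized
        True once rows have been normalised to unit total area.
    """

    values: pd.DataFrame
    groups: pd.Series
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        self.groups = pd.Series(self.groups)
        idx = self.values.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ProfileValidationError(f"duplicate sample ids: {dups}")
        cols = self.values.columns
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ProfileValidationError(f"duplicate metabolite names: {dups}")
        if not self.groups.index.equals(idx):
            self.groups = self.groups.reindex(idx)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()].tolist()
            raise ProfileValidationError(f"missing group label for samples: {missing}")
        arr = self.values.to_numpy(dtype=float)
        bad = ~np.isfinite(arr)
        if bad.any():
            raise ProfileValidationError(
                f"missing or non-finite values at cells: {self._cells(bad)}"
            )
        neg = arr < 0
        if neg.any():
            raise ProfileValidationError(
                f"negative concentrations at cells: {self._cells(neg)}"
            )
        if self.normalized:
            sums = arr.sum(axis=1)
            off = np.abs(sums - 1.0) > _ROW_SUM_TOL
            if off.any():
                raise ProfileValidationError(
                    "normalized flag set but row sums deviate from 1 for samples: "
                    f"{list(idx[off])}"
                )

    def _cells(self, mask: np.ndarray) -> list[tuple[str, str]]:
        rows, cols = np.nonzero(mask)
        return [
            (str(self.values.index[r]), str(self.values.columns[c]))
            for r, c in zip(rows[:10], cols[:10])
        ]

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.index]

    @property
    def metabolite_names(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def group_counts(self) -> dict[str, int]:
        return self.groups.value_counts().to_dict()

    def select_groups(self, names: Iterable[str]) -> "ProfileMatrix":
        """Subset to samples belonging to the given groups (order preserved)."""
        names = list(names)
        unknown = set(names) - set(self.groups.unique())
        if unknown:
            raise ProfileValidationError(f"unknown group name(s): {sorted(unknown)}")
        mask = self.groups.isin(names)
        return ProfileMatrix(
            self.values.loc[mask].copy(), self.groups.loc[mask].copy(), self.normalized
        )

    def copy(self) -> "ProfileMatrix":
        return ProfileMatrix(self.values.copy(), self.groups.copy(), self.normalized)

    def to_csv(self, path: str | Path) -> None:
        """Write as CSV with columns ``sample_id, group, <metabolites...>``."""
        out = self.values.copy()
        out.insert(0, "group", self.groups)
        out.index.name = "sample_id"
        out.to_csv(path)

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        out.insert(0, "group", self.groups)
        out.index.name = "sample_id"
        return out


def read_profiles(path: str | Path, sep: str = ",") -> ProfileMatrix:
    """Read a delimited concentration table into a validated ProfileMatrix.

    Expected layout: header row; first column ``sample_id``, second column
    ``group``, remaining columns metabolite concentrations. Missing or
    negative cells and duplicate sample ids are rejected with an error
    naming the offending cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    if df.shape[1] < 3 or df.columns[0] != "sample_id" or df.columns[1] != "group":
        raise ProfileValidationError(
            "expected header starting with 'sample_id,group', got "
            f"{list(df.columns[:2])}"
        )
    df = df.set_index("sample_id")
    groups = df["group"].astype(str)
    values = df.drop(columns=["group"]).apply(pd.to_numeric, errors="coerce")
    return ProfileMatrix(values, groups)


def exclude_metabolites(m: ProfileMatrix, names: Sequence[str]) -> ProfileMatrix:
    """Drop the named metabolite columns, preserving the order of the rest."""
    unknown = [n for n in names if n not in m.values.columns]
    if unknown:
        raise ProfileValidationError(f"cannot exclude unknown metabolite(s): {unknown}")
    if not names:
        return m.copy()
    # dropping columns breaks the unit row-sum invariant, so the result is
    # no longer normalized even if the input was
    return ProfileMatrix(m.values.drop(columns=list(names)), m.groups.copy(), False)


def normalize_total_area(m: ProfileMatrix) -> ProfileMatrix:
    """Divide each sample's concentrations by their sum (total-area normalisation).

    Idempotent, and invariant to per-sample dilution (multiplying a row by a
    positive constant leaves the result unchanged).
    """
    arr = m.values.to_numpy(dtype=float)
    sums = arr.sum(axis=1)
    if (sums <= 0).any():
        bad = [m.sample_ids[i] for i in np.nonzero(sums <= 0)[0]]
        raise ProfileValidationError(f"nonpositive row sum for samples: {bad}")
    vals = pd.DataFrame(arr / sums[:, None], index=m.values.index, columns=m.values.columns)
    return ProfileMatrix(vals, m.groups.copy(), normalized=True)


@dataclass
class ScaledMatrix:
    """Column-centred/scaled data with the parameters needed to scale new samples.

    ``transform`` applies the stored centre/scale to new rows so that held-out
    or external samples are projected with the training-set parameters.
    """

    values: np.ndarray
    center: np.ndarray
    scale_: np.ndarray
    method: str
    metabolite_names: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def transform(self, x: "pd.DataFrame | np.ndarray") -> np.ndarray:
        if isinstance(x, pd.DataFrame):
            if list(x.columns) != list(self.metabolite_names):
                raise ProfileValidationError(
                    "metabolite columns do not match scaling parameters"
                )
            x = x.to_numpy(dtype=float)
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.center.shape[0]:
            raise ProfileValidationError(
                f"expected {self.center.shape[0]} metabolites, got {x.shape[-1]}"
            )
        return (x - self.center) / self.scale_


_SCALING_METHODS = ("center", "unit-variance", "pareto")


def scale(m: "ProfileMatrix | pd.DataFrame", method: str = "unit-variance") -> ScaledMatrix:
    """Centre (and optionally scale) each metabolite column.

    Methods: ``center`` (mean-centre only), ``unit-variance`` (autoscale:
    centre and divide by the sample standard deviation, n-1 denominator) and
    ``pareto`` (divide by the square root of the standard deviation). The
    scaled matrix records the per-metabolite parameters so external samples
    can be projected consistently.
    """
    if method not in _SCALING_METHODS:
        raise ValueError(f"unknown scaling method {method!r}; choose from {_SCALING_METHODS}")
    if isinstance(m, ProfileMatrix):
        df = m.values
        sample_ids = m.sample_ids
    else:
        df = pd.DataFrame(m)
        sample_ids = [str(i) for i in df.index]
    arr = df.to_numpy(dtype=float)
    if arr.shape[0] < 2:
        raise ProfileValidationError("scaling requires at least 2 samples")
    center = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    if method == "center":
        scl = np.ones_like(sd)
    else:
        zero = sd == 0
        if zero.any():
            names = [str(df.columns[i]) for i in np.nonzero(zero)[0]]
            raise ProfileValidationError(
                f"zero-variance metabolite(s) cannot be scaled: {names}"
            )
        scl = sd if method == "unit-variance" else np.sqrt(sd)
    return ScaledMatrix(
        values=(arr - center) / scl,
        center=center,
        scale_=scl,
        method=method,
        metabolite_names=[str(c) for c in df.columns],
        sample_ids=sample_ids,
    )
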