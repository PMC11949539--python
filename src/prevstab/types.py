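"""Core data containers for prevalence stability analysis.

The analysis operates on a *wide* presence/absence table: one row per
sampled unit (e.g. a coral colony or a habitat), a grouping label per row
(host species, site, ...), and one binary column per target species.
Missing entries (unscored units) are allowed and shrink the effective
sample size of the affected (group, species) pair.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ValidationReport",
    "StabilityParams",
    "OccurrenceTable",
    "PrevalenceCurve",
    "StabilityResult",
]


@dataclasses.dataclass(frozen=True)
class ValidationReport:
    """Outcome of validating an occurrence table.

    ``issues`` holds ``(row, column, message)`` triples where ``row`` is the
    1-based data-row index (header excluded) and ``column`` the column name.
    """

    issues: tuple[tuple[int, str, str], ...] = ()

    @property
    def ok(self) -> bool:
        return not self.issues

    def __str__(self) -> str:
        if self.ok:
            return "validation passed"
        lines = [f"row {r}, column {c!r}: {m}" for r, c, m in self.issues]
        return f"{len(self.issues)} validation issue(s):\n" + "\n".join(lines)


class ValidationError(ValueError):
    """Raised when an input table violates the presence/absence contract."""

    def __init__(self, report: ValidationReport, message: str | None = None):
        self.report = report
        super().__init__(message or str(report))


@dataclasses.dataclass(frozen=True)
class StabilityParams:
    """Resampling and stability-detector parameters.

    Parameters
    ----------
    n_replicates
        Number of independent random subsamples averaged at each subsample
        size k (the method's *n*; default 50).
    successive_points
        Number of successive curve means the flatness window spans (the
        method's *x*; default 10).
    mean_diff_threshold
        Threshold *y*, in percentage points, on each within-window
        successive difference; compared against ``y / sqrt(k)``.
    delta_threshold
        Threshold *z*, in percentage points, on the range (max - min) of the
        window means (the window's delta).
    seed
        Base seed for all randomness; ``None`` means non-reproducible
        entropy from the OS.
    """

    n_replicates: int = 50
    successive_points: int = 10
    mean_diff_threshold: float = 2.0
    delta_threshold: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.n_replicates, (int, np.integer)) or self.n_replicates < 1:
            raise ValueError(f"n_replicates must be a positive integer, got {self.n_replicates!r}")
        if not isinstance(self.successive_points, (int, np.integer)) or self.successive_points < 2:
            raise ValueError(
                f"successive_points must be an integer >= 2, got {self.successive_points!r}"
            )
        if not (self.mean_diff_threshold > 0):
            raise ValueError("mean_diff_threshold must be strictly positive")
        if not (self.delta_threshold > 0):
            raise ValueError("delta_threshold must be strictly positive")
        if self.seed is not None and not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer or None")


def _check_binary(values: np.ndarray) -> None:
    finite = values[~np.isnan(values)]
    bad = finite[(finite != 0.0) & (finite != 1.0)]
    if bad.size:
        raise ValueError(f"occurrence values must be 0, 1 or missing; found {bad[:5]!r}")


@dataclasses.dataclass(frozen=True)
class OccurrenceTable:
    """Validated wide-format presence/absence table.

    ``values`` is a float matrix with entries 0.0, 1.0 or NaN (missing);
    ``groups`` carries one label per row; ``species_names`` one name per
    column, in file order.
    """

    groups: tuple[str, ...]
    species_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 2 or vals.shape[0] < 1 or vals.shape[1] < 1:
            raise ValueError("occurrence table needs at least one row and one species column")
        if len(self.groups) != vals.shape[0]:
            raise ValueError("one group label required per row")
        if len(self.species_names) != vals.shape[1]:
            raise ValueError("one species name required per column")
        if any((not isinstance(g, str)) or not g.strip() for g in self.groups):
            raise ValueError("group labels must be non-empty strings")
        if len(set(self.species_names)) != len(self.species_names):
            raise ValueError("duplicate species column names")
        _check_binary(vals)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def group_order(self) -> tuple[str, ...]:
        """Groups in order of first appearance."""
        return tuple(dict.fromkeys(self.groups))

    def column(self, group: str, species: str) -> np.ndarray:
        """Rows of ``group`` for ``species`` (may contain NaN)."""
        j = self.species_names.index(species)
        mask = np.array([g == group for g in self.groups])
        if not mask.any():
            raise KeyError(f"no rows for group {group!r}")
        return self.values[mask, j]

    def k_max(self, group: str, species: str) -> int:
        """Number of scored (non-missing) units for a (group, species) pair."""
        col = self.column(group, species)
        return int(np.sum(~np.isnan(col)))

    def pairs(self) -> Iterator[tuple[str, str]]:
        """(group, species) pairs: groups by first appearance, species in column order."""
        for g in self.group_order():
            for s in self.species_names:
                yield g, s

    def to_dataframe(self, group_column: str = "group") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.species_names))
        df.insert(0, group_column, list(self.groups))
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, group_column: str | int | None = None) -> "OccurrenceTable":
        if group_column is None:
            group_column = 0
        if isinstance(group_column, int):
            gname = df.columns[group_column]
        else:
            if group_column not in df.columns:
                raise KeyError(f"group column {group_column!r} not in table")
            gname = group_column
        groups = tuple(str(g).strip() for g in df[gname])
        species = tuple(str(c) for c in df.columns if c != gname)
        values = df[list(species)].to_numpy(dtype=float)
        return cls(groups=groups, species_names=species, values=values)


@dataclasses.dataclass(frozen=True)
class PrevalenceCurve:
    """Mean prevalence (percent) as a function of subsample size k.

    ``means[k-1]`` is the average, over ``n_replicates`` random
    without-replacement subsamples of size k, of the subsample's proportion
    of presences, times 100. By construction ``means[-1]`` equals the
    full-sample (observed) prevalence exactly.
    """

    group: str
    species: str
    k_max: int
    means: np.ndarray
    observed_prevalence: float
    n_replicates: int
    resampling: str = "cumulative"

    def __post_init__(self) -> None:
        m = np.asarray(self.means, dtype=float)
        object.__setattr__(self, "means", m)
        if m.ndim != 1 or m.size != self.k_max or self.k_max < 1:
            raise ValueError("means must be a 1-D array of length k_max >= 1")
        if np.any((m < 0) | (m > 100)):
            raise ValueError("prevalence means must lie in [0, 100]")


@dataclasses.dataclass(frozen=True)
class StabilityResult:
    """Verdict of the windowed stability detector for one (group, species) pair.

    ``stability_point`` is the minimum number of samples at which the
    prevalence curve satisfies the flatness criterion (the last index of the
    first qualifying window), or ``None`` when the criterion is never met —
    the "na" verdict meaning sampling effort is insufficient.
    """

    group: str
    species: str
    stability_point: int | None
    estimated_prevalence: float
    tail_prevalence: float
    k_max: int
    params: StabilityParams
    window_delta: float = math.nan
    note: str = ""

    def __post_init__(self) -> None:
        if self.stability_point is not None:
            if not (1 <= self.stability_point <= self.k_max):
                raise ValueError("stability_point must lie in [1, k_max]")
            if not (self.window_delta < self.params.delta_threshold):
                raise ValueError("accepted window delta must be below the delta threshold")

    @property
    def is_na(self) -> bool:
        return self.stability_point is None
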