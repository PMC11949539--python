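"""CSV input/output for occurrence tables and stability results.

Occurrence input is wide-format delimited text with a header: column 1 (by
default) holds the grouping label, every other column one species, cells
``0``, ``1`` or empty (missing). Result output is a tidy CSV, one row per
(group, species) pair, with the "na" verdict spelled literally.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import OccurrenceTable, StabilityResult, ValidationError, ValidationReport

__all__ = [
    "read_occurrence_csv",
    "write_results_csv",
    "read_results_csv",
    "make_fixture_table",
    "RESULT_COLUMNS",
]

_MISSING_TOKENS = {"", "na", "n/a", "nan"}

RESULT_COLUMNS = [
    "group",
    "species",
    "k_max",
    "stability_point",
    "estimated_prevalence",
    "tail_prevalence",
    "n_replicates",
    "successive_points",
    "mean_diff_threshold",
    "delta_threshold",
    "seed",
]


def _parse_cell(raw: str) -> float:
    """'' / na -> NaN; 0/1 (or 0.0/1.0) -> float; anything else -> ValueError."""
    s = raw.strip()
    if s.lower() in _MISSING_TOKENS:
        return math.nan
    try:
        v = float(s)
    except ValueError:
        raise ValueError(f"not a binary value: {raw!r}")
    if v not in (0.0, 1.0):
        raise ValueError(f"not a binary value: {raw!r}")
    return v


def read_occurrence_csv(
    path: str | Path,
    group_column: str | int | None = None,
    *,
    delimiter: str = ",",
) -> OccurrenceTable:
    """Read and validate a wide presence/absence CSV.

    ``group_column`` may be a column name or 0-based position; default is
    the first column. Empty cells (and ``na``/``NA``) become missing. Any
    other non-binary cell is collected into a :class:`ValidationError`
    naming the offending row and column.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter=delimiter))
    if not rows:
        raise ValidationError(ValidationReport(((0, "", "file is empty"),)))
    header = [h.strip() for h in rows[0]]
    data_rows = [r for r in rows[1:] if any(c.strip() for c in r)]
    if not data_rows:
        raise ValidationError(ValidationReport(((0, "", "no data rows"),)))

    if group_column is None:
        group_column = 0
    if isinstance(group_column, int):
        if not 0 <= group_column < len(header):
            raise ValidationError(
                ValidationReport(((0, str(group_column), "group column position out of range"),))
            )
        gidx = group_column
    else:
        if group_column not in header:
            raise ValidationError(
                ValidationReport(((0, group_column, "group column not found in header"),))
            )
        gidx = header.index(group_column)

    species = [h for i, h in enumerate(header) if i != gidx]
    dup = {s for s in species if species.count(s) > 1}
    if dup:
        raise ValidationError(
            ValidationReport(tuple((0, s, "duplicate species column name") for s in sorted(dup)))
        )
    if not species:
        raise ValidationError(ValidationReport(((0, "", "no species columns"),)))

    issues: list[tuple[int, str, str]] = []
    groups: list[str] = []
    values = np.full((len(data_rows), len(species)), math.nan)
    for i, row in enumerate(data_rows, start=1):
        row = list(row) + [""] * (len(header) - len(row))
        g = row[gidx].strip()
        if not g:
            issues.append((i, header[gidx], "empty group label"))
        groups.append(g or "?")
        j = 0
        for ci, cell in enumerate(row[: len(header)]):
            if ci == gidx:
                continue
            try:
                values[i - 1, j] = _parse_cell(cell)
            except ValueError as exc:
                issues.append((i, header[ci], str(exc)))
            j += 1
    if issues:
        raise ValidationError(ValidationReport(tuple(issues)))
    return OccurrenceTable(groups=tuple(groups), species_names=tuple(species), values=values)


def _fmt_point(sp: int | None) -> str:
    return "na" if sp is None else str(sp)


def _fmt_float(v: float) -> str:
    return "na" if (v is None or (isinstance(v, float) and math.isnan(v))) else repr(float(v))


def write_results_csv(results: Sequence[StabilityResult], path: str | Path) -> Path:
    """Write one tidy row per result; NA verdicts are rendered as ``na``."""
    if not results:
        raise ValueError("no results to write")
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(RESULT_COLUMNS)
        for r in results:
            p = r.params
            w.writerow(
                [
                    r.group,
                    r.species,
                    r.k_max,
                    _fmt_point(r.stability_point),
                    _fmt_float(r.estimated_prevalence),
                    _fmt_float(r.tail_prevalence),
                    p.n_replicates,
                    p.successive_points,
                    repr(float(p.mean_diff_threshold)),
                    repr(float(p.delta_threshold)),
                    "" if p.seed is None else p.seed,
                ]
            )
    return path


def read_results_csv(path: str | Path) -> pd.DataFrame:
    """Read a results CSV back; ``na`` becomes NaN, numerics are typed."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("stability_point", "estimated_prevalence", "tail_prevalence"):
        df[col] = pd.to_numeric(df[col], errors="coerce")  # "na" -> NaN
    for col in ("k_max", "n_replicates", "successive_points"):
        df[col] = df[col].astype(int)
    for col in ("mean_diff_threshold", "delta_threshold"):
        df[col] = df[col].astype(float)
    df["seed"] = pd.to_numeric(df["seed"], errors="coerce")
    return df


def make_fixture_table(
    spec: Sequence[tuple[str, str, int, int]],
    seed: int | None = None,
) -> OccurrenceTable:
    """Build a synthetic occurrence table with exact per-pair totals.

    ``spec`` lists ``(group, species, k_max, count_of_ones)`` entries. For
    each group the number of rows is the largest ``k_max`` among its
    species; species scored on fewer units get missing entries in the
    remaining rows, at shuffled positions. Species a group's spec omits
    are entirely missing for that group.
    """
    if not spec:
        raise ValueError("fixture spec is empty")
    seen = set()
    for group, species, k_max, ones in spec:
        if k_max < 1:
            raise ValueError(f"k_max must be >= 1 for ({group!r}, {species!r})")
        if not 0 <= ones <= k_max:
            raise ValueError(
                f"count_of_ones must lie in [0, k_max] for ({group!r}, {species!r})"
            )
        if (group, species) in seen:
            raise ValueError(f"duplicate spec entry for ({group!r}, {species!r})")
        seen.add((group, species))

    groups_order = list(dict.fromkeys(g for g, *_ in spec))
    species_order = list(dict.fromkeys(s for _, s, *_ in spec))
    rng = np.random.default_rng(seed)

    blocks = []
    labels: list[str] = []
    for g in groups_order:
        entries = [(s, k, o) for gg, s, k, o in spec if gg == g]
        n_rows = max(k for _, k, _ in entries)
        block = np.full((n_rows, len(species_order)), math.nan)
        for s, k, o in entries:
            col = np.full(n_rows, math.nan)
            scored = np.concatenate([np.ones(o), np.zeros(k - o), np.full(n_rows - k, math.nan)])
            col[:] = scored[rng.permutation(n_rows)]
            block[:, species_order.index(s)] = col
        blocks.append(block)
        labels.extend([g] * n_rows)
    return OccurrenceTable(
        groups=tuple(labels),
        species_names=tuple(species_order),
        values=np.vstack(blocks),
    )
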