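"""Reading, validating and aggregating long-format survey tables.

Three record schemas are supported, mirroring a spatially replicated
pollination survey (M sites, each a gridded plot surveyed over R rounds per
year for T years):

* ``flowers``  — per-round flower counts per plant species per subplot;
* ``visits``   — per-round pollinator visits per plant x pollinator pair;
* ``fruitset`` — per-individual fruits produced / flowers marked.

Tables are aggregated into dense :class:`MetacommunityTensor` arrays
indexed ``[unit, patch, time]`` where the "unit" is a plant species, a
pollinator species, or a plant-pollinator pair depending on the variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCHEMAS: dict[str, list[str]] = {
    "flowers": ["year", "round", "site", "subplot", "plant", "count"],
    "visits": ["year", "round", "site", "subplot", "plant", "pollinator", "visits"],
    "fruitset": ["year", "site", "plant", "individual", "flowers_marked", "fruits"],
}

#: columns holding observation values (not keys) per table kind
VALUE_COLUMNS: dict[str, list[str]] = {
    "flowers": ["count"],
    "visits": ["visits"],
    "fruitset": ["flowers_marked", "fruits"],
}

VARIABLES = (
    "flower_availability",
    "visitation_rate",
    "interaction_frequency",
    "fruit_set",
)


class SchemaError(ValueError):
    """Input table does not match the expected column schema."""


class ValidationError(ValueError):
    """Input table violates a value constraint (negative count, etc.)."""


@dataclass(frozen=True)
class SurveyTable:
    """A validated long-format survey table.

    Attributes
    ----------
    kind:
        One of ``flowers``, ``visits``, ``fruitset``.
    data:
        Records with the schema of ``kind``; key combinations are unique
        (duplicates have been merged by summation).
    n_merged:
        Number of raw rows that were collapsed into existing keys.
    """

    kind: str
    data: pd.DataFrame
    n_merged: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SCHEMAS:
            raise SchemaError(f"unknown table kind {self.kind!r}")

    @property
    def years(self) -> list:
        return sorted(self.data["year"].unique())

    @property
    def sites(self) -> list:
        return sorted(self.data["site"].unique())

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class MetacommunityTensor:
    """Dense nonnegative array ``values[unit, patch, time]`` plus labels.

    ``observed`` marks cells backed by data. For count-like variables every
    cell is observed (an absent species-site-year is a true zero). For
    fruit set, a cell with no marked individuals is *missing*, not zero,
    and is masked out.
    """

    values: np.ndarray
    unit_labels: list
    patch_labels: list
    time_labels: list
    variable: str
    observed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("tensor must be 3-D (unit, patch, time)")
        u, k, t = self.values.shape
        if (u, k, t) != (len(self.unit_labels), len(self.patch_labels), len(self.time_labels)):
            raise ValueError("label lengths do not match tensor shape")
        if u < 1 or k < 1:
            raise ValueError("need at least 1 unit and 1 patch")
        if t < 2:
            raise ValueError("temporal dimension < 2")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("tensor values must be finite and nonnegative")
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}")
        if self.observed is not None:
            self.observed = np.asarray(self.observed, dtype=bool)
            if self.observed.shape != self.values.shape:
                raise ValueError("observed mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def _validate_frame(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    cols = SCHEMAS[kind]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{kind} table is missing required column(s): {', '.join(missing)}"
        )
    df = df[cols].copy()
    for c in VALUE_COLUMNS[kind]:
        bad = df.index[~np.isfinite(pd.to_numeric(df[c], errors="coerce"))]
        if len(bad):
            raise ValidationError(f"non-numeric {c!r} at row {bad[0]}")
        df[c] = pd.to_numeric(df[c])
        neg = df.index[df[c] < 0]
        if len(neg):
            raise ValidationError(f"negative {c!r} at row {neg[0]}")
    if kind == "fruitset":
        zero = df.index[df["flowers_marked"] < 1]
        if len(zero):
            raise ValidationError(f"flowers_marked < 1 at row {zero[0]}")
        over = df.index[df["fruits"] > df["flowers_marked"]]
        if len(over):
            raise ValidationError(f"fruits > flowers_marked at row {over[0]}")
    return df


def _merge_duplicates(df: pd.DataFrame, kind: str) -> tuple[pd.DataFrame, int]:
    value_cols = VALUE_COLUMNS[kind]
    key_cols = [c for c in SCHEMAS[kind] if c not in value_cols]
    n_raw = len(df)
    merged = df.groupby(key_cols, as_index=False, sort=True)[value_cols].sum()
    n_merged = n_raw - len(merged)
    if n_merged:
        logger.info("%s table: summed %d duplicate-key row(s)", kind, n_merged)
    return merged, n_merged


def survey_table_from_frame(df: pd.DataFrame, kind: str) -> SurveyTable:
    """Validate an in-memory DataFrame and wrap it as a :class:`SurveyTable`.

    Duplicate keys are merged by summing their value columns (field sheets
    legitimately split one observation over several rows); the number of
    merged rows is recorded and logged.
    """
    if kind not in SCHEMAS:
        raise SchemaError(f"unknown table kind {kind!r}")
    df = _validate_frame(df, kind)
    merged, n_merged = _merge_duplicates(df, kind)
    return SurveyTable(kind=kind, data=merged, n_merged=n_merged)


def read_survey_table(path, kind: str) -> SurveyTable:
    """Read a CSV survey table of the given kind, validating as we go."""
    df = pd.read_csv(path)
    return survey_table_from_frame(df, kind)


def write_survey_table(table: SurveyTable, path) -> None:
    table.data.to_csv(path, index=False)


def _pivot_dense(
    df: pd.DataFrame, unit_col, value_col: str, agg: str
) -> tuple[np.ndarray, list, list, list]:
    """Aggregate to one value per (unit, site, year), zero-filling the full
    cartesian grid of the globally observed unit/site/year universes."""
    if isinstance(unit_col, list):
        df = df.assign(_unit=list(zip(*(df[c] for c in unit_col))))
        unit_col = "_unit"
    grouped = df.groupby([unit_col, "site", "year"])[value_col].agg(agg)
    units = sorted(df[unit_col].unique())
    sites = sorted(df["site"].unique())
    years = sorted(df["year"].unique())
    full = grouped.reindex(
        pd.MultiIndex.from_product([units, sites, years]), fill_value=0.0
    )
    values = full.to_numpy(dtype=float).reshape(len(units), len(sites), len(years))
    return values, units, sites, years


def build_tensor(
    table: SurveyTable, variable: str, annualize: str = "sum"
) -> MetacommunityTensor:
    """Aggregate a count table into a ``[unit, site, year]`` tensor.

    Subplots and sampling rounds are collapsed to a single value per
    (unit, site, year). With ``annualize="sum"`` the annual value is the
    total over the R rounds; with ``"mean"`` it is that total divided by
    the number of distinct rounds in the table (a per-round average).
    The unit universe is the union of units seen in any site-year; absent
    combinations are true zeros for count variables.

    The unit depends on ``variable``: plant species for
    ``flower_availability``, pollinator species for ``visitation_rate``
    (visits summed over the plants they were made on), and the
    (plant, pollinator) pair for ``interaction_frequency``.
    """
    kind_for = {
        "flower_availability": "flowers",
        "visitation_rate": "visits",
        "interaction_frequency": "visits",
    }
    if variable not in kind_for:
        raise ValueError(
            f"build_tensor handles count variables, not {variable!r}; "
            "use aggregate_fruitset for fruit set"
        )
    if table.kind != kind_for[variable]:
        raise ValueError(
            f"variable {variable!r} requires a {kind_for[variable]!r} table, "
            f"got {table.kind!r}"
        )
    if annualize not in ("sum", "mean"):
        raise ValueError("annualize must be 'sum' or 'mean'")
    df = table.data
    if df["year"].nunique() < 2:
        raise ValueError("temporal dimension < 2")

    if variable == "flower_availability":
        unit_col, value_col = "plant", "count"
    elif variable == "visitation_rate":
        unit_col, value_col = "pollinator", "visits"
    else:
        unit_col, value_col = ["plant", "pollinator"], "visits"

    values, units, sites, years = _pivot_dense(df, unit_col, value_col, "sum")
    if annualize == "mean":
        values = values / df["round"].nunique()
    return MetacommunityTensor(
        values=values,
        unit_labels=units,
        patch_labels=sites,
        time_labels=years,
        variable=variable,
    )


def aggregate_fruitset(
    table: SurveyTable, mode: str = "pooled"
) -> MetacommunityTensor:
    """Aggregate per-individual fruit-set records to population cells.

    ``pooled`` (default) divides total fruits by total flowers marked per
    (plant, site, year); ``individual_mean`` averages the per-individual
    proportions unweighted. Cells with no marked individuals are flagged
    as missing (masked), not zero-filled: an unmeasured fruit set is
    unknown, unlike an uncensused flower count.
    """
    if table.kind != "fruitset":
        raise ValueError(f"expected a fruitset table, got {table.kind!r}")
    if mode not in ("pooled", "individual_mean"):
        raise ValueError("mode must be 'pooled' or 'individual_mean'")
    df = table.data
    if df.empty:
        raise ValueError("empty fruit-set table")
    if df["year"].nunique() < 2:
        raise ValueError("temporal dimension < 2")

    if mode == "pooled":
        grouped = df.groupby(["plant", "site", "year"]).apply(
            lambda g: g["fruits"].sum() / g["flowers_marked"].sum(),
            include_groups=False,
        )
    else:
        grouped = (
            df.assign(prop=df["fruits"] / df["flowers_marked"])
            .groupby(["plant", "site", "year"])["prop"]
            .mean()
        )
    units = sorted(df["plant"].unique())
    sites = sorted(df["site"].unique())
    years = sorted(df["year"].unique())
    idx = pd.MultiIndex.from_product([units, sites, years])
    full = grouped.reindex(idx)
    shape = (len(units), len(sites), len(years))
    observed = full.notna().to_numpy().reshape(shape)
    values = full.fillna(0.0).to_numpy(dtype=float).reshape(shape)
    n_missing = int((~observed).sum())
    if n_missing:
        logger.warning(
            "fruit set: %d plant-site-year cell(s) have no marked individuals; "
            "flagged missing (excluded from the partition)",
            n_missing,
        )
    return MetacommunityTensor(
        values=values,
        unit_labels=units,
        patch_labels=sites,
        time_labels=years,
        variable="fruit_set",
        observed=observed,
    )


def write_tidy(rows: pd.DataFrame, path) -> None:
    """Write a long-format ``variable,level,component,value`` results table."""
    expected = ["variable", "level", "component", "value"]
    rows = rows[expected]
    rows.to_csv(path, index=False)
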