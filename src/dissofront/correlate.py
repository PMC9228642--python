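"""Per-formulation property table and rate-vs-kinetics linear correlations."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dissolution import MechanismCall
from .errors import DegenerateDataError, InsufficientPointsError
from .rates import ReplicateSummary

__all__ = ["CorrelationResult", "linear_correlation", "build_property_table"]


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    slope: float
    intercept: float
    r_squared: float
    n_used: int
    excluded_ids: list[str] = field(default_factory=list)


def linear_correlation(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """OLS slope/intercept plus squared Pearson correlation of paired values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise InsufficientPointsError("insufficient pairs")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("ND entries not allowed; filter first")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise DegenerateDataError("degenerate predictor")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    syy = float(np.sum((y - y.mean()) ** 2))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    r_squared = 0.0 if syy == 0 else (sxy * sxy) / (sxx * syy)
    return CorrelationResult(
        x_name=x_name,
        y_name=y_name,
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        n_used=int(x.size),
    )


def build_property_table(
    rates: list[ReplicateSummary],
    mechanisms: list[tuple[str, MechanismCall]] | dict[str, MechanismCall] | None = None,
    dt: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Join rate summaries, dissolution rates and DT into one row per formulation.

    Columns are ``{kind}_rate_{medium}`` plus ``dissolution_rate_k`` and
    ``dt_{medium}``; missing entries are NaN (ND).  Formulations present in
    only some sources are retained with a warning.
    """
    rows: dict[str, dict[str, float]] = {}

    def _row(fid: str) -> dict[str, float]:
        return rows.setdefault(fid, {})

    seen_rate_keys: set[tuple[str, str, str]] = set()
    for rs in rates:
        key = (rs.formulation_id, rs.medium, rs.kind)
        if key in seen_rate_keys:
            raise ValueError(f"duplicate key: {key}")
        seen_rate_keys.add(key)
        _row(rs.formulation_id)[f"{rs.kind}_rate_{rs.medium}"] = rs.mean_rate

    if mechanisms:
        items = mechanisms.items() if isinstance(mechanisms, dict) else mechanisms
        seen_m: set[str] = set()
        for fid, call in items:
            if fid in seen_m:
                raise ValueError(f"duplicate key: {fid}")
            seen_m.add(fid)
            _row(fid)["dissolution_rate_k"] = call.dissolution_rate_k

    if dt:
        for fid, per_medium in dt.items():
            for medium, value in per_medium.items():
                _row(fid)[f"dt_{medium}"] = value

    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "formulation_id"
    incomplete = table.index[table.isna().any(axis=1)].tolist()
    if incomplete:
        warnings.warn(f"formulations with ND entries: {incomplete}", stacklevel=2)
    return table


def correlate_columns(
    table: pd.DataFrame,
    x_col: str,
    y_col: str,
    exclude_zero_x: bool = True,
) -> CorrelationResult:
    """Correlate two property-table columns, dropping ND rows.

    ``exclude_zero_x`` drops formulations whose predictor is exactly 0
    (e.g. total non-wetting), which would otherwise anchor the regression
    with a point the process never generated.
    """
    sub = table[[x_col, y_col]].dropna()
    excluded = sorted(set(table.index) - set(sub.index))
    if exclude_zero_x:
        zero = sub.index[sub[x_col] == 0].tolist()
        excluded += zero
        sub = sub[sub[x_col] != 0]
    res = linear_correlation(sub[x_col], sub[y_col], x_name=x_col, y_name=y_col)
    res.excluded_ids = excluded
    return res
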