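"""Distance-vs-time series to rates: OLS slope per replicate, mean ± SD across."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import BadTimeAxisError, InsufficientPointsError
from .imaging import BoundaryTrace

__all__ = [
    "RateSeries",
    "RateEstimate",
    "ReplicateSummary",
    "estimate_rate",
    "summarize_replicates",
    "series_from_trace",
]


@dataclass
class RateSeries:
    """One replicate's distance (mm) vs time (min) series for one boundary kind."""

    times: np.ndarray
    distances: np.ndarray
    kind: str = ""
    replicate_id: str = ""
    medium: str = ""
    formulation_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.times.size != self.distances.size:
            raise ValueError("times and distances must have equal length")
        if self.times.size < 3:
            raise InsufficientPointsError("insufficient points")
        if np.any(np.diff(self.times) <= 0):
            raise BadTimeAxisError("bad time axis")


@dataclass
class RateEstimate:
    """OLS line through a rate series; the slope is the reported rate (mm/min)."""

    slope: float
    intercept: float
    r_squared: float  # NaN when the distance series has zero variance
    n_points: int
    degenerate: bool = False
    kind: str = ""
    replicate_id: str = ""
    medium: str = ""
    formulation_id: str = ""


@dataclass
class ReplicateSummary:
    """Mean ± sample SD of per-replicate slopes."""

    mean_rate: float
    sd_rate: float
    n: int
    kind: str = ""
    medium: str = ""
    formulation_id: str = ""
    flags: list[str] = field(default_factory=list)


def estimate_rate(series: RateSeries) -> RateEstimate:
    """Ordinary least squares with a free intercept; slope = rate in mm/min."""
    t = series.times
    d = series.distances
    ok = np.isfinite(d)
    if ok.sum() < 3:
        raise InsufficientPointsError("insufficient points")
    t, d = t[ok], d[ok]
    t_bar = t.mean()
    d_bar = d.mean()
    sxx = float(np.sum((t - t_bar) ** 2))
    sxy = float(np.sum((t - t_bar) * (d - d_bar)))
    slope = sxy / sxx
    intercept = d_bar - slope * t_bar
    sst = float(np.sum((d - d_bar) ** 2))
    if sst == 0:
        r2, degenerate = float("nan"), True
    else:
        ssr = float(np.sum((d - (intercept + slope * t)) ** 2))
        r2, degenerate = 1.0 - ssr / sst, False
    return RateEstimate(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n_points=int(t.size),
        degenerate=degenerate,
        kind=series.kind,
        replicate_id=series.replicate_id,
        medium=series.medium,
        formulation_id=series.formulation_id,
    )


def summarize_replicates(estimates: list[RateEstimate]) -> ReplicateSummary:
    """Mean and sample SD (n-1 denominator) of replicate slopes."""
    if not estimates:
        raise ValueError("no replicates")
    kinds = {e.kind for e in estimates}
    media = {e.medium for e in estimates}
    forms = {e.formulation_id for e in estimates}
    if len(kinds) > 1 or len(media) > 1 or len(forms) > 1:
        raise ValueError("estimates mix kind/medium/formulation")
    slopes = np.array([e.slope for e in estimates])
    flags: list[str] = []
    if slopes.size == 1:
        sd = 0.0
        flags.append("single replicate")
        warnings.warn("single replicate: SD reported as 0", stacklevel=2)
    else:
        sd = float(np.std(slopes, ddof=1))
    return ReplicateSummary(
        mean_rate=float(slopes.mean()),
        sd_rate=sd,
        n=int(slopes.size),
        kind=kinds.pop(),
        medium=media.pop(),
        formulation_id=forms.pop(),
        flags=flags,
    )


def series_from_trace(trace: BoundaryTrace, formulation_id: str = "") -> RateSeries:
    """Adapt a tracker output (aggregated median series) into a RateSeries.

    Frames whose non-occluded ray fraction falls below 50% are dropped and
    the series is flagged by the caller via NaN count if needed.
    """
    frac_ok = trace.n_rays_used / trace.occluded.shape[1]
    keep = frac_ok >= 0.5
    return RateSeries(
        times=trace.times[keep],
        distances=trace.distance[keep],
        kind=trace.kind,
        replicate_id=trace.replicate_id,
        medium=trace.medium,
        formulation_id=formulation_id,
    )
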