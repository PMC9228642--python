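"""Kinetic model fitting for cumulative dissolution profiles.

Two three-parameter models are supported: a power law with a burst offset
(``F = F0 + K*t^n``) and a two-term diffusion/relaxation split
(``F = k1*t^m + k2*t^(2m)``).  Fitting is unweighted least squares with a
deterministic multi-start over the exponent; goodness of fit is reported
as R², AIC = N*ln(WSS) + 2p and MSC = ln(SST/WSS) - 2p/N.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, lsq_linear

from .errors import (
    BadTimeAxisError,
    DegenerateDataError,
    FitFailedError,
    InsufficientPointsError,
    InvalidParametersError,
)

__all__ = [
    "DissolutionProfile",
    "KineticModelSpec",
    "ModelFit",
    "MechanismCall",
    "KP_F0_MODEL",
    "PS_MODEL",
    "MODELS",
    "eval_model",
    "fit_model",
    "goodness_of_fit",
    "select_model",
    "classify_mechanism",
]

_EPS = 1e-9


@dataclass
class DissolutionProfile:
    """Cumulative % dissolved vs time (hours) for one formulation."""

    times: np.ndarray
    released: np.ndarray
    formulation_id: str = ""
    n_replicates: int = 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.released = np.asarray(self.released, dtype=float)
        if self.times.size != self.released.size:
            raise ValueError("times and released must have equal length")
        if self.times.size < 4:
            raise InsufficientPointsError("need at least 4 points")
        if np.any(np.diff(self.times) <= 0):
            raise BadTimeAxisError("bad time axis")
        # tolerate tiny negative observations: a fitted two-term curve with
        # negative k1 undershoots 0 slightly at early times
        if np.any((self.released < -1.0) | (self.released > 100)):
            raise ValueError("released must lie in [0, 100]")


@dataclass(frozen=True)
class KineticModelSpec:
    """Model identity, parameter names, and box bounds."""

    model_id: str
    param_names: tuple[str, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.param_names) == len(self.lower) == len(self.upper)):
            raise ValueError("inconsistent bound lengths")
        if any(lo > hi for lo, hi in zip(self.lower, self.upper)):
            raise ValueError("bounds internally inconsistent")

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def check(self, parameters: dict[str, float]) -> np.ndarray:
        try:
            vec = np.array([float(parameters[p]) for p in self.param_names])
        except KeyError as exc:
            raise InvalidParametersError(f"invalid parameters: missing {exc}") from exc
        lo = np.asarray(self.lower)
        hi = np.asarray(self.upper)
        if np.any(vec < lo - 1e-12) or np.any(vec > hi + 1e-12):
            raise InvalidParametersError("invalid parameters")
        return vec


#: F(t) = F0 + K*t^n; F0 in [0, 100], K >= 0, n in (0, 2]
KP_F0_MODEL = KineticModelSpec(
    model_id="KP_F0",
    param_names=("F0", "K", "n"),
    lower=(0.0, 0.0, _EPS),
    upper=(100.0, np.inf, 2.0),
)

#: F(t) = k1*t^m + k2*t^(2m); k1, k2 unbounded, m in (0, 1]
PS_MODEL = KineticModelSpec(
    model_id="PS",
    param_names=("k1", "k2", "m"),
    lower=(-np.inf, -np.inf, _EPS),
    upper=(np.inf, np.inf, 1.0),
)

MODELS = {"KP_F0": KP_F0_MODEL, "PS": PS_MODEL}


@dataclass
class ModelFit:
    """One model fitted to one profile."""

    model_id: str
    parameters: dict[str, float]
    wss: float
    r_squared: float
    aic: float
    msc: float
    n_obs: int
    n_params: int
    flags: list[str] = field(default_factory=list)


@dataclass
class MechanismCall:
    """Release-mechanism classification from a diffusion/relaxation fit."""

    label: str  # diffusion_dominant | erosion_relaxation_dominant | mixed
    burst: bool
    dissolution_rate_k: float
    formulation_id: str = ""
    flags: list[str] = field(default_factory=list)


def _predict(model_id: str, vec: np.ndarray, t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if model_id == "KP_F0":
        f0, k, n = vec
        return f0 + k * np.power(t, n)
    if model_id == "PS":
        k1, k2, m = vec
        return k1 * np.power(t, m) + k2 * np.power(t, 2 * m)
    raise ValueError(f"unknown model {model_id!r}")


def eval_model(spec: KineticModelSpec, parameters: dict[str, float], times) -> np.ndarray:
    """Evaluate the model at the given times (hours); parameters are checked."""
    vec = spec.check(parameters)
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    return _predict(spec.model_id, vec, times)


def goodness_of_fit(observed, predicted, p: int) -> tuple[float, float, float]:
    """(R², AIC, MSC) for an unweighted fit with ``p`` parameters.

    WSS = 0 yields sentinel -inf AIC / +inf MSC; constant observations are
    rejected because SST (and hence R²) is undefined.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size != pred.size:
        raise ValueError("length mismatch")
    n = obs.size
    if n < max(p, 3):
        raise InsufficientPointsError("too few observations")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        raise DegenerateDataError("degenerate observations")
    wss = float(np.sum((obs - pred) ** 2))
    if wss == 0:
        return 1.0, -math.inf, math.inf
    r2 = 1.0 - wss / sst
    aic = n * math.log(wss) + 2 * p
    msc = math.log(sst / wss) - 2 * p / n
    return r2, aic, msc


def _linear_solve(model_id: str, expo: float, t: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Best linear coefficients for a fixed exponent (seed for refinement)."""
    if model_id == "KP_F0":
        design = np.column_stack([np.ones_like(t), np.power(t, expo)])
        res = lsq_linear(design, f, bounds=([0, 0], [100, np.inf]))
        return np.array([res.x[0], res.x[1], expo])
    design = np.column_stack([np.power(t, expo), np.power(t, 2 * expo)])
    coef, *_ = np.linalg.lstsq(design, f, rcond=None)
    return np.array([coef[0], coef[1], expo])


def fit_model(profile: DissolutionProfile, spec: KineticModelSpec) -> ModelFit:
    """Least-squares fit with a deterministic multi-start over the exponent.

    t = 0 points are excluded (the power law is singular there); each start
    solves the conditionally-linear coefficients exactly, then refines all
    parameters with a bounded trust-region pass.  The best WSS wins.
    """
    keep = profile.times > 0
    t = profile.times[keep]
    f = profile.released[keep]
    if t.size < spec.n_params + 1:
        raise InsufficientPointsError("underdetermined")

    lo = np.asarray(spec.lower)
    hi = np.asarray(spec.upper)
    expo_hi = hi[-1] if np.isfinite(hi[-1]) else 2.0
    expo_grid = np.arange(0.1, expo_hi + 1e-9, 0.1)

    best: tuple[float, np.ndarray] | None = None
    for expo in expo_grid:
        x0 = _linear_solve(spec.model_id, expo, t, f)
        x0 = np.clip(x0, lo + 1e-12, np.minimum(hi, 1e12))
        try:
            res = least_squares(
                lambda v: _predict(spec.model_id, v, t) - f,
                x0,
                bounds=(lo, hi),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:
            continue
        wss = float(np.sum(res.fun**2))
        if best is None or wss < best[0]:
            best = (wss, res.x)
    if best is None:
        raise FitFailedError("fit failed")

    wss, vec = best
    pred = _predict(spec.model_id, vec, t)
    r2, aic, msc = goodness_of_fit(f, pred, spec.n_params)
    return ModelFit(
        model_id=spec.model_id,
        parameters=dict(zip(spec.param_names, (float(v) for v in vec))),
        wss=wss,
        r_squared=r2,
        aic=aic,
        msc=msc,
        n_obs=int(t.size),
        n_params=spec.n_params,
    )


def select_model(fits: list[ModelFit]) -> ModelFit:
    """Pick the fit preferred by the majority of {R² high, AIC low, MSC high}.

    With equal N and p the three criteria always agree; on a full tie the
    first fit is returned flagged ``tie``.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to select")
    n = len(fits)
    by_r2 = max(range(n), key=lambda i: fits[i].r_squared)
    by_aic = min(range(n), key=lambda i: fits[i].aic)
    by_msc = max(range(n), key=lambda i: fits[i].msc)
    votes = [by_r2, by_aic, by_msc]
    if all(
        fits[i].wss == fits[0].wss and fits[i].n_params == fits[0].n_params
        for i in range(n)
    ):
        winner = fits[0]
        winner.flags = list({*winner.flags, "tie"})
        return winner
    counts = {i: votes.count(i) for i in set(votes)}
    top, top_votes = max(counts.items(), key=lambda kv: kv[1])
    if top_votes < 2:
        winner = fits[by_aic]
        winner.flags = list({*winner.flags, "criteria disagree"})
        return winner
    return fits[top]


def classify_mechanism(ps_fit: ModelFit, kp_fit: ModelFit | None = None) -> MechanismCall:
    """Label the dominant release route and extract the dissolution rate.

    The rate is the positive coefficient of the two-term fit (the larger
    one if both are positive; 0 with a warning if neither is).  Burst
    release is read off the companion burst-offset fit when supplied, at
    4-decimal report precision.
    """
    if ps_fit.model_id != "PS":
        raise ValueError("not a Peppas-Sahlin fit")
    k1 = ps_fit.parameters["k1"]
    k2 = ps_fit.parameters["k2"]
    if abs(k1 - k2) <= 1e-6:
        label = "mixed"
    elif k1 > k2:
        label = "diffusion_dominant"
    else:
        label = "erosion_relaxation_dominant"
    flags: list[str] = []
    positives = [k for k in (k1, k2) if k > 0]
    if positives:
        rate = max(positives)
    else:
        rate = 0.0
        flags.append("no positive rate constant")
        warnings.warn("neither coefficient is positive; rate set to 0", stacklevel=2)
    burst = False
    if kp_fit is not None and kp_fit.model_id == "KP_F0":
        burst = round(kp_fit.parameters["F0"], 4) > 0
    return MechanismCall(
        label=label,
        burst=burst,
        dissolution_rate_k=rate,
        flags=flags,
    )
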