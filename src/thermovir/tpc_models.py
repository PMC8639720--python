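"""Thermal performance curve (TPC) models and cardinal-temperature formulas.

Four temperature-response models are provided, the ones a mycologist or
insect ecologist typically reaches for when describing how a fungal
biopesticide's growth rate or kill rate depends on ambient temperature:

* a straight line ``y(T) = a + b T`` over the rising limb, whose root
  ``T_min = -a/b`` estimates the lower developmental threshold;
* the Briere-1 unimodal model ``r(T) = n T (T - T_min) sqrt(T_max - T)``
  with both thresholds explicit and a closed-form optimum;
* Logan-1 and Logan-4, asymmetric exponential-rise / sharp-crash models
  commonly fitted to temperature-mortality data.

All evaluators accept scalars or numpy arrays and broadcast; mortality
models operate on proportions in [0, 1], never percentages.  Predicted
values are deliberately *not* clipped here — clipping to [0, 1] is the
business of the spatial/reporting layer, so that least-squares fitting
sees the raw functional form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Callable

import numpy as np

__all__ = [
    "LinearParams",
    "Briere1Params",
    "Logan1Params",
    "Logan4Params",
    "CardinalTemperatures",
    "eval_linear",
    "tmin_linear",
    "se_tmin_linear",
    "eval_briere1",
    "topt_briere1",
    "eval_logan1",
    "eval_logan4",
    "numeric_topt",
    "params_from_dict",
    "params_to_dict",
]


@dataclass(frozen=True)
class LinearParams:
    """Straight-line growth model ``y(T) = a + b T``.

    Parameters
    ----------
    a : intercept, in response units (e.g. mm/day).
    b : slope, response units per degC.  Must be nonzero for threshold
        extraction.
    se_b : standard error of the slope, used by the threshold-SE formula.
    """

    a: float
    b: float
    se_b: float | None = None


@dataclass(frozen=True)
class Briere1Params:
    """Briere-1 unimodal rate model ``r(T) = n T (T - t_min) sqrt(t_max - T)``.

    ``n`` is an empirical scale constant (response units per degC^2.5);
    ``t_min`` and ``t_max`` are the lower and upper temperature thresholds
    in degC; ``m`` is the empirical exponent constant entering the
    closed-form optimum (2 by the Briere-1 convention).
    """

    n: float
    t_min: float
    t_max: float
    m: float = 2.0

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise ValueError(f"require t_min < t_max, got {self.t_min} >= {self.t_max}")
        if not math.isfinite(self.n):
            raise ValueError("scale constant n must be finite")


@dataclass(frozen=True)
class Logan1Params:
    """Logan-1 mortality model ``m(T) = y0 (e^{pT} - e^{p t_max - (t_max - T)/v})``.

    ``y0`` is a scale (proportion), ``p`` a rate constant (1/degC), ``v``
    the boundary-width constant (degC) controlling how sharply the curve
    crashes as T approaches ``t_max``.  The model is exactly zero at
    ``t_max`` for every parameterization.
    """

    y0: float
    p: float
    v: float
    t_max: float

    def __post_init__(self) -> None:
        if not self.v > 0:
            raise ValueError("boundary-width constant v must be positive")


@dataclass(frozen=True)
class Logan4Params:
    """Logan-4 sigmoid-rise / exponential-crash mortality model.

    ``m(T) = alpha (1/(1 + k e^{-b (T - t_min)}) - e^{s (t_max - (T - t_min))/dt})``

    with ``s = -1`` when ``sign_corrected`` (the standard Logan
    formulation, default for fitting) and ``s = +1`` for the literal
    positive-exponent variant.
    """

    alpha: float
    k: float
    b: float
    t_min: float
    t_max: float
    dt: float
    sign_corrected: bool = True

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("boundary-width constant dt must be positive")
        if not self.t_min < self.t_max:
            raise ValueError(f"require t_min < t_max, got {self.t_min} >= {self.t_max}")


@dataclass(frozen=True)
class CardinalTemperatures:
    """Cardinal temperature triple (degC): lower threshold, optimum, upper threshold."""

    t_min: float
    t_opt: float | None = None
    t_max: float | None = None
    se_t_min: float | None = None

    def __post_init__(self) -> None:
        vals = [v for v in (self.t_min, self.t_opt, self.t_max) if v is not None]
        if any(x > y + 1e-9 for x, y in zip(vals, vals[1:])):
            raise ValueError(f"cardinal temperatures must be ordered: {vals}")


def eval_linear(params: LinearParams, t):
    """Evaluate the straight-line model ``a + b t``."""
    return params.a + params.b * np.asarray(t, dtype=float) if np.ndim(t) else params.a + params.b * float(t)


def tmin_linear(params: LinearParams) -> float:
    """Lower temperature threshold of the linear model, ``T_min = -a/b``.

    The threshold is the root of the fitted line: the temperature at which
    the extrapolated growth rate reaches zero.
    """
    if params.b == 0:
        raise ZeroDivisionError("slope b = 0: linear threshold undefined")
    return -params.a / params.b


def se_tmin_linear(y_mean: float, b: float, se_b: float, s2: float, n: int) -> float:
    """Standard error of the linear ``T_min`` estimate.

    ``SE = (y_m / b) * sqrt(S^2 / (N y_m^2) + (SE_b / b)^2)``

    where ``y_m`` is the mean response, ``S^2`` the residual mean square of
    the linear fit, ``SE_b`` the slope standard error and ``N`` the sample
    size.
    """
    if n < 1:
        raise ValueError("sample size must be >= 1")
    if b == 0 or y_mean == 0:
        raise ZeroDivisionError("b and y_mean must be nonzero")
    if s2 < 0:
        raise ValueError("residual mean square must be >= 0")
    return abs(y_mean / b) * math.sqrt(s2 / (n * y_mean**2) + (se_b / b) ** 2)


def eval_briere1(params: Briere1Params, t):
    """Evaluate Briere-1, clamped to zero outside [t_min, t_max].

    Outside the thermal window the square root is undefined and the
    biological rate is nil, so the model returns 0 there; this makes
    spatial projection total over any temperature grid.
    """
    t_arr = np.asarray(t, dtype=float)
    inside = (t_arr >= params.t_min) & (t_arr <= params.t_max)
    safe = np.where(inside, t_arr, params.t_min)
    val = params.n * safe * (safe - params.t_min) * np.sqrt(params.t_max - safe)
    out = np.where(inside, val, 0.0)
    return out if np.ndim(t) else float(out)


def topt_briere1(params: Briere1Params) -> float:
    """Closed-form optimum temperature of the Briere-1 model.

    ``T_opt = [2 m T_max + (m+1) T_min
              + sqrt(4 m^2 T_max^2 + (m+1)^2 T_min^2 - 4 m^2 T_min T_max)]
              / (4 m + 2)``

    For ``t_min = 0`` this reduces to ``(4m / (4m + 2)) t_max``.  The
    result always lies strictly between the two thresholds.
    """
    m, tmin, tmax = params.m, params.t_min, params.t_max
    if m <= 0:
        raise ValueError("exponent constant m must be positive")
    disc = 4 * m**2 * tmax**2 + (m + 1) ** 2 * tmin**2 - 4 * m**2 * tmin * tmax
    # disc = (2m*tmax - (m+1)*tmin)^2 + ... is provably nonnegative for tmin < tmax
    assert disc >= 0, "discriminant negative for valid parameters"
    return (2 * m * tmax + (m + 1) * tmin + math.sqrt(disc)) / (4 * m + 2)


def eval_logan1(params: Logan1Params, t):
    """Evaluate the Logan-1 mortality model (proportion scale)."""
    t_arr = np.asarray(t, dtype=float)
    val = params.y0 * (
        np.exp(params.p * t_arr)
        - np.exp(params.p * params.t_max - (params.t_max - t_arr) / params.v)
    )
    return val if np.ndim(t) else float(val)


def eval_logan4(params: Logan4Params, t):
    """Evaluate the Logan-4 mortality model (proportion scale)."""
    t_arr = np.asarray(t, dtype=float)
    shifted = t_arr - params.t_min
    sigmoid = 1.0 / (1.0 + params.k * np.exp(-params.b * shifted))
    expo = (params.t_max - shifted) / params.dt
    if params.sign_corrected:
        expo = -expo
    val = params.alpha * (sigmoid - np.exp(expo))
    return val if np.ndim(t) else float(val)


def numeric_topt(
    model_eval: Callable[[float], float],
    t_lo: float,
    t_hi: float,
    *,
    grid: int = 2001,
    tol: float = 1e-8,
) -> tuple[float, bool]:
    """Numeric argmax of a temperature-response function on [t_lo, t_hi].

    Dense grid scan followed by golden-section refinement of the winning
    bracket; accurate to well under 1e-6 degC for smooth unimodal curves.
    Serves as the independent oracle for closed-form optima and as the
    only route for models without one.

    Returns ``(t_opt, is_constant)``; for a constant function ``t_lo`` is
    returned with the flag set.
    """
    if not t_lo < t_hi:
        raise ValueError("require t_lo < t_hi")
    ts = np.linspace(t_lo, t_hi, grid)
    ys = np.asarray([model_eval(float(t)) for t in ts], dtype=float)
    if np.allclose(ys, ys[0], rtol=0.0, atol=1e-15):
        return float(t_lo), True
    i = int(np.argmax(ys))
    lo = ts[max(i - 1, 0)]
    hi = ts[min(i + 1, grid - 1)]
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = float(lo), float(hi)
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = model_eval(c), model_eval(d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = model_eval(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = model_eval(d)
    return (a + b) / 2.0, False


# --- flat key-value serialization -----------------------------------------
# Parameter sets round-trip through {"model": <name>, <param>: <value>, ...}
# blocks; the CLI and the spatial module exchange fitted models this way.

_MODEL_REGISTRY: dict[str, type] = {
    "linear": LinearParams,
    "briere1": Briere1Params,
    "logan1": Logan1Params,
    "logan4": Logan4Params,
}

_EVALUATORS: dict[str, Callable] = {
    "linear": eval_linear,
    "briere1": eval_briere1,
    "logan1": eval_logan1,
    "logan4": eval_logan4,
}


def model_evaluator(name: str) -> Callable:
    """Return the evaluator function for a registered model name."""
    try:
        return _EVALUATORS[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; known: {sorted(_EVALUATORS)}") from None


def params_to_dict(params) -> dict:
    """Serialize a parameter dataclass to a flat dict with a 'model' key."""
    for name, cls in _MODEL_REGISTRY.items():
        if isinstance(params, cls):
            d = {"model": name}
            for f in fields(params):
                v = getattr(params, f.name)
                if v is not None:
                    d[f.name] = v
            return d
    raise TypeError(f"not a registered parameter set: {type(params).__name__}")


def params_from_dict(d: dict):
    """Rebuild a parameter dataclass from a flat dict with a 'model' key."""
    d = dict(d)
    name = str(d.pop("model"))
    cls = _MODEL_REGISTRY[name]
    valid = {f.name for f in fields(cls)}
    kwargs = {}
    for k, v in d.items():
        if k not in valid:
            raise KeyError(f"unknown parameter {k!r} for model {name!r}")
        if k == "sign_corrected":
            kwargs[k] = v in (True, "true", "True", "1", 1)
        else:
            kwargs[k] = float(v)
    return cls(**kwargs)
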