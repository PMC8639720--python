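"""Least-squares fitting of temperature-response models and model selection.

The workflow mirrors standard thermal-biology practice: replicate radial
growth measurements are reduced to per-replicate growth rates (mm/day),
a straight line is fitted to the rising limb (with the convention of
omitting the supra-optimal 33 and 35 degC points, which fall off the
line), unimodal nonlinear models are fitted to the full temperature
range by bounded multi-start least squares, and candidates are ranked by
AIC with adjusted R^2 and RMSE as tie-breakers.

Replicates enter fits as individual observations (never pre-averaged),
preserving the error structure.  Mortality fits use unweighted least
squares on proportions; likelihood-based binomial fitting is out of
scope here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .tpc_models import (
    Briere1Params,
    LinearParams,
    Logan1Params,
    Logan4Params,
    eval_briere1,
    eval_linear,
    eval_logan1,
    eval_logan4,
    params_to_dict,
)

__all__ = [
    "ResponseDataset",
    "GoodnessOfFit",
    "FitResult",
    "ModelRanking",
    "radial_growth_rate",
    "fit_linear_growth",
    "fit_nonlinear",
    "goodness_of_fit",
    "select_best",
]

DEFAULT_EXCLUDE_TEMPS: tuple[float, ...] = (33.0, 35.0)


@dataclass
class ResponseDataset:
    """Temperature-indexed replicated responses for one isolate.

    ``response_kind`` is ``"growth_rate"`` (mm/day) or
    ``"mortality_proportion"`` (in [0, 1]).
    """

    temperature_c: np.ndarray
    response: np.ndarray
    replicate: np.ndarray
    response_kind: str = "growth_rate"
    isolate: str = ""

    def __post_init__(self) -> None:
        self.temperature_c = np.asarray(self.temperature_c, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        self.replicate = np.asarray(self.replicate)
        if not (len(self.temperature_c) == len(self.response) == len(self.replicate)):
            raise ValueError("temperature, response and replicate must be equal length")
        if np.isnan(self.temperature_c).any() or np.isnan(self.response).any():
            raise ValueError("missing temperatures or responses are not allowed")
        if len(np.unique(self.temperature_c)) < 2:
            raise ValueError("need at least 2 distinct temperatures")
        if self.response_kind == "mortality_proportion":
            if self.response.min() < 0 or self.response.max() > 1:
                raise ValueError("mortality responses must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.response)

    @property
    def temperatures(self) -> np.ndarray:
        return np.unique(self.temperature_c)

    def subset_excluding(self, exclude_temps: Iterable[float]) -> "ResponseDataset":
        """Drop observations at the given temperatures (exact match)."""
        excl = set(float(t) for t in exclude_temps)
        keep = np.array([float(t) not in excl for t in self.temperature_c])
        if keep.sum() == 0:
            raise ValueError("all observations excluded")
        return ResponseDataset(
            self.temperature_c[keep],
            self.response[keep],
            self.replicate[keep],
            response_kind=self.response_kind,
            isolate=self.isolate,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "isolate": self.isolate,
                "temperature_c": self.temperature_c,
                "replicate": self.replicate,
                "response": self.response,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, response_kind: str = "growth_rate", isolate: str | None = None
    ) -> "ResponseDataset":
        df = pd.read_csv(path)
        if isolate is not None:
            df = df[df["isolate"] == isolate]
        labels = df["isolate"].unique()
        if len(labels) > 1:
            raise ValueError(f"multiple isolates in file; pass isolate= (found {list(labels)})")
        return cls(
            df["temperature_c"].to_numpy(),
            df["response"].to_numpy(),
            df["replicate"].to_numpy(),
            response_kind=response_kind,
            isolate=str(labels[0]) if len(labels) else "",
        )


@dataclass(frozen=True)
class GoodnessOfFit:
    rss: float
    tss: float
    r2: float
    adj_r2: float
    rmse: float
    aic: float
    msc: float
    n_obs: int
    k_params: int
    tss_zero: bool = False


@dataclass
class FitResult:
    """A fitted model with its goodness-of-fit and selection criteria."""

    model: str
    params: object
    gof: GoodnessOfFit
    param_se: dict[str, float] | None = None
    residual_mean_square: float = float("nan")  # S^2 = RSS / (n - k)
    y_mean: float = float("nan")
    converged: bool = True
    excluded_temperatures: tuple[float, ...] = ()

    @property
    def rss(self) -> float:
        return self.gof.rss

    @property
    def aic(self) -> float:
        return self.gof.aic

    def to_dict(self) -> dict:
        """Flat key-value block (model + parameters) consumed by the spatial layer."""
        return params_to_dict(self.params)


@dataclass
class ModelRanking:
    fits: list[FitResult]
    rule: str = "AIC asc; ties: adj R2 desc, RMSE asc; non-converged last"

    @property
    def best(self) -> FitResult:
        return self.fits[0]


def radial_growth_rate(
    measurements: pd.DataFrame, plug_diameter: float = 8.0
) -> ResponseDataset:
    """Reduce daily two-diameter colony measurements to growth rates.

    ``measurements`` needs columns ``isolate, temperature_c, replicate,
    day, diameter1_mm, diameter2_mm``.  Per replicate, the two orthogonal
    diameters are averaged each day, the inoculation-plug diameter is
    subtracted and the remainder halved to a radius; the growth rate is
    the OLS slope of radius against day, in mm/day, floored at zero.
    """
    required = {"isolate", "temperature_c", "replicate", "day", "diameter1_mm", "diameter2_mm"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (measurements[["diameter1_mm", "diameter2_mm"]].to_numpy() < plug_diameter - 1e-9).any():
        raise ValueError("diameters below the plug diameter")
    temps, rates, reps = [], [], []
    isolates = measurements["isolate"].unique()
    if len(isolates) != 1:
        raise ValueError("one isolate per dataset; split the table first")
    for (temp, rep), grp in measurements.groupby(["temperature_c", "replicate"], sort=True):
        days = grp["day"].to_numpy(dtype=float)
        if len(days) < 2:
            raise ValueError(f"replicate {rep} at {temp} degC has fewer than 2 days")
        if len(np.unique(days)) != len(days):
            raise ValueError(f"duplicate observation days in replicate {rep} at {temp} degC")
        order = np.argsort(days)
        radius = (
            grp[["diameter1_mm", "diameter2_mm"]].mean(axis=1).to_numpy(dtype=float)
            - plug_diameter
        ) / 2.0
        slope = np.polyfit(days[order], radius[order], 1)[0]
        temps.append(float(temp))
        rates.append(max(float(slope), 0.0))
        reps.append(rep)
    return ResponseDataset(
        np.array(temps), np.array(rates), np.array(reps),
        response_kind="growth_rate", isolate=str(isolates[0]),
    )


def goodness_of_fit(
    observed: Sequence[float], predicted: Sequence[float], k_params: int
) -> GoodnessOfFit:
    """Residual-based fit metrics and selection criteria.

    RSS, R^2, adjusted R^2 and RMSE are the usual least-squares
    quantities.  AIC uses the least-squares form ``n ln(RSS/n) + 2k``;
    MSC is ``ln(TSS/RSS) - 2k/n`` (bigger is better).  A perfect fit
    (RSS = 0) is reported with infinite sentinels; constant observations
    (TSS = 0) leave R^2 undefined and set the ``tss_zero`` flag.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted must have equal length")
    n = len(y)
    if n < k_params + 1:
        raise ValueError(f"need n >= k+1 observations (n={n}, k={k_params})")
    rss = float(np.sum((y - yhat) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    rmse = math.sqrt(rss / n)
    if tss == 0.0:
        return GoodnessOfFit(rss, tss, math.nan, math.nan, rmse,
                             aic=_aic_ls(n, rss, k_params), msc=math.nan,
                             n_obs=n, k_params=k_params, tss_zero=True)
    if rss == 0.0:
        return GoodnessOfFit(rss, tss, 1.0, 1.0, 0.0, aic=-math.inf, msc=math.inf,
                             n_obs=n, k_params=k_params)
    r2 = 1.0 - rss / tss
    adj_r2 = 1.0 - (rss / (n - k_params)) / (tss / (n - 1))
    msc = math.log(tss / rss) - 2.0 * k_params / n
    return GoodnessOfFit(rss, tss, r2, adj_r2, rmse, _aic_ls(n, rss, k_params), msc,
                         n_obs=n, k_params=k_params)


def _aic_ls(n: int, rss: float, k: int) -> float:
    if rss == 0.0:
        return -math.inf
    return n * math.log(rss / n) + 2 * k


def fit_linear_growth(
    data: ResponseDataset,
    exclude_temps: Iterable[float] = DEFAULT_EXCLUDE_TEMPS,
) -> FitResult:
    """OLS straight-line fit of response on temperature.

    By default the 33 and 35 degC observations are omitted: they sit past
    the optimum and drag the line off the rising limb, which is the only
    part the linear threshold formula is meant for.  The result carries
    the slope SE, residual mean square and mean response needed by the
    threshold and threshold-SE formulas.
    """
    exclude_temps = list(exclude_temps)
    kept = data.subset_excluding(exclude_temps) if exclude_temps else data
    t, y = kept.temperature_c, kept.response
    if len(np.unique(t)) < 2:
        raise ValueError("need >= 2 distinct temperatures after exclusion")
    n = len(y)
    X = np.column_stack([np.ones(n), t])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    yhat = X @ coef
    gof = goodness_of_fit(y, yhat, 2)
    s2 = gof.rss / (n - 2) if n > 2 else math.nan
    sxx = float(np.sum((t - t.mean()) ** 2))
    se_b = math.sqrt(s2 / sxx) if n > 2 else math.nan
    se_a = math.sqrt(s2 * (1.0 / n + t.mean() ** 2 / sxx)) if n > 2 else math.nan
    return FitResult(
        model="linear",
        params=LinearParams(a=a, b=b, se_b=se_b),
        gof=gof,
        param_se={"a": se_a, "b": se_b},
        residual_mean_square=s2,
        y_mean=float(y.mean()),
        converged=True,
        excluded_temperatures=tuple(sorted(float(x) for x in exclude_temps)),
    )


# --- nonlinear fitting -----------------------------------------------------

# (parameter order, log10-sampled flags); threshold bounds are data-driven
_NL_SPECS = {
    "briere1": (("n", "t_min", "t_max"), (True, False, False)),
    "logan1": (("y0", "p", "v", "t_max"), (True, False, False, False)),
    "logan4": (("alpha", "k", "b", "t_min", "t_max", "dt"),
               (True, True, False, False, False, False)),
}

_NL_BUILDERS = {
    "briere1": lambda th: Briere1Params(n=th[0], t_min=th[1], t_max=th[2]),
    "logan1": lambda th: Logan1Params(y0=th[0], p=th[1], v=th[2], t_max=th[3]),
    "logan4": lambda th: Logan4Params(alpha=th[0], k=th[1], b=th[2], t_min=th[3],
                                      t_max=th[4], dt=th[5]),
}

_NL_EVALS = {"briere1": eval_briere1, "logan1": eval_logan1, "logan4": eval_logan4}


def default_bounds(model: str, data: ResponseDataset) -> dict[str, tuple[float, float]]:
    """Data-driven parameter boxes for the multi-start search.

    Thresholds bracket the observed temperature range (t_min in
    [-15, min T], t_max in [max T, max T + 5]); scale constants get
    generous log-spanning boxes anchored to the response magnitude.
    """
    t_lo, t_hi = float(data.temperature_c.min()), float(data.temperature_c.max())
    y_max = max(float(np.abs(data.response).max()), 1e-6)
    # peak of t*(t - tmin)*sqrt(tmax - t) with the widest threshold box,
    # used to anchor the Briere scale constant
    tt = np.linspace(max(t_lo, 0.1), t_hi + 4.9, 200)
    g_peak = float(np.max(tt * (tt + 15.0) * np.sqrt(np.maximum(t_hi + 5.0 - tt, 0.0))))
    if model == "briere1":
        return {
            "n": (1e-12, 1e3 * y_max / g_peak),
            "t_min": (-15.0, t_lo),
            "t_max": (t_hi, t_hi + 5.0),
        }
    if model == "logan1":
        return {
            "y0": (1e-6, 10.0 * y_max),
            "p": (1e-3, 1.0),
            "v": (0.05, 30.0),
            "t_max": (t_hi, t_hi + 5.0),
        }
    if model == "logan4":
        return {
            "alpha": (1e-3, 1e6),
            "k": (1e-3, 1e6),
            "b": (1e-3, 5.0),
            "t_min": (-15.0, t_lo),
            "t_max": (t_hi, t_hi + 5.0),
            "dt": (0.1, 50.0),
        }
    raise KeyError(f"no default bounds for model {model!r}")


def fit_nonlinear(
    data: ResponseDataset,
    model: str,
    n_starts: int = 32,
    bounds: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> FitResult:
    """Bounded least-squares fit with seeded Latin-hypercube multi-start.

    ``n_starts`` starting points are drawn from a Latin hypercube over
    the parameter box (log10 space for scale constants); each is refined
    with a trust-region-reflective solver and the lowest-RSS solution is
    returned.  ``converged`` is False when no start converges — never a
    silent failure.  ``model="linear"`` delegates to the closed-form OLS
    (no temperature exclusions).
    """
    if model == "linear":
        res = fit_linear_growth(data, exclude_temps=())
        return res
    if model not in _NL_SPECS:
        raise KeyError(f"unknown model {model!r}")
    names, logflags = _NL_SPECS[model]
    box = default_bounds(model, data)
    if bounds:
        box.update(bounds)
    lo = np.array([box[nm][0] for nm in names])
    hi = np.array([box[nm][1] for nm in names])
    if (lo >= hi).any():
        raise ValueError("degenerate bounds")
    evaluator = _NL_EVALS[model]
    builder = _NL_BUILDERS[model]
    t, y = data.temperature_c, data.response

    def residuals(theta: np.ndarray) -> np.ndarray:
        return np.asarray(evaluator(builder(theta), t)) - y

    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n_starts)
    slo = np.where(logflags, np.log10(np.where(logflags, lo, 1.0)), lo)
    shi = np.where(logflags, np.log10(np.where(logflags, hi, 1.0)), hi)
    starts = slo + unit * (shi - slo)
    starts = np.where(logflags, 10.0 ** starts, starts)

    best = None
    any_success = False
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if not np.isfinite(sol.cost):
            continue
        any_success = any_success or sol.success
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(f"every start failed for model {model!r}")
    theta = best.x
    params = builder(theta)
    yhat = np.asarray(evaluator(params, t))
    gof = goodness_of_fit(y, yhat, len(names))
    n = len(y)
    s2 = gof.rss / (n - len(names)) if n > len(names) else math.nan
    param_se = _curvature_se(best.jac, s2, names)
    return FitResult(
        model=model,
        params=params,
        gof=gof,
        param_se=param_se,
        residual_mean_square=s2,
        y_mean=float(y.mean()),
        converged=bool(any_success),
    )


def _curvature_se(jac: np.ndarray, s2: float, names: tuple[str, ...]) -> dict[str, float] | None:
    """Asymptotic parameter SEs from the Gauss-Newton curvature (J'J)^-1 S^2."""
    if not math.isfinite(s2):
        return None
    try:
        cov = np.linalg.pinv(jac.T @ jac) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return None
    return dict(zip(names, (float(x) for x in se)))


def select_best(fits: Sequence[FitResult]) -> ModelRanking:
    """Rank fitted models: ascending AIC, ties by higher adjusted R^2 then
    lower RMSE; non-converged fits always rank after converged ones."""
    if not fits:
        raise ValueError("no fits to rank")

    # |dAIC| < 1e-9 counts as a tie: quantize the primary key
    def key(i: int):
        f = fits[i]
        adj = f.gof.adj_r2 if math.isfinite(f.gof.adj_r2) else -math.inf
        aic = f.gof.aic
        aic_q = -math.inf if aic == -math.inf else round(aic / 1e-9) * 1e-9
        return (not f.converged, aic_q, -adj, f.gof.rmse)

    order = sorted(range(len(fits)), key=key)
    return ModelRanking([fits[i] for i in order])
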