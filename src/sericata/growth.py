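"""Sigmoid development-rate model and the body-length → ADH regression grid.

Two model families live here:

* a four-parameter sigmoid of development rate against temperature,
  ``F(x) = y0 + a / (1 + exp(-(x - x0)/b))``, whose inflection ``x0`` is the
  optimum development temperature; and
* six ordinary regressions of (Log10-)ADH on larval body length
  (linear / quadratic / logarithmic x {ADH, Log10ADH}), with adjusted-R² /
  MSE model selection and t-based 95 % prediction intervals, calibrated on
  feeding larvae only (ADH <= 1551.60).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import expit

from . import constants

FAMILIES = ("linear", "quadratic", "logarithm")
RESPONSES = ("adh", "log10adh")


# --------------------------------------------------------------------------
# Four-parameter sigmoid
# --------------------------------------------------------------------------

def sigmoid(x, a, b, x0, y0):
    """F(x) = y0 + a / (1 + exp(-(x - x0)/b))."""
    x = np.asarray(x, dtype=float)
    return y0 + a * expit((x - x0) / b)  # expit avoids overflow at extreme x


@dataclass(frozen=True)
class SigmoidFit:
    """Converged four-parameter sigmoid fit of rate on temperature.

    ``x0`` is the inflection (optimum development temperature, °C);
    ``1/b`` the steepness; ``y0`` the minimum rate; ``a`` the rate range.
    """

    a: float
    b: float
    x0: float
    y0: float
    covariance: np.ndarray
    ci95_x0: float
    r2_adj: float
    mse: float
    n: int

    def predict(self, x):
        return sigmoid(x, self.a, self.b, self.x0, self.y0)


def _sigmoid_p0(temps: np.ndarray, rates: np.ndarray) -> list[float]:
    # Documented initialization: y0 <- min rate, a <- range,
    # x0 <- temperature at mid-range rate, b <- temperature span / 4.
    y0 = float(rates.min())
    a = float(np.ptp(rates)) or 1.0
    mid = y0 + a / 2.0
    x0 = float(temps[np.argmin(np.abs(rates - mid))])
    b = float(np.ptp(temps)) / 4.0 or 1.0
    return [a, b, x0, y0]


def fit_sigmoid(
    points: Iterable[tuple[float, float]],
    max_restarts: int = 8,
    seed: int = 0,
) -> SigmoidFit:
    """Nonlinear least-squares fit of the four-parameter sigmoid.

    Deterministic given identical inputs: a fixed initialization rule plus a
    bounded number of seeded multi-start perturbations on failure. Raises on
    non-convergence with the best residual attained.
    """
    pts = sorted((float(t), float(r)) for t, r in points)
    temps = np.array([t for t, _ in pts])
    rates = np.array([r for _, r in pts])
    if temps.size < 5:
        raise ValueError("need at least 5 points to fit 4 parameters")
    if np.any(rates <= 0):
        raise ValueError("rates must be positive")

    p0 = np.array(_sigmoid_p0(temps, rates))
    rng = np.random.default_rng(seed)
    best_err = np.inf
    last_exc: Exception | None = None
    for attempt in range(max_restarts + 1):
        trial = p0 if attempt == 0 else p0 * rng.lognormal(0.0, 0.3, size=4)
        try:
            popt, pcov = optimize.curve_fit(
                sigmoid, temps, rates, p0=trial, maxfev=20000
            )
        except RuntimeError as exc:  # pragma: no cover - exercised on failure
            last_exc = exc
            continue
        resid = rates - sigmoid(temps, *popt)
        err = float(resid @ resid)
        if np.all(np.isfinite(pcov)) and popt[0] > 0 and popt[1] > 0:
            break
        best_err = min(best_err, err)
    else:  # pragma: no cover
        raise RuntimeError(
            f"sigmoid fit did not converge; best residual SS {best_err:.4g}"
        ) from last_exc

    n = temps.size
    df = n - 4
    resid = rates - sigmoid(temps, *popt)
    sse = float(resid @ resid)
    sst = float(((rates - rates.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / df if df > 0 else np.nan
    mse = sse / df if df > 0 else np.nan
    se_x0 = float(np.sqrt(pcov[2, 2]))
    ci95 = float(stats.t.ppf(0.975, df) * se_x0) if df > 0 else np.inf
    return SigmoidFit(
        a=float(popt[0]), b=float(popt[1]), x0=float(popt[2]), y0=float(popt[3]),
        covariance=pcov, ci95_x0=ci95, r2_adj=float(r2_adj), mse=float(mse), n=n,
    )


@dataclass(frozen=True)
class SigmoidBands:
    temps: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pi_low: np.ndarray
    pi_high: np.ndarray


def sigmoid_bands(fit: SigmoidFit, temps: Sequence[float], level: float = 0.95) -> SigmoidBands:
    """Delta-method confidence band and prediction band around the fit.

    The prediction band adds the residual variance (MSE) to the delta-method
    variance, so it contains the confidence band everywhere.
    """
    if not np.all(np.isfinite(fit.covariance)):
        raise ValueError("singular covariance; bands undefined")
    x = np.asarray(temps, dtype=float)
    a, b, x0, y0 = fit.a, fit.b, fit.x0, fit.y0
    z = (x - x0) / b
    s = 1.0 / (1.0 + np.exp(-z))
    mean = y0 + a * s
    ds = s * (1.0 - s)  # d/dz of the logistic
    grads = np.stack([
        s,                      # dF/da
        -a * ds * z / b,        # dF/db
        -a * ds / b,            # dF/dx0
        np.ones_like(x),        # dF/dy0
    ], axis=1)
    var_mean = np.einsum("ij,jk,ik->i", grads, fit.covariance, grads)
    var_mean = np.maximum(var_mean, 0.0)
    tcrit = stats.t.ppf(0.5 + level / 2.0, fit.n - 4)
    half_ci = tcrit * np.sqrt(var_mean)
    half_pi = tcrit * np.sqrt(var_mean + fit.mse)
    return SigmoidBands(x, mean, mean - half_ci, mean + half_ci,
                        mean - half_pi, mean + half_pi)


# --------------------------------------------------------------------------
# Length -> ADH regression grid
# --------------------------------------------------------------------------

def _design_matrix(family: str, x: np.ndarray) -> np.ndarray:
    if family == "linear":
        return np.column_stack([np.ones_like(x), x])
    if family == "quadratic":
        return np.column_stack([np.ones_like(x), x, x**2])
    if family == "logarithm":
        return np.column_stack([np.ones_like(x), np.log10(x)])
    raise ValueError(f"unknown family {family!r}")


@dataclass(frozen=True)
class LengthAdhModel:
    """One fitted regression of (Log10-)ADH on larval body length.

    Carries the design summary (X'X inverse, residual df, scale) needed for
    t-based prediction intervals without the raw data, so fits serialize to
    JSON and reload losslessly.
    """

    family: str                      # linear | quadratic | logarithm
    response: str                    # adh | log10adh
    coefficients: np.ndarray         # ordered (intercept first)
    r2: float
    r2_adj: float
    se_est: float                    # standard error of estimation
    mse: float                       # == se_est**2
    n: int
    df_resid: int
    xtx_inv: np.ndarray | None       # (X'X)^-1; None for published summaries
    length_range_mm: tuple[float, float]
    #: adjusted R² evaluated on the Log10 scale (equals r2_adj for log10adh
    #: models); -inf when the model predicts non-positive ADH somewhere.
    r2_adj_log10: float = np.nan

    def design_row(self, length_mm: float) -> np.ndarray:
        return _design_matrix(self.family, np.asarray([float(length_mm)]))[0]

    def predict_response(self, length_mm) -> np.ndarray:
        """Point prediction on the fitted response scale (ADH or Log10 ADH)."""
        x = np.atleast_1d(np.asarray(length_mm, dtype=float))
        return _design_matrix(self.family, x) @ self.coefficients

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "response": self.response,
            "coefficients": list(map(float, self.coefficients)),
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "se_est": self.se_est,
            "mse": self.mse,
            "n": self.n,
            "df_resid": self.df_resid,
            "xtx_inv": None if self.xtx_inv is None else self.xtx_inv.tolist(),
            "length_range_mm": list(self.length_range_mm),
            "r2_adj_log10": self.r2_adj_log10,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LengthAdhModel":
        return cls(
            family=d["family"], response=d["response"],
            coefficients=np.asarray(d["coefficients"], dtype=float),
            r2=d["r2"], r2_adj=d["r2_adj"], se_est=d["se_est"], mse=d["mse"],
            n=d["n"], df_resid=d["df_resid"],
            xtx_inv=None if d["xtx_inv"] is None else np.asarray(d["xtx_inv"]),
            length_range_mm=tuple(d["length_range_mm"]),
            r2_adj_log10=d.get("r2_adj_log10", np.nan),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "LengthAdhModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _log10_pseudo_r2_adj(pred_adh: np.ndarray, adh: np.ndarray, p: int) -> float:
    """Adjusted R² of a raw-scale model's predictions judged on the Log10 scale."""
    if np.any(pred_adh <= 0):
        return -np.inf
    ly, lp = np.log10(adh), np.log10(pred_adh)
    sse = float(((ly - lp) ** 2).sum())
    sst = float(((ly - ly.mean()) ** 2).sum())
    n = adh.size
    r2 = 1.0 - sse / sst
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def fit_length_models(
    lengths_mm: Sequence[float], adh: Sequence[float]
) -> dict[tuple[str, str], LengthAdhModel]:
    """Fit the six-model grid: {linear, quadratic, logarithm} x {ADH, Log10ADH}.

    Returns a dict keyed by ``(family, response)``. Each model reports
    ``r2_adj = 1 - (1 - R²)(n-1)/(n-p-1)``, ``se_est = sqrt(SSE/(n-p-1))`` and
    ``mse = se_est²``.
    """
    x = np.asarray(lengths_mm, dtype=float)
    y = np.asarray(adh, dtype=float)
    if x.size != y.size:
        raise ValueError("lengths and ADH differ in size")
    if x.size < 10:
        raise ValueError("need at least 10 points")
    for name, arr in (("length", x), ("adh", y)):
        bad = np.flatnonzero(arr <= 0)
        if bad.size:
            raise ValueError(
                f"non-positive {name} at record {int(bad[0])} "
                f"(value {arr[bad[0]]!r}); Log10 models undefined"
            )
    lrange = (float(x.min()), float(x.max()))
    models: dict[tuple[str, str], LengthAdhModel] = {}
    for response in RESPONSES:
        yy = np.log10(y) if response == "log10adh" else y
        for family in FAMILIES:
            X = _design_matrix(family, x)
            res = sm.OLS(yy, X).fit()
            p = X.shape[1] - 1  # predictors excluding intercept
            se = float(np.sqrt(res.ssr / res.df_resid))
            if response == "log10adh":
                pseudo = float(res.rsquared_adj)
            else:
                pseudo = _log10_pseudo_r2_adj(res.fittedvalues, y, p)
            models[(family, response)] = LengthAdhModel(
                family=family, response=response,
                coefficients=np.asarray(res.params, dtype=float),
                r2=float(res.rsquared), r2_adj=float(res.rsquared_adj),
                se_est=se, mse=se**2,
                n=int(res.nobs), df_resid=int(res.df_resid),
                xtx_inv=np.asarray(res.normalized_cov_params),
                length_range_mm=lrange, r2_adj_log10=pseudo,
            )
    return models


@dataclass(frozen=True)
class SelectionResult:
    best: LengthAdhModel
    ranking: pd.DataFrame  # full audit table, both response scales


def select_best(models: dict[tuple[str, str], LengthAdhModel]) -> SelectionResult:
    """Rank the six-model grid and pick the default working model.

    Within each response scale models are ranked by max adjusted R², ties
    broken by min MSE. Across scales the Log10ADH winner is preferred when its
    adjusted R² is at least the raw-scale winner's adjusted R² evaluated on
    the comparable Log10 scale (raw- and log-scale MSEs are incommensurable).
    Both rankings are always returned for audit.
    """
    rows = []
    for (family, response), m in models.items():
        rows.append({
            "family": family, "response": response, "r2_adj": m.r2_adj,
            "mse": m.mse, "se_est": m.se_est, "r2_adj_log10": m.r2_adj_log10,
        })
    ranking = (
        pd.DataFrame(rows)
        .sort_values(["response", "r2_adj", "mse"], ascending=[True, False, True])
        .reset_index(drop=True)
    )

    def winner(response: str) -> LengthAdhModel:
        cand = [m for (f, r), m in models.items() if r == response]
        return max(cand, key=lambda m: (m.r2_adj, -m.mse))

    log_best = winner("log10adh")
    raw_best = winner("adh")
    best = log_best if log_best.r2_adj >= raw_best.r2_adj_log10 else raw_best
    return SelectionResult(best=best, ranking=ranking)


@dataclass(frozen=True)
class AdhPrediction:
    point: float
    lo: float
    hi: float
    level: float
    extrapolated: bool


def predict_adh(
    model: LengthAdhModel,
    length_mm: float,
    level: float = 0.95,
    bias_correct: bool = False,
) -> AdhPrediction:
    """Point ADH and t-based prediction interval at one body length.

    Predictions are made on the fitted response scale and back-transformed
    (``10**``) for Log10ADH models; by default the naive back-transform is
    used (``bias_correct=True`` applies the lognormal smearing factor
    ``10**(ln(10)/2 * mse)``). Lengths outside the calibration range are not
    rejected but flagged ``extrapolated``.
    """
    if length_mm <= 0:
        raise ValueError("length must be positive")
    xrow = model.design_row(length_mm)
    pred = float(xrow @ model.coefficients)
    if model.xtx_inv is not None:
        leverage = float(xrow @ model.xtx_inv @ xrow)
    else:
        # Published summary without the design matrix: leverage ~ 1/n.
        leverage = 1.0 / model.n
    tcrit = stats.t.ppf(0.5 + level / 2.0, model.df_resid)
    half = tcrit * model.se_est * np.sqrt(1.0 + leverage)
    lo, hi = pred - half, pred + half
    if model.response == "log10adh":
        point, lo, hi = 10.0**pred, 10.0**lo, 10.0**hi
        if bias_correct:
            point *= 10.0 ** (np.log(10.0) / 2.0 * model.mse)
    else:
        point = pred
        lo = max(lo, np.nextafter(0.0, 1.0))
    lmin, lmax = model.length_range_mm
    return AdhPrediction(
        point=float(point), lo=float(lo), hi=float(hi), level=level,
        extrapolated=not (lmin <= length_mm <= lmax),
    )


def published_length_model() -> LengthAdhModel:
    """The packaged best-fit length model: Log10(ADH) = 2.295 + 0.327 Log10(x).

    Built from published summary statistics only (no design matrix), so its
    prediction intervals use the residual scale with leverage 1/n.
    """
    b0, b1 = constants.LENGTH_MODEL_COEFFS
    se = constants.LENGTH_MODEL_SE
    n = constants.LENGTH_MODEL_N
    return LengthAdhModel(
        family="logarithm", response="log10adh",
        coefficients=np.array([b0, b1]),
        r2=np.nan, r2_adj=constants.LENGTH_MODEL_R2_ADJ,
        se_est=se, mse=se**2, n=n, df_resid=n - 2, xtx_inv=None,
        length_range_mm=constants.LENGTH_MODEL_RANGE_MM,
        r2_adj_log10=constants.LENGTH_MODEL_R2_ADJ,
    )
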