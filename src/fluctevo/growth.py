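"""Growth-rate estimation and generalist/specialist classification.

The specific growth rate of a culture is the time derivative of log
biomass; its maximum over the curve, ``mu_max`` (1/min), is estimated
either by differentiating a cubic smoothing spline fitted to log(OD830), or
by a nonlinear least-squares fit of the modified Gompertz law (the two
agree closely on well-behaved curves and serve as mutual cross-checks).

Adaptation of an evolved strain is summarised by its relative growth rate
(mean evolved ``mu_max`` over replicates divided by the ancestor's mean at
the same temperature) and a two-sample t-test whose variance is pooled
across all replicate groups measured at that temperature.  A strain is a
*generalist* if its relative growth rate increased significantly at both
15 and 43 degC, a *specialist* if at exactly one, and *not significant*
otherwise; significant decreases never create a specialist call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import curve_fit

from fluctevo.stats import (
    PooledTResult,
    fisher_exact_2x2,
    pooled_group_t,
    variance_ratio_test,
)

__all__ = [
    "GrowthCurve",
    "GrowthRateEstimate",
    "RelativeGrowthResult",
    "StrategyCall",
    "GompertzFitError",
    "estimate_growth_rate",
    "fit_gompertz",
    "relative_growth_test",
    "classify_strategy",
    "variance_ratio_test",
    "fisher_strategy_enrichment",
    "estimate_replicate_rates",
]

DEFAULT_WINDOW_MIN = 2500.0
_E = math.e


@dataclass(frozen=True)
class GrowthCurve:
    """One replicate OD830 time series at a single temperature."""

    culture_id: str
    time_min: np.ndarray
    od830: np.ndarray
    temperature_C: int = 37
    replicate_id: int = 1

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        od = np.asarray(self.od830, dtype=float)
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "od830", od)
        if t.size != od.size:
            raise ValueError("time and OD arrays differ in length")
        if t.size < 10:
            raise ValueError("growth curve needs at least 10 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if not np.all(np.isfinite(od)) or np.any(od <= 0):
            raise ValueError("OD830 must be finite and positive")


@dataclass(frozen=True)
class GrowthRateEstimate:
    mu_max: float  # 1/min
    t_at_max: float  # min
    method: str  # "spline" | "gompertz"
    smoothing: float | str | None = None
    window_min: float = DEFAULT_WINDOW_MIN
    warning: str | None = None
    params: dict = field(default_factory=dict)


class GompertzFitError(RuntimeError):
    """Nonlinear fit failed; carries the initial values that were tried."""

    def __init__(self, message: str, init: dict):
        super().__init__(f"{message} (initial values: {init})")
        self.init = init


def _truncate(curve: GrowthCurve, window_min: float):
    mask = curve.time_min <= curve.time_min[0] + window_min
    t, od = curve.time_min[mask], curve.od830[mask]
    if t.size < 10:
        raise ValueError("fewer than 10 samples inside the analysis window")
    return t, od


def _cv_smoothing(t: np.ndarray, od: np.ndarray, lam_grid: np.ndarray, folds: int = 3) -> float:
    """Roughness penalty selected by interleaved k-fold cross-validation.

    Every ``folds``-th point is held out (endpoints always kept to avoid
    extrapolation).  The winner is the *largest* penalty whose held-out
    squared error is within one standard error of the minimum (the 1-SE
    rule): prediction error is nearly flat across a wide penalty range,
    while the derivative - the quantity of interest - is far more stable
    under the stronger smoothing.
    """
    fold_errs = np.zeros((lam_grid.size, folds))
    for li, lam in enumerate(lam_grid):
        for f in range(folds):
            test = np.zeros(t.size, dtype=bool)
            test[f::folds] = True
            test[0] = test[-1] = False
            sp = make_smoothing_spline(t[~test], od[~test], lam=lam)
            r = od[test] - sp(t[test])
            fold_errs[li, f] = float(r @ r)
    total = fold_errs.sum(axis=1)
    imin = int(np.argmin(total))
    se = fold_errs[imin].std(ddof=1) * math.sqrt(folds)
    admissible = np.nonzero(total <= total[imin] + se)[0]
    return float(lam_grid[admissible.max()])


def estimate_growth_rate(
    curve: GrowthCurve,
    smoothing: float | str = "auto",
    *,
    window_min: float = DEFAULT_WINDOW_MIN,
    log_scale: bool = True,
    min_detect_od: float = 0.005,
) -> GrowthRateEstimate:
    """Spline estimate of ``mu_max``, the maximum specific growth rate.

    A cubic smoothing spline S(t) is fitted to the OD830 series over the
    analysis window (default ~2,500 min); ``smoothing="auto"`` selects the
    roughness penalty by interleaved cross-validation on a fixed log-spaced
    grid whose lower end acts as a floor against interpolating noise.  The
    growth rate is the maximum of d log S/dt = S'(t)/S(t), the derivative
    of log-OD, evaluated where the fitted curve clears the measurement
    noise floor (``min_detect_od`` or five robust noise SDs, whichever is
    larger) - additive plate-reader noise makes log-OD itself unusable at
    low densities.  A monotone-decreasing series yields ``mu_max <= 0``
    with a warning flag rather than an error.  ``log_scale=False`` returns
    the maximum raw-OD derivative instead (OD units/min, for comparison
    only).
    """
    t, od = _truncate(curve, window_min)
    if np.ptp(od) < 1e-12:
        # perfectly flat series: the derivative is identically zero
        return GrowthRateEstimate(
            mu_max=0.0, t_at_max=float(t[0]), method="spline",
            smoothing=smoothing, window_min=window_min,
        )
    if smoothing == "auto":
        lam = _cv_smoothing(t, od, np.logspace(0, 10, 12))
    else:
        lam = float(smoothing)
    spline = make_smoothing_spline(t, od, lam=lam)
    fitted = spline(t)
    resid = od - fitted
    noise_sd = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    grid = np.union1d(t, np.linspace(t[0], t[-1], 4 * t.size))
    S = spline(grid)
    D = spline.derivative()(grid)
    if log_scale:
        mask = S >= max(min_detect_od, 5.0 * noise_sd)
        if not mask.any():
            mask = S >= max(float(S.max()) * 0.05, 1e-12)
        rate = D[mask] / S[mask]
        sub = grid[mask]
    else:
        rate, sub = D, grid
    i = int(np.argmax(rate))
    mu = float(rate[i])
    warning = "non-positive maximum derivative (declining series?)" if mu <= 0 else None
    return GrowthRateEstimate(
        mu_max=mu,
        t_at_max=float(sub[i]),
        method="spline",
        smoothing=lam,
        window_min=window_min,
        warning=warning,
    )


def _gompertz_log_od(t, log_od0, A, mu, lag):
    z = mu * _E / A * (lag - t) + 1.0
    return log_od0 + A * np.exp(-np.exp(np.minimum(z, 700.0)))


def fit_gompertz(
    curve: GrowthCurve,
    *,
    window_min: float = DEFAULT_WINDOW_MIN,
) -> GrowthRateEstimate:
    """Nonlinear least-squares fit of the modified Gompertz law in log-OD.

    Initialisation is deterministic: the lag from the first time OD exceeds
    twice the inoculum, ``mu`` from the spline estimate, the asymptote from
    the maximum observed OD.  Raises :class:`GompertzFitError` (carrying the
    initialisation) on non-convergence or degenerate input.
    """
    t, od = _truncate(curve, window_min)
    y = np.log(od)
    A0 = float(y.max() - y.min())
    above = np.nonzero(od >= 2.0 * od[0])[0]
    lag0 = float(t[above[0]]) if above.size else float(t[0] + (t[-1] - t[0]) / 4)
    try:
        mu0 = max(estimate_growth_rate(curve, window_min=window_min).mu_max, 1e-6)
    except ValueError:
        mu0 = 1e-3
    init = {"log_od0": float(y[0]), "A": A0, "mu": mu0, "lag": lag0}
    if A0 < 1e-8:
        raise GompertzFitError("no growth in the series: Gompertz asymptote is zero", init)
    try:
        popt, _ = curve_fit(
            _gompertz_log_od,
            t,
            y,
            p0=[init["log_od0"], A0, mu0, lag0],
            bounds=([-np.inf, 1e-9, 1e-9, 0.0], [np.inf, np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise GompertzFitError(f"Gompertz fit did not converge: {exc}", init) from exc
    log_od0, A, mu, lag = (float(v) for v in popt)
    return GrowthRateEstimate(
        mu_max=mu,
        t_at_max=lag + A / (mu * _E),  # inflection of the Gompertz curve
        method="gompertz",
        window_min=window_min,
        params={"log_od0": log_od0, "A": A, "mu_max": mu, "lag": lag},
    )


def estimate_replicate_rates(
    assay: pd.DataFrame,
    method: str = "spline",
    **kwargs,
) -> pd.DataFrame:
    """Estimate ``mu_max`` for every (strain, replicate) in a tidy assay frame.

    Expects columns ``strain_id, replicate, time_min, od830`` (plus
    ``temperature_C``); returns one row per replicate with the estimate.
    """
    estimator = {"spline": estimate_growth_rate, "gompertz": fit_gompertz}[method]
    rows = []
    for (sid, rep), grp in assay.groupby(["strain_id", "replicate"], sort=True):
        grp = grp.sort_values("time_min")
        curve = GrowthCurve(
            culture_id=str(sid),
            time_min=grp["time_min"].to_numpy(),
            od830=grp["od830"].to_numpy(),
            temperature_C=int(grp["temperature_C"].iloc[0]) if "temperature_C" in grp else 37,
            replicate_id=int(rep),
        )
        est = estimator(curve, **kwargs)
        rows.append(
            {
                "strain_id": sid,
                "replicate": rep,
                "temperature_C": curve.temperature_C,
                "mu_max": est.mu_max,
                "method": est.method,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RelativeGrowthResult:
    strain_id: str
    temperature_C: int
    ratio: float  # mean evolved mu / mean ancestor mu, dimensionless
    test: PooledTResult

    @property
    def t_stat(self) -> float:
        return self.test.t_stat

    @property
    def p_value(self) -> float:
        return self.test.p_value


def relative_growth_test(
    evolved,
    ancestor,
    pooled_pool=None,
    *,
    strain_id: str = "",
    temperature_C: int = 0,
) -> RelativeGrowthResult:
    """Relative growth rate and pooled-variance t-test against the ancestor.

    ``evolved`` and ``ancestor`` are replicate ``mu_max`` values (original
    scale); ``pooled_pool`` lists every replicate group measured at this
    temperature, from which the common standard deviation is estimated with
    ``df = sum(n_i - 1)``.  Defaults to pooling only the two compared
    groups, which is the classical equal-variance two-sample t-test.
    """
    evolved = np.asarray(evolved, dtype=float)
    ancestor = np.asarray(ancestor, dtype=float)
    result = pooled_group_t(evolved, ancestor, pooled_pool)
    if result.mean_0 <= 0:
        raise ValueError("ancestor mean growth rate must be positive for a ratio")
    return RelativeGrowthResult(
        strain_id=strain_id,
        temperature_C=int(temperature_C),
        ratio=result.mean_1 / result.mean_0,
        test=result,
    )


CATEGORIES = ("generalist", "specialist_15", "specialist_43", "not_significant")


@dataclass(frozen=True)
class StrategyCall:
    strain_id: str
    category: str
    result_15: RelativeGrowthResult
    result_43: RelativeGrowthResult
    alpha: float = 0.05


def classify_strategy(
    result_15: RelativeGrowthResult,
    result_43: RelativeGrowthResult,
    alpha: float = 0.05,
    *,
    strict_ratio_gates: bool = False,
) -> StrategyCall:
    """Classify a strain as generalist / specialist / not significant.

    A temperature shows a *significant increase* when p < alpha and the
    relative growth ratio exceeds 1.  Generalist: both temperatures;
    specialist: exactly one (a significant *decrease* at the other
    temperature neither creates a call nor vetoes this one); otherwise not
    significant.  ``strict_ratio_gates`` additionally requires ratio >= 1.15
    at 15 degC and >= 1.30 at 43 degC.
    """
    if {result_15.temperature_C, result_43.temperature_C} != {15, 43}:
        raise ValueError("expected one result at 15 degC and one at 43 degC")
    if result_15.temperature_C == 43:  # order-invariant
        result_15, result_43 = result_43, result_15
    if result_15.strain_id != result_43.strain_id:
        raise ValueError(
            f"mismatched strains: {result_15.strain_id!r} vs {result_43.strain_id!r}"
        )

    def increased(res: RelativeGrowthResult, gate: float) -> bool:
        ok = res.p_value < alpha and res.ratio > 1.0
        if strict_ratio_gates:
            ok = ok and res.ratio >= gate
        return ok

    up15 = increased(result_15, 1.15)
    up43 = increased(result_43, 1.30)
    if up15 and up43:
        category = "generalist"
    elif up15:
        category = "specialist_15"
    elif up43:
        category = "specialist_43"
    else:
        category = "not_significant"
    return StrategyCall(
        strain_id=result_15.strain_id,
        category=category,
        result_15=result_15,
        result_43=result_43,
        alpha=alpha,
    )


def fisher_strategy_enrichment(counts) -> float:
    """Two-sided Fisher exact p for a 2x2 strategy-by-group count table."""
    return fisher_exact_2x2(counts)


def strategy_table(calls) -> pd.DataFrame:
    """Flatten strategy calls into a per-strain results table."""
    rows = []
    for call in calls:
        rows.append(
            {
                "strain_id": call.strain_id,
                "category": call.category,
                "ratio_15": call.result_15.ratio,
                "p_15": call.result_15.p_value,
                "t_15": call.result_15.t_stat,
                "ratio_43": call.result_43.ratio,
                "p_43": call.result_43.p_value,
                "t_43": call.result_43.t_stat,
            }
        )
    return pd.DataFrame(rows)
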