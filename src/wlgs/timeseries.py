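"""Time-series handling of the cohesion index and its correlates.

Measurement series in this setting are irregular — proximity sessions run
twice a week, ethological video scoring every other week, questionnaires
monthly.  To compare them day-by-day all are oversampled onto a common
daily grid with an interpolating cubic spline that keeps the original
points fixed, then correlated over the overlapping days.  The long-run
cohesion trend is quantified by ordinary least squares of CRTI on mission
day (the standardized slope of a simple regression equals the Pearson
correlation), and near-term forecasting uses an ARIMA model with lag-1
differencing, order chosen by information criterion.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .errors import (
    ConstantSeriesError,
    ExtrapolationError,
    FitError,
    InsufficientDataError,
    InsufficientOverlapError,
)
from .sociometry import ChoiceTable


def _as_series(series: pd.Series | Sequence[float]) -> pd.Series:
    s = pd.Series(series) if not isinstance(series, pd.Series) else series
    if s.index.duplicated().any():
        raise ValueError("duplicate days in series")
    if not np.isfinite(s.to_numpy(dtype=float)).all():
        raise ValueError("series values must be finite")
    return s.sort_index()


def spline_resample(series: pd.Series, grid: np.ndarray | None = None) -> pd.Series:
    """Oversample an irregular series onto a daily grid.

    An interpolating natural cubic spline is fitted through the observed
    (day, value) points — the original points stay fixed — and evaluated
    at every integer day between the first and last observation (or at an
    explicit ``grid``).  No extrapolation: requesting days outside the
    observed range raises :class:`ExtrapolationError`.
    """
    s = _as_series(series)
    if len(s) < 4:
        raise InsufficientDataError("cubic spline needs at least 4 points")
    days = s.index.to_numpy(dtype=float)
    if grid is None:
        grid = np.arange(int(np.ceil(days[0])), int(np.floor(days[-1])) + 1)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < days[0] or grid.max() > days[-1]:
        raise ExtrapolationError("requested days fall outside the observed range")
    cs = interpolate.CubicSpline(days, s.to_numpy(dtype=float), bc_type="natural")
    out = pd.Series(cs(grid), index=grid.astype(int), name=s.name)
    return out


@dataclass
class TrendResult:
    """Simple-regression trend: standardized slope (= Pearson r), fit
    quality and two-sided p-value, plus the raw slope/intercept."""

    beta: float  # standardized slope
    r_squared: float
    p_value: float
    slope: float
    intercept: float


def linear_trend(series: pd.Series) -> TrendResult:
    """OLS of value on day; the standardized beta of a simple regression
    equals the Pearson correlation between value and day."""
    s = _as_series(series)
    if len(s) < 3:
        raise InsufficientDataError("trend needs at least 3 points")
    y = s.to_numpy(dtype=float)
    x = s.index.to_numpy(dtype=float)
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        raise ConstantSeriesError("trend undefined for a constant series")
    res = stats.linregress(x, y)
    return TrendResult(
        beta=float(res.rvalue),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
    )


def correlate_series(
    a: pd.Series, b: pd.Series, method: str = "pearson"
) -> tuple[float, float]:
    """Correlate two daily series over the intersection of their days."""
    a, b = _as_series(a), _as_series(b)
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise InsufficientOverlapError("fewer than 3 overlapping days")
    x = a.loc[common].to_numpy(dtype=float)
    y = b.loc[common].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantSeriesError("correlation undefined for a constant series")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method: {method!r}")
    return float(r), float(p)


def choices_correlation(
    wlgs_choices: ChoiceTable, questionnaire: ChoiceTable
) -> tuple[float, float]:
    """Spearman rank correlation between two choice tables over their
    ordered (chooser, chosen) cells — 30 cells for a crew of 6."""
    if wlgs_choices.members != questionnaire.members:
        raise ValueError("choice tables cover different crews")
    a = wlgs_choices.ordered_cells()
    b = questionnaire.ordered_cells()
    x, y = a.to_numpy(), b.to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantSeriesError("rank correlation undefined: a table has no variance")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


@dataclass
class ForecastResult:
    """A fitted ARIMA model and its residual diagnostics."""

    order: tuple[int, int, int]
    aic: float
    params: pd.Series
    fitted_days: pd.Index
    resid_acf: np.ndarray
    resid_pacf: np.ndarray
    _result: object  # statsmodels results, kept for forecasting

    def to_report(self) -> dict:
        return {
            "order": list(self.order),
            "aic": self.aic,
            "params": {k: float(v) for k, v in self.params.items()},
            "resid_acf": [float(v) for v in self.resid_acf],
            "resid_pacf": [float(v) for v in self.resid_pacf],
        }

    def write_report(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_report(), indent=2), encoding="utf-8")


def fit_arima(
    series: pd.Series,
    d: int = 1,
    max_pq: int = 3,
    ic: str = "bic",
    order: tuple[int, int, int] | None = None,
    n_diag_lags: int = 20,
) -> ForecastResult:
    """Fit an ARIMA(p, d, q) to a daily series.

    By default p and q (each up to ``max_pq``, at fixed differencing
    order ``d``) are selected by the lowest information criterion (BIC by
    default; its stronger parameter penalty keeps degenerate series from
    attracting spurious AR/MA terms).  Pass an explicit ``order`` to skip
    the search.  Candidates that fail to converge are skipped; if every
    candidate fails a :class:`FitError` is raised.  Residual ACF/PACF are
    reported for diagnostic inspection of the differenced (stationary)
    fit.
    """
    from statsmodels.tsa.arima.model import ARIMA
    from statsmodels.tsa.stattools import acf, pacf

    if ic not in ("aic", "bic"):
        raise ValueError(f"unknown information criterion: {ic!r}")
    s = _as_series(series)
    if len(s) < 30:
        raise InsufficientDataError("ARIMA needs at least 30 observations")
    y = s.to_numpy(dtype=float)
    candidates = (
        [order] if order is not None else
        [(p, d, q) for p in range(max_pq + 1) for q in range(max_pq + 1)]
    )
    best = None
    for cand in candidates:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = ARIMA(y, order=cand).fit()
        except Exception:
            continue
        crit = getattr(res, ic)
        if not np.isfinite(crit):
            continue
        if best is None or crit < best[1]:
            best = (cand, crit, res)
    if best is None:
        raise FitError("no ARIMA candidate converged")
    order, _, res = best
    d = order[1]
    aic = res.aic
    resid = np.asarray(res.resid, dtype=float)[d:]
    lags = min(n_diag_lags, len(resid) // 2 - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r_acf = acf(resid, nlags=lags, fft=True)
        r_pacf = pacf(resid, nlags=lags)
    return ForecastResult(
        order=order,
        aic=float(aic),
        params=pd.Series(res.params, index=res.param_names),
        fitted_days=s.index,
        resid_acf=r_acf,
        resid_pacf=r_pacf,
        _result=res,
    )


def forecast(fitted: ForecastResult, horizon: int, level: float = 0.95) -> pd.DataFrame:
    """Point forecasts and central prediction intervals for ``horizon``
    days past the fitted range; columns ``forecast, lo, hi`` indexed by
    day."""
    if horizon < 1:
        raise ValueError("horizon must be at least 1")
    fc = fitted._result.get_forecast(steps=horizon)
    ci = fc.conf_int(alpha=1 - level)
    ci = np.asarray(ci, dtype=float)
    last_day = int(fitted.fitted_days[-1])
    days = np.arange(last_day + 1, last_day + 1 + horizon)
    return pd.DataFrame(
        {
            "forecast": np.asarray(fc.predicted_mean, dtype=float),
            "lo": ci[:, 0],
            "hi": ci[:, 1],
        },
        index=pd.Index(days, name="day"),
    )


def read_series(path: str | Path, value_col: str | None = None) -> pd.Series:
    """Read a ``day,value`` CSV into a day-indexed series."""
    df = pd.read_csv(path)
    if value_col is None:
        value_col = [c for c in df.columns if c != "day"][0]
    return pd.Series(
        df[value_col].to_numpy(dtype=float), index=df["day"].astype(int), name=value_col
    )


def write_series(series: pd.Series, path: str | Path) -> None:
    s = _as_series(series)
    pd.DataFrame({"day": s.index, s.name or "value": s.to_numpy()}).to_csv(path, index=False)
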