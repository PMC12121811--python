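"""Per-class projection of areas and carbon densities.

Three forecasters, all point-valued:

* :class:`GM11` — the first-order single-variable grey model, written from
  scratch: cumulative-sum (AGO) transform, background values
  z¹(k) = ½(x¹(k) + x¹(k−1)), least-squares development coefficient ``a`` and
  grey input ``b`` from x⁰(k) = −a·z¹(k) + b, exponential time response
  x̂¹(k) = (x⁰(1) − b/a)·e^{−a(k−1)} + b/a restored by first differencing.
* :class:`ArimaForecaster` — a thin deterministic wrapper over statsmodels
  ARIMA with exhaustive (p, d, q) ≤ (2, 2, 2) order selection by AICc.
* :class:`EnsembleForecaster` — the arithmetic mean of the two, which is how
  the projected areas and densities feeding the impact equations are built.

Classes whose series are trendless noise around a stable level (lakes, ice
and snow, wasteland, wetland density) are better served by their historical
mean than by either extrapolator; :func:`apply_stationary_overrides` swaps
those entries in.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .accounting import historical_mean
from .io import CarbonAccountTable, ValidationError

QUANTITY_COLUMNS = {"area": "area_km2", "density": "density_gm2"}

#: (class, quantity) pairs replaced by their 2000-2020 historical mean in the
#: study configuration: series that fluctuate around a stable level.
DEFAULT_OVERRIDES: tuple[tuple[str, str], ...] = (
    ("lake", "area"),
    ("ice_snow", "area"),
    ("wasteland", "area"),
    ("wetland", "density"),
    ("lake", "density"),
)


class GM11(BaseEstimator):
    """GM(1,1) grey forecaster.

    Fitted attributes: ``a_`` (development coefficient), ``b_`` (grey input),
    ``x0_1_`` (initial condition), ``n_obs_``.  ``predict(steps)`` returns the
    restored x̂⁰ value ``steps`` observations past the end of the training
    series; in-sample reconstructions come from ``fitted_values()``.
    """

    def fit(self, y, X=None):
        y = np.asarray(y, dtype=float).reshape(-1)
        if y.size < 4:
            raise ValidationError(f"GM(1,1) needs >= 4 observations, got {y.size}")
        if (y <= 0).any():
            raise ValidationError("GM(1,1) requires strictly positive values")
        x1 = np.cumsum(y)
        z1 = 0.5 * (x1[1:] + x1[:-1])
        B = np.column_stack([-z1, np.ones_like(z1)])
        sol, _, rank, _ = np.linalg.lstsq(B, y[1:], rcond=None)
        if rank < 2:
            raise ValidationError("degenerate series: grey normal equations singular")
        self.a_, self.b_ = float(sol[0]), float(sol[1])
        self.x0_1_ = float(y[0])
        self.n_obs_ = int(y.size)
        return self

    @classmethod
    def from_params(cls, a: float, b: float, x0_1: float, n_obs: int = 4) -> "GM11":
        """Build an already-'fitted' model from explicit grey parameters."""
        model = cls()
        model.a_, model.b_, model.x0_1_, model.n_obs_ = (
            float(a), float(b), float(x0_1), int(n_obs),
        )
        return model

    def _x1_hat(self, k: np.ndarray) -> np.ndarray:
        # k is 1-based position in the AGO series
        if abs(self.a_) < 1e-12:  # limit form: x1 grows linearly by b
            return self.x0_1_ + self.b_ * (k - 1)
        c = self.x0_1_ - self.b_ / self.a_
        return c * np.exp(-self.a_ * (k - 1)) + self.b_ / self.a_

    def _x0_hat(self, k: np.ndarray) -> np.ndarray:
        k = np.asarray(k)
        out = self._x1_hat(k) - self._x1_hat(k - 1)
        return np.where(k == 1, self.x0_1_, out)

    def fitted_values(self) -> np.ndarray:
        """In-sample reconstruction x̂⁰(1..n)."""
        self._check_fitted()
        return self._x0_hat(np.arange(1, self.n_obs_ + 1))

    def predict(self, steps):
        """Forecast ``steps`` observations past the training series.

        Accepts a positive int or an array of them; returns a scalar or array.
        """
        self._check_fitted()
        arr = np.asarray(steps)
        if (arr <= 0).any():
            raise ValidationError("steps_ahead must be positive")
        out = self._x0_hat(self.n_obs_ + arr)
        return float(out) if np.isscalar(steps) else out

    def _check_fitted(self) -> None:
        if not hasattr(self, "a_"):
            raise ValidationError("GM11 is not fitted")


class ArimaForecaster(BaseEstimator):
    """Deterministic ARIMA point forecaster.

    When ``order`` is None the order is selected exhaustively over
    (p, d, q) ∈ {0,1,2}³ by corrected AIC, ties broken by smallest p+d+q then
    lexicographically.  The deterministic trend term is a constant for d = 0,
    a drift (linear) term for d = 1 and nothing for d ≥ 2, so integrated fits
    extrapolate trends rather than flattening.
    """

    MAX_ORDER = (2, 2, 2)

    def __init__(self, order: tuple[int, int, int] | None = None):
        self.order = order

    def fit(self, y, X=None):
        y = np.asarray(y, dtype=float).reshape(-1)
        if self.order is None and y.size < 8:
            raise ValidationError(
                f"automatic order selection needs >= 8 observations, got {y.size}"
            )
        if self.order is not None:
            self.order_ = tuple(self.order)
            self.results_ = self._fit_order(y, self.order_, raise_on_error=True)
        else:
            candidates = []
            for order in itertools.product(
                *(range(m + 1) for m in self.MAX_ORDER)
            ):
                res = self._fit_order(y, order, raise_on_error=False)
                if res is None or not np.isfinite(res.aicc):
                    continue
                candidates.append((res.aicc, sum(order), order, res))
            if not candidates:
                raise ValidationError("no ARIMA order could be fitted to the series")
            candidates.sort(key=lambda c: (c[0], c[1], c[2]))
            _, _, self.order_, self.results_ = candidates[0]
        self.n_obs_ = int(y.size)
        return self

    @staticmethod
    def _fit_order(y, order, *, raise_on_error: bool):
        from statsmodels.tsa.arima.model import ARIMA

        d = order[1]
        trend = "c" if d == 0 else "t" if d == 1 else "n"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return ARIMA(y, order=order, trend=trend).fit()
        except (ValueError, IndexError, np.linalg.LinAlgError) as exc:
            if raise_on_error:
                raise ValidationError(
                    f"ARIMA order {order} could not be fitted: {exc}"
                ) from exc
            return None

    def predict(self, steps):
        if not hasattr(self, "results_"):
            raise ValidationError("ArimaForecaster is not fitted")
        arr = np.asarray(steps)
        if (arr <= 0).any():
            raise ValidationError("steps_ahead must be positive")
        horizon = int(arr.max())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            path = np.asarray(self.results_.forecast(horizon))
        out = path[arr - 1]
        return float(out) if np.isscalar(steps) else out


class EnsembleForecaster(BaseEstimator):
    """Arithmetic mean of the GM(1,1) and ARIMA point forecasts."""

    def __init__(self, arima_order: tuple[int, int, int] | None = None):
        self.arima_order = arima_order

    def fit(self, y, X=None):
        self.grey_ = GM11().fit(y)
        self.arima_ = ArimaForecaster(order=self.arima_order).fit(y)
        self.n_obs_ = int(np.asarray(y).size)
        return self

    def predict(self, steps):
        return ensemble_mean(self.grey_.predict(steps), self.arima_.predict(steps))


def ensemble_mean(grey_value, arima_value):
    """The combination rule: plain arithmetic mean of the two forecasts."""
    return (grey_value + arima_value) / 2.0


@dataclass
class ForecastSet:
    """Per-(class, quantity, year) point forecasts with provenance.

    ``df`` columns: class, quantity ∈ {area, density}, year, grey, arima,
    value, method ∈ {grey, arima, ensemble, mean_override}, input_years.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["class", "quantity", "year", "grey", "arima", "value",
                 "method", "input_years"]
    ))

    def value(self, class_name: str, quantity: str, year: int) -> float:
        row = self._row(class_name, quantity, year)
        return float(row["value"])

    def method(self, class_name: str, quantity: str, year: int) -> str:
        return str(self._row(class_name, quantity, year)["method"])

    def _row(self, class_name: str, quantity: str, year: int) -> pd.Series:
        m = self.df[
            (self.df["class"] == class_name)
            & (self.df["quantity"] == quantity)
            & (self.df["year"] == year)
        ]
        if len(m) == 0:
            raise KeyError(f"no forecast for ({class_name}, {quantity}, {year})")
        return m.iloc[0]

    def per_class(self, quantity: str, year: int) -> pd.Series:
        sub = self.df[(self.df["quantity"] == quantity) & (self.df["year"] == year)]
        return sub.set_index("class")["value"].astype(float)

    def add(self, **kwargs) -> None:
        row = pd.DataFrame([kwargs]).reindex(columns=self.df.columns)
        if self.df.empty:
            self.df = row
        else:
            self.df = pd.concat([self.df, row], ignore_index=True)


def ensemble_forecast(
    series: pd.Series,
    target_year: int,
    *,
    quantity: str = "area",
    class_name: str = "",
    arima_order: tuple[int, int, int] | None = None,
) -> dict:
    """Ensemble point forecast of a year-indexed series at ``target_year``.

    Returns a ForecastSet entry dict carrying both component forecasts.
    """
    s = pd.Series(series).dropna().sort_index()
    last_year = int(s.index.max())
    steps = target_year - last_year
    if steps <= 0:
        raise ValidationError(
            f"target year {target_year} is not beyond the series end {last_year}"
        )
    try:
        grey = GM11().fit(s.to_numpy()).predict(steps)
        arima = ArimaForecaster(order=arima_order).fit(s.to_numpy()).predict(steps)
    except ValidationError as exc:
        raise ValidationError(
            f"forecast failed for ({class_name or '<series>'}, {quantity}, "
            f"{target_year}): {exc}"
        ) from exc
    return {
        "class": class_name, "quantity": quantity, "year": target_year,
        "grey": grey, "arima": arima, "value": ensemble_mean(grey, arima),
        "method": "ensemble",
        "input_years": f"{int(s.index.min())}-{last_year}",
    }


def forecast_accounts(
    history: CarbonAccountTable,
    target_years: list[int],
    *,
    classes: list[str] | None = None,
    quantities: tuple[str, ...] = ("area", "density"),
    arima_orders: dict | None = None,
) -> ForecastSet:
    """Ensemble-forecast every available (class, quantity) series."""
    classes = classes if classes is not None else history.classes
    arima_orders = arima_orders or {}
    fs = ForecastSet()
    for cls in classes:
        for quantity in quantities:
            col = QUANTITY_COLUMNS[quantity]
            series = history.series(cls, col)
            if series.empty:
                continue
            for year in target_years:
                fs.add(**ensemble_forecast(
                    series, year, quantity=quantity, class_name=cls,
                    arima_order=arima_orders.get((cls, quantity)),
                ))
    return fs


def apply_stationary_overrides(
    forecasts: ForecastSet,
    history: CarbonAccountTable,
    override_spec: tuple[tuple[str, str], ...] = DEFAULT_OVERRIDES,
) -> ForecastSet:
    """Replace named (class, quantity) forecasts with historical means.

    Every target year in the forecast set gets the same mean value, tagged
    ``mean_override``.  An override naming a class/quantity with no history is
    an error.  Entries absent from the forecast set are added for every target
    year present in it.
    """
    if not override_spec:
        return ForecastSet(forecasts.df.copy())
    df = forecasts.df.copy()
    years = sorted(df["year"].unique())
    for cls, quantity in override_spec:
        col = QUANTITY_COLUMNS[quantity]
        try:
            series = history.series(cls, col)
        except KeyError as exc:
            raise ValidationError(
                f"override for ({cls}, {quantity}) but history has no such series"
            ) from exc
        if series.empty:
            raise ValidationError(
                f"override for ({cls}, {quantity}) but history has no such series"
            )
        mean = historical_mean(series)
        provenance = f"{int(series.index.min())}-{int(series.index.max())}"
        sel = (df["class"] == cls) & (df["quantity"] == quantity)
        df = df[~sel]
        new_rows = [
            {
                "class": cls, "quantity": quantity, "year": y,
                "grey": np.nan, "arima": np.nan, "value": mean,
                "method": "mean_override", "input_years": provenance,
            }
            for y in years
        ]
        df = pd.concat([df, pd.DataFrame(new_rows)], ignore_index=True)
    df = df.sort_values(["quantity", "class", "year"]).reset_index(drop=True)
    return ForecastSet(df)
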