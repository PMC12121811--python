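"""Unit-consistent carbon accounting and density-trend fitting.

Unit conventions, fixed package-wide: areas in km², carbon densities in g/m²,
annual sequestration amounts and standing stocks in 10⁴ t.  The two
conversions used everywhere are

    density [g/m²]  = sequestration [10⁴ t] / area [km²] × 10⁴
    stock [10⁴ t]   = area [km²] × density [g/m²] / 10⁴

(10⁴ t = 10¹⁰ g and 1 km² = 10⁶ m², so km²·g/m² = 10⁶ g = 1 t.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .io import ValidationError, as_class_series


def carbon_density(area_km2: float, seq_1e4t: float) -> float:
    """Carbon density in g/m² from area (km²) and sequestration (10⁴ t)."""
    if area_km2 <= 0:
        raise ValidationError(f"area must be > 0, got {area_km2}")
    if seq_1e4t < 0:
        raise ValidationError(f"sequestration must be >= 0, got {seq_1e4t}")
    return seq_1e4t / area_km2 * 1e4


def sequestration_from_density(area_km2: float, density_gm2: float) -> float:
    """Sequestration (10⁴ t) from area (km²) and density (g/m²)."""
    if area_km2 < 0 or density_gm2 < 0:
        raise ValidationError("area and density must be >= 0")
    return area_km2 * density_gm2 / 1e4


def historical_mean(series) -> float:
    """Arithmetic mean of a yearly series (the stationary-class estimate)."""
    values = np.asarray(pd.Series(series).dropna(), dtype=float)
    if values.size == 0:
        raise ValidationError("cannot take the mean of an empty series")
    return float(values.mean())


def total_standing_stock(areas, densities) -> float:
    """Σ area × density over classes, in 10⁴ t.

    Both inputs are per-class mappings or Series over the same class set;
    a class present in one but not the other is an error.
    """
    a = as_class_series(areas, "area")
    d = as_class_series(densities, "density")
    only_a = set(a.index) - set(d.index)
    only_d = set(d.index) - set(a.index)
    if only_a or only_d:
        raise ValidationError(
            f"class sets differ: areas-only {sorted(only_a)}, "
            f"densities-only {sorted(only_d)}"
        )
    d = d.loc[a.index]
    return float((a * d).sum() / 1e4)


@dataclass
class DensityTrend:
    """Fitted linear density trend for one class.

    ``annual_increment`` is the least-squares slope in g/m² per year;
    ``relative_beta`` is the dimensionless per-horizon growth coefficient
    β = slope × horizon / ρ(reference year), the factor by which the
    effective density ρ(1+β) is scaled in the transfer equations.
    """

    class_name: str
    annual_increment: float
    relative_beta: float
    fit_r2: float
    n_years: int
    horizon_years: int
    reference_year: int
    reference_density: float


class DensityTrendModel(BaseEstimator, RegressorMixin):
    """OLS linear trend of a per-class yearly series.

    scikit-learn-style univariate regressor on (year, value); the fitted
    attributes expose the slope (g/m² yr⁻¹), intercept and R².

    Parameters
    ----------
    horizon_years : projection horizon over which the relative growth
        coefficient β accumulates.
    reference_year : year whose observed value anchors β; defaults to the
        last observed year.
    """

    def __init__(self, horizon_years: int = 5, reference_year: int | None = None):
        self.horizon_years = horizon_years
        self.reference_year = reference_year

    def fit(self, X, y=None):
        """Fit on years X (1-D or column vector) and values y."""
        x = np.asarray(X, dtype=float).reshape(-1)
        yv = np.asarray(y, dtype=float).reshape(-1)
        if x.size != yv.size:
            raise ValidationError("years and values differ in length")
        if x.size < 3:
            raise ValidationError(f"need >= 3 yearly observations, got {x.size}")
        if np.ptp(x) == 0:
            raise ValidationError("zero variance in year")
        res = stats.linregress(x, yv)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r2_ = float(res.rvalue**2) if np.ptp(yv) > 0 else 1.0
        self.n_obs_ = int(x.size)
        self.years_ = x
        self.values_ = yv
        ref_year = self.reference_year if self.reference_year is not None else int(x.max())
        self.reference_year_ = int(ref_year)
        where = np.flatnonzero(x == ref_year)
        if where.size:
            self.reference_value_ = float(yv[where[0]])
        else:  # reference year outside the sample: use the fitted line
            self.reference_value_ = float(self.intercept_ + self.slope_ * ref_year)
        if self.reference_value_ > 0:
            self.beta_ = self.slope_ * self.horizon_years / self.reference_value_
        else:
            self.beta_ = 0.0
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.slope_ * x


def fit_density_trend(
    series: pd.Series,
    horizon_years: int,
    reference_year: int | None = None,
    class_name: str = "",
) -> DensityTrend:
    """Fit an OLS density trend on a year-indexed series and derive β."""
    s = pd.Series(series).dropna().sort_index()
    model = DensityTrendModel(
        horizon_years=horizon_years, reference_year=reference_year
    ).fit(s.index.to_numpy(), s.to_numpy())
    return DensityTrend(
        class_name=class_name,
        annual_increment=model.slope_,
        relative_beta=model.beta_,
        fit_r2=model.r2_,
        n_years=model.n_obs_,
        horizon_years=horizon_years,
        reference_year=model.reference_year_,
        reference_density=model.reference_value_,
    )
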