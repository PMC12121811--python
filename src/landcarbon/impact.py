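"""Transfer-in/transfer-out impact of land-use change on carbon sequestration.

For classes i with areas S (km²), effective carbon densities
e_i = ρ_i(1 + β_i) (g/m²) and transition probabilities a(i, q):

    ZR_i = Σ_t S_t · (e_i − e_t) · a(t, i)     transfer-in impact (t)
    ZC_i = Σ_t S_i · (e_t − e_i) · a(i, t)     transfer-out impact (t)
    GTYX = Σ_i (ZR_i + ZC_i)                   total impact (t)
    GTZG = Σ_i S_i ρ_i / 10⁴ + GTYX / 10⁴      total sequestration (10⁴ t)

km² × g/m² = 10⁶ g = 1 t, so no unit factor appears inside ZR/ZC.  The
diagonal terms vanish because e_i − e_i = 0.  Written this way, each ordered
flow (t → i) contributes the same quantity once to ZR_i and once (negated
source-side view) to ZC_t, which forces Σ ZR = Σ ZC on any input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import forecasting
from .accounting import fit_density_trend, total_standing_stock
from .io import CarbonAccountTable, ValidationError, as_class_series
from .transitions import TransitionMatrix

#: Classes with no tabulated carbon accounts carry zero density and zero
#: trend unless overridden.
ZERO_DENSITY_CLASSES = ("construction", "ice_snow", "wasteland")


@dataclass
class EffectiveDensity:
    """Carbon density ρ (g/m²) with its per-horizon growth coefficient β."""

    class_name: str
    rho: float
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValidationError(f"negative density for {self.class_name}")

    @property
    def effective(self) -> float:
        return self.rho * (1.0 + self.beta)


def effective_density_series(
    rho: Mapping[str, float] | pd.Series,
    beta: Mapping[str, float] | pd.Series | None = None,
    *,
    class_order: tuple[str, ...],
    default_rho: float = 0.0,
    default_beta: float = 0.0,
) -> pd.Series:
    """Per-class effective densities ρ(1+β) aligned to ``class_order``."""
    r = pd.Series(rho, dtype=float).reindex(list(class_order)).fillna(default_rho)
    if beta is None:
        b = pd.Series(default_beta, index=list(class_order), dtype=float)
    else:
        b = pd.Series(beta, dtype=float).reindex(list(class_order)).fillna(default_beta)
    if (r < 0).any():
        raise ValidationError("negative carbon density")
    eff = r * (1.0 + b)
    eff.name = "effective_gm2"
    return eff


@dataclass
class ImpactBreakdown:
    """Per-class ZR/ZC ledger and the total impact GTYX, all in tons."""

    zr: pd.Series
    zc: pd.Series
    metadata: dict = field(default_factory=dict)
    #: fixture mode may carry independently printed subtotals that differ
    #: from ZR+ZC by rounding of the underlying unprinted values
    subtotal_override: pd.Series | None = None

    @property
    def subtotal(self) -> pd.Series:
        s = self.subtotal_override if self.subtotal_override is not None else (
            self.zr + self.zc
        )
        s = s.copy()
        s.name = "subtotal_t"
        return s

    @property
    def gtyx(self) -> float:
        return float(self.subtotal.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"zr_t": self.zr, "zc_t": self.zc, "subtotal_t": self.subtotal}
        ).rename_axis("class")

    @classmethod
    def from_components(
        cls,
        zr: Mapping[str, float],
        zc: Mapping[str, float],
        subtotals: Mapping[str, float] | None = None,
        **metadata,
    ) -> "ImpactBreakdown":
        """Fixture mode: aggregate externally supplied per-class ZR/ZC.

        When printed per-class ``subtotals`` are supplied they take precedence
        over ZR+ZC in the aggregation (they may differ by rounding); a
        deviation beyond 1 t is an error.
        """
        zr_s = as_class_series(zr, "zr_t")
        zc_s = as_class_series(zc, "zc_t")
        if set(zr_s.index) != set(zc_s.index):
            raise ValidationError("ZR and ZC class sets differ")
        zc_s = zc_s.loc[zr_s.index]
        sub_s = None
        if subtotals is not None:
            sub_s = as_class_series(subtotals, "subtotal_t").loc[zr_s.index]
            if ((zr_s + zc_s - sub_s).abs() > 1.0).any():
                raise ValidationError(
                    "supplied subtotals deviate from ZR+ZC by more than 1 t"
                )
        return cls(zr=zr_s, zc=zc_s, metadata=metadata, subtotal_override=sub_s)


def _aligned(areas, eff, matrix: TransitionMatrix):
    order = list(matrix.class_order)
    S = pd.Series(areas, dtype=float).reindex(order)
    e = pd.Series(eff, dtype=float).reindex(order)
    inbound = matrix.probs.sum(axis=0) > 0
    outbound = matrix.probs.sum(axis=1) > 0
    touched = inbound | outbound
    missing_e = e.isna().to_numpy() & touched
    if missing_e.any():
        names = [order[i] for i in np.flatnonzero(missing_e)]
        raise ValidationError(f"missing effective density for classes {names}")
    missing_s = S.isna().to_numpy() & touched
    if missing_s.any():
        names = [order[i] for i in np.flatnonzero(missing_s)]
        raise ValidationError(f"missing area for classes {names}")
    return S.fillna(0.0).to_numpy(), e.fillna(0.0).to_numpy(), order


def transfer_in(
    class_name: str, areas, eff, matrix: TransitionMatrix
) -> float:
    """ZR for one class: impact of area flowing in from all other classes."""
    return float(transfer_in_all(areas, eff, matrix)[class_name])


def transfer_out(
    class_name: str, areas, eff, matrix: TransitionMatrix
) -> float:
    """ZC for one class: impact of area flowing out to all other classes."""
    return float(transfer_out_all(areas, eff, matrix)[class_name])


def transfer_in_all(areas, eff, matrix: TransitionMatrix) -> pd.Series:
    """Vector of ZR_i = Σ_t S_t (e_i − e_t) a(t,i), in tons."""
    S, e, order = _aligned(areas, eff, matrix)
    A = matrix.probs
    zr = e * (A.T @ S) - A.T @ (S * e)
    return pd.Series(zr, index=order, name="zr_t")


def transfer_out_all(areas, eff, matrix: TransitionMatrix) -> pd.Series:
    """Vector of ZC_i = Σ_t S_i (e_t − e_i) a(i,t), in tons."""
    S, e, order = _aligned(areas, eff, matrix)
    A = matrix.probs
    zc = S * (A @ e) - S * e * A.sum(axis=1)
    return pd.Series(zc, index=order, name="zc_t")


def total_impact(areas, eff, matrix: TransitionMatrix, **metadata) -> ImpactBreakdown:
    """Full per-class ZR/ZC breakdown and total impact GTYX."""
    zr = transfer_in_all(areas, eff, matrix)
    zc = transfer_out_all(areas, eff, matrix)
    metadata.setdefault("class_order", list(matrix.class_order))
    return ImpactBreakdown(zr=zr, zc=zc, metadata=metadata)


def total_with_impact(areas, densities, gtyx_t: float) -> float:
    """GTZG in 10⁴ t: standing stock Σ S·ρ plus the impact term.

    ``gtyx_t`` is in tons.  A magnitude heuristic warns when the impact looks
    like it was already divided by 10⁴: impacts comparable to the stock in
    10⁴-t units but tiny against it in tons are suspicious.
    """
    stock = total_standing_stock(areas, densities)
    if gtyx_t != 0 and abs(gtyx_t) < stock * 1e-3:
        warnings.warn(
            f"impact {gtyx_t:g} is small against the stock ({stock:g} x 1e4 t); "
            "check that it is expressed in tons, not 1e4 t",
            stacklevel=2,
        )
    return stock + gtyx_t / 1e4


@dataclass
class ScenarioConfig:
    """Knobs for a projection run.

    ``beta_source`` is ``"fitted"`` (β from the OLS density trend over the
    horizon to the target year) or ``"explicit"`` (taken from ``betas``).
    ``override_spec`` lists (class, quantity) pairs projected by historical
    mean instead of the forecaster ensemble; pairs whose class has no series
    in the supplied history are dropped.
    """

    beta_source: str = "fitted"
    betas: dict = field(default_factory=dict)
    override_spec: tuple[tuple[str, str], ...] = forecasting.DEFAULT_OVERRIDES
    arima_orders: dict = field(default_factory=dict)
    default_density: float = 0.0
    default_beta: float = 0.0


@dataclass
class ScenarioResult:
    forecasts: "forecasting.ForecastSet"
    betas: pd.Series
    breakdown: ImpactBreakdown
    total_1e4t: float


def run_scenario(
    history: CarbonAccountTable,
    matrix: TransitionMatrix,
    target_year: int,
    config: ScenarioConfig | None = None,
) -> ScenarioResult:
    """Forecast → β derivation → effective densities → GTYX → GTZG.

    Areas and densities at ``target_year`` come from the grey/ARIMA ensemble
    (or historical-mean overrides); β per class from the density trend fitted
    on the history over the horizon ending at ``target_year``; the impact
    equations then price every transition flow at the effective-density
    difference.
    """
    config = config or ScenarioConfig()
    order = matrix.class_order
    present = set(history.classes)
    overrides = tuple(
        (c, q) for c, q in config.override_spec
        if c in present and not history.series(
            c, forecasting.QUANTITY_COLUMNS[q]
        ).empty
    )
    fs = forecasting.forecast_accounts(
        history, [target_year], arima_orders=config.arima_orders
    )
    fs = forecasting.apply_stationary_overrides(fs, history, overrides)

    areas = fs.per_class("area", target_year).reindex(list(order)).fillna(0.0)
    densities = fs.per_class("density", target_year).reindex(list(order))
    densities = densities.fillna(config.default_density)

    last_year = max(history.years)
    horizon = target_year - last_year
    if config.beta_source == "explicit":
        betas = pd.Series(config.betas, dtype=float).reindex(list(order))
        betas = betas.fillna(config.default_beta)
    elif config.beta_source == "fitted":
        vals = {}
        for cls in order:
            try:
                series = history.series(cls, "density_gm2")
            except KeyError:
                vals[cls] = config.default_beta
                continue
            if len(series) < 3:
                vals[cls] = config.default_beta
                continue
            trend = fit_density_trend(series, horizon, class_name=cls)
            vals[cls] = trend.relative_beta
        betas = pd.Series(vals).reindex(list(order))
    else:
        raise ValidationError(f"unknown beta_source {config.beta_source!r}")

    rho_now = {}
    for cls in order:
        try:
            series = history.series(cls, "density_gm2")
            rho_now[cls] = float(series.loc[series.index.max()])
        except KeyError:
            rho_now[cls] = config.default_density
    eff = effective_density_series(
        rho_now, betas, class_order=order,
        default_rho=config.default_density, default_beta=config.default_beta,
    )
    breakdown = total_impact(
        areas, eff, matrix,
        target_year=target_year, horizon_years=horizon,
        areas_used=areas.to_dict(), effective_densities_used=eff.to_dict(),
    )
    total = total_with_impact(areas, densities, breakdown.gtyx)
    return ScenarioResult(
        forecasts=fs, betas=betas, breakdown=breakdown, total_1e4t=total
    )


class CarbonImpactModel(BaseEstimator):
    """scikit-learn-style facade over the scenario pipeline.

    ``fit(history, matrix)`` stores the account history and transition
    matrix; ``predict(target_year)`` returns the projected total
    sequestration GTZG (10⁴ t) for each requested year, with the full
    :class:`ScenarioResult` kept in ``results_``.
    """

    def __init__(
        self,
        beta_source: str = "fitted",
        betas: dict | None = None,
        override_spec: tuple = forecasting.DEFAULT_OVERRIDES,
        arima_orders: dict | None = None,
        default_density: float = 0.0,
        default_beta: float = 0.0,
    ):
        self.beta_source = beta_source
        self.betas = betas
        self.override_spec = override_spec
        self.arima_orders = arima_orders
        self.default_density = default_density
        self.default_beta = default_beta

    def _config(self) -> ScenarioConfig:
        return ScenarioConfig(
            beta_source=self.beta_source,
            betas=dict(self.betas or {}),
            override_spec=tuple(self.override_spec),
            arima_orders=dict(self.arima_orders or {}),
            default_density=self.default_density,
            default_beta=self.default_beta,
        )

    def fit(self, history: CarbonAccountTable, matrix: TransitionMatrix):
        if not isinstance(matrix, TransitionMatrix):
            raise ValidationError("matrix must be a TransitionMatrix")
        self.history_ = history
        self.matrix_ = matrix
        self.results_ = {}
        return self

    def predict(self, target_years) -> np.ndarray:
        if not hasattr(self, "history_"):
            raise ValidationError("CarbonImpactModel is not fitted")
        scalar = np.isscalar(target_years)
        years = [target_years] if scalar else list(target_years)
        totals = []
        for year in years:
            result = run_scenario(
                self.history_, self.matrix_, int(year), self._config()
            )
            self.results_[int(year)] = result
            totals.append(result.total_1e4t)
        return totals[0] if scalar else np.asarray(totals)
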