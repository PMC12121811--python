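"""Packaged reference tables and synthetic ground-truth generators.

The reference tables are the printed per-class accounts (2000–2020), the
averaged transition-probability matrix, the grey/ARIMA/ensemble projections
and the impact/total tables for the Sichuan mountainous-area study, shipped
as CSV with a JSON manifest.  Values are stored verbatim as printed; known
internal inconsistencies of the source (transposed lake/wetland columns in
the totals table, ±1 t subtotal rounding, an inconsistent 2021 row) are
flagged in the manifest, never silently corrected.

The synthetic side generates categorical rasters evolving by a known per-cell
Markov transition matrix and per-class account series with known linear
trends, so estimators can be checked against ground truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .io import (
    DEFAULT_CLASSES,
    CarbonAccountTable,
    LandUseClass,
    LandUseRaster,
    ValidationError,
)
from .transitions import TransitionMatrix

_DATA = resources.files("landcarbon") / "data"

FIXTURE_NAMES = (
    "table1_accounts", "table2_matrix", "table3_grey_areas",
    "table4_grey_densities", "table5_arima_areas", "table6_arima_densities",
    "table7_areas", "table8_densities", "table9_impacts", "table10_totals",
    "table11_impacts", "table12_totals",
)


def manifest() -> dict:
    """The fixture manifest: source, units and data-quality flags per table."""
    with (_DATA / "manifest.json").open() as fh:
        return json.load(fh)


def load_fixture(name: str):
    """Load a packaged table by name.

    ``table1_accounts`` returns a :class:`CarbonAccountTable`,
    ``table2_matrix`` a :class:`TransitionMatrix`; the rest are DataFrames.
    Units and flags ride along in ``.attrs`` (or ``.metadata`` for the
    matrix).
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    meta = manifest()[name]
    with (_DATA / meta["file"]).open() as fh:
        df = pd.read_csv(fh, index_col=0 if name == "table2_matrix" else None)
    if name == "table1_accounts":
        with warnings.catch_warnings():
            # small-area densities reconstruct only to printed rounding
            warnings.simplefilter("ignore")
            table = CarbonAccountTable(df)
        return table
    if name == "table2_matrix":
        tm = TransitionMatrix.from_dataframe(df, interval_years=1)
        tm.metadata = meta  # type: ignore[attr-defined]
        return tm
    df.attrs.update(meta)
    return df


@dataclass
class SyntheticScenario:
    """Ground truth for synthetic data generation.

    ``true_matrix`` drives per-cell Markov transitions; ``class_shares`` is
    the initial composition; ``trend_spec`` maps class name to a dict with
    area/density intercepts (at the first year), slopes per year and noise
    standard deviations.  Everything is reproducible from ``seed``.
    """

    true_matrix: np.ndarray
    class_shares: np.ndarray
    raster_shape: tuple[int, int] = (100, 100)
    seed: int = 0
    cell_area_km2: float = 0.0009  # a 30 m cell
    classes: tuple[LandUseClass, ...] = DEFAULT_CLASSES
    trend_spec: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.true_matrix = np.asarray(self.true_matrix, dtype=float)
        self.class_shares = np.asarray(self.class_shares, dtype=float)
        n = len(self.classes)
        if self.true_matrix.shape != (n, n):
            raise ValidationError(
                f"true_matrix shape {self.true_matrix.shape} does not match "
                f"{n} classes"
            )
        if (self.true_matrix < 0).any() or not np.allclose(
            self.true_matrix.sum(axis=1), 1.0, atol=1e-9
        ):
            raise ValidationError("true_matrix must be row-stochastic")
        if self.class_shares.shape != (n,) or not np.isclose(
            self.class_shares.sum(), 1.0
        ):
            raise ValidationError("class_shares must sum to 1")

    @classmethod
    def two_class(
        cls, p_stay_a: float = 0.9, p_stay_b: float = 0.8, **kwargs
    ) -> "SyntheticScenario":
        """Convenience two-class scenario (codes 1 and 2)."""
        classes = (LandUseClass(1, "a"), LandUseClass(2, "b"))
        matrix = np.array(
            [[p_stay_a, 1 - p_stay_a], [1 - p_stay_b, p_stay_b]]
        )
        return cls(
            true_matrix=matrix, class_shares=np.array([0.5, 0.5]),
            classes=classes, **kwargs,
        )


def generate_markov_rasters(
    scenario: SyntheticScenario, epochs: int
) -> list[LandUseRaster]:
    """Simulate a raster time series under per-cell i.i.d. Markov dynamics.

    Epoch 0 is sampled from ``class_shares``; each subsequent epoch draws
    every cell's next class independently from the true matrix row of its
    current class.
    """
    if epochs < 1:
        raise ValidationError("need at least one epoch")
    rng = np.random.default_rng(scenario.seed)
    codes = np.array([c.code for c in scenario.classes])
    n = len(codes)
    shape = scenario.raster_shape
    state = rng.choice(n, size=shape, p=scenario.class_shares)
    rasters = [LandUseRaster(
        grid=codes[state], cell_area_km2=scenario.cell_area_km2,
        nodata=0, classes=scenario.classes,
    )]
    cum = np.cumsum(scenario.true_matrix, axis=1)
    for _ in range(epochs - 1):
        u = rng.random(size=shape)
        # next state = first column of the current row's CDF exceeding u
        state = (u[..., None] > cum[state]).sum(axis=-1)
        rasters.append(LandUseRaster(
            grid=codes[state], cell_area_km2=scenario.cell_area_km2,
            nodata=0, classes=scenario.classes,
        ))
    return rasters


def generate_account_series(
    scenario: SyntheticScenario, years: int, start_year: int = 2000
) -> CarbonAccountTable:
    """Per-class account series with known linear trends plus noise.

    ``trend_spec`` entries look like ``{"area": (intercept, slope, sd),
    "density": (intercept, slope, sd)}`` per class name; sequestration is
    derived from area and density through the unit identity, so the generated
    table always satisfies the account-table consistency invariant.  Negative
    generated values are clipped to zero with a warning.
    """
    if not scenario.trend_spec:
        raise ValidationError("scenario has no trend_spec")
    rng = np.random.default_rng(scenario.seed + 1)
    t = np.arange(years, dtype=float)
    rows = []
    for cls_name, spec in scenario.trend_spec.items():
        a0, a1, a_sd = spec["area"]
        d0, d1, d_sd = spec["density"]
        area = a0 + a1 * t + (rng.normal(0, a_sd, years) if a_sd > 0 else 0.0)
        dens = d0 + d1 * t + (rng.normal(0, d_sd, years) if d_sd > 0 else 0.0)
        area = np.asarray(area, dtype=float)
        dens = np.asarray(dens, dtype=float)
        if (area < 0).any() or (dens < 0).any():
            warnings.warn(
                f"negative generated values for {cls_name} clipped to 0",
                stacklevel=2,
            )
            area = np.clip(area, 0, None)
            dens = np.clip(dens, 0, None)
        seq = area * dens / 1e4
        for k in range(years):
            rows.append((
                start_year + k, cls_name,
                float(area[k]), float(seq[k]), float(dens[k]),
            ))
    df = pd.DataFrame(
        rows, columns=["year", "class", "area_km2", "seq_1e4t", "density_gm2"]
    )
    return CarbonAccountTable(df)


def study_trend_spec() -> dict:
    """A nine-class trend spec shaped like the study region's accounts.

    Intercepts and slopes mirror the 2000–2020 magnitudes (a dominant forest/
    grassland landscape with slowly rising densities); noise levels are of
    the order of the year-to-year scatter in the printed series.
    """
    return {
        "cultivated": {"area": (15900, -60, 120), "density": (410, 6.3, 20)},
        "forest": {"area": (128800, 230, 150), "density": (460, 4.0, 18)},
        "shrub": {"area": (3300, 2, 150), "density": (360, 4.6, 25)},
        "grassland": {"area": (154600, -230, 180), "density": (230, 1.6, 12)},
        "lake": {"area": (1270, 0, 160), "density": (149, 0, 14)},
        "wetland": {"area": (210, 0, 100), "density": (185, 0, 22)},
    }
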