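"""Transition-probability estimation from categorical raster pairs.

The probability that class-``i`` area becomes class ``q`` over an interval is
estimated by cross-tabulating co-valid cells of two aligned rasters:

    a(i, q) = count(i -> q) * k / S_i

with ``k`` the cell area and ``S_i`` the class-``i`` area at the first epoch,
so raster-derived rows are exactly row-stochastic.  Pairs are counted directly
rather than through the ``100*from + to`` encoding trick sometimes used for
cross-tabulation; the two are equivalent for codes below 100 and direct
counting has no code-range restriction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import CLASS_NAMES, LandUseRaster, ValidationError

ROW_SUM_TOL = 1e-9


@dataclass
class TransitionMatrix:
    """Row-stochastic class-to-class transition probabilities.

    ``probs[i, q]`` is the probability that class-``i`` area is class ``q``
    after ``interval_years`` years.  Rows for classes absent at the source
    epoch are all-zero and listed in ``empty_rows``.
    """

    probs: np.ndarray
    class_order: tuple[str, ...] = CLASS_NAMES
    interval_years: int = 1
    source_periods: list[tuple[int, int]] = field(default_factory=list)
    empty_rows: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        n = len(self.class_order)
        if self.probs.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.probs.shape} does not match "
                f"{n} classes"
            )
        if (self.probs < -1e-12).any() or (self.probs > 1 + 1e-12).any():
            raise ValidationError("transition probabilities must lie in [0, 1]")

    @property
    def n_classes(self) -> int:
        return len(self.class_order)

    def row_sums(self) -> np.ndarray:
        return self.probs.sum(axis=1)

    def is_row_stochastic(self, tol: float = ROW_SUM_TOL) -> bool:
        """True when every occupied row sums to 1 within ``tol``."""
        sums = self.row_sums()
        occupied = ~np.isin(self.class_order, self.empty_rows)
        return bool(np.all(np.abs(sums[occupied] - 1.0) <= tol))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.probs, index=list(self.class_order), columns=list(self.class_order)
        ).rename_axis("from_class")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, interval_years: int = 1
    ) -> "TransitionMatrix":
        if list(df.index) != list(df.columns):
            raise ValidationError("matrix row and column labels differ")
        empty = tuple(df.index[(df.sum(axis=1) == 0)])
        return cls(
            probs=df.to_numpy(dtype=float),
            class_order=tuple(df.index),
            interval_years=interval_years,
            empty_rows=empty,
        )


@dataclass
class RouteClassification:
    """Off-diagonal transfer routes labelled by carbon-density ordering.

    A route ``i -> q`` with positive probability is *favorable* when the
    destination's effective density exceeds the source's (carbon gain),
    *unfavorable* when it is lower, *neutral* when equal.
    """

    routes: pd.DataFrame  # columns: from_class, to_class, probability, label

    @property
    def counts(self) -> dict[str, int]:
        base = {"favorable": 0, "unfavorable": 0, "neutral": 0}
        base.update(self.routes["label"].value_counts().to_dict())
        return base

    @property
    def n_routes(self) -> int:
        return len(self.routes)

    def to_records(self) -> list[dict]:
        return self.routes.to_dict(orient="records")


def _check_aligned(r1: LandUseRaster, r2: LandUseRaster) -> None:
    if r1.grid.shape != r2.grid.shape:
        raise ValidationError(
            f"raster shapes differ: {r1.grid.shape} vs {r2.grid.shape}"
        )
    if not np.isclose(r1.cell_area_km2, r2.cell_area_km2):
        raise ValidationError(
            f"cell areas differ: {r1.cell_area_km2} vs {r2.cell_area_km2} km^2"
        )


def transition_counts(
    raster_t: LandUseRaster, raster_t_plus_n: LandUseRaster
) -> np.ndarray:
    """Cross-tabulate co-valid cells of two aligned rasters.

    Returns the n×n matrix whose (i, q) entry is the number of cells holding
    class ``i`` at the first epoch and class ``q`` at the second.  Cells that
    are nodata in either epoch are excluded.
    """
    _check_aligned(raster_t, raster_t_plus_n)
    classes = raster_t.classes
    n = len(classes)
    code_to_idx = np.full(max(c.code for c in classes) + 1, -1, dtype=np.int64)
    for idx, c in enumerate(classes):
        code_to_idx[c.code] = idx
    mask = raster_t.valid_mask & raster_t_plus_n.valid_mask
    src = code_to_idx[raster_t.grid[mask]]
    dst = code_to_idx[raster_t_plus_n.grid[mask]]
    counts = np.bincount(src * n + dst, minlength=n * n).reshape(n, n)
    return counts


def transition_probability(
    counts: np.ndarray,
    cell_area_km2: float,
    areas_t: pd.Series | None = None,
    *,
    class_order: tuple[str, ...] = CLASS_NAMES,
    interval_years: int = 1,
    area_rtol: float = 0.05,
) -> TransitionMatrix:
    """Convert a count matrix to transition probabilities a(i,q) = n·k / S_i.

    When ``areas_t`` (per-class km² at the source epoch) is omitted it is
    derived from the counts themselves, making every occupied row sum to
    exactly 1.  When supplied, it is cross-checked against the counted area.
    """
    counts = np.asarray(counts, dtype=float)
    if cell_area_km2 <= 0:
        raise ValidationError("cell_area_km2 must be > 0")
    counted_areas = counts.sum(axis=1) * cell_area_km2
    if areas_t is None:
        areas = counted_areas
    else:
        areas = np.asarray(
            pd.Series(areas_t).reindex(list(class_order)).to_numpy(), dtype=float
        )
        if (areas < 0).any():
            raise ValidationError("negative class area supplied")
    bad = (areas == 0) & (counts.sum(axis=1) > 0)
    if bad.any():
        names = [class_order[i] for i in np.flatnonzero(bad)]
        raise ValidationError(f"zero source area but nonzero counts for {names}")
    if areas_t is not None:
        occupied = (counted_areas > 0) & (areas > 0)
        if not np.allclose(
            areas[occupied], counted_areas[occupied], rtol=area_rtol
        ):
            warnings.warn(
                "supplied class areas deviate from counted areas by more "
                f"than {area_rtol:.0%}", stacklevel=2,
            )
    probs = np.zeros_like(counts)
    occ = areas > 0
    probs[occ] = counts[occ] * cell_area_km2 / areas[occ, None]
    empty = tuple(class_order[i] for i in np.flatnonzero(~occ))
    return TransitionMatrix(
        probs=probs, class_order=class_order, interval_years=interval_years,
        empty_rows=empty,
    )


def average_transition_matrix(
    matrices: list[TransitionMatrix],
) -> TransitionMatrix:
    """Entrywise arithmetic mean of transition matrices over periods."""
    if not matrices:
        raise ValidationError("cannot average an empty list of matrices")
    first = matrices[0]
    for m in matrices[1:]:
        if m.class_order != first.class_order:
            raise ValidationError("matrices have differing class orders")
        if m.interval_years != first.interval_years:
            raise ValidationError("matrices have differing interval lengths")
    probs = np.mean([m.probs for m in matrices], axis=0)
    periods = [p for m in matrices for p in m.source_periods]
    empty = tuple(
        c for c in first.class_order
        if all(c in m.empty_rows for m in matrices)
    )
    return TransitionMatrix(
        probs=probs, class_order=first.class_order,
        interval_years=first.interval_years, source_periods=periods,
        empty_rows=empty,
    )


def classify_routes(
    matrix: TransitionMatrix,
    densities: pd.Series,
    *,
    default_density: float | None = 0.0,
) -> RouteClassification:
    """Label every realized off-diagonal route by the density ordering.

    ``densities`` maps class name to effective carbon density (g/m²); classes
    missing from it take ``default_density`` (None disables the default and
    makes a missing class a hard error).
    """
    dens = pd.Series(densities, dtype=float).reindex(list(matrix.class_order))
    if dens.isna().any():
        if default_density is None:
            missing = list(dens.index[dens.isna()])
            raise ValidationError(f"no density for classes {missing}")
        dens = dens.fillna(default_density)
    rows = []
    for i, src in enumerate(matrix.class_order):
        for q, dst in enumerate(matrix.class_order):
            if i == q or matrix.probs[i, q] <= 0:
                continue
            delta = dens[dst] - dens[src]
            label = "favorable" if delta > 0 else "unfavorable" if delta < 0 else "neutral"
            rows.append((src, dst, float(matrix.probs[i, q]), label))
    df = pd.DataFrame(
        rows, columns=["from_class", "to_class", "probability", "label"]
    )
    return RouteClassification(routes=df)


class TransitionEstimator(BaseEstimator):
    """Estimate an averaged transition matrix from a raster time series.

    Consecutive raster pairs spaced ``interval_years`` apart are
    cross-tabulated and the per-period probability matrices averaged, the way
    a multi-year mean transition matrix is built from annual land-cover maps.

    Attributes
    ----------
    counts_ : list of per-period count matrices
    matrices_ : list of per-period TransitionMatrix
    transition_matrix_ : the period-averaged TransitionMatrix
    n_periods_ : number of pairs used
    """

    def __init__(self, interval_years: int = 1):
        self.interval_years = interval_years

    def fit(self, rasters: list[LandUseRaster], years: list[int] | None = None):
        if len(rasters) < 2:
            raise ValidationError("need at least two rasters to estimate transitions")
        if years is None:
            years = list(range(len(rasters)))
        self.counts_ = []
        self.matrices_ = []
        order = tuple(c.name for c in rasters[0].classes)
        for r1, r2, y1, y2 in zip(rasters[:-1], rasters[1:], years[:-1], years[1:]):
            counts = transition_counts(r1, r2)
            tm = transition_probability(
                counts, r1.cell_area_km2, class_order=order,
                interval_years=self.interval_years,
            )
            tm.source_periods = [(y1, y2)]
            self.counts_.append(counts)
            self.matrices_.append(tm)
        self.transition_matrix_ = average_transition_matrix(self.matrices_)
        self.n_periods_ = len(self.matrices_)
        return self

    def transform(self, X=None) -> TransitionMatrix:
        """Return the fitted averaged transition matrix."""
        if not hasattr(self, "transition_matrix_"):
            raise ValidationError("TransitionEstimator is not fitted")
        return self.transition_matrix_
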