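"""Reading, writing and validation of land-use rasters and carbon account tables.

Two raster container formats are supported: ESRI ASCII grid (``.asc``, plain
text, carries the cell size in its header) and single-band integer TIFF
(``.tif``/``.tiff``), for which the cell area must be given explicitly unless
the file carries resolution tags.  Account tables are CSV with the header
``year,class,area_km2,seq_1e4t,density_gm2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd


class LandUseClass(NamedTuple):
    """A land-use category: integer raster code plus label."""

    code: int
    name: str


#: Canonical nine-class scheme, in code order 1..9.
DEFAULT_CLASSES: tuple[LandUseClass, ...] = (
    LandUseClass(1, "cultivated"),
    LandUseClass(2, "forest"),
    LandUseClass(3, "shrub"),
    LandUseClass(4, "grassland"),
    LandUseClass(5, "lake"),
    LandUseClass(6, "ice_snow"),
    LandUseClass(7, "wasteland"),
    LandUseClass(8, "construction"),
    LandUseClass(9, "wetland"),
)

CLASS_NAMES: tuple[str, ...] = tuple(c.name for c in DEFAULT_CLASSES)
CODE_TO_NAME: dict[int, str] = {c.code: c.name for c in DEFAULT_CLASSES}
NAME_TO_CODE: dict[str, int] = {c.name: c.code for c in DEFAULT_CLASSES}

ACCOUNT_COLUMNS = ("year", "class", "area_km2", "seq_1e4t", "density_gm2")


class ValidationError(ValueError):
    """Raised when an input file violates a structural invariant."""


@dataclass
class LandUseRaster:
    """Categorical land-cover grid.

    Parameters
    ----------
    grid : 2-D integer array of class codes, with ``nodata`` marking cells
        outside the study area.
    cell_area_km2 : area of one grid cell in km² (the ``k`` of the
        cross-tabulation probability estimator).
    nodata : sentinel code, excluded from all tallies.
    classes : the class scheme the codes refer to.
    origin : optional (x, y) of the lower-left corner, carried through I/O.
    """

    grid: np.ndarray
    cell_area_km2: float
    nodata: int = 0
    classes: Sequence[LandUseClass] = DEFAULT_CLASSES
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValidationError(f"raster grid must be 2-D, got {self.grid.ndim}-D")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValidationError("raster grid must hold integer class codes")
        if self.cell_area_km2 <= 0:
            raise ValidationError(f"cell_area_km2 must be > 0, got {self.cell_area_km2}")
        codes = {c.code for c in self.classes}
        bad = np.unique(self.grid[(self.grid != self.nodata)])
        bad = sorted(int(v) for v in bad if int(v) not in codes)
        if bad:
            raise ValidationError(f"unknown class codes in raster: {bad}")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.grid != self.nodata

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def class_areas(self) -> pd.Series:
        """Mapped area per class in km², indexed by class name."""
        names = [c.name for c in self.classes]
        counts = {
            c.name: int((self.grid == c.code).sum()) for c in self.classes
        }
        return pd.Series(counts, index=names, dtype=float) * self.cell_area_km2


def read_landuse_raster(
    path: str | Path,
    *,
    cell_area_km2: float | None = None,
    nodata: int | None = None,
    classes: Sequence[LandUseClass] = DEFAULT_CLASSES,
) -> LandUseRaster:
    """Read a categorical raster from an ESRI ASCII grid or single-band TIFF.

    For ``.asc`` the cell area defaults to ``cellsize**2 / 1e6`` (cell size in
    metres); an explicit ``cell_area_km2`` overrides it.  For TIFF the cell
    area must be supplied unless the file has X/Y resolution tags written by
    :func:`write_landuse_raster`.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".asc":
        grid, header = _read_ascii_grid(path)
        if nodata is None:
            nodata = int(header.get("nodata_value", 0))
        if cell_area_km2 is None:
            cell_area_km2 = header["cellsize"] ** 2 / 1e6
        origin = (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0))
    elif suffix in (".tif", ".tiff"):
        import tifffile

        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            grid = page.asarray()
            if cell_area_km2 is None:
                res = page.tags.get("XResolution")
                # (1, 1) is tifffile's placeholder for "no resolution"
                if res is None or tuple(res.value) == (1, 1):
                    raise ValidationError(
                        f"{path.name}: TIFF has no resolution tags; "
                        "pass cell_area_km2 explicitly"
                    )
                num, den = res.value
                cell_size_m = den / num  # stored as pixels per metre
                cell_area_km2 = cell_size_m**2 / 1e6
        if nodata is None:
            nodata = 0
        origin = (0.0, 0.0)
    else:
        raise ValidationError(f"unsupported raster format: {path.suffix!r}")
    if not np.issubdtype(grid.dtype, np.integer):
        if not np.allclose(grid, np.round(grid)):
            raise ValidationError(f"{path.name}: raster holds non-integer values")
        grid = grid.astype(np.int64)
    return LandUseRaster(
        grid=grid, cell_area_km2=float(cell_area_km2), nodata=nodata,
        classes=classes, origin=origin,
    )


def write_landuse_raster(path: str | Path, raster: LandUseRaster) -> Path:
    """Write a raster as ESRI ASCII grid (``.asc``) or TIFF (``.tif``)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".asc":
        cellsize_m = float(np.sqrt(raster.cell_area_km2 * 1e6))
        nrows, ncols = raster.grid.shape
        header = (
            f"ncols {ncols}\nnrows {nrows}\n"
            f"xllcorner {raster.origin[0]}\nyllcorner {raster.origin[1]}\n"
            f"cellsize {cellsize_m!r}\nNODATA_value {raster.nodata}\n"
        )
        body = "\n".join(" ".join(str(int(v)) for v in row) for row in raster.grid)
        path.write_text(header + body + "\n")
    elif suffix in (".tif", ".tiff"):
        import tifffile

        cell_size_m = float(np.sqrt(raster.cell_area_km2 * 1e6))
        # resolution tag = pixels per unit; unit chosen as metres
        res = (1.0 / cell_size_m, 1.0 / cell_size_m)
        tifffile.imwrite(path, raster.grid.astype(np.int32), resolution=res)
    else:
        raise ValidationError(f"unsupported raster format: {path.suffix!r}")
    return path


def _read_ascii_grid(path: Path) -> tuple[np.ndarray, dict]:
    header: dict[str, float] = {}
    lines = path.read_text().splitlines()
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        ):
            header[parts[0].lower()] = float(parts[1])
        else:
            break
    if "cellsize" not in header:
        raise ValidationError(f"{path.name}: not an ESRI ASCII grid (no cellsize)")
    grid = np.loadtxt(lines[i:], dtype=np.int64, ndmin=2)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if grid.shape != (nrows, ncols):
        raise ValidationError(
            f"{path.name}: grid shape {grid.shape} does not match header "
            f"({nrows}, {ncols})"
        )
    return grid, header


@dataclass
class CarbonAccountTable:
    """Tidy per-year, per-class carbon accounts.

    One row per (year, class) with area in km², annual carbon sequestration in
    10⁴ t, and carbon density in g/m².  Density may be absent (NaN) for classes
    with no tabulated carbon (e.g. construction land).
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.df)
        missing = [c for c in ACCOUNT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"account table missing columns: {missing}")
        if len(df) == 0:
            raise ValidationError("account table has no records")
        dup = df.duplicated(subset=["year", "class"])
        if dup.any():
            pairs = df.loc[dup, ["year", "class"]].itertuples(index=False)
            raise ValidationError(
                "duplicate (year, class) records: " + ", ".join(map(str, pairs))
            )
        if (df["area_km2"].dropna() < 0).any():
            raise ValidationError("negative area_km2 in account table")
        if (df["seq_1e4t"].dropna() < 0).any():
            raise ValidationError("negative seq_1e4t in account table")
        self.df = df.reset_index(drop=True)
        self._check_density_consistency()

    def _check_density_consistency(self) -> None:
        # Printed sequestration is commonly rounded; tolerate the rounding
        # (+/-0.5 on seq_1e4t and +/-0.5 on the printed density itself).
        sub = self.df.dropna(subset=["area_km2", "seq_1e4t", "density_gm2"])
        sub = sub[sub["area_km2"] > 0]
        implied = sub["seq_1e4t"] / sub["area_km2"] * 1e4
        tol = 0.5 + 0.5e4 / sub["area_km2"]
        bad = (implied - sub["density_gm2"]).abs() > tol
        for _, row in sub[bad].iterrows():
            warnings.warn(
                f"density inconsistent for ({row['year']}, {row['class']}): "
                f"stored {row['density_gm2']:g} g/m^2 vs implied "
                f"{row['seq_1e4t'] / row['area_km2'] * 1e4:.2f} g/m^2",
                stacklevel=3,
            )

    @property
    def years(self) -> list[int]:
        return sorted(self.df["year"].unique())

    @property
    def classes(self) -> list[str]:
        return [c for c in CLASS_NAMES if c in set(self.df["class"])] + sorted(
            set(self.df["class"]) - set(CLASS_NAMES)
        )

    def series(self, class_name: str, quantity: str) -> pd.Series:
        """Yearly series of ``area_km2``, ``seq_1e4t`` or ``density_gm2``."""
        if quantity not in ("area_km2", "seq_1e4t", "density_gm2"):
            raise KeyError(f"unknown quantity {quantity!r}")
        sub = self.df[self.df["class"] == class_name]
        if len(sub) == 0:
            raise KeyError(f"class {class_name!r} not in account table")
        return sub.set_index("year")[quantity].sort_index().dropna()

    def pivot(self, quantity: str) -> pd.DataFrame:
        """Years × classes table of one quantity."""
        return self.df.pivot(index="year", columns="class", values=quantity)


def read_account_table(path: str | Path) -> CarbonAccountTable:
    """Read a CSV carbon account table and validate it."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path.name}: no records") from None
    if len(df) == 0:
        raise ValidationError(f"{path.name}: no records")
    if "density_gm2" not in df.columns:
        df["density_gm2"] = np.nan
    return CarbonAccountTable(df)


def write_account_table(path: str | Path, table: CarbonAccountTable) -> Path:
    path = Path(path)
    table.df.to_csv(path, index=False)
    return path


def read_matrix_csv(path: str | Path) -> pd.DataFrame:
    """Read a labelled class-by-class matrix (first column = source class)."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    df.index.name = "from_class"
    return df


def write_matrix_csv(path: str | Path, matrix: pd.DataFrame) -> Path:
    # %.17g round-trips every double exactly
    matrix.to_csv(Path(path), index_label="from_class", float_format="%.17g")
    return Path(path)


def class_order_codes(classes: Iterable[LandUseClass] = DEFAULT_CLASSES) -> list[int]:
    return [c.code for c in classes]


def as_class_series(values: Mapping[str, float] | pd.Series, name: str = "") -> pd.Series:
    """Coerce a per-class mapping to a Series indexed in canonical order."""
    s = pd.Series(values, dtype=float)
    order = [c for c in CLASS_NAMES if c in s.index] + [
        c for c in s.index if c not in CLASS_NAMES
    ]
    s = s.loc[order]
    s.name = name or s.name
    return s
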