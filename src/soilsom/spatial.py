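"""Ordinary kriging of point indices and zonal aggregation to unit polygons.

Point-sampled values (per-metal contamination factors, RI) are interpolated
onto a regular grid by ordinary kriging — the best linear unbiased predictor
under a fitted variogram, with weights constrained to sum to 1 — and the
grid is averaged within each administrative-unit polygon (cell-center
point-in-polygon rule) to give one value per unit.

Coordinates are kept in geographic degrees throughout; anisotropy and
projection effects are ignored, which is adequate at the city scale the
pipeline targets. Variograms are estimated on 12 distance lags up to half
the bounding-box diagonal and fitted by pair-count-weighted least squares;
spherical (default) and exponential families are supported. Duplicate
sample locations are averaged before the kriging system is built.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import shapely
from scipy import linalg
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist, pdist, squareform
from shapely.geometry import mapping as shapely_mapping, shape as shapely_shape

from .errors import ConfigError, DataError, GeometryError, NumericalError, SchemaError


@dataclass(frozen=True)
class VariogramModel:
    """Parametric semivariogram gamma(h).

    ``spherical``: nugget + psill * (1.5 h/a - 0.5 (h/a)^3) for h < a, sill beyond.
    ``exponential``: nugget + psill * (1 - exp(-3h/a)) (practical range a).
    gamma(0) = 0 by convention.
    """

    family: str
    nugget: float
    partial_sill: float
    range_param: float

    def __post_init__(self) -> None:
        if self.family not in ("spherical", "exponential"):
            raise ConfigError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.partial_sill < 0 or self.range_param <= 0:
            raise ConfigError("need nugget >= 0, partial_sill >= 0, range > 0")

    def __call__(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        a = self.range_param
        if self.family == "spherical":
            r = np.minimum(h / a, 1.0)
            g = self.partial_sill * (1.5 * r - 0.5 * r ** 3)
        else:
            g = self.partial_sill * (1.0 - np.exp(-3.0 * h / a))
        out = np.where(h > 0, self.nugget + g, 0.0)
        return out


@dataclass(frozen=True)
class GridSpec:
    """Regular grid: cell centers at origin + (index + 1/2) * cell_size."""

    x_origin: float
    y_origin: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1 or self.cell_size <= 0:
            raise ConfigError("grid needs n_rows, n_cols >= 1 and cell_size > 0")

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat (x, y) arrays of all cell centers, row-major (row 0 at y_origin)."""
        xs = self.x_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y_origin + (np.arange(self.n_rows) + 0.5) * self.cell_size
        xx, yy = np.meshgrid(xs, ys)
        return xx.ravel(), yy.ravel()

    @classmethod
    def cover(cls, x, y, cell_size: float, pad: float = 0.0) -> "GridSpec":
        """Smallest grid of the given resolution covering the points."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        x0, y0 = x.min() - pad, y.min() - pad
        n_cols = max(int(np.ceil((x.max() + pad - x0) / cell_size)), 1)
        n_rows = max(int(np.ceil((y.max() + pad - y0) / cell_size)), 1)
        return cls(x_origin=x0, y_origin=y0, cell_size=cell_size,
                   n_rows=n_rows, n_cols=n_cols)


@dataclass
class Grid:
    """A grid spec plus its row-major value array (NaN = outside domain)."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(
            self.spec.n_rows, self.spec.n_cols)

    def to_frame(self) -> pd.DataFrame:
        x, y = self.spec.centers()
        return pd.DataFrame({"x": x, "y": y, "value": self.values.ravel()})


@dataclass
class UnitPolygon:
    """An administrative unit: id, shapely (multi)polygon in lon/lat, attributes."""

    unit_id: str
    geometry: shapely.Geometry
    attributes: dict | None = None

    def __post_init__(self) -> None:
        if not self.geometry.is_valid:
            self.geometry = shapely.make_valid(self.geometry)
        if not self.geometry.is_valid or self.geometry.area == 0:
            raise GeometryError(f"unit {self.unit_id!r}: invalid or zero-area geometry")


def _dedup_points(x, y, v) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average values at duplicate coordinates (exact match after rounding to 1e-9)."""
    df = pd.DataFrame({"x": np.round(x, 9), "y": np.round(y, 9), "v": v})
    g = df.groupby(["x", "y"], sort=True, as_index=False)["v"].mean()
    if len(g) < len(df):
        warnings.warn(f"{len(df) - len(g)} duplicate sample location(s) averaged "
                      "before kriging", stacklevel=3)
    return g["x"].to_numpy(), g["y"].to_numpy(), g["v"].to_numpy()


def empirical_variogram(x, y, values, n_lags: int = 12,
                        max_dist: float | None = None) -> pd.DataFrame:
    """Binned empirical semivariogram.

    Semivariance in lag l is the mean over point pairs in that distance bin
    of (v_i - v_j)^2 / 2. ``max_dist`` defaults to half the bounding-box
    diagonal. Lags with no pairs get NaN semivariance and n_pairs 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    v = np.asarray(values, float)
    if len(x) < 2:
        raise DataError("need at least 2 points")
    pts = np.column_stack([x, y])
    d = pdist(pts)
    if np.all(d == 0):
        raise GeometryError("all points coincident: variogram undefined")
    if max_dist is None:
        span = pts.max(0) - pts.min(0)
        max_dist = float(np.hypot(*span)) / 2.0
    if max_dist <= 0:
        raise ConfigError("max_dist must be positive")
    gam = pdist(v[:, None], metric="sqeuclidean") / 2.0
    edges = np.linspace(0.0, max_dist, n_lags + 1)
    idx = np.digitize(d, edges[1:-1], right=False)
    keep = d <= max_dist
    rows = []
    for l in range(n_lags):
        m = keep & (idx == l)
        rows.append({
            "lag": 0.5 * (edges[l] + edges[l + 1]),
            "semivariance": float(gam[m].mean()) if m.any() else np.nan,
            "n_pairs": int(m.sum()),
        })
    return pd.DataFrame(rows)


def fit_variogram(lag_table: pd.DataFrame, family: str = "spherical") -> VariogramModel:
    """Fit a variogram model to a lag table by pair-count-weighted least squares.

    Minimizes sum_l n_pairs_l * (gamma_emp_l - gamma_model_l)^2 over
    (nugget, partial sill, range); empty lags are ignored. Deterministic:
    a single multi-start over fixed initial ranges.
    """
    tab = lag_table[(lag_table["n_pairs"] > 0) & lag_table["semivariance"].notna()]
    if len(tab) < 3:
        raise DataError(f"need at least 3 nonempty lags, got {len(tab)}")
    h = tab["lag"].to_numpy(float)
    g = tab["semivariance"].to_numpy(float)
    w = np.sqrt(tab["n_pairs"].to_numpy(float))
    hmax = h.max()
    gvar = max(g.max(), 1e-12)
    lo = [0.0, 0.0, 1e-6 * hmax]
    hi = [2 * gvar + 1e-9, 4 * gvar + 1e-9, 4 * hmax]

    def resid(p):
        m = VariogramModel(family, max(p[0], 0.0), max(p[1], 0.0), max(p[2], lo[2]))
        return w * (m(h) - g)

    best = None
    for r0 in (0.25 * hmax, 0.5 * hmax, hmax):
        p0 = [min(0.1 * gvar, hi[0] / 2), min(gvar, hi[1] / 2), r0]
        sol = least_squares(resid, p0, bounds=(lo, hi), method="trf")
        if best is None or sol.cost < best.cost:
            best = sol
    nugget, psill, rng = best.x
    return VariogramModel(family, float(max(nugget, 0.0)), float(max(psill, 0.0)),
                          float(max(rng, lo[2])))


def kriging_weights(x, y, model: VariogramModel, targets: np.ndarray,
                    dedup: bool = True):
    """Ordinary kriging weights for each target location.

    Solves the standard semivariance system with the unbiasedness constraint
    (weights sum to 1). Returns (weights [n_targets x n_points], x, y) with
    the possibly deduplicated point coordinates.
    """
    xs = np.asarray(x, float)
    ys = np.asarray(y, float)
    if dedup:
        xs, ys, _ = _dedup_points(xs, ys, np.zeros_like(xs))
    pts = np.column_stack([xs, ys])
    n = len(pts)
    if n < 2:
        raise DataError("need at least 2 non-coincident points")
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = model(squareform(pdist(pts)))
    a[n, :n] = 1.0
    a[:n, n] = 1.0
    a[n, n] = 0.0
    targets = np.atleast_2d(np.asarray(targets, float))
    b = np.empty((n + 1, len(targets)))
    b[:n] = model(cdist(pts, targets))
    b[n] = 1.0
    try:
        lu = linalg.lu_factor(a)
        sol = linalg.lu_solve(lu, b)
    except linalg.LinAlgError as e:  # pragma: no cover
        raise NumericalError(f"singular kriging system: {e}") from e
    return sol[:n].T, xs, ys


def krige_grid(x, y, values, model: VariogramModel, grid_spec: GridSpec) -> Grid:
    """Ordinary kriging prediction at every grid cell center.

    Duplicate point locations are averaged first. With a zero nugget the
    prediction at a sampled location reproduces the observation.
    """
    xs, ys, vs = _dedup_points(np.asarray(x, float), np.asarray(y, float),
                               np.asarray(values, float))
    gx, gy = grid_spec.centers()
    w, _, _ = kriging_weights(xs, ys, model, np.column_stack([gx, gy]), dedup=False)
    pred = w @ vs
    return Grid(spec=grid_spec, values=pred)


def zonal_mean(grid: Grid, units: Iterable[UnitPolygon]) -> dict[str, float]:
    """Mean grid value over the cell centers inside each unit polygon.

    Units covering no cell center map to NaN (missing-value flag).
    """
    gx, gy = grid.spec.centers()
    vals = grid.values.ravel()
    out: dict[str, float] = {}
    for unit in units:
        geom = unit.geometry
        if not geom.is_valid:
            raise GeometryError(f"invalid geometry for unit {unit.unit_id!r}")
        shapely.prepare(geom)
        inside = shapely.contains_xy(geom, gx, gy)
        sel = vals[inside]
        sel = sel[np.isfinite(sel)]
        out[unit.unit_id] = float(sel.mean()) if len(sel) else float("nan")
    return out


def units_from_geojson(obj: Mapping, id_property: str = "unit_id") -> list[UnitPolygon]:
    """Build unit polygons from a parsed GeoJSON FeatureCollection."""
    if obj.get("type") != "FeatureCollection":
        raise DataError("expected a GeoJSON FeatureCollection")
    units = []
    for feat in obj.get("features", []):
        props = dict(feat.get("properties") or {})
        if id_property not in props:
            raise SchemaError(f"GeoJSON feature missing property {id_property!r}")
        uid = str(props.pop(id_property))
        geom = shapely_shape(feat["geometry"])
        units.append(UnitPolygon(unit_id=uid, geometry=geom, attributes=props))
    return units


def units_to_geojson(units: Iterable[UnitPolygon], id_property: str = "unit_id") -> dict:
    """Serialize unit polygons to an RFC 7946 FeatureCollection (lon-lat order)."""
    features = []
    for u in units:
        props = {id_property: u.unit_id}
        props.update(u.attributes or {})
        features.append({
            "type": "Feature",
            "properties": props,
            "geometry": shapely_mapping(u.geometry),
        })
    return {"type": "FeatureCollection", "features": features}
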