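"""Batch self-organizing map (Kohonen map) on a hexagonal or rectangular lattice.

The map projects z-scored case vectors onto a small 2-D lattice of codebook
(weight) vectors. Training is the deterministic batch rule: every epoch each
case is assigned to its best matching unit (BMU, nearest codebook vector in
Euclidean distance), and each unit's vector is replaced by the
neighborhood-kernel-weighted mean of the cases, with a Gaussian kernel whose
radius shrinks linearly through a rough phase and a fine-tuning phase.

Map quality is summarized by the quantization error (QE, mean distance from
each case to its BMU) and the topographic error (TE, the fraction of cases
whose first and second BMUs are not lattice neighbours). The U-matrix (mean
codebook distance to lattice neighbours) and per-variable component planes
support visual interpretation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ConfigError, DataError

_SQ32 = np.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class SOMConfig:
    """Lattice geometry and training schedule.

    ``radius_start`` defaults to ``max(n_rows, n_cols) / 4`` (at least 1);
    the rough phase shrinks it linearly to 1, the fine-tuning phase from 1
    to ``radius_end``.
    """

    n_rows: int
    n_cols: int
    lattice: str = "hexagonal"
    neighborhood: str = "gaussian"
    init: str = "linear"
    rough_epochs: int = 10
    finetune_epochs: int = 20
    radius_start: float | None = None
    radius_end: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1 or self.n_rows * self.n_cols < 2:
            raise ConfigError("lattice must have at least 2 units")
        if self.lattice not in ("hexagonal", "rectangular"):
            raise ConfigError(f"unknown lattice {self.lattice!r}")
        if self.neighborhood != "gaussian":
            raise ConfigError("only the gaussian neighborhood is supported")
        if self.init not in ("linear", "random"):
            raise ConfigError(f"unknown init {self.init!r}")
        if self.rough_epochs < 1 or self.finetune_epochs < 1:
            raise ConfigError("epochs must be >= 1")
        r0 = self.radius_start if self.radius_start is not None else self.default_radius_start()
        if not (r0 >= self.radius_end >= 0):
            raise ConfigError("need radius_start >= radius_end >= 0")

    def default_radius_start(self) -> float:
        return max(max(self.n_rows, self.n_cols) / 4.0, 1.0)

    @property
    def n_units(self) -> int:
        return self.n_rows * self.n_cols


@dataclass
class NormParams:
    """Per-variable z-score parameters; constant columns are flagged and map to zero."""

    mean: np.ndarray
    sd: np.ndarray
    constant: np.ndarray  # boolean mask of constant columns


@dataclass
class SOMModel:
    config: SOMConfig
    codebook: np.ndarray          # units x dims, on the normalized scale
    unit_xy: np.ndarray           # units x 2 lattice coordinates (row-major from top-left)
    norm_params: NormParams
    variable_names: list[str]

    @property
    def n_units(self) -> int:
        return self.codebook.shape[0]

    @property
    def dims(self) -> int:
        return self.codebook.shape[1]

    def denormalized_codebook(self) -> np.ndarray:
        return self.codebook * self.norm_params.sd + self.norm_params.mean


@dataclass(frozen=True)
class MapQuality:
    """One row of a map-size scan: lattice shape with its QE and TE."""

    n_rows: int
    n_cols: int
    qe: float
    te: float


def lattice_coords(n_rows: int, n_cols: int, lattice: str = "hexagonal") -> np.ndarray:
    """Unit positions in the plane, row-major from the top-left.

    Hexagonal: odd rows shifted right by 1/2, row pitch sqrt(3)/2, so the six
    nearest units sit at distance exactly 1. Rectangular: integer grid.
    """
    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    if lattice == "hexagonal":
        x = cols + 0.5 * (rows % 2)
        y = rows * _SQ32
    else:
        x = cols.astype(float)
        y = rows.astype(float)
    return np.column_stack([x, y])


def lattice_adjacency(unit_xy: np.ndarray) -> np.ndarray:
    """Boolean neighbour matrix: units at lattice distance 1 (tolerance 1e-6)."""
    d = cdist(unit_xy, unit_xy)
    adj = np.abs(d - 1.0) < 1e-6
    np.fill_diagonal(adj, False)
    return adj


def normalize(data) -> tuple[np.ndarray, NormParams]:
    """Z-score each column; constant columns map to zeros and are flagged.

    Accepts a DataFrame (numeric columns) or 2-D array with at least 2 rows.
    """
    if isinstance(data, pd.DataFrame):
        try:
            arr = data.to_numpy(dtype=float)
        except (TypeError, ValueError) as e:
            for j, c in enumerate(data.columns):
                col = pd.to_numeric(data[c], errors="coerce")
                if col.isna().any() and data[c].notna().any():
                    i = int(np.argmax(col.isna().to_numpy()))
                    raise DataError(f"non-numeric cell at row {i}, column {c!r}") from e
            raise DataError(str(e)) from e
    else:
        arr = np.asarray(data, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise DataError("need a 2-D table with at least 2 cases")
    if np.isnan(arr).any():
        rows, cols = np.nonzero(np.isnan(arr))
        raise DataError(f"NaN cells at (row, col): {list(zip(rows.tolist(), cols.tolist()))[:10]}")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant column(s) mapped to zero and "
                      "excluded from distances", stacklevel=2)
    safe_sd = np.where(constant, 1.0, sd)
    z = (arr - mean) / safe_sd
    return z, NormParams(mean=mean, sd=safe_sd, constant=constant)


def denormalize(z: np.ndarray, params: NormParams) -> np.ndarray:
    return z * params.sd + params.mean


def _linear_init(z: np.ndarray, unit_xy: np.ndarray, n_rows: int, n_cols: int) -> np.ndarray:
    """Principal-plane initialization: span the lattice over the first two PCs."""
    n = z.shape[0]
    u, s, vt = np.linalg.svd(z - z.mean(0), full_matrices=False)
    # sign convention: largest-magnitude loading positive, for determinism
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] = -vt[k]
    sds = s / np.sqrt(max(n - 1, 1))
    # map the longer lattice axis onto PC1
    ax = unit_xy.copy()
    extent = ax.max(0) - ax.min(0)
    if extent[1] > extent[0]:
        ax = ax[:, ::-1]
        extent = extent[::-1]
    coeff = np.zeros((ax.shape[0], 2))
    for k in range(2):
        if extent[k] > 0:
            coeff[:, k] = 2.0 * (ax[:, k] - ax[:, k].mean()) / (extent[k] / 2.0) / 2.0
        # else: flat axis contributes nothing
    code = np.tile(z.mean(0), (ax.shape[0], 1))
    for k in range(min(2, vt.shape[0])):
        code += np.outer(coeff[:, k] * sds[k], vt[k])
    return code


def train(data, config: SOMConfig, variable_names: Sequence[str] | None = None) -> SOMModel:
    """Train a batch SOM on raw data (z-scored internally).

    Deterministic for a fixed config (linear init uses no randomness; random
    init is seeded). Units that attract no kernel mass in an epoch keep
    their previous vector.
    """
    if isinstance(data, pd.DataFrame) and variable_names is None:
        variable_names = [str(c) for c in data.columns]
    z, params = normalize(data)
    n, dims = z.shape
    if variable_names is None:
        variable_names = [f"var{j}" for j in range(dims)]
    if n < config.n_units:
        warnings.warn(f"fewer cases ({n}) than map units ({config.n_units})", stacklevel=2)

    unit_xy = lattice_coords(config.n_rows, config.n_cols, config.lattice)
    if config.init == "linear":
        codebook = _linear_init(z, unit_xy, config.n_rows, config.n_cols)
    else:
        rng = np.random.default_rng(config.seed)
        codebook = z[rng.integers(0, n, size=config.n_units)].astype(float).copy()

    lat_d2 = cdist(unit_xy, unit_xy) ** 2
    r0 = config.radius_start if config.radius_start is not None else config.default_radius_start()

    schedule = []
    for e in range(config.rough_epochs):
        f = e / max(config.rough_epochs - 1, 1)
        schedule.append(r0 + f * (1.0 - r0))
    for e in range(config.finetune_epochs):
        f = e / max(config.finetune_epochs - 1, 1)
        schedule.append(1.0 + f * (config.radius_end - 1.0))

    for sigma in schedule:
        d = cdist(z, codebook)
        bmus = np.argmin(d, axis=1)
        h = np.exp(-lat_d2 / (2.0 * max(sigma, 1e-9) ** 2))   # units x units
        sums = np.zeros((config.n_units, dims))
        counts = np.zeros(config.n_units)
        np.add.at(sums, bmus, z)
        np.add.at(counts, bmus, 1.0)
        num = h @ sums
        den = h @ counts
        ok = den > 1e-12
        codebook[ok] = num[ok] / den[ok, None]

    return SOMModel(config=config, codebook=codebook, unit_xy=unit_xy,
                    norm_params=params, variable_names=list(variable_names))


def _prepare_cases(model: SOMModel, data) -> np.ndarray:
    """Z-score query cases with the model's stored parameters."""
    if isinstance(data, pd.DataFrame):
        data = data.to_numpy(dtype=float)
    arr = np.atleast_2d(np.asarray(data, dtype=float))
    if arr.shape[1] != model.dims:
        raise DataError(f"dimension mismatch: case has {arr.shape[1]} variables, "
                        f"model has {model.dims}")
    return (arr - model.norm_params.mean) / model.norm_params.sd


def bmu(model: SOMModel, x) -> tuple[int, int]:
    """Best and second-best matching unit for one case; ties go to the lowest unit index."""
    z = _prepare_cases(model, np.asarray(x, dtype=float).reshape(1, -1))
    d = np.linalg.norm(model.codebook - z, axis=1)
    best = int(np.argmin(d))
    d2 = d.copy()
    d2[best] = np.inf
    return best, int(np.argmin(d2))


def bmus(model: SOMModel, data, normalized: bool = False) -> np.ndarray:
    """BMU index for every case (vectorized)."""
    z = np.asarray(data, float) if normalized else _prepare_cases(model, data)
    return np.argmin(cdist(z, model.codebook), axis=1)


def quantization_error(model: SOMModel, data) -> float:
    """Mean Euclidean distance (normalized scale) from each case to its BMU."""
    z = _prepare_cases(model, data)
    if z.shape[0] == 0:
        raise DataError("empty data")
    d = cdist(z, model.codebook)
    return float(d.min(axis=1).mean())


def topographic_error(model: SOMModel, data) -> float:
    """Fraction of cases whose first and second BMUs are not lattice neighbours."""
    z = _prepare_cases(model, data)
    if z.shape[0] == 0:
        raise DataError("empty data")
    if model.n_units < 2:
        raise DataError("need at least 2 units")
    d = cdist(z, model.codebook)
    order = np.argsort(d, axis=1, kind="stable")
    first, second = order[:, 0], order[:, 1]
    adj = lattice_adjacency(model.unit_xy)
    return float(np.mean(~adj[first, second]))


def u_matrix(model: SOMModel) -> tuple[np.ndarray, pd.DataFrame]:
    """Inter-unit codebook distances along lattice edges.

    Returns the per-unit field (n_rows x n_cols; mean distance to lattice
    neighbours) and the edge table (unit_i, unit_j, distance), i < j.
    """
    adj = lattice_adjacency(model.unit_xy)
    dist = cdist(model.codebook, model.codebook)
    ii, jj = np.nonzero(np.triu(adj))
    edges = pd.DataFrame({"unit_i": ii, "unit_j": jj, "distance": dist[ii, jj]})
    with np.errstate(invalid="ignore"):
        per_unit = np.where(adj, dist, np.nan)
        field = np.nanmean(per_unit, axis=1)
    return field.reshape(model.config.n_rows, model.config.n_cols), edges


def component_planes(model: SOMModel) -> dict[str, np.ndarray]:
    """One n_rows x n_cols plane per variable, denormalized to original units."""
    code = model.denormalized_codebook()
    shape = (model.config.n_rows, model.config.n_cols)
    return {name: code[:, j].reshape(shape) for j, name in enumerate(model.variable_names)}


#: The nine candidate lattice shapes scanned by default (40 to 198 units).
DEFAULT_SIZE_CANDIDATES: tuple[tuple[int, int], ...] = (
    (8, 5), (9, 6), (10, 7), (12, 7), (12, 8), (13, 9), (14, 10), (16, 11), (18, 11),
)


def map_size_scan(
    data,
    candidate_sizes: Iterable[tuple[int, int]] = DEFAULT_SIZE_CANDIDATES,
    config: SOMConfig | None = None,
) -> tuple[list[MapQuality], tuple[int, int]]:
    """Train one SOM per candidate lattice shape and pick the best.

    Selection: minimum QE, ties broken by minimum TE (then by fewer units).
    The shared seed and schedule come from ``config`` (shape fields ignored).
    """
    candidates = list(candidate_sizes)
    if not candidates:
        raise ConfigError("need at least one candidate size")
    template = config if config is not None else SOMConfig(n_rows=2, n_cols=2)
    records: list[MapQuality] = []
    for r, c in candidates:
        if r * c < 2:
            raise ConfigError(f"candidate {r}x{c} has fewer than 2 units")
        cfg = replace(template, n_rows=r, n_cols=c)
        model = train(data, cfg)
        records.append(MapQuality(n_rows=r, n_cols=c,
                                  qe=quantization_error(model, data),
                                  te=topographic_error(model, data)))
    best = min(records, key=lambda q: (q.qe, q.te, q.n_rows * q.n_cols))
    return records, (best.n_rows, best.n_cols)
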