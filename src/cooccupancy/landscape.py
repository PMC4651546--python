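"""Gridded landscapes and landscape covariates.

The study system is a square grid of survey cells (one camera station per
cell), surrounded by a one-cell buffer so that every interior cell has a
complete first-order neighborhood (its eight surrounding cells).  Covariates
come in two families:

* linear-feature densities (road, water) and distance to water, used in the
  predator submodel at two spatial scales — the cell itself and the mean over
  its first-order neighborhood;
* a nine-class landcover composition (proportions summing to one), used in
  the prey submodel.

All covariates are centered and scaled over interior cells before entering
any linear predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Landcover classes, in the canonical order used by the prey linear predictor.
LANDCOVER_CLASSES = (
    "aspen",
    "dea",  # deciduous forest excluding aspen
    "evergreen",
    "mixed",
    "shrub",
    "grassland",
    "ww",  # woody wetland
    "ehw",  # emergent herbaceous wetland
    "unsuitable",
)

#: Predator-submodel covariates, in the canonical order of its linear predictor:
#: road/water density at cell scale, road/water density at neighborhood scale,
#: distance to nearest water.
PREDATOR_COVARIATES = (
    "road_cell",
    "water_cell",
    "road_neigh",
    "water_neigh",
    "dist_water",
)

#: Default Dirichlet-like concentration mimicking an uneven northern-forest
#: composition dominated by deciduous forest and woody wetland.
DEFAULT_LANDCOVER_CONCENTRATION = {
    "aspen": 1.5,
    "dea": 3.8,
    "evergreen": 0.9,
    "mixed": 1.3,
    "shrub": 0.8,
    "grassland": 0.5,
    "ww": 2.9,
    "ehw": 0.4,
    "unsuitable": 0.6,
}

_NEIGHBOR_OFFSETS = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]


@dataclass(frozen=True)
class LandscapeGrid:
    """Geometry of a buffered survey grid.

    Cells are stored row-major over the *full* grid (interior plus buffer);
    ``cell_ids`` label interior cells only, also row-major.  ``neighbor_index``
    maps each interior cell to the flat full-grid indices of its eight
    first-order neighbors, which may include buffer cells.
    """

    n_rows: int
    n_cols: int
    buffer_width: int = 1
    cell_ids: np.ndarray = field(init=False, repr=False)
    interior_index: np.ndarray = field(init=False, repr=False)
    neighbor_index: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid needs at least 2x2 interior cells")
        if self.buffer_width < 1:
            raise ValueError("buffer_width must be >= 1 so every interior cell has 8 neighbors")
        b = self.buffer_width
        full_cols = self.n_cols + 2 * b
        rows, cols = np.meshgrid(
            np.arange(b, b + self.n_rows), np.arange(b, b + self.n_cols), indexing="ij"
        )
        flat = (rows * full_cols + cols).ravel()
        neigh = np.empty((flat.size, 8), dtype=np.int64)
        for j, (dr, dc) in enumerate(_NEIGHBOR_OFFSETS):
            neigh[:, j] = ((rows + dr) * full_cols + (cols + dc)).ravel()
        object.__setattr__(self, "cell_ids", np.arange(flat.size, dtype=np.int64))
        object.__setattr__(self, "interior_index", flat)
        object.__setattr__(self, "neighbor_index", neigh)

    @property
    def n_interior(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_full(self) -> int:
        b = self.buffer_width
        return (self.n_rows + 2 * b) * (self.n_cols + 2 * b)


@dataclass
class RawCovariates:
    """Unscaled covariates over the full (interior + buffer) grid.

    ``landcover`` holds per-cell class proportions in ``LANDCOVER_CLASSES``
    order; each row is a composition summing to one.
    """

    road_density: np.ndarray  # (n_full,)
    water_density: np.ndarray  # (n_full,)
    dist_water: np.ndarray  # (n_full,)
    landcover: np.ndarray  # (n_full, 9)

    def __post_init__(self) -> None:
        if np.any(self.road_density < 0) or np.any(self.water_density < 0):
            raise ValueError("densities must be nonnegative")
        if np.any(self.landcover < 0):
            raise ValueError("landcover proportions must be nonnegative")
        sums = self.landcover.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("landcover proportions must sum to 1 per cell")


@dataclass
class CovariateTable:
    """Centered and scaled per-interior-cell covariates plus scaling constants.

    ``data`` is indexed by ``cell_id`` with predator covariates first
    (``PREDATOR_COVARIATES``) then the nine landcover classes.  ``center`` and
    ``scale`` allow back-transformation to raw units.
    """

    data: pd.DataFrame
    center: pd.Series
    scale: pd.Series
    grid: LandscapeGrid

    @property
    def n_cells(self) -> int:
        return len(self.data)

    def predator_design(self) -> np.ndarray:
        """(n_cells, 5) design matrix for the predator occupancy predictors."""
        return self.data.loc[:, list(PREDATOR_COVARIATES)].to_numpy(dtype=float)

    def prey_design(self) -> np.ndarray:
        """(n_cells, 9) design matrix for the prey occupancy predictor."""
        return self.data.loc[:, list(LANDCOVER_CLASSES)].to_numpy(dtype=float)


def _smooth(field_arr: np.ndarray, shape: tuple[int, int], smoothness: float) -> np.ndarray:
    """Blend an iid field with its 8-neighbor (toroidal) average.

    smoothness=0 leaves the field iid; 1 replaces it by the local mean,
    inducing strong positive autocorrelation between adjacent cells.
    """
    if smoothness <= 0:
        return field_arr
    grid = field_arr.reshape(shape)
    acc = np.zeros_like(grid)
    for dr, dc in _NEIGHBOR_OFFSETS:
        acc += np.roll(np.roll(grid, dr, axis=0), dc, axis=1)
    return ((1.0 - smoothness) * grid + smoothness * acc / 8.0).ravel()


def generate_landscape(
    n_rows: int = 8,
    n_cols: int = 8,
    buffer_width: int = 1,
    seed: int | np.random.Generator | None = None,
    spatial_smoothness: float = 0.0,
    landcover_concentration: dict[str, float] | None = None,
) -> tuple[LandscapeGrid, RawCovariates]:
    """Draw a buffered grid and raw covariates for it.

    Densities are lognormal (positive, right-skewed, like km of road per
    cell); distance to water is lognormal; landcover is a normalized-gamma
    (Dirichlet) composition with configurable concentration.  A positive
    ``spatial_smoothness`` correlates neighboring cells by mixing each
    underlying Gaussian/log-gamma field with its local average.
    """
    grid = LandscapeGrid(n_rows, n_cols, buffer_width)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b = buffer_width
    shape = (n_rows + 2 * b, n_cols + 2 * b)
    n_full = shape[0] * shape[1]

    def lognormal_field(mu: float, sd: float) -> np.ndarray:
        z = _smooth(rng.normal(size=n_full), shape, spatial_smoothness)
        return np.exp(mu + sd * z)

    road = lognormal_field(0.0, 0.6)
    water = lognormal_field(-0.5, 0.6)
    dist = lognormal_field(0.0, 0.8)

    conc_map = dict(DEFAULT_LANDCOVER_CONCENTRATION)
    if landcover_concentration:
        conc_map.update(landcover_concentration)
    conc = np.array([conc_map[c] for c in LANDCOVER_CLASSES])
    # Dirichlet via normalized gammas so the log-fields can be spatially smoothed.
    logg = np.log(rng.gamma(shape=conc, scale=1.0, size=(n_full, len(conc))))
    for j in range(logg.shape[1]):
        logg[:, j] = _smooth(logg[:, j], shape, spatial_smoothness)
    gam = np.exp(logg)
    landcover = gam / gam.sum(axis=1, keepdims=True)

    return grid, RawCovariates(road, water, dist, landcover)


def neighborhood_density(
    raw: RawCovariates, grid: LandscapeGrid, cell_id: int, variable: str
) -> float:
    """Mean of ``variable`` over the 8 first-order neighbors of an interior cell.

    The focal cell is excluded; buffer cells count as neighbors but cannot be
    focal.
    """
    if not 0 <= cell_id < grid.n_interior:
        raise ValueError(f"cell_id {cell_id} is not an interior cell")
    values = getattr(raw, variable)
    return float(values[grid.neighbor_index[cell_id]].mean())


def standardize(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Center and scale one covariate column; returns (scaled, mean, sd).

    Uses the sample standard deviation (denominator n-1), the convention
    applied to every covariate column: [1, 2, 3] -> [-1, 0, 1].
    """
    values = np.asarray(values, dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0:
        raise ValueError("zero-variance column cannot be scaled")
    return (values - mean) / sd, mean, sd


def scale_covariates(raw: RawCovariates, grid: LandscapeGrid) -> CovariateTable:
    """Assemble the per-interior-cell covariate table, centered and scaled.

    Neighborhood densities are means over each interior cell's eight
    neighbors (buffer cells contribute to these means but are not sampling
    units); centering/scaling constants are computed over interior cells
    only, with the sample (n-1) standard deviation.
    """
    idx = grid.interior_index
    cols: dict[str, np.ndarray] = {
        "road_cell": raw.road_density[idx],
        "water_cell": raw.water_density[idx],
        "road_neigh": raw.road_density[grid.neighbor_index].mean(axis=1),
        "water_neigh": raw.water_density[grid.neighbor_index].mean(axis=1),
        "dist_water": raw.dist_water[idx],
    }
    for j, name in enumerate(LANDCOVER_CLASSES):
        cols[name] = raw.landcover[idx, j]
    df = pd.DataFrame(cols, index=pd.Index(grid.cell_ids, name="cell_id"))
    if len(df) < 2:
        raise ValueError("need at least 2 interior cells to scale covariates")
    dead = df.columns[df.std(ddof=1) == 0].tolist()
    if dead:
        raise ValueError(f"zero-variance covariate column(s): {', '.join(dead)}")
    scaled = {}
    center = {}
    scale = {}
    for name in df.columns:
        scaled[name], center[name], scale[name] = standardize(df[name].to_numpy())
    return CovariateTable(
        pd.DataFrame(scaled, index=df.index), pd.Series(center), pd.Series(scale), grid
    )
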