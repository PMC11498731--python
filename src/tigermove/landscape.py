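"""Raster covariate stack: construction, transforms and point sampling.

All rasters live on one planar grid in projected metres.  Arrays are
row-major ``arr[i, j]`` with the cell-centre of ``(i, j)`` at
``(x0 + (j + 0.5) * cell, y0 + (i + 0.5) * cell)`` where ``(x0, y0)`` is
the minimum (south-west) corner of the grid.  Continuous layers are
sampled bilinearly, categorical layers by nearest neighbour, so sampling
at a cell centre returns the stored value exactly for every layer.

Forest cover arrives as a 6-class product and is collapsed to the
3-class scheme used by the selection analysis: dense + moderately dense
-> forest; open + shrub -> open forest; everything else (including
water) -> non-forest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage

# 6-class forest-cover codes (input product)
FOREST6_DENSE = 1
FOREST6_MOD_DENSE = 2
FOREST6_OPEN = 3
FOREST6_SHRUB = 4
FOREST6_NONFOREST = 5
FOREST6_WATER = 6
FOREST6_CODES = (
    FOREST6_DENSE,
    FOREST6_MOD_DENSE,
    FOREST6_OPEN,
    FOREST6_SHRUB,
    FOREST6_NONFOREST,
    FOREST6_WATER,
)

# 3-class scheme (analysis)
FOREST3_NONFOREST = 0
FOREST3_FOREST = 1
FOREST3_OPENFOREST = 2
FOREST3_LABELS = {FOREST3_NONFOREST: "non_forest",
                  FOREST3_FOREST: "forest",
                  FOREST3_OPENFOREST: "open_forest"}

#: layer roles treated as categorical (nearest-neighbour sampling/resampling)
CATEGORICAL_ROLES = frozenset({"forest6", "forest3", "water_mask", "village_mask"})


class LayerError(ValueError):
    """Raised for invalid layer values or incompatible grids."""


@dataclass(frozen=True)
class Grid:
    """Planar raster grid: SW corner, square cell size (m), shape."""

    x0: float
    y0: float
    cell: float
    nrow: int
    ncol: int

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid's outer edges."""
        return (self.x0, self.y0,
                self.x0 + self.ncol * self.cell,
                self.y0 + self.nrow * self.cell)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.x0 + (np.arange(self.ncol) + 0.5) * self.cell
        ys = self.y0 + (np.arange(self.nrow) + 0.5) * self.cell
        return xs, ys

    def contains(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        return (np.asarray(x) >= xmin) & (np.asarray(x) <= xmax) \
            & (np.asarray(y) >= ymin) & (np.asarray(y) <= ymax)

    def frac_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Fractional (row, col) array indices of points; cell centres map to integers."""
        fi = (np.asarray(y, dtype=float) - self.y0) / self.cell - 0.5
        fj = (np.asarray(x, dtype=float) - self.x0) / self.cell - 0.5
        return fi, fj


@dataclass
class LandscapeStack:
    """Aligned raster layers keyed by role, on one shared :class:`Grid`.

    Expected roles: ``ndvi`` (unitless, [-1, 1]), ``builtup_fraction``
    ([0, 1]), ``water_mask`` (binary), ``forest6`` (categorical);
    derived: ``village_mask``, ``dist_village`` (m), ``dist_water`` (m),
    ``forest3``.
    """

    grid: Grid
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for role, arr in self.layers.items():
            self._check_shape(role, arr)

    def _check_shape(self, role: str, arr: np.ndarray) -> None:
        if arr.shape != (self.grid.nrow, self.grid.ncol):
            raise LayerError(
                f"layer {role!r} shape {arr.shape} does not match grid "
                f"({self.grid.nrow}, {self.grid.ncol})")

    def add(self, role: str, arr: np.ndarray) -> None:
        arr = np.asarray(arr)
        self._check_shape(role, arr)
        self.layers[role] = arr

    def __getitem__(self, role: str) -> np.ndarray:
        return self.layers[role]

    def __contains__(self, role: str) -> bool:
        return role in self.layers

    def derive(self, builtup_threshold: float = 0.75) -> "LandscapeStack":
        """Compute the derived layers from the base ones, in place.

        ``village_mask`` (built-up fraction >= threshold), ``dist_village``,
        ``dist_water`` (Euclidean metres) and ``forest3``.
        Returns self for chaining.
        """
        if "builtup_fraction" in self:
            self.add("village_mask",
                     threshold_builtup(self["builtup_fraction"], builtup_threshold))
        if "village_mask" in self:
            self.add("dist_village",
                     euclidean_distance(self["village_mask"], self.grid.cell))
        if "water_mask" in self:
            self.add("dist_water",
                     euclidean_distance(self["water_mask"], self.grid.cell))
        if "forest6" in self:
            self.add("forest3", reclassify_forest(self["forest6"]))
        return self


def threshold_builtup(builtup_fraction: np.ndarray, threshold: float = 0.75) -> np.ndarray:
    """Binary settlement raster: 1 where built-up fraction >= threshold.

    The default 0.75 matches the conventional cut used to declare a cell
    a village/settlement from a continuous built-up product.
    """
    frac = np.asarray(builtup_fraction, dtype=float)
    if np.any((frac < 0) | (frac > 1) | ~np.isfinite(frac)):
        raise LayerError("builtup_fraction values must lie in [0, 1]")
    return (frac >= threshold).astype(np.uint8)


def euclidean_distance(source: np.ndarray, cell: float) -> np.ndarray:
    """Distance (m) from each cell centre to the nearest source-cell centre.

    Source cells are exactly 0.  Raises if the source set is empty.
    """
    src = np.asarray(source).astype(bool)
    if not src.any():
        raise LayerError("distance transform: source raster has no source cells")
    return ndimage.distance_transform_edt(~src) * float(cell)


def reclassify_forest(forest6: np.ndarray) -> np.ndarray:
    """Collapse the 6-class forest product to the 3-class analysis scheme.

    dense + moderately dense -> forest; open + shrub -> open forest;
    non-forest and water -> non-forest.  Unknown codes raise.
    """
    arr = np.asarray(forest6)
    codes = np.unique(arr)
    unknown = set(codes.tolist()) - set(FOREST6_CODES)
    if unknown:
        raise LayerError(f"unknown forest6 codes: {sorted(unknown)}")
    out = np.full(arr.shape, FOREST3_NONFOREST, dtype=np.uint8)
    out[(arr == FOREST6_DENSE) | (arr == FOREST6_MOD_DENSE)] = FOREST3_FOREST
    out[(arr == FOREST6_OPEN) | (arr == FOREST6_SHRUB)] = FOREST3_OPENFOREST
    return out


def _resample_layer(arr: np.ndarray, src: Grid, dst: Grid, categorical: bool) -> np.ndarray:
    xs, ys = dst.cell_centers()
    px, py = np.meshgrid(xs, ys)
    fi, fj = src.frac_index(px.ravel(), py.ravel())
    order = 0 if categorical else 1
    out = ndimage.map_coordinates(np.asarray(arr, dtype=float), [fi, fj],
                                  order=order, mode="nearest")
    out = out.reshape(dst.nrow, dst.ncol)
    if categorical:
        out = out.astype(np.asarray(arr).dtype)
    return out


def resample_stack(stack: LandscapeStack, target_cell: float = 100.0) -> LandscapeStack:
    """Resample every layer onto a shared grid at ``target_cell`` metres.

    Continuous layers bilinear, categorical nearest-neighbour.  The
    target grid covers the source extent with the same SW corner.
    """
    g = stack.grid
    if g.cell == target_cell:
        return stack
    xmin, ymin, xmax, ymax = g.extent
    ncol = max(1, int(round((xmax - xmin) / target_cell)))
    nrow = max(1, int(round((ymax - ymin) / target_cell)))
    dst = Grid(xmin, ymin, target_cell, nrow, ncol)
    out = LandscapeStack(dst)
    for role, arr in stack.layers.items():
        out.add(role, _resample_layer(arr, g, dst, role in CATEGORICAL_ROLES))
    return out


def sample_layer(stack: LandscapeStack, role: str, x, y) -> np.ndarray:
    """Sample one layer at planar points; bilinear unless the role is categorical."""
    arr = np.asarray(stack[role], dtype=float)
    fi, fj = stack.grid.frac_index(x, y)
    order = 0 if role in CATEGORICAL_ROLES else 1
    out = ndimage.map_coordinates(arr, [np.atleast_1d(fi), np.atleast_1d(fj)],
                                  order=order, mode="nearest")
    if role in CATEGORICAL_ROLES:
        out = out.astype(stack[role].dtype)
    return out


def sample_covariates(x, y, stack: LandscapeStack,
                      roles: tuple[str, ...] = ("ndvi", "dist_village", "dist_water", "forest3"),
                      ) -> "pandas.DataFrame":
    """Covariate vector per point, with an ``in_extent`` flag.

    Out-of-extent points are clamped to the edge value and flagged rather
    than silently dropped; callers decide what to do with them.
    """
    import pandas as pd

    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    out = {"x": x, "y": y, "in_extent": stack.grid.contains(x, y)}
    for role in roles:
        out[role] = sample_layer(stack, role, x, y)
    return pd.DataFrame(out)


def forest3_onehot(forest3_codes: np.ndarray) -> "pandas.DataFrame":
    """Dummy-code forest3 with non-forest as the reference category."""
    import pandas as pd

    codes = np.asarray(forest3_codes)
    return pd.DataFrame({
        "forest": (codes == FOREST3_FOREST).astype(float),
        "open_forest": (codes == FOREST3_OPENFOREST).astype(float),
    })


@dataclass(frozen=True)
class Standardizer:
    """Per-covariate z-score constants, kept for back-transforming coefficients."""

    means: dict[str, float]
    sds: dict[str, float]

    @classmethod
    def fit(cls, table, columns) -> "Standardizer":
        means, sds = {}, {}
        for c in columns:
            v = np.asarray(table[c], dtype=float)
            v = v[np.isfinite(v)]
            sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
            if v.size < 2 or sd == 0.0:
                raise LayerError(f"cannot standardize {c!r}: zero variance")
            means[c] = float(np.mean(v))
            sds[c] = sd
        return cls(means, sds)

    def transform(self, table):
        out = table.copy()
        for c in self.means:
            if c in table:
                out[c] = (np.asarray(table[c], dtype=float) - self.means[c]) / self.sds[c]
        return out

    def transform_value(self, column: str, value):
        return (np.asarray(value, dtype=float) - self.means[column]) / self.sds[column]

    def inverse_value(self, column: str, z):
        return np.asarray(z, dtype=float) * self.sds[column] + self.means[column]


def standardize(values) -> tuple[np.ndarray, float, float]:
    """z-score a vector; returns (z, mean, sd).  Errors on zero variance."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise LayerError("standardize needs at least 2 values")
    mu, sd = float(np.mean(v)), float(np.std(v, ddof=1))
    if sd == 0.0:
        raise LayerError("standardize: zero variance")
    return (v - mu) / sd, mu, sd


# ---------------------------------------------------------------------------
# raster I/O (planar TIFF with JSON grid metadata in the description tag)

def write_raster(path, arr: np.ndarray, grid: Grid) -> None:
    import tifffile

    meta = json.dumps({"x0": grid.x0, "y0": grid.y0, "cell": grid.cell,
                       "nrow": grid.nrow, "ncol": grid.ncol})
    tifffile.imwrite(str(path), np.asarray(arr), description=meta)


def read_raster(path) -> tuple[np.ndarray, Grid]:
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].tags.get("ImageDescription")
        if desc is None:
            raise LayerError(f"{path}: no grid metadata in TIFF description")
        meta = json.loads(desc.value)
    grid = Grid(meta["x0"], meta["y0"], meta["cell"], meta["nrow"], meta["ncol"])
    if arr.shape != (grid.nrow, grid.ncol):
        raise LayerError(f"{path}: array shape {arr.shape} mismatches metadata grid")
    return arr, grid


def read_stack(roles_yaml) -> LandscapeStack:
    """Load a stack from a YAML mapping of role -> raster path.

    Paths are resolved relative to the YAML file.  All rasters must share
    one grid; a mismatch names both grids in the error.
    """
    from pathlib import Path

    roles_yaml = Path(roles_yaml)
    with open(roles_yaml) as fh:
        roles = yaml.safe_load(fh)
    stack = None
    for role, rel in roles.items():
        arr, grid = read_raster(roles_yaml.parent / rel)
        if stack is None:
            stack = LandscapeStack(grid)
        elif grid != stack.grid:
            raise LayerError(
                f"grid mismatch: layer {role!r} on {grid} vs stack on {stack.grid}")
        stack.add(role, arr)
    if stack is None:
        raise LayerError(f"{roles_yaml}: no layers declared")
    return stack


def write_stack(stack: LandscapeStack, outdir, roles_yaml_name: str = "layers.yaml") -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    roles = {}
    for role in sorted(stack.layers):
        fname = f"{role}.tif"
        write_raster(outdir / fname, stack.layers[role], stack.grid)
        roles[role] = fname
    with open(outdir / roles_yaml_name, "w") as fh:
        yaml.safe_dump(roles, fh, sort_keys=True)
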