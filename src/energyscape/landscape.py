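"""Derived environmental covariate layers on a shared grid.

The landscape is a categorical land-cover grid (with at least a developed and
a forest class), a binary roads grid, and continuous layers derived from them:

* distance to the forest edge (m) — unsigned, for forest and non-forest cells
  alike, measured cell-center to nearest opposite-class cell center;
* proportion of urban area (developed classes or roads) within a focal disc
  (default radius 240 m, cell-center inclusion);
* landscape heterogeneity within the same disc, quantified as the Shannon
  diversity of land-cover classes (the choice of diversity index is a
  documented, substitutable default);
* distance to roads (m).

All layers share one :class:`~energyscape.geometry.GridGeometry`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import GridGeometry

__all__ = [
    "LandscapeStack",
    "distance_to_forest_edge",
    "focal_proportion_urban",
    "focal_heterogeneity",
    "distance_to_roads",
    "pct_urban_in_homerange",
    "derive_layers",
    "disc_kernel",
]

DEFAULT_FOCAL_RADIUS = 240.0  # m; perception-distance radius for focal stats

#: continuous covariates every model stage uses, in canonical order
CONTINUOUS_COVARIATES = (
    "dist_forest_edge",
    "prop_urban_240",
    "heterogeneity",
    "dist_roads",
)


@dataclass
class LandscapeStack:
    """Aligned categorical and continuous landscape layers."""

    geometry: GridGeometry
    land_cover: np.ndarray  # integer class codes, shape (ny, nx)
    class_names: list[str]  # index -> name; "developed*" and "*forest*" special
    roads: np.ndarray  # boolean, shape (ny, nx)
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shp = self.geometry.shape
        if self.land_cover.shape != shp or self.roads.shape != shp:
            raise ValueError("land_cover/roads shape does not match geometry")
        if self.land_cover.min() < 0 or self.land_cover.max() >= len(self.class_names):
            raise ValueError("land_cover codes outside class_names range")
        for name, layer in self.layers.items():
            if layer.shape != shp:
                raise ValueError(f"layer {name!r} shape does not match geometry")

    # -- class masks -------------------------------------------------------
    def class_mask(self, predicate) -> np.ndarray:
        codes = [i for i, n in enumerate(self.class_names) if predicate(n)]
        return np.isin(self.land_cover, codes)

    @property
    def developed_mask(self) -> np.ndarray:
        return self.class_mask(lambda n: n.startswith("developed"))

    @property
    def forest_mask(self) -> np.ndarray:
        return self.class_mask(lambda n: "forest" in n)

    @property
    def urban_mask(self) -> np.ndarray:
        """Developed land cover or roads — the working definition of urban."""
        return self.developed_mask | self.roads

    # -- point extraction --------------------------------------------------
    def covariates_at(self, x, y) -> dict[str, np.ndarray]:
        """Sample land cover (as class-name strings) and all continuous
        layers at world coordinates."""
        iy, ix = self.geometry.world_to_cell(x, y)
        names = np.asarray(self.class_names, dtype=object)
        out: dict[str, np.ndarray] = {"land_cover": names[self.land_cover[iy, ix]]}
        for name, layer in self.layers.items():
            out[name] = layer[iy, ix]
        return out


def disc_kernel(radius: float, cell_size: float) -> np.ndarray:
    """Boolean disc footprint: cells whose centers lie within `radius` of the
    focal cell center."""
    r_cells = int(np.floor(radius / cell_size))
    offs = np.arange(-r_cells, r_cells + 1)
    dy, dx = np.meshgrid(offs, offs, indexing="ij")
    return (dy**2 + dx**2) * cell_size**2 <= radius**2


def _focal_fraction(indicator: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Fraction of in-grid disc cells for which `indicator` is true."""
    k = kernel.astype(float)
    num = ndimage.convolve(indicator.astype(float), k, mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones_like(indicator, dtype=float), k, mode="constant", cval=0.0)
    return num / den


def distance_to_forest_edge(stack: LandscapeStack) -> np.ndarray:
    """Unsigned distance (m) from each cell center to the nearest cell center
    of the opposite forest/non-forest class."""
    forest = stack.forest_mask
    if forest.all() or not forest.any():
        raise ValueError("forest-edge distance undefined on a single-class map")
    cs = stack.geometry.cell_size
    # edt measures distance to the nearest zero-valued cell
    d_from_forest = ndimage.distance_transform_edt(forest) * cs
    d_from_nonforest = ndimage.distance_transform_edt(~forest) * cs
    return np.where(forest, d_from_forest, d_from_nonforest)


def focal_proportion_urban(
    stack: LandscapeStack, radius: float = DEFAULT_FOCAL_RADIUS
) -> np.ndarray:
    """Per-cell fraction of disc cells classed developed or road."""
    if radius < stack.geometry.cell_size:
        raise ValueError("focal radius smaller than one cell")
    kernel = disc_kernel(radius, stack.geometry.cell_size)
    return _focal_fraction(stack.urban_mask, kernel)


def focal_heterogeneity(
    stack: LandscapeStack, radius: float = DEFAULT_FOCAL_RADIUS
) -> np.ndarray:
    """Shannon diversity H = -sum(p_k ln p_k) of land-cover classes within the
    focal disc."""
    if radius < stack.geometry.cell_size:
        raise ValueError("focal radius smaller than one cell")
    kernel = disc_kernel(radius, stack.geometry.cell_size).astype(float)
    den = ndimage.convolve(
        np.ones(stack.geometry.shape), kernel, mode="constant", cval=0.0
    )
    H = np.zeros(stack.geometry.shape)
    for code in range(len(stack.class_names)):
        ind = (stack.land_cover == code).astype(float)
        cnt = ndimage.convolve(ind, kernel, mode="constant", cval=0.0)
        p = cnt / den
        with np.errstate(divide="ignore", invalid="ignore"):
            H -= np.where(p > 0, p * np.log(p), 0.0)
    return H


def distance_to_roads(stack: LandscapeStack) -> np.ndarray:
    """Distance (m) to the nearest road cell center; 0 on road cells."""
    if not stack.roads.any():
        raise ValueError("no road cells: distance to roads undefined")
    return ndimage.distance_transform_edt(~stack.roads) * stack.geometry.cell_size


def pct_urban_in_homerange(stack: LandscapeStack, ud95_mask: np.ndarray) -> float:
    """Fraction of home-range (95% UD) cells that are developed or road."""
    ud95_mask = np.asarray(ud95_mask, dtype=bool)
    if ud95_mask.shape != stack.geometry.shape:
        raise ValueError("mask shape does not match geometry")
    if not ud95_mask.any():
        raise ValueError("empty home-range mask")
    return float(stack.urban_mask[ud95_mask].mean())


def write_landscape(outdir, stack: LandscapeStack) -> None:
    """Write land cover, roads and derived layers as ASCII grids + sidecar."""
    import json
    from pathlib import Path

    from .geometry import write_ascii_grid

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(outdir / "land_cover.asc", stack.land_cover.astype(float), stack.geometry)
    write_ascii_grid(outdir / "roads.asc", stack.roads.astype(float), stack.geometry)
    for name, layer in sorted(stack.layers.items()):
        write_ascii_grid(outdir / f"{name}.asc", layer, stack.geometry)
    with open(outdir / "classes.json", "w") as fh:
        json.dump({"class_names": stack.class_names}, fh, sort_keys=True)
        fh.write("\n")


def read_landscape(outdir) -> LandscapeStack:
    import json
    from pathlib import Path

    from .geometry import read_ascii_grid

    outdir = Path(outdir)
    land, geom = read_ascii_grid(outdir / "land_cover.asc")
    roads, _ = read_ascii_grid(outdir / "roads.asc")
    with open(outdir / "classes.json") as fh:
        class_names = json.load(fh)["class_names"]
    stack = LandscapeStack(
        geometry=geom,
        land_cover=land.astype(int),
        class_names=class_names,
        roads=roads.astype(bool),
    )
    for p in sorted(outdir.glob("*.asc")):
        name = p.stem
        if name in ("land_cover", "roads"):
            continue
        layer, _ = read_ascii_grid(p)
        stack.layers[name] = layer
    return stack


def derive_layers(stack: LandscapeStack, radius: float = DEFAULT_FOCAL_RADIUS) -> LandscapeStack:
    """Compute all derived continuous layers in place and return the stack."""
    stack.layers["dist_forest_edge"] = distance_to_forest_edge(stack)
    stack.layers["prop_urban_240"] = focal_proportion_urban(stack, radius)
    stack.layers["heterogeneity"] = focal_heterogeneity(stack, radius)
    stack.layers["dist_roads"] = (
        distance_to_roads(stack)
        if stack.roads.any()
        else np.full(stack.geometry.shape, np.nan)
    )
    return stack
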