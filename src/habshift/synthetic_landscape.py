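"""Seed-reproducible synthetic mountain landscapes for pipeline testing.

The generator emulates the statistical structure the downstream analysis
assumes, without reproducing any real climatology:

* an elevation field decreasing north-to-south with ridge noise;
* temperature-like layers coupled to elevation through a fixed lapse rate
  (6.5 °C per km) plus a west–east gradient and low-pass-filtered noise;
* precipitation-like layers with gradients and autocorrelated noise,
  strictly positive;
* a future scenario built from the current one by an additive temperature
  field whose spatial mean equals ``temperature_delta`` exactly and a
  multiplicative precipitation field whose spatial mean equals
  ``precipitation_scale`` exactly (mid-century, mid-range emissions
  magnitudes by default);
* river/road/settlement density surfaces held identical between scenarios,
  since such layers have no future projection;
* a forest mask thresholded at a quantile so it covers a fixed fraction of
  the extent;
* optionally, pure-noise decoy layers for variable-screening tests.

A :class:`TruthSpec` defines a known true suitability surface (logistic in
linear + quadratic terms of standardized climate layers plus a Gaussian
elevation envelope), from which presences are sampled; this ground truth is
what parameter-recovery tests measure the fitted model against.

Every product is a pure function of (spec, truth, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid_model import (
    Grid,
    GridGeometry,
    GridStack,
    cell_center,
    write_grid,
    write_points_csv,
)

__all__ = [
    "ScenarioSpec",
    "TruthSpec",
    "Landscape",
    "make_landscape",
    "default_truth",
    "true_suitability",
    "sample_occurrences",
    "make_reserves",
    "write_fixture_set",
]

LAPSE_C_PER_KM = 6.5


@dataclass(frozen=True)
class ScenarioSpec:
    """Dimensions, climate-layer count, and future-scenario deltas.

    ``temperature_delta`` (°C, additive) defaults to +1.5, the middle of a
    mid-range-pathway mid-century warming band; ``precipitation_scale``
    (multiplicative) defaults to 0.9 (a modest drying).
    """

    n_rows: int = 100
    n_cols: int = 100
    cell_size_km: float = 1.0
    n_climate_layers: int = 6
    autocorrelation_range_cells: float = 8.0
    temperature_delta: float = 1.5
    precipitation_scale: float = 0.9
    forest_fraction: float = 0.6
    n_decoy_layers: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("landscape dimensions must be positive")
        if self.n_climate_layers < 2:
            raise ValueError("need at least one temperature and one precipitation layer")
        if not (0.0 < self.forest_fraction < 1.0):
            raise ValueError("forest_fraction must lie in (0, 1)")

    @property
    def temp_names(self) -> list[str]:
        n_temp = (self.n_climate_layers + 1) // 2
        return [f"temp{i + 1}" for i in range(n_temp)]

    @property
    def prec_names(self) -> list[str]:
        n_temp = (self.n_climate_layers + 1) // 2
        return [f"prec{i + 1}" for i in range(self.n_climate_layers - n_temp)]


@dataclass(frozen=True)
class TruthSpec:
    """Known generating model for suitability.

    suitability = logistic( intercept
                            + sum_l lin[l] * z_l + quad[l] * z_l²
                            - ((elev - elev_opt_m) / elev_breadth_m)² )

    where z_l = (layer_l - center[l]) / scale[l]. Values lie in (0, 1) at
    every valid cell and the surface is a deterministic function of the
    layers.
    """

    linear: dict[str, float] = field(default_factory=dict)
    quadratic: dict[str, float] = field(default_factory=dict)
    centers: dict[str, float] = field(default_factory=dict)
    scales: dict[str, float] = field(default_factory=dict)
    elev_opt_m: float | None = None
    elev_breadth_m: float = 1200.0
    intercept: float = 0.0


@dataclass
class Landscape:
    """Everything make_landscape produces, bundled."""

    current: GridStack
    future: GridStack
    elevation: Grid
    forest: Grid
    spec: ScenarioSpec


def _smooth_noise(rng: np.random.Generator, shape, range_cells: float) -> np.ndarray:
    """Low-pass-filtered unit-variance noise with the given correlation range."""
    raw = rng.standard_normal(shape)
    sm = gaussian_filter(raw, sigma=max(range_cells / 2.0, 0.5), mode="reflect")
    sd = sm.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return sm / sd


def make_landscape(spec: ScenarioSpec) -> Landscape:
    """Generate co-registered current/future stacks, elevation and forest."""
    rng = np.random.default_rng(spec.seed)
    shape = (spec.n_rows, spec.n_cols)
    rr = np.linspace(0.0, 1.0, spec.n_rows)[:, None] * np.ones((1, spec.n_cols))
    cc = np.ones((spec.n_rows, 1)) * np.linspace(0.0, 1.0, spec.n_cols)[None, :]
    rc = spec.autocorrelation_range_cells

    # elevation: high in the north, ridge noise, clipped to a mountain range
    elev = 3200.0 - 2000.0 * rr + 500.0 * _smooth_noise(rng, shape, rc)
    elev = np.clip(elev, 200.0, 3800.0)

    mask0 = np.zeros(shape, dtype=bool)
    geom_kwargs = dict(cell_size_km=spec.cell_size_km, origin_xy=(0.0, spec.n_rows * spec.cell_size_km))
    elevation = Grid(values=elev, nodata_mask=mask0.copy(), **geom_kwargs)

    current: dict[str, np.ndarray] = {}
    future: dict[str, np.ndarray] = {}

    # the first temperature layer is an annual-mean analogue, strongly
    # lapse-coupled to elevation; later ones emulate range/seasonality
    # summaries — weak elevation coupling, their own gradients and noise —
    # so the default layer set is only weakly mutually correlated, like a
    # post-screening bioclimatic set
    for i, name in enumerate(spec.temp_names):
        base = 12.0 - 6.0 * i
        lapse_frac = 1.0 if i == 0 else 0.2
        grad = 0.0 if i == 0 else 2.0 * (1.0 if i % 2 == 0 else -1.0)
        layer = (
            base
            - lapse_frac * LAPSE_C_PER_KM * elev / 1000.0
            + grad * cc
            + (0.8 if i == 0 else 2.5) * _smooth_noise(rng, shape, rc)
        )
        # additive warming field: spatial mean exactly temperature_delta, and
        # exactly zero when the delta is zero (null scenario ⇒ future == current)
        delta_noise = _smooth_noise(rng, shape, rc)
        delta = spec.temperature_delta * (1.0 + 0.2 * (delta_noise - delta_noise.mean()))
        current[name] = layer
        future[name] = layer + delta

    for i, name in enumerate(spec.prec_names):
        # orographic component: wetter on the high ground, which also ties
        # every precipitation layer loosely to elevation
        layer = (
            800.0
            + 150.0 * rr
            + 100.0 * cc
            + 0.08 * elev
            + 120.0 * _smooth_noise(rng, shape, rc)
            + 60.0 * i
        )
        layer = np.clip(layer, 50.0, None)
        # multiplicative field: spatial mean exactly precipitation_scale, and
        # exactly 1 when the scale is 1
        mult_noise = _smooth_noise(rng, shape, rc)
        mult = 1.0 + (spec.precipitation_scale - 1.0) * (
            1.0 + 0.2 * (mult_noise - mult_noise.mean())
        )
        current[name] = layer
        future[name] = layer * mult

    # non-climate layers: held identical between scenarios
    for name, amp in (("river_density", 1.0), ("road_density", 0.6), ("settlement_density", 0.4)):
        dens = amp * np.abs(_smooth_noise(rng, shape, rc * 0.75))
        current[name] = dens
        future[name] = dens

    for i in range(spec.n_decoy_layers):
        noise = _smooth_noise(rng, shape, rc)
        current[f"decoy{i + 1}"] = noise
        future[f"decoy{i + 1}"] = noise

    current["elevation"] = elev
    future["elevation"] = elev

    # forest mask from an autocorrelated field, thresholded at a quantile so
    # coverage equals forest_fraction up to ties
    forest_field = _smooth_noise(rng, shape, rc) + 0.5 * (1.0 - rr)
    thresh = np.quantile(forest_field, 1.0 - spec.forest_fraction)
    forest_vals = (forest_field >= thresh).astype(float)
    forest = Grid(values=forest_vals, nodata_mask=mask0.copy(), **geom_kwargs)

    cur_stack = GridStack(
        {n: Grid(values=v, nodata_mask=mask0.copy(), **geom_kwargs) for n, v in current.items()}
    )
    fut_stack = GridStack(
        {n: Grid(values=v, nodata_mask=mask0.copy(), **geom_kwargs) for n, v in future.items()}
    )
    return Landscape(current=cur_stack, future=fut_stack, elevation=elevation, forest=forest, spec=spec)


def default_truth(landscape: Landscape) -> TruthSpec:
    """A strongly niche-structured truth built from current-layer statistics.

    The species prefers a narrow band of the first temperature layer (so an
    elevation-coupled warming shifts its optimum upslope), wetter cells, and
    mid elevations. Centers/scales are frozen from the *current* stack so the
    identical transform applies to the future scenario.
    """
    spec = landscape.spec
    t1 = spec.temp_names[0]
    layers = [t1]
    linear = {t1: 0.0}
    quadratic = {t1: -12.0}  # narrow thermal band: a montane specialist
    if spec.prec_names:
        p1 = spec.prec_names[0]
        layers.append(p1)
        linear[p1] = 2.0
        quadratic[p1] = -1.0
    centers = {}
    scales = {}
    for name in layers:
        vals = landscape.current[name].values
        centers[name] = float(vals.mean())
        scales[name] = float(max(vals.std(), 1e-9))
    return TruthSpec(
        linear=linear,
        quadratic=quadratic,
        centers=centers,
        scales=scales,
        elev_opt_m=float(landscape.elevation.values.mean()),
        elev_breadth_m=600.0,
        intercept=-0.5,
    )


def true_suitability(stack: GridStack, truth: TruthSpec, elevation: Grid | None = None) -> Grid:
    """Evaluate the generating suitability model on a stack.

    Deterministic; raises if a layer named in the truth is missing.
    """
    names = sorted(set(truth.linear) | set(truth.quadratic))
    for name in names:
        if name not in stack:
            raise ValueError(f"layer {name!r} required by the truth is missing")
    geom = stack.geometry
    eta = np.full(geom.shape, truth.intercept, dtype=float)
    for name in names:
        center = truth.centers.get(name, 0.0)
        scale = truth.scales.get(name, 1.0)
        z = (stack[name].values - center) / scale
        eta += truth.linear.get(name, 0.0) * z
        eta += truth.quadratic.get(name, 0.0) * z**2
    if truth.elev_opt_m is not None:
        if elevation is None:
            if "elevation" not in stack:
                raise ValueError("truth uses elevation but no elevation layer given")
            elevation = stack["elevation"]
        zel = (elevation.values - truth.elev_opt_m) / truth.elev_breadth_m
        eta -= zel**2
    suit = 1.0 / (1.0 + np.exp(-eta))
    nodata = ~stack.valid_mask
    suit = suit.copy()
    suit[nodata] = np.nan
    first = stack[stack.names[0]]
    return Grid(
        values=suit,
        nodata_mask=nodata,
        cell_size_km=geom.cell_size_km,
        origin_xy=geom.origin_xy,
        layer_name="true_suitability",
    )


def sample_occurrences(
    suitability: Grid, forest: Grid, n: int, seed: int
) -> np.ndarray:
    """Sample n presence points from forest cells ∝ true suitability.

    Cells are drawn with replacement (several records may share a cell, which
    keeps downstream one-per-cell thinning meaningful); each point is
    jittered uniformly within its cell. Returns an (n, 2) x,y array.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    geom = suitability.geometry
    eligible = suitability.valid_mask & forest.valid_mask & (forest.values > 0)
    weights = np.where(eligible, np.nan_to_num(suitability.values, nan=0.0), 0.0)
    total = weights.sum()
    if total <= 0:
        raise ValueError("no eligible forest cell with positive suitability")
    rng = np.random.default_rng(seed)
    flat_p = (weights / total).ravel()
    idx = rng.choice(flat_p.size, size=n, replace=True, p=flat_p)
    rows, cols = np.unravel_index(idx, geom.shape)
    cs = geom.cell_size_km
    x0, y0 = geom.origin_xy
    jitter = rng.uniform(0.0, 1.0, size=(n, 2))
    xs = x0 + (cols + jitter[:, 0]) * cs
    ys = y0 - (rows + jitter[:, 1]) * cs
    return np.column_stack([xs, ys])


def make_reserves(
    geom: GridGeometry,
    n_reserves: int = 19,
    seed: int = 0,
    cover_fraction: float = 0.3,
    max_retries: int = 2000,
) -> dict:
    """Place non-overlapping rectangular reserves; returns GeoJSON dict.

    Rectangle sizes are drawn so expected total coverage is roughly
    ``cover_fraction`` of the extent; placement is rejection sampling with a
    bounded retry budget.
    """
    if n_reserves < 1:
        raise ValueError("n_reserves must be >= 1")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = geom.extent
    width = xmax - xmin
    height = ymax - ymin
    target_area = cover_fraction * width * height / n_reserves
    side_mean = float(np.sqrt(target_area))

    placed: list[tuple[float, float, float, float]] = []
    features = []
    attempts = 0
    for i in range(n_reserves):
        ok = False
        while attempts < max_retries:
            attempts += 1
            w = side_mean * rng.uniform(0.6, 1.4)
            h = side_mean * rng.uniform(0.6, 1.4)
            w = min(w, width)
            h = min(h, height)
            x = rng.uniform(xmin, xmax - w)
            y = rng.uniform(ymin, ymax - h)
            box = (x, y, x + w, y + h)
            if all(
                box[2] <= b[0] or box[0] >= b[2] or box[3] <= b[1] or box[1] >= b[3]
                for b in placed
            ):
                placed.append(box)
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place reserve {i + 1} of {n_reserves} without overlap "
                f"after {max_retries} attempts"
            )
        x0b, y0b, x1b, y1b = placed[-1]
        ring = [[x0b, y0b], [x1b, y0b], [x1b, y1b], [x0b, y1b], [x0b, y0b]]
        features.append(
            {
                "type": "Feature",
                "properties": {"name": f"reserve_{i + 1:02d}"},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_fixture_set(
    landscape: Landscape,
    truth: TruthSpec,
    out_dir: str | Path,
    n_occurrences: int = 273,
    n_reserves: int = 19,
    seed: int = 0,
) -> dict:
    """Write the full fixture set (.asc grids, occurrences.csv,
    reserves.geojson, manifest.json) and return the manifest."""
    out = Path(out_dir)
    (out / "current").mkdir(parents=True, exist_ok=True)
    (out / "future").mkdir(parents=True, exist_ok=True)
    for name in landscape.current.names:
        write_grid(landscape.current[name], out / "current" / f"{name}.asc")
        write_grid(landscape.future[name], out / "future" / f"{name}.asc")
    write_grid(landscape.elevation, out / "elevation.asc")
    write_grid(landscape.forest, out / "forest.asc")

    suit = true_suitability(landscape.current, truth, elevation=landscape.elevation)
    write_grid(suit, out / "true_suitability.asc")
    occ = sample_occurrences(suit, landscape.forest, n_occurrences, seed=seed + 1)
    write_points_csv(occ, out / "occurrences.csv")
    reserves = make_reserves(landscape.current.geometry, n_reserves, seed=seed + 2)
    with open(out / "reserves.geojson", "w") as fh:
        json.dump(reserves, fh)

    manifest = {
        "spec": landscape.spec.__dict__,
        "truth": {
            "linear": truth.linear,
            "quadratic": truth.quadratic,
            "centers": truth.centers,
            "scales": truth.scales,
            "elev_opt_m": truth.elev_opt_m,
            "elev_breadth_m": truth.elev_breadth_m,
            "intercept": truth.intercept,
        },
        "n_occurrences": n_occurrences,
        "n_reserves": n_reserves,
        "seed": seed,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
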