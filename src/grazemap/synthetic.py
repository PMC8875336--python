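"""Synthetic grazing-day generator.

Emulates the observational setting the pipeline is built for: a ~210 ha
semi-arid paddock, a flock of ~200 sheep penned at night, collars fixing
every 2 min from dawn departure (06:00) to evening return (18:00), a
midday rest at the pen, a short visit to a water point, and grazing loops
drawn toward high-NDVI patches.  Every generator is deterministic given
its seed, and :func:`simulate_trajectory` returns the planted ground
truth (per-segment intake and the resulting intensity field) so recovery
tests can compare estimates against a known answer.

The movement model is a correlated random walk with von Mises turning
angles and a Metropolis-style acceptance step biased toward higher NDVI;
it is synthetic scaffolding with configurable parameters, not a claim
about sheep cognition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from .geodata import Raster, compute_ndvi, sample_raster
from .intensity import GridSpec, IntakeModel, daily_intake
from .trajectory import Segment, Trajectory, segmentize


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the synthetic paddock and flock."""

    seed: int = 0
    area_extent: tuple[float, float] = (1450.0, 1450.0)  # metres; ~210 ha
    fix_interval: float = 120.0  # s
    day_start: float = 6.0  # local clock hours
    day_end: float = 18.0
    pen_location: tuple[float, float] = (200.0, 1250.0)  # north corner
    water_location: tuple[float, float] = (1000.0, 400.0)
    n_grazing_patches: int = 6
    flock_size: int = 200
    weight_class_proportions: tuple[float, float, float] = (0.15, 0.70, 0.15)
    # movement-model knobs (declared assumptions; no published values exist)
    grazing_speed: float = 0.45  # m/s mean while grazing
    transit_speed: float = 1.0  # m/s while walking to/from waypoints
    turning_kappa: float = 4.0  # von Mises concentration
    ndvi_bias_temperature: float = 0.05  # Metropolis acceptance scale
    rest_duration: float = 3600.0  # s, midday rest at the pen
    drink_duration: float = 900.0  # s at the water point
    dwell_jitter: float = 1.0  # m position noise while resting/drinking
    anchor: tuple[float, float] = (39.0, 107.6)  # lat, lon of local (0, 0)

    def __post_init__(self) -> None:
        if abs(sum(self.weight_class_proportions) - 1.0) > 1e-9:
            raise ValueError("weight class proportions must sum to 1")
        if self.fix_interval <= 0:
            raise ValueError("fix_interval must be positive")
        if self.day_end <= self.day_start:
            raise ValueError("day_end must be after day_start")
        for name, (px, py) in (("pen", self.pen_location), ("water", self.water_location)):
            if not (0 <= px <= self.area_extent[0] and 0 <= py <= self.area_extent[1]):
                raise ValueError(f"{name} location outside area extent")

    @property
    def n_fixes(self) -> int:
        day_seconds = (self.day_end - self.day_start) * 3600.0
        return int(round(day_seconds / self.fix_interval)) + 1

    def grid_spec(self, cell_size: float = 13.0, half_width: float = 3.0) -> GridSpec:
        # one-cell margin so segment buffers at the paddock boundary stay
        # inside the grid (keeps conservative allocation exactly conservative)
        return GridSpec(
            origin=(-cell_size, self.area_extent[1] + cell_size),
            extent=(self.area_extent[0] + 2 * cell_size, self.area_extent[1] + 2 * cell_size),
            cell_size=cell_size,
            half_width=half_width,
        )


@dataclass
class GroundTruth:
    """What the simulator actually did, for recovery tests."""

    intensity_field: Raster  # g/m2
    zone_polygons: list[tuple[Polygon, str]]
    per_segment_intake: list[tuple[int, float]]  # (segment index, grams)
    daily_intake_g: float
    grid: GridSpec


# -- flock weights --------------------------------------------------------

WEIGHT_CLASS_BOUNDS = ((30.0, 40.0), (40.0, 60.0), (60.0, 75.0))


def weight_class_counts(flock_size: int, proportions: Sequence[float]) -> list[int]:
    """Integer class sizes by the largest-remainder method (always sum to flock)."""
    if flock_size <= 0:
        raise ValueError("flock_size must be positive")
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    raw = [flock_size * p for p in proportions]
    counts = [int(np.floor(r)) for r in raw]
    short = flock_size - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)], kind="stable")
    for i in range(short):
        counts[order[i]] += 1
    return counts


def simulate_flock_weights(config: SimulationConfig) -> list[float]:
    """Draw body weights (kg): exact class counts, uniform within class bounds."""
    rng = np.random.default_rng(config.seed + 1_000_003)
    counts = weight_class_counts(config.flock_size, config.weight_class_proportions)
    weights: list[float] = []
    for count, (lo, hi) in zip(counts, WEIGHT_CLASS_BOUNDS):
        weights.extend(rng.uniform(lo, hi, size=count).tolist())
    return weights


# -- rasters --------------------------------------------------------------

def generate_terrain(config: SimulationConfig, cell_size: float = 30.0,
                     amplitude: float = 25.0, base_elevation: float = 1300.0,
                     noise_sd: float = 0.3) -> Raster:
    """Smooth synthetic DEM: low-frequency sinusoids plus small noise."""
    rng = np.random.default_rng(config.seed + 2_000_003)
    w, h = config.area_extent
    ncols = int(np.ceil(w / cell_size))
    nrows = int(np.ceil(h / cell_size))
    xs = (np.arange(ncols) + 0.5) * cell_size
    ys = h - (np.arange(nrows) + 0.5) * cell_size
    X, Y = np.meshgrid(xs, ys)
    phases = rng.uniform(0, 2 * np.pi, size=4)
    z = base_elevation + amplitude * (
        0.6 * np.sin(2 * np.pi * X / w + phases[0])
        + 0.4 * np.cos(2 * np.pi * Y / h + phases[1])
        + 0.25 * np.sin(4 * np.pi * (X + Y) / (w + h) + phases[2])
        + 0.15 * np.cos(4 * np.pi * (X - Y) / (w + h) + phases[3])
    )
    if amplitude > 0 and noise_sd > 0:
        z = z + rng.normal(0, noise_sd, size=z.shape)
    return Raster(z, (0.0, h), cell_size, band_meaning="dem")


def grazing_patch_centers(config: SimulationConfig) -> np.ndarray:
    """Deterministic high-NDVI patch centres, away from the paddock border."""
    rng = np.random.default_rng(config.seed + 3_000_003)
    w, h = config.area_extent
    return np.column_stack(
        [
            rng.uniform(0.15 * w, 0.85 * w, size=config.n_grazing_patches),
            rng.uniform(0.15 * h, 0.85 * h, size=config.n_grazing_patches),
        ]
    )


def generate_bands(config: SimulationConfig, dem: Raster) -> tuple[Raster, Raster]:
    """NIR and red reflectance rasters whose NDVI is smooth and patchy.

    The target NDVI field is a low background plus Gaussian bumps at the
    grazing patch centres, with peak values drawn in [0.58, 0.90]; bands
    are constructed as nir = s*(1+v)/2, red = s*(1-v)/2 for a fixed band
    sum s, which reproduces v exactly and keeps reflectances in (0, 1].
    """
    rng = np.random.default_rng(config.seed + 4_000_003)
    X, Y = dem.cell_centers()
    v = np.full(dem.shape, 0.0)
    background = 0.18 + 0.04 * np.sin(2 * np.pi * X / config.area_extent[0]) \
        * np.cos(2 * np.pi * Y / config.area_extent[1])
    v += background
    centers = grazing_patch_centers(config)
    peaks = rng.uniform(0.58, 0.90, size=len(centers))
    sigma = 0.08 * min(config.area_extent)
    for (cx, cy), peak in zip(centers, peaks):
        d2 = (X - cx) ** 2 + (Y - cy) ** 2
        v = np.maximum(v, background + (peak - background) * np.exp(-0.5 * d2 / sigma**2))
    v = np.clip(v, 0.0, 0.95)
    band_sum = 0.6
    nir = band_sum * (1 + v) / 2
    red = band_sum * (1 - v) / 2
    return (
        Raster(nir, dem.origin, dem.cell_size, band_meaning="nir"),
        Raster(red, dem.origin, dem.cell_size, band_meaning="red"),
    )


# -- temperature ----------------------------------------------------------

@dataclass
class TemperatureSeries:
    """Diurnal air temperature sampled at the collar fix interval."""

    seconds_of_day: np.ndarray
    values: np.ndarray  # deg C
    season: str

    def at(self, second_of_day: float | np.ndarray) -> np.ndarray | float:
        return np.interp(second_of_day, self.seconds_of_day, self.values)


SEASON_MEANS = {"summer": 24.0, "autumn": 10.0}
TEMP_AMPLITUDE = 6.0
TEMP_PEAK_HOUR = 14.0


def generate_temperature(
    day_index: int,
    season: str,
    seed: int,
    config: SimulationConfig | None = None,
    noise_sd: float = 0.3,
) -> TemperatureSeries:
    """Sinusoidal diurnal temperature curve plus noise, peaking early afternoon."""
    if season not in SEASON_MEANS:
        raise ValueError(f"season must be one of {sorted(SEASON_MEANS)}")
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed + 5_000_003 + day_index)
    t = cfg.day_start * 3600 + np.arange(cfg.n_fixes) * cfg.fix_interval
    hours = t / 3600.0
    mean = SEASON_MEANS[season]
    temp = mean + TEMP_AMPLITUDE * np.cos(2 * np.pi * (hours - TEMP_PEAK_HOUR) / 24.0)
    if noise_sd > 0:
        temp = temp + rng.normal(0, noise_sd, size=temp.shape)
    return TemperatureSeries(t, temp, season)


# -- trajectory simulation ------------------------------------------------

def _reflect(p: np.ndarray, extent: tuple[float, float]) -> np.ndarray:
    out = p.copy()
    for k, lim in enumerate(extent):
        if out[k] < 0:
            out[k] = -out[k]
        if out[k] > lim:
            out[k] = 2 * lim - out[k]
        out[k] = float(np.clip(out[k], 0, lim))
    return out


def simulate_trajectory(
    config: SimulationConfig,
    animal_weight: float,
    day_index: int = 0,
    ndvi: Raster | None = None,
    intake_model: IntakeModel = IntakeModel(),
) -> tuple[Trajectory, GroundTruth]:
    """One animal-day of collar fixes plus the planted intake ground truth.

    The day runs 06:00-18:00 at the fix interval: departure from the pen,
    grazing loops toward high-NDVI patches (correlated random walk with
    Metropolis NDVI acceptance), one drinking visit, one midday rest at
    the pen, and a guided return so the last fix lands within 20 m of the
    pen.  Ground truth allocates the daily intake IZ over segments in
    proportion to duration and bins it by segment midpoint on the 13-m
    grid.
    """
    if animal_weight <= 0:
        raise ValueError(f"animal weight must be positive, got {animal_weight}")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 7_000_003 + day_index, int(animal_weight * 1000)])
    )
    if ndvi is None:
        dem = generate_terrain(config)
        nir, red = generate_bands(config, dem)
        ndvi = compute_ndvi(nir, red)

    n = config.n_fixes
    dt = config.fix_interval
    pen = np.asarray(config.pen_location, float)
    water = np.asarray(config.water_location, float)
    patches = grazing_patch_centers(config)

    # phase schedule in fix indices
    rest_len = max(1, int(round(config.rest_duration / dt)))
    drink_len = max(1, int(round(config.drink_duration / dt)))
    rest_start = n // 2 - rest_len // 2
    drink_start = n // 4
    return_start = n - max(4, int(0.1 * n))

    def ndvi_at(p: np.ndarray) -> float:
        try:
            v = sample_raster(ndvi, (float(p[0]), float(p[1])))
        except ValueError:
            return 0.0
        return 0.0 if np.isclose(v, ndvi.nodata) else float(v)

    pos = pen + rng.normal(0, 2.0, size=2)
    pos = _reflect(pos, config.area_extent)
    heading = rng.uniform(0, 2 * np.pi)
    target = patches[rng.integers(len(patches))]
    xs = np.empty(n)
    ys = np.empty(n)
    xs[0], ys[0] = pos
    for i in range(1, n):
        in_drink = drink_start <= i < drink_start + drink_len
        in_rest = rest_start <= i < rest_start + rest_len
        pre_drink = drink_start - 10 <= i < drink_start
        pre_rest = rest_start - 12 <= i < rest_start
        returning = i >= return_start
        if in_drink or in_rest:
            anchor_pt = water if in_drink else pen
            pos = anchor_pt + rng.normal(0, config.dwell_jitter, size=2)
        elif pre_drink or pre_rest or returning:
            goal = water if pre_drink else pen
            vec = goal - pos
            dist = np.hypot(*vec)
            step_max = config.transit_speed * dt
            if dist <= 2 * step_max:
                # close enough: snap to the goal so no mid-speed fix lands
                # inside the dwell zone
                pos = goal + rng.normal(0, config.dwell_jitter, size=2)
            else:
                direction = vec / dist
                pos = pos + direction * step_max + rng.normal(0, 1.0, size=2)
                heading = float(np.arctan2(direction[1], direction[0]))
        else:
            # grazing: correlated walk, Metropolis acceptance toward higher NDVI
            if rng.random() < 0.02:  # occasionally retarget a patch
                target = patches[rng.integers(len(patches))]
            pull = target - pos
            pull_angle = np.arctan2(pull[1], pull[0])
            for _attempt in range(6):
                turn = rng.vonmises(0.0, config.turning_kappa)
                cand_heading = 0.7 * heading + 0.3 * pull_angle + turn
                step = max(0.0, rng.normal(config.grazing_speed, 0.15)) * dt
                cand = pos + step * np.array([np.cos(cand_heading), np.sin(cand_heading)])
                cand = _reflect(cand, config.area_extent)
                dv = ndvi_at(cand) - ndvi_at(pos)
                if dv >= 0 or rng.random() < np.exp(dv / config.ndvi_bias_temperature):
                    pos, heading = cand, cand_heading
                    break
        pos = _reflect(pos, config.area_extent)
        xs[i], ys[i] = pos
    # guarantee the return contract
    d_end = np.hypot(*(pos - pen))
    if d_end > 15.0:
        xs[-1], ys[-1] = pen + rng.normal(0, 2.0, size=2)

    base = np.datetime64("2020-08-01", "ns") + np.timedelta64(day_index, "D")
    seconds = np.round(config.day_start * 3600 + np.arange(n) * dt).astype(np.int64)
    times = base + seconds.astype("timedelta64[s]").astype("timedelta64[ns]")
    traj = Trajectory(f"sheep-{int(animal_weight)}kg", times, xs, ys)

    # ground truth: constant-rate intake by duration, binned at midpoints
    segments, _ = segmentize(traj, max_speed=np.inf)
    tz = sum(s.duration for s in segments)
    iz = daily_intake(animal_weight, intake_model)
    grid = config.grid_spec()
    field = grid.raster_template("intensity")
    vals = field.values
    per_seg: list[tuple[int, float]] = []
    for k, seg in enumerate(segments):
        grams = iz * seg.duration / tz
        per_seg.append((k, grams))
        r, c = grid.cell_of(*seg.midpoint)
        nrows, ncols = grid.shape
        if 0 <= r < nrows and 0 <= c < ncols:
            vals[r, c] += grams / grid.cell_area
    zone_polys = [
        (box(pen[0] - 20, pen[1] - 20, pen[0] + 20, pen[1] + 20), "rest"),
        (box(water[0] - 15, water[1] - 15, water[0] + 15, water[1] + 15), "drinking"),
    ]
    truth = GroundTruth(field, zone_polys, per_seg, iz, grid)
    return traj, truth


# -- planted regression features ------------------------------------------

FEATURE_ORDER = ("NDVI", "S", "T", "Ftemp", "C", "P", "D", "E")

# planted linear dependence on the five trajectory/vegetation variables
PLANTED_COEFFS = {"NDVI": 2.0, "S": 0.5, "T": 0.8, "Ftemp": 0.6, "C": 1.0}


def planted_feature_table(
    n: int, seed: int, noise_sd: float = 0.05
) -> pd.DataFrame:
    """Feature table whose target depends only on NDVI, weight, duration,
    temperature and moving distance (plus Gaussian noise) — terrain
    features are pure distractors.  Used by recovery tests to check that
    the network and the combination screen find the planted signal.
    """
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "T": rng.uniform(100, 140, n),
            "C": rng.uniform(10, 70, n),
            "P": rng.uniform(0, 20, n),
            "E": rng.uniform(1250, 1350, n),
            "D": rng.uniform(0, 360, n),
            "NDVI": rng.uniform(0.1, 0.9, n),
            "S": rng.uniform(30, 75, n),
            "Ftemp": rng.uniform(5, 30, n),
        }
    )
    z = sum(
        PLANTED_COEFFS[k] * (df[k] - df[k].mean()) / df[k].std(ddof=1)
        for k in PLANTED_COEFFS
    )
    df["target"] = z + rng.normal(0, noise_sd, n)
    return df
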