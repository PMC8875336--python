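"""Fix ingestion, segmentation, kernel-density clustering and zone exclusion.

A *fix* is one GPS collar record (timestamp + position); a *trajectory* is
the fixes of one animal over one local day; a *segment* joins two
consecutive fixes and carries the duration ``T`` and walking distance ``C``
that later become model features.  Kernel density over the fixes locates
aggregation zones (rest areas / pens, drinking points); fixes inside rest
and drinking zones are excluded before any intake is allocated, because
time spent there removes no forage.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union

from .geodata import Raster, lonlat_to_planar

if TYPE_CHECKING:  # pragma: no cover
    from .intensity import GridSpec

logger = logging.getLogger(__name__)

MAX_SPEED_DEFAULT = 3.0  # m/s; sheep cannot sustain more between 2-min fixes
REST_SPEED_THRESHOLD = 0.05  # m/s mean within-cluster fix speed
REST_MIN_DWELL = 1800.0  # s
EARTH_RADIUS_M = 6_371_000.0


# -- data model -----------------------------------------------------------

@dataclass
class Trajectory:
    """Fixes of one animal over one local day, in planar metres.

    ``lon``/``lat`` are retained when the source was geographic, in which
    case segment lengths use the haversine formula instead of Euclidean
    distance.
    """

    animal_id: str
    times: np.ndarray  # datetime64[ns], strictly increasing
    x: np.ndarray
    y: np.ndarray
    lon: np.ndarray | None = None
    lat: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.times)
        if len(self.x) != n or len(self.y) != n:
            raise ValueError("times/x/y length mismatch")
        if n and not np.all(np.diff(self.times).astype("timedelta64[ns]").astype(np.int64) > 0):
            raise ValueError("fix times must be strictly increasing")
        if n and not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("fix coordinates must be finite")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def day(self):
        return pd.Timestamp(self.times[0]).date() if len(self) else None

    def fix_speeds(self) -> np.ndarray:
        """Forward-difference speed (m/s) per fix; last fix repeats the previous."""
        if len(self) < 2:
            return np.zeros(len(self))
        dt = np.diff(self.times).astype("timedelta64[s]").astype(float)
        d = np.hypot(np.diff(self.x), np.diff(self.y))
        v = np.concatenate([d / dt, [d[-1] / dt[-1]]])
        return v

    def subset(self, keep: np.ndarray) -> "Trajectory":
        return Trajectory(
            self.animal_id,
            self.times[keep],
            self.x[keep],
            self.y[keep],
            None if self.lon is None else self.lon[keep],
            None if self.lat is None else self.lat[keep],
        )


@dataclass(frozen=True)
class Segment:
    """Path between two consecutive fixes: duration T (s), length C (m)."""

    p0: tuple[float, float]
    p1: tuple[float, float]
    t0: np.datetime64
    t1: np.datetime64
    duration: float
    length: float

    @property
    def midpoint(self) -> tuple[float, float]:
        return ((self.p0[0] + self.p1[0]) / 2, (self.p0[1] + self.p1[1]) / 2)

    @property
    def midpoint_time(self) -> np.datetime64:
        return self.t0 + np.timedelta64(int(self.duration * 1e9 / 2), "ns")

    @property
    def speed(self) -> float:
        return self.length / self.duration


ZONE_CLASSES = ("rest", "drinking", "grazing")


@dataclass(frozen=True)
class Zone:
    polygon: Polygon
    zone_class: str
    cluster_id: int

    def __post_init__(self) -> None:
        if self.zone_class not in ZONE_CLASSES:
            raise ValueError(f"zone class must be one of {ZONE_CLASSES}")


@dataclass
class ZoneMap:
    """Kernel density, five-grade classification and classified clusters."""

    density: Raster
    grades: Raster
    clusters: list[Zone] = field(default_factory=list)

    def polygons(self, zone_class: str) -> list[Polygon]:
        return [z.polygon for z in self.clusters if z.zone_class == zone_class]


# -- ingestion ------------------------------------------------------------

@dataclass
class FixIngest:
    trajectories: list[Trajectory]
    n_dropped: int = 0
    n_duplicates: int = 0


REQUIRED_COLUMNS = ("animal_id", "timestamp")


def read_fixes(
    path: str | Path,
    dialect: str = "csv",
    anchor: tuple[float, float] = (39.0, 107.6),
) -> FixIngest:
    """Read collar fixes and split them into one trajectory per animal per day.

    CSV dialect expects columns ``animal_id,timestamp,lon,lat`` (or planar
    ``x,y``); GPX track points are the alternate dialect.  Rows with
    unparseable time or coordinates are dropped and counted; duplicate
    timestamps within an animal collapse to the first occurrence.
    """
    if dialect == "csv":
        df = pd.read_csv(path, dtype={"animal_id": str})
    elif dialect == "gpx":
        df = _read_gpx(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    geographic = {"lon", "lat"} <= set(df.columns)
    if not geographic and not {"x", "y"} <= set(df.columns):
        raise ValueError("missing required column 'lon'/'lat' (or planar 'x'/'y')")

    n_raw = len(df)
    if n_raw == 0:
        logger.warning("read_fixes: empty input %s", path)
        return FixIngest([], 0, 0)
    df = df.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    if getattr(df["timestamp"].dt, "tz", None) is not None:
        df["timestamp"] = df["timestamp"].dt.tz_localize(None)
    coord_cols = ["lon", "lat"] if geographic else ["x", "y"]
    for c in coord_cols:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    ok = df["timestamp"].notna() & np.isfinite(df[coord_cols]).all(axis=1)
    n_dropped = int((~ok).sum())
    df = df[ok]

    df = df.sort_values(["animal_id", "timestamp"], kind="stable")
    dup = df.duplicated(subset=["animal_id", "timestamp"])
    n_duplicates = int(dup.sum())
    df = df[~dup]

    trajectories: list[Trajectory] = []
    for (animal, day), grp in df.groupby(
        ["animal_id", df["timestamp"].dt.date], sort=True
    ):
        if geographic:
            x, y = lonlat_to_planar(grp["lon"].to_numpy(), grp["lat"].to_numpy(), anchor)
            traj = Trajectory(
                str(animal), grp["timestamp"].to_numpy(), x, y,
                grp["lon"].to_numpy(), grp["lat"].to_numpy(),
            )
        else:
            traj = Trajectory(
                str(animal), grp["timestamp"].to_numpy(),
                grp["x"].to_numpy(), grp["y"].to_numpy(),
            )
        trajectories.append(traj)
    if n_dropped:
        logger.info("read_fixes: dropped %d malformed rows of %d", n_dropped, n_raw)
    return FixIngest(trajectories, n_dropped, n_duplicates)


def _read_gpx(path: str | Path) -> pd.DataFrame:
    ns = {"gpx": "http://www.topografix.com/GPX/1/1"}
    root = ET.parse(path).getroot()
    rows = []
    for trk in root.findall("gpx:trk", ns):
        name_el = trk.find("gpx:name", ns)
        animal = name_el.text if name_el is not None else "track"
        for pt in trk.iter("{http://www.topografix.com/GPX/1/1}trkpt"):
            time_el = pt.find("gpx:time", ns)
            rows.append(
                {
                    "animal_id": animal,
                    "timestamp": time_el.text if time_el is not None else None,
                    "lon": pt.get("lon"),
                    "lat": pt.get("lat"),
                }
            )
    return pd.DataFrame(rows, columns=["animal_id", "timestamp", "lon", "lat"])


def haversine(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance in metres on a sphere of radius 6371 km."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(h)))


# -- segmentation ---------------------------------------------------------

def segmentize(
    trajectory: Trajectory,
    max_speed: float = MAX_SPEED_DEFAULT,
    max_gap: float | None = None,
) -> tuple[list[Segment], int]:
    """Build consecutive segments, filtering GPS glitches and time gaps.

    Segment length uses haversine on lon/lat when the trajectory retains
    geographic coordinates, Euclidean distance on planar input.  Pairs whose
    implied speed exceeds ``max_speed`` are flagged as glitches and removed
    (returned as a count).  Pairs whose time gap exceeds ``max_gap``
    (default 1.5x the median fix interval) are not bridged — this keeps
    runs split by zone exclusion independent.
    """
    n = len(trajectory)
    if n < 2:
        logger.warning("segmentize: trajectory %s has < 2 fixes", trajectory.animal_id)
        return [], 0
    dt = np.diff(trajectory.times).astype("timedelta64[ns]").astype(np.int64) / 1e9
    if max_gap is None:
        max_gap = 1.5 * float(np.median(dt))
    if trajectory.lon is not None and trajectory.lat is not None:
        lengths = np.array(
            [
                haversine(
                    trajectory.lon[i], trajectory.lat[i],
                    trajectory.lon[i + 1], trajectory.lat[i + 1],
                )
                for i in range(n - 1)
            ]
        )
    else:
        lengths = np.hypot(np.diff(trajectory.x), np.diff(trajectory.y))
    segments: list[Segment] = []
    n_glitch = 0
    for i in range(n - 1):
        if dt[i] > max_gap:
            continue
        if lengths[i] / dt[i] > max_speed:
            n_glitch += 1
            continue
        segments.append(
            Segment(
                p0=(float(trajectory.x[i]), float(trajectory.y[i])),
                p1=(float(trajectory.x[i + 1]), float(trajectory.y[i + 1])),
                t0=trajectory.times[i],
                t1=trajectory.times[i + 1],
                duration=float(dt[i]),
                length=float(lengths[i]),
            )
        )
    if n_glitch:
        logger.info("segmentize: removed %d over-speed segments (> %g m/s)", n_glitch, max_speed)
    return segments, n_glitch


# -- kernel density -------------------------------------------------------

def silverman_bandwidth(x: np.ndarray, y: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth (metres) for 2-D fix coordinates."""
    n = len(x)
    if n < 2:
        return 1.0
    sigma = 0.5 * (np.std(x, ddof=1) + np.std(y, ddof=1))
    return float(max(sigma * n ** (-1.0 / 6.0), 1e-6))


def kernel_density(
    fixes_xy: np.ndarray,
    bandwidth: float | None,
    grid: "GridSpec",
) -> Raster:
    """Gaussian kernel density of fix points on the analysis grid.

    The kernel is truncated at 4 bandwidths, and the surface is rescaled so
    that it integrates (sum x cell area) to the number of fixes.  Values are
    points per square metre.
    """
    pts = np.atleast_2d(np.asarray(fixes_xy, dtype=float))
    if pts.shape[0] < 1 or pts.shape[1] != 2:
        raise ValueError("need >= 1 fix as an (n, 2) array")
    if bandwidth is None:
        bandwidth = silverman_bandwidth(pts[:, 0], pts[:, 1])
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    template = grid.raster_template("density")
    X, Y = template.cell_centers()
    h2 = bandwidth * bandwidth
    cutoff2 = (4.0 * bandwidth) ** 2
    dens = np.zeros(template.shape)
    norm = 1.0 / (2.0 * np.pi * h2)
    for px, py in pts:  # n is small (hundreds); keeps memory flat
        d2 = (X - px) ** 2 + (Y - py) ** 2
        near = d2 <= cutoff2
        dens[near] += norm * np.exp(-0.5 * d2[near] / h2)
    total = dens.sum() * grid.cell_area
    if total > 0:
        dens *= len(pts) / total
    return template.copy_with(dens, "density")


# -- grading --------------------------------------------------------------

GRADE_LABELS = {1: "extremely low", 2: "low", 3: "medium", 4: "high", 5: "extremely high"}


def _jenks_breaks(values: np.ndarray, k: int) -> np.ndarray:
    """Natural-breaks style thresholds via 1-D k-means (k cluster upper edges)."""
    from sklearn.cluster import KMeans

    uniq = np.unique(values)
    k = min(k, len(uniq))
    km = KMeans(n_clusters=k, n_init=4, random_state=0).fit(values.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    # break between consecutive clusters = midpoint of adjacent extremes
    breaks = []
    for lo, hi in zip(order[:-1], order[1:]):
        breaks.append((values[km.labels_ == lo].max() + values[km.labels_ == hi].min()) / 2)
    return np.asarray(breaks)


def grade_density(density: Raster, scheme: str = "quantile") -> Raster:
    """Classify a density surface into five grades (5 = extremely high).

    Nonzero cells are partitioned by the chosen scheme (``quantile``,
    ``jenks`` or ``equal_interval``); zero-density cells are grade 1.
    Grading is monotone: higher density never receives a lower grade.
    """
    vals = density.values
    valid = density.mask()
    nonzero = valid & (vals > 0)
    grades = np.full(density.shape, density.nodata)
    grades[valid] = 1.0
    nz = vals[nonzero]
    if nz.size == 0:
        logger.warning("grade_density: all-zero density, everything grade 1")
        return density.copy_with(grades, "grades")
    if scheme == "quantile":
        breaks = np.quantile(nz, [0.2, 0.4, 0.6, 0.8])
    elif scheme == "equal_interval":
        breaks = nz.min() + (nz.max() - nz.min()) * np.array([0.2, 0.4, 0.6, 0.8])
    elif scheme == "jenks":
        breaks = _jenks_breaks(nz, 5)
    else:
        raise ValueError(f"unknown grading scheme {scheme!r}")
    grades[nonzero] = 1.0 + np.searchsorted(breaks, nz, side="left")
    return density.copy_with(grades, "grades")


# -- zone classification and exclusion ------------------------------------

def _cluster_polygon(rows: np.ndarray, cols: np.ndarray, raster: Raster) -> Polygon:
    s = raster.cell_size
    x0, y0 = raster.origin
    boxes = [
        box(x0 + c * s, y0 - (r + 1) * s, x0 + (c + 1) * s, y0 - r * s)
        for r, c in zip(rows, cols)
    ]
    return unary_union(boxes)


def classify_zones(
    grades: Raster,
    trajectories: Sequence[Trajectory],
    water_point: tuple[float, float] | None = None,
    overrides: Sequence[tuple[Polygon, str]] | None = None,
    rest_speed_threshold: float = REST_SPEED_THRESHOLD,
    rest_min_dwell: float = REST_MIN_DWELL,
    density: Raster | None = None,
) -> ZoneMap:
    """Classify high-density clusters as rest / drinking / grazing zones.

    Connected components of grade >= 4 become candidate clusters.  A cluster
    whose mean within-cluster fix speed is below ``rest_speed_threshold``
    with total dwell >= ``rest_min_dwell`` is a rest area (pens included); a
    cluster containing the water point is a drinking area; anything else is
    grazing.  Explicit override polygons win over the rules and are added
    as clusters themselves.
    """
    high = grades.mask() & (grades.values >= 4)
    labels, n_lab = ndimage.label(high, structure=np.ones((3, 3)))

    xs = np.concatenate([t.x for t in trajectories]) if trajectories else np.array([])
    ys = np.concatenate([t.y for t in trajectories]) if trajectories else np.array([])
    speeds = np.concatenate([t.fix_speeds() for t in trajectories]) if trajectories else np.array([])
    dts = (
        np.concatenate(
            [
                np.append(np.diff(t.times).astype("timedelta64[s]").astype(float), 0.0)
                for t in trajectories
            ]
        )
        if trajectories
        else np.array([])
    )

    zones: list[Zone] = []
    override_list = list(overrides or [])
    for cid in range(1, n_lab + 1):
        rows, cols = np.nonzero(labels == cid)
        poly = _cluster_polygon(rows, cols, grades)
        cls = None
        for opoly, ocls in override_list:
            if poly.intersects(opoly):
                cls = ocls
                break
        if cls is None:
            if xs.size:
                inside = shapely.contains_xy(poly, xs, ys)
            else:
                inside = np.zeros(0, dtype=bool)
            dwell = float(dts[inside].sum()) if inside.any() else 0.0
            mean_speed = float(speeds[inside].mean()) if inside.any() else np.inf
            # the water-point rule outranks the dwell rule: a drinking
            # aggregation is also near-stationary
            if water_point is not None and poly.covers(Point(*water_point)):
                cls = "drinking"
            elif mean_speed < rest_speed_threshold and dwell >= rest_min_dwell:
                cls = "rest"
            else:
                cls = "grazing"
        zones.append(Zone(poly, cls, cid))
    for j, (opoly, ocls) in enumerate(override_list):
        zones.append(Zone(opoly, ocls, n_lab + 1 + j))
    dens = density if density is not None else grades
    return ZoneMap(dens, grades, zones)


def exclude_zones(trajectory: Trajectory, zones: ZoneMap) -> tuple[Trajectory, int]:
    """Drop fixes inside rest and drinking polygons.

    Returns the filtered trajectory and the removed-fix count.  Gaps left
    by removal are respected downstream: :func:`segmentize` never bridges a
    time gap larger than 1.5 fix intervals, so no segment spans an excluded
    block.  Idempotent.
    """
    if len(trajectory) == 0:
        return trajectory, 0
    remove = np.zeros(len(trajectory), dtype=bool)
    for zone in zones.clusters:
        if zone.zone_class in ("rest", "drinking"):
            remove |= shapely.contains_xy(zone.polygon, trajectory.x, trajectory.y)
    return trajectory.subset(~remove), int(remove.sum())
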