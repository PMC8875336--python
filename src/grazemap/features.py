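"""Per-segment feature assembly, standardization and factor combinations.

Each retained trajectory segment yields one sample with eight candidate
predictors — segment duration T (s), walking distance C (m), slope P
(deg), elevation E (m), aspect D (deg), NDVI, sheep weight S (kg) and
ambient temperature Ftemp (degC) — and the grazing intensity of the grid
cell containing the segment midpoint as the regression target (g/m2).
Features are z-scored (sample standard deviation, n-1) before training.
The nine factor combinations X1..X9 are fixed inclusion masks over the
eight predictors, used to screen which subset carries the signal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

from .geodata import Raster, sample_raster

if TYPE_CHECKING:  # pragma: no cover
    from .intensity import IntensityGrid
    from .synthetic import TemperatureSeries
    from .trajectory import Segment

logger = logging.getLogger(__name__)

#: Combination-table column order: vegetation index, sheep weight, duration,
#: temperature, moving distance, slope, aspect, elevation.
COMBO_FEATURE_ORDER = ("NDVI", "S", "T", "Ftemp", "C", "P", "D", "E")

#: CSV column order for feature tables.
CSV_COLUMNS = ("T", "C", "P", "E", "D", "NDVI", "S", "Ftemp", "target")

#: The nine screened factor combinations (inclusion flags over
#: COMBO_FEATURE_ORDER).  X1 is all eight; X7 is the vegetation/animal/
#: trajectory subset {NDVI, S, T, Ftemp, C}.
COMBINATIONS: Mapping[str, tuple[int, ...]] = {
    "X1": (1, 1, 1, 1, 1, 1, 1, 1),
    "X2": (1, 1, 1, 1, 0, 0, 0, 0),
    "X3": (0, 0, 0, 0, 1, 1, 1, 1),
    "X4": (1, 1, 0, 0, 1, 1, 1, 1),
    "X5": (1, 0, 1, 0, 1, 1, 1, 1),
    "X6": (0, 1, 1, 1, 0, 1, 1, 1),
    "X7": (1, 1, 1, 1, 1, 0, 0, 0),
    "X8": (1, 1, 1, 1, 1, 1, 0, 0),
    "X9": (1, 1, 1, 1, 1, 1, 1, 0),
}


def combination_columns(combo_id: str) -> list[str]:
    """Feature names included in a combination, in combination-table order."""
    if combo_id not in COMBINATIONS:
        raise ValueError(f"unknown combination {combo_id!r}; valid: {sorted(COMBINATIONS)}")
    flags = COMBINATIONS[combo_id]
    return [name for name, f in zip(COMBO_FEATURE_ORDER, flags) if f]


def extract_features(
    segments: Sequence["Segment"],
    rasters: Mapping[str, Raster],
    temperature: "TemperatureSeries",
    weight: float,
    intensity: "IntensityGrid",
) -> pd.DataFrame:
    """One feature row per segment, sampled at the segment midpoint.

    ``rasters`` must provide ``ndvi``, ``dem``, ``slope`` and ``aspect``.
    The target is the intensity F of the cell containing the midpoint.
    Rows where any raster returns nodata (or the midpoint falls outside
    coverage) are dropped; the count is stored in ``df.attrs['n_dropped']``.
    """
    required = {"ndvi", "dem", "slope", "aspect"}
    missing = required - set(rasters)
    if missing:
        raise ValueError(f"missing rasters: {sorted(missing)}")
    if not segments:
        raise ValueError("no segments to extract features from")
    rows = []
    n_dropped = 0
    nrows_g, ncols_g = intensity.grid.shape
    for seg in segments:
        mx, my = seg.midpoint
        try:
            vals = {
                "NDVI": sample_raster(rasters["ndvi"], (mx, my)),
                "E": sample_raster(rasters["dem"], (mx, my)),
                "P": sample_raster(rasters["slope"], (mx, my)),
                "D": sample_raster(rasters["aspect"], (mx, my)),
            }
        except ValueError:
            n_dropped += 1
            continue
        if any(np.isclose(v, rasters["ndvi"].nodata) for v in vals.values()):
            n_dropped += 1
            continue
        r, c = intensity.grid.cell_of(mx, my)
        if not (0 <= r < nrows_g and 0 <= c < ncols_g):
            n_dropped += 1
            continue
        mid_t = pd.Timestamp(seg.midpoint_time)
        second_of_day = (
            mid_t - mid_t.normalize()
        ).total_seconds()
        rows.append(
            {
                "T": seg.duration,
                "C": seg.length,
                "P": vals["P"],
                "E": vals["E"],
                "D": vals["D"],
                "NDVI": vals["NDVI"],
                "S": weight,
                "Ftemp": float(temperature.at(second_of_day)),
                "target": float(intensity.values.values[r, c]),
            }
        )
    if not rows:
        raise ValueError("no segment midpoint is covered by the rasters")
    if n_dropped:
        logger.info("extract_features: dropped %d of %d segments", n_dropped, len(segments))
    df = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    df.attrs["n_dropped"] = n_dropped
    return df


@dataclass
class Standardization:
    """Per-column z-score parameters (sample sd, n-1), reusable on new data."""

    means: pd.Series
    stds: pd.Series

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col in self.means.index:
            if col in out:
                out[col] = (out[col] - self.means[col]) / self.stds[col]
        return out

    def inverse(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col in self.means.index:
            if col in out:
                out[col] = out[col] * self.stds[col] + self.means[col]
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"means": self.means.to_dict(), "stds": self.stds.to_dict()}, indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Standardization":
        d = json.loads(Path(path).read_text())
        return cls(pd.Series(d["means"]), pd.Series(d["stds"]))


def standardize(
    table: pd.DataFrame, columns: Sequence[str] | None = None
) -> tuple[pd.DataFrame, Standardization]:
    """Z-score the given columns (default: all); error on constant columns."""
    if len(table) < 2:
        raise ValueError("need >= 2 rows to standardize")
    cols = list(columns) if columns is not None else list(table.columns)
    means = table[cols].mean()
    stds = table[cols].std(ddof=1)
    constant = stds.index[stds <= 0].tolist()
    if constant:
        raise ValueError(f"constant column(s) cannot be standardized: {constant}")
    std = Standardization(means, stds)
    return std.transform(table), std


def select_combination(
    table: pd.DataFrame,
    combo_id: str,
    aspect_encoding: str = "sincos",
    keep_target: bool = True,
) -> pd.DataFrame:
    """Filter feature columns to one combination.

    Aspect is circular; with ``aspect_encoding='sincos'`` (default) the D
    column expands into ``D_sin``/``D_cos`` to avoid the 0/360 degree
    discontinuity.  ``'raw'`` keeps D as degrees.  Row order is preserved;
    column order follows the combination-table header order.
    """
    cols = combination_columns(combo_id)
    out = pd.DataFrame(index=table.index)
    for name in cols:
        if name == "D" and aspect_encoding == "sincos":
            rad = np.radians(table["D"])
            out["D_sin"] = np.sin(rad)
            out["D_cos"] = np.cos(rad)
        elif aspect_encoding not in ("sincos", "raw"):
            raise ValueError(f"unknown aspect encoding {aspect_encoding!r}")
        else:
            out[name] = table[name]
    if keep_target and "target" in table:
        out["target"] = table["target"]
    return out
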