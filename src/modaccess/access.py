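"""Cumulative-opportunity accessibility counts and deprivation summaries.

For each zone, mode, intensity category and time threshold the count is
the number of facilities of that intensity whose travel time from the
zone's population-weighted centroid is within the threshold (inclusive:
"within 20 minutes" reads as <= 20). Unreachable facilities never count.
Population-adjusted counts are facilities per 1,000 residents (the base
is configurable). Quintile summaries report the median with (min, max)
per quintile from Q1 (most affluent) to Q5 (most deprived), the layout
used for deprivation-gradient tables.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .facilities import Facility, INTENSITIES
from .journeys import TravelTimeMatrix


def count_accessible(
    matrix: TravelTimeMatrix,
    facilities: Sequence[Facility],
    intensity: str,
    threshold_min: float,
) -> pd.Series:
    """Per-zone count of facilities of one intensity within the threshold."""
    if intensity not in INTENSITIES:
        raise ValueError(f"unknown intensity {intensity!r}")
    by_id = {f.facility_id: f for f in facilities}
    cols = [
        j
        for j, fid in enumerate(matrix.destinations)
        if fid in by_id and by_id[fid].intensity == intensity
    ]
    if not cols:
        return pd.Series(0, index=matrix.origins, name="count")
    sub = matrix.minutes[:, cols]
    counts = (np.isfinite(sub) & (sub <= threshold_min)).sum(axis=1)
    return pd.Series(counts.astype(int), index=matrix.origins, name="count")


def population_adjust(count, population, per_capita_base: float = 1000.0):
    """Counts per ``per_capita_base`` residents: count * base / population."""
    population = np.asarray(population, dtype=float)
    if (population <= 0).any():
        raise ValueError("population must be positive")
    return np.asarray(count, dtype=float) * per_capita_base / population


def accessibility_table(
    matrices: dict[str, TravelTimeMatrix],
    facilities: Sequence[Facility],
    zones: pd.DataFrame,
    config: AnalysisConfig = AnalysisConfig(),
) -> pd.DataFrame:
    """Long table: zone_id, mode, intensity, threshold, count, adjusted_count.

    ``zones`` must carry ``zone_id`` and ``population`` columns. Light
    facilities are excluded unless ``config.include_light`` is set.
    """
    zones = zones.set_index("zone_id") if "zone_id" in zones.columns else zones
    intensities = list(config.intensities)
    if config.include_light and "light" not in intensities:
        intensities = ["light"] + intensities
    rows = []
    for mode, matrix in matrices.items():
        pop = zones.loc[matrix.origins, "population"].to_numpy(float)
        for intensity in intensities:
            for thr in config.thresholds_min:
                counts = count_accessible(matrix, facilities, intensity, thr)
                adjusted = population_adjust(counts.to_numpy(), pop, config.per_capita_base)
                for z, c, a in zip(matrix.origins, counts.to_numpy(), adjusted):
                    rows.append(
                        {
                            "zone_id": z,
                            "mode": mode,
                            "intensity": intensity,
                            "threshold": thr,
                            "count": int(c),
                            "adjusted_count": a,
                        }
                    )
    return pd.DataFrame(rows)


def quintile_summary(table: pd.DataFrame, zones: pd.DataFrame) -> pd.DataFrame:
    """Median (min, max) of raw and adjusted counts per deprivation quintile.

    One row per quintile x mode x intensity x threshold, quintiles 1 (most
    affluent) to 5 (most deprived); a quintile with no zones yields a row
    of missing values rather than being dropped.
    """
    zones = zones.set_index("zone_id") if "zone_id" in zones.columns else zones
    if not set(zones["quintile"].unique()) <= {1, 2, 3, 4, 5}:
        raise ValueError("quintile labels must be 1..5")
    merged = table.merge(
        zones[["quintile"]], left_on="zone_id", right_index=True, how="left"
    )
    rows = []
    for (mode, intensity, thr), grp in merged.groupby(
        ["mode", "intensity", "threshold"], sort=True
    ):
        for q in (1, 2, 3, 4, 5):
            sub = grp[grp["quintile"] == q]
            base = {"mode": mode, "intensity": intensity, "threshold": thr, "quintile": q}
            if sub.empty:
                rows.append(
                    base
                    | {k: np.nan for k in (
                        "median", "min", "max", "adj_median", "adj_min", "adj_max")}
                    | {"n_zones": 0}
                )
                continue
            rows.append(
                base
                | {
                    "median": float(sub["count"].median()),
                    "min": float(sub["count"].min()),
                    "max": float(sub["count"].max()),
                    "adj_median": float(sub["adjusted_count"].median()),
                    "adj_min": float(sub["adjusted_count"].min()),
                    "adj_max": float(sub["adjusted_count"].max()),
                    "n_zones": int(len(sub)),
                }
            )
    return pd.DataFrame(rows)
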