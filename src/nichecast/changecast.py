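"""Scenario projection bookkeeping: GCM averaging, binarization,
suitability classes, area accounting, presence-triple coding, and
centroid tracking.

Areas are spherical-rectangle cell areas on a sphere of radius
6371.0088 km (cos-latitude scaling by row); a nominal mode charges a
fixed 25 km^2 per cell for hand-checkable fixtures.  Change
percentages are expressed relative to the current suitable area, and
the net change is exactly expansion minus contraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geo_io import AlignmentError, EnvStack, GridGeometry, SuitabilityMap
from .maxent_core import MaxentModel, predict
from .tuneval import ThresholdSet

__all__ = [
    "EARTH_RADIUS_KM",
    "BinaryMap",
    "ChangeSummary",
    "TripleCodeMap",
    "average_gcms",
    "binarize",
    "classify_suitability",
    "cell_area",
    "cell_areas",
    "change_map",
    "triple_code",
    "centroid",
    "run_scenarios",
]

EARTH_RADIUS_KM = 6371.0088

#: Cell states of a BinaryMap.
ABSENT, PRESENT, NODATA = 0, 1, -1

#: Change-map categories.
STABLE_ABSENT, EXPANSION, CONTRACTION, STABLE_PRESENT = 0, 1, 2, 3


@dataclass(eq=False)
class BinaryMap:
    """Per-cell present/absent/nodata states on a grid."""

    geometry: GridGeometry
    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != self.geometry.shape:
            raise AlignmentError("states shape does not match grid")

    @property
    def present(self) -> np.ndarray:
        return self.states == PRESENT

    @property
    def valid(self) -> np.ndarray:
        return self.states != NODATA


@dataclass
class ChangeSummary:
    """Areas and percentages of a current-vs-future binary comparison.

    Percentages are relative to the current suitable area; the net
    change is expansion minus contraction, exactly.
    """

    expansion_km2: float
    stable_km2: float
    contraction_km2: float
    absent_km2: float
    current_suitable_km2: float

    @property
    def expansion_pct(self) -> float:
        return 100.0 * self.expansion_km2 / self.current_suitable_km2

    @property
    def no_change_pct(self) -> float:
        return 100.0 * self.stable_km2 / self.current_suitable_km2

    @property
    def contraction_pct(self) -> float:
        return 100.0 * self.contraction_km2 / self.current_suitable_km2

    @property
    def net_change_pct(self) -> float:
        return self.expansion_pct - self.contraction_pct


@dataclass(eq=False)
class TripleCodeMap:
    """(current, 2050s, 2070s) presence-triple coding of each cell.

    ``codes`` holds ``4*b_current + 2*b_mid + b_late`` (0..7, -1 for
    nodata); ``areas`` maps each triple to its km^2 total.
    """

    geometry: GridGeometry
    codes: np.ndarray
    areas: pd.Series


def cell_area(geometry: GridGeometry, row: int, nominal: bool = False) -> float:
    """Area in km^2 of any cell in a given row.

    Spherical rectangle: ``(R * dphi) * (R * dlambda * cos(phi_center))``
    — cells shrink with the cosine of the center latitude.  Nominal
    mode returns a flat 25 km^2.
    """
    if nominal:
        return 25.0
    d = np.deg2rad(geometry.cell_size_deg)
    _, lat = geometry.cell_center(row, 0)
    return float(EARTH_RADIUS_KM * d * EARTH_RADIUS_KM * d * np.cos(np.deg2rad(lat)))


def cell_areas(geometry: GridGeometry, nominal: bool = False) -> np.ndarray:
    """Per-cell area grid in km^2."""
    if nominal:
        return np.full(geometry.shape, 25.0)
    rows = np.array([cell_area(geometry, r) for r in range(geometry.n_rows)])
    return np.broadcast_to(rows[:, None], geometry.shape).copy()


def average_gcms(maps: Sequence[SuitabilityMap]) -> SuitabilityMap:
    """Cell-wise arithmetic mean of member suitability maps.

    The mean is taken on the displayed (logistic) scale; a cell is
    nodata if it is nodata in any member.
    """
    if not maps:
        raise ValueError("need at least one map")
    geom = maps[0].geometry
    for m in maps[1:]:
        if not geom.same_grid(m.geometry):
            raise AlignmentError("member maps do not share a grid")
    stack = np.stack([m.values for m in maps])
    mean = stack.mean(axis=0)  # NaN propagates: nodata in any member wins
    return SuitabilityMap(geom.with_mask(~np.isfinite(mean)), mean)


def binarize(smap: SuitabilityMap, t: float) -> BinaryMap:
    """Present where suitability is strictly greater than the threshold."""
    if not 0.0 < t < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    states = np.full(smap.geometry.shape, NODATA, dtype=np.int8)
    valid = smap.valid_mask
    states[valid] = np.where(smap.values[valid] > t, PRESENT, ABSENT)
    return BinaryMap(smap.geometry, states)


def classify_suitability(
    smap: SuitabilityMap, thresholds: ThresholdSet, nominal: bool = False
) -> tuple[np.ndarray, pd.Series]:
    """Four-class suitability map and per-class areas.

    Classes: 0 unsuitable [0, t]; 1 low (t, e1]; 2 moderate (e1, e2];
    3 high (e2, 1]; nodata is -1.
    """
    t, e1, e2, _ = thresholds.bin_edges
    classes = np.full(smap.geometry.shape, -1, dtype=np.int8)
    valid = smap.valid_mask
    v = smap.values
    classes[valid] = np.digitize(v[valid], [t, e1, e2], right=True)
    areas = cell_areas(smap.geometry, nominal=nominal)
    names = ["unsuitable", "low", "moderate", "high"]
    per_class = pd.Series(
        {
            name: float(areas[(classes == k) & valid].sum())
            for k, name in enumerate(names)
        },
        name="area_km2",
    )
    return classes, per_class


def change_map(
    current: BinaryMap, future: BinaryMap, nominal: bool = False
) -> tuple[np.ndarray, ChangeSummary]:
    """Categorize current-to-future transitions and account their areas.

    Categories: expansion (absent to present), contraction (present to
    absent), stable presence, stable absence.  Percentages in the
    summary are relative to the current suitable area.
    """
    if not current.geometry.same_grid(future.geometry):
        raise AlignmentError("binary maps do not share a grid")
    valid = current.valid & future.valid
    cats = np.full(current.geometry.shape, NODATA, dtype=np.int8)
    cur, fut = current.present, future.present
    cats[valid & ~cur & fut] = EXPANSION
    cats[valid & cur & ~fut] = CONTRACTION
    cats[valid & cur & fut] = STABLE_PRESENT
    cats[valid & ~cur & ~fut] = STABLE_ABSENT
    areas = cell_areas(current.geometry, nominal=nominal)

    def area_of(code: int) -> float:
        return float(areas[cats == code].sum())

    current_suitable = float(areas[valid & cur].sum())
    summary = ChangeSummary(
        expansion_km2=area_of(EXPANSION),
        stable_km2=area_of(STABLE_PRESENT),
        contraction_km2=area_of(CONTRACTION),
        absent_km2=area_of(STABLE_ABSENT),
        current_suitable_km2=current_suitable,
    )
    return cats, summary


def triple_code(
    current: BinaryMap,
    map_mid: BinaryMap,
    map_late: BinaryMap,
    nominal: bool = False,
) -> TripleCodeMap:
    """Eight-way (current, mid-century, late-century) presence coding."""
    for other in (map_mid, map_late):
        if not current.geometry.same_grid(other.geometry):
            raise AlignmentError("binary maps do not share a grid")
    valid = current.valid & map_mid.valid & map_late.valid
    codes = np.full(current.geometry.shape, -1, dtype=np.int8)
    codes[valid] = (
        4 * current.present[valid]
        + 2 * map_mid.present[valid]
        + map_late.present[valid]
    )
    areas = cell_areas(current.geometry, nominal=nominal)
    labels = {}
    for code in range(8):
        bits = ((code >> 2) & 1, (code >> 1) & 1, code & 1)
        labels[bits] = float(areas[codes == code].sum())
    return TripleCodeMap(current.geometry, codes, pd.Series(labels, name="area_km2"))


def centroid(
    bmap: BinaryMap, nominal: bool = False, weights: SuitabilityMap | None = None
) -> tuple[float, float]:
    """Centroid of the suitable range.

    Default: area-weighted mean of present-cell centers.  Passing a
    suitability map additionally weights each present cell by its
    suitability.
    """
    rows, cols = np.nonzero(bmap.present)
    if len(rows) == 0:
        raise ValueError("no present cells; centroid undefined")
    geom = bmap.geometry
    lon = geom.origin_lon + (cols + 0.5) * geom.cell_size_deg
    lat = geom.origin_lat - (rows + 0.5) * geom.cell_size_deg
    w = cell_areas(geom, nominal=nominal)[rows, cols]
    if weights is not None:
        w = w * weights.values[rows, cols]
    w = w / w.sum()
    return float(w @ lon), float(w @ lat)


def run_scenarios(
    model: MaxentModel,
    current_stack: EnvStack,
    scenario_stacks: Mapping[tuple[str, str], Sequence[EnvStack]],
    t: float,
    nominal: bool = False,
) -> dict:
    """Project and summarize every (SSP, period) scenario group.

    ``scenario_stacks`` maps ``(ssp, period)`` to its GCM member
    stacks (any number of members).  Returns a dict with the current
    map/binary, per-scenario mean maps, binary maps, change categories
    and summaries, a Table-2-style summary frame, per-SSP
    presence-triple maps (when both periods are present), and the
    centroid track.
    """
    if not scenario_stacks:
        raise ValueError("no scenario groups given")
    current_map = predict(model, current_stack)
    current_bin = binarize(current_map, t)
    results: dict = {
        "current_map": current_map,
        "current_binary": current_bin,
        "scenarios": {},
    }
    table_rows = []
    cur_centroid = centroid(current_bin, nominal=nominal)
    centroids = {"current": cur_centroid}
    for (ssp, period), members in scenario_stacks.items():
        if not members:
            raise ValueError(f"scenario group {(ssp, period)} is empty")
        mean_map = average_gcms([predict(model, s) for s in members])
        bmap = binarize(mean_map, t)
        cats, summary = change_map(current_bin, bmap, nominal=nominal)
        results["scenarios"][(ssp, period)] = {
            "mean_map": mean_map,
            "binary": bmap,
            "categories": cats,
            "summary": summary,
        }
        centroids[f"{ssp}-{period}"] = centroid(bmap, nominal=nominal)
        table_rows.append(
            {
                "ssp": ssp,
                "period": period,
                "expansion_pct": summary.expansion_pct,
                "no_change_pct": summary.no_change_pct,
                "contraction_pct": summary.contraction_pct,
                "net_change_pct": summary.net_change_pct,
            }
        )
    results["change_table"] = pd.DataFrame(table_rows)
    triples = {}
    by_ssp: dict[str, dict[str, BinaryMap]] = {}
    for (ssp, period), res in results["scenarios"].items():
        by_ssp.setdefault(ssp, {})[period] = res["binary"]
    for ssp, periods in by_ssp.items():
        if len(periods) == 2:
            mid, late = [periods[k] for k in sorted(periods)]
            triples[ssp] = triple_code(current_bin, mid, late, nominal=nominal)
    results["triple_codes"] = triples
    results["centroids"] = centroids
    return results
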