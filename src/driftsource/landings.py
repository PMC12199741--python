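"""Landing tallies, region aggregation, drift-time and covariate statistics.

Turns landing records from the transport module into the headline outputs of a
backtracking study: per-cell landing counts and percentages of all released
particles, aggregation into named lat/lon region boxes, drift-time summaries
with pairwise rank-sum tests, position density clouds, and association of
monthly landing counts with ENSO phase or season.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .stats import pairwise_rank_sum, TestReport

PHASES = ("El Niño", "La Niña", "Neutral")
_SEASON_OF_MONTH = {12: "DJF", 1: "DJF", 2: "DJF", 3: "MAM", 4: "MAM", 5: "MAM",
                    6: "JJA", 7: "JJA", 8: "JJA", 9: "SON", 10: "SON", 11: "SON"}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (0.05 -> 0.1), not banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def season_of(month: int) -> str:
    """Meteorological season label (DJF/MAM/JJA/SON) of a calendar month."""
    return _SEASON_OF_MONTH[int(month)]


@dataclass
class RegionBox:
    """Named lat/lon box; lon is wrap-aware (lo > hi spans the 0/360 seam).

    Membership is inclusive at lower bounds and exclusive at upper bounds.
    """

    name: str
    lat: tuple
    lon: tuple

    def __post_init__(self):
        if self.lat[0] >= self.lat[1]:
            raise ValidationError(f"region {self.name}: degenerate latitude range")
        if (self.lon[0] % 360.0) == (self.lon[1] % 360.0):
            raise ValidationError(f"region {self.name}: degenerate longitude range")

    def contains(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon, dtype=float) % 360.0
        lat = np.asarray(lat, dtype=float)
        lo, hi = self.lon[0] % 360.0, self.lon[1] % 360.0
        if lo < hi:
            in_lon = (lon >= lo) & (lon < hi)
        else:
            in_lon = (lon >= lo) | (lon < hi)
        return in_lon & (lat >= self.lat[0]) & (lat < self.lat[1])

    def _lon_intervals(self):
        lo, hi = self.lon[0] % 360.0, self.lon[1] % 360.0
        return [(lo, hi)] if lo < hi else [(lo, 360.0), (0.0, hi)]

    def overlaps(self, other: "RegionBox") -> bool:
        if self.lat[0] >= other.lat[1] or other.lat[0] >= self.lat[1]:
            return False
        for a0, a1 in self._lon_intervals():
            for b0, b1 in other._lon_intervals():
                if a0 < b1 and b0 < a1:
                    return True
        return False


#: the study's three regions of interest
DEFAULT_REGIONS = (
    RegionBox("Japan", lat=(29.0, 43.5), lon=(135.0, 150.0)),
    RegionBox("central Pacific", lat=(0.5, 18.0), lon=(188.0, 205.0)),   # 155–172°W
    RegionBox("ETP", lat=(-2.5, 12.0), lon=(250.0, 271.5)),              # 88.5–110°W
)


def tally_landings(records: pd.DataFrame, total_released: int) -> pd.DataFrame:
    """Per-cell landing counts and percentages of all released particles.

    One row per cell with >= 1 landing, sorted by count descending.  ``percent``
    is exact; ``percent_1dp`` is the half-up one-decimal display value.
    """
    if total_released < len(records):
        raise ValidationError("total_released smaller than the number of landings")
    if records.empty:
        return pd.DataFrame(columns=["cell_id", "count", "percent", "percent_1dp"])
    counts = records.groupby("cell_id").size().rename("count").reset_index()
    counts["percent"] = 100.0 * counts["count"] / total_released
    counts["percent_1dp"] = counts["percent"].map(lambda p: round_half_up(p, 1))
    return counts.sort_values(["count", "cell_id"], ascending=[False, True]).reset_index(drop=True)


def aggregate_regions(table: pd.DataFrame, centroids: Dict[int, tuple],
                      boxes: Sequence[RegionBox], total_released: int) -> pd.DataFrame:
    """Aggregate per-cell counts into region boxes by cell centroid.

    A cell contributes to the (validated disjoint) box containing its centroid;
    cells in no box form the "other" residue.  Percentages are of
    ``total_released``.
    """
    boxes = list(boxes)
    for i, a in enumerate(boxes):
        for b in boxes[i + 1:]:
            if a.overlaps(b):
                raise ValidationError(f"regions {a.name!r} and {b.name!r} overlap")
    rows = {b.name: 0 for b in boxes}
    rows["other"] = 0
    for _, rec in table.iterrows():
        lon, lat = centroids[int(rec["cell_id"])]
        for b in boxes:
            if b.contains(lon, lat):
                rows[b.name] += int(rec["count"])
                break
        else:
            rows["other"] += int(rec["count"])
    out = pd.DataFrame({"region": list(rows), "count": list(rows.values())})
    out["percent"] = 100.0 * out["count"] / total_released
    out["percent_1dp"] = out["percent"].map(lambda p: round_half_up(p, 1))
    return out


def region_of_cells(centroids: Dict[int, tuple], boxes: Sequence[RegionBox]) -> Dict[int, str]:
    """cell id -> region name ("other" if in no box)."""
    out = {}
    for cid, (lon, lat) in centroids.items():
        out[cid] = next((b.name for b in boxes if b.contains(lon, lat)), "other")
    return out


def drift_time_summary(records: pd.DataFrame, cell_to_region: Dict[int, str],
                       include_other: bool = False):
    """Per-region drift-time stats plus pairwise rank-sum tests.

    Returns (summary DataFrame with n/mean/median, list of TestReport).
    Groups with zero observations are dropped with a warning.
    """
    df = records.copy()
    df["region"] = df["cell_id"].map(cell_to_region)
    if not include_other:
        df = df[df["region"] != "other"]
    groups = {r: g["drift_days"].to_numpy(dtype=float) for r, g in df.groupby("region")}
    empty = [r for r, v in groups.items() if len(v) == 0]
    for r in empty:
        warnings.warn(f"region {r!r} has no landings; excluded from tests")
        del groups[r]
    if len(groups) < 2:
        raise ValidationError("need at least two regions with landings")
    summary = pd.DataFrame({
        "region": list(groups),
        "n": [len(v) for v in groups.values()],
        "mean_days": [float(np.mean(v)) for v in groups.values()],
        "median_days": [float(np.median(v)) for v in groups.values()],
    })
    return summary, pairwise_rank_sum(groups)


def density_cloud(trajectories: pd.DataFrame, resolution: float = 1.0,
                  lon_range=(0.0, 360.0), lat_range=(-80.0, 90.0)):
    """Proportion of all logged particle positions per lon/lat pixel.

    Returns (H, lon_edges, lat_edges) with H indexed (lat, lon) and ΣH = 1.
    """
    if trajectories.empty:
        raise ValidationError("empty trajectory log")
    lon = np.asarray(trajectories["lon"], dtype=float) % 360.0
    lat = np.asarray(trajectories["lat"], dtype=float)
    lon0 = lon_range[0] % 360.0
    extent = (lon_range[1] - lon_range[0]) % 360.0 or 360.0
    x = (lon - lon0) % 360.0
    xe = np.arange(0.0, extent + resolution * 0.5, resolution)
    ye = np.arange(lat_range[0], lat_range[1] + resolution * 0.5, resolution)
    H, _, _ = np.histogram2d(lat, x, bins=[ye, xe])
    return H / H.sum(), lon0 + xe, ye


def read_enso_csv(path) -> pd.Series:
    """ENSO phase per month from a CSV with columns year, month, phase."""
    df = pd.read_csv(path)
    idx = pd.PeriodIndex(pd.to_datetime(dict(year=df["year"], month=df["month"], day=1)),
                         freq="M")
    return pd.Series(df["phase"].to_numpy(), index=idx, name="phase")


def covariate_association(records: pd.DataFrame, enso: pd.Series,
                          cell_to_region: Dict[int, str], by: str = "phase",
                          paired: bool = False):
    """Monthly landing counts per region, compared between ENSO phases or seasons.

    Landings are binned by landing month over the full span of the ENSO series;
    months with no landings count as zero.  Within each region, all pairwise
    rank-sum tests between phase (or season) month-groups are run with
    Bonferroni correction within that family.  ``paired=True`` switches to the
    Wilcoxon signed-rank test on equal-length groups (months matched in
    chronological order) — provided because the pairing unit of a "paired rank
    sum" on unequal phase-month counts is undefined.

    Returns (monthly counts DataFrame, {region: [TestReport, ...]}).
    """
    if by not in ("phase", "season"):
        raise ValidationError("by must be 'phase' or 'season'")
    df = records.copy()
    df["region"] = df["cell_id"].map(cell_to_region)
    df = df[df["region"] != "other"]
    months = pd.PeriodIndex(pd.to_datetime(df["landing_date"]), freq="M")
    missing = set(months) - set(enso.index)
    if missing:
        raise ValidationError(f"ENSO series does not label months: {sorted(missing)[:3]} ...")
    df["month"] = months

    all_months = enso.index
    tables = []
    for region, g in df.groupby("region"):
        counts = g.groupby("month").size().reindex(all_months, fill_value=0)
        tab = pd.DataFrame({"region": region, "month": all_months,
                            "count": counts.to_numpy(), "phase": enso.to_numpy()})
        tab["season"] = [season_of(m.month) for m in all_months]
        tables.append(tab)
    monthly = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
        columns=["region", "month", "count", "phase", "season"])

    reports: Dict[str, List[TestReport]] = {}
    from itertools import combinations
    from .stats import bonferroni, rank_sum_test
    from scipy import stats as sps
    for region, tab in monthly.groupby("region"):
        groups = {k: v["count"].to_numpy(dtype=float) for k, v in tab.groupby(by)}
        names = [k for k in groups if len(groups[k])]
        pairs = list(combinations(names, 2))
        fam = []
        for a, b in pairs:
            if paired:
                if len(groups[a]) != len(groups[b]):
                    raise ValidationError("paired tests require equal-length groups")
                d = groups[a] - groups[b]
                if np.all(d == 0):
                    stat, p = 0.0, 1.0
                else:
                    res = sps.wilcoxon(groups[a], groups[b])
                    stat, p = float(res.statistic), float(res.pvalue)
            else:
                stat, p = rank_sum_test(groups[a], groups[b])
            fam.append(TestReport(a, b, stat, p, bonferroni(p, len(pairs)), len(pairs)))
        reports[region] = fam
    return monthly, reports
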