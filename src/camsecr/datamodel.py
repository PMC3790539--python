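"""Domain types and file I/O for camera-trap capture–recapture studies.

The analyses downstream (SECR density estimation, social-structure
inference, residency classification) all start from the same three flat
files: a registry of fixed camera traps on a projected (planar, metres)
coordinate system, a log of when each camera was actually filming, and a
table of timestamped detections of identified individuals.  This module
parses those files, bins continuous camera operation into discrete
sampling occasions, and assembles effort-corrected capture histories
(individual x detector x occasion counts).

Coordinates are planar metres throughout; areas are reported in km²
(conversion applied once via :data:`M2_PER_KM2`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import shape as shapely_shape
from shapely.ops import unary_union

M2_PER_KM2 = 1e6

#: individuals regarded as weaned / independently moving; younger animals
#: are excluded from capture histories (they do not move independently
#: and are excluded from the comparison methods as well).
WEANED_AGE_CLASSES = frozenset({"adult", "adolescent"})

AGE_CLASSES = ("adult", "adolescent", "juvenile", "infant")
SEXES = ("male", "female", "unknown")

#: sentinel id for detections where the animal could not be identified;
#: such rows feed identification-rate summaries but never capture histories.
UNIDENTIFIED = "UNID"


class DataFormatError(ValueError):
    """A file does not conform to the expected CSV/GeoJSON dialect."""


class ValidationError(ValueError):
    """Parsed data are internally inconsistent (e.g. unknown camera id)."""


class ParameterError(ValueError):
    """An argument is outside its valid domain."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CameraTrap:
    """A fixed camera trap at planar coordinates (metres)."""

    camera_id: str
    x: float
    y: float
    grid_cell: str = ""
    coverage: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.x) or not np.isfinite(self.y):
            raise ValidationError(f"camera {self.camera_id}: non-finite coordinates")


@dataclass(frozen=True)
class DetectionRecord:
    """One identified (or anonymous) visit of an individual at a camera."""

    individual_id: str
    camera_id: str
    timestamp: datetime
    sex: str = "unknown"
    age_class: str = "adult"
    group_hint: str = ""

    @property
    def identified(self) -> bool:
        return self.individual_id != UNIDENTIFIED


@dataclass
class Occasion:
    """Half-open date range [start, end); a boundary detection belongs to
    the later occasion."""

    start: date
    end: date

    @property
    def days(self) -> int:
        return (self.end - self.start).days

    def contains(self, ts: datetime | date) -> bool:
        d = ts.date() if isinstance(ts, datetime) else ts
        return self.start <= d < self.end


@dataclass
class EffortMatrix:
    """Fraction of each occasion during which each camera was filming.

    ``e[k, s]`` is in [0, 1] for camera index ``k`` and occasion ``s``.
    """

    camera_ids: list[str]
    occasions: list[Occasion]
    e: np.ndarray  # (K, S)

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=float)
        if self.e.shape != (len(self.camera_ids), len(self.occasions)):
            raise ParameterError("effort matrix shape mismatch")
        if (self.e < 0).any() or (self.e > 1).any():
            raise ValidationError("effort entries must lie in [0, 1]")


@dataclass
class CaptureHistory:
    """Detection counts per individual x detector x occasion, with effort.

    ``y[i, k, s]`` is a non-negative count.  ``covariates`` carries one row
    per individual (index = individual id) with at least a ``sex`` column
    and optionally a boolean ``solitary`` column used by the group /
    grouphet detection models.
    """

    individual_ids: list[str]
    cameras: list[CameraTrap]
    occasions: list[Occasion]
    effort: np.ndarray  # (K, S)
    y: np.ndarray  # (n, K, S) int
    covariates: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    @property
    def n_detections(self) -> int:
        return int(self.y.sum())

    def camera_xy(self) -> np.ndarray:
        return np.array([[c.x, c.y] for c in self.cameras], dtype=float)

    def subset_individuals(self, keep: Sequence[str]) -> "CaptureHistory":
        idx = [self.individual_ids.index(i) for i in keep]
        return CaptureHistory(
            individual_ids=list(keep),
            cameras=self.cameras,
            occasions=self.occasions,
            effort=self.effort,
            y=self.y[idx],
            covariates=self.covariates.loc[list(keep)],
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Iterable[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing required column(s) {missing}")


def read_cameras(path) -> list[CameraTrap]:
    """Read the camera registry (camera_id,x,y,grid_cell[,coverage_*])."""
    df = pd.read_csv(path, dtype={"camera_id": str, "grid_cell": str})
    _require_columns(df, ["camera_id", "x", "y"], str(path))
    if df["camera_id"].duplicated().any():
        dupes = df.loc[df["camera_id"].duplicated(), "camera_id"].tolist()
        raise ValidationError(f"duplicate camera ids: {dupes}")
    cov_cols = [c for c in df.columns if c.startswith("coverage_")]
    cams = []
    for row in df.itertuples(index=False):
        cov = {c[len("coverage_"):]: float(getattr(row, c)) for c in cov_cols}
        cams.append(
            CameraTrap(
                camera_id=row.camera_id,
                x=float(row.x),
                y=float(row.y),
                grid_cell=str(getattr(row, "grid_cell", "") or ""),
                coverage=cov,
            )
        )
    return cams


def read_detections(path, cameras: Sequence[CameraTrap] | None = None) -> list[DetectionRecord]:
    """Read timestamped detection records.

    Timestamps are parsed to naive datetimes at minute resolution.  If a
    camera registry is given, rows referring to unknown cameras raise a
    :class:`ValidationError` naming the offenders.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["individual_id", "camera_id", "timestamp"], str(path))
    if df.empty:
        return []
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    bad = df.loc[ts.isna()]
    if len(bad):
        raise DataFormatError(
            f"{path}: {len(bad)} malformed timestamp(s), first at row {bad.index[0]}"
        )
    if cameras is not None:
        known = {c.camera_id for c in cameras}
        offenders = sorted(set(df["camera_id"]) - known)
        if offenders:
            raise ValidationError(f"unknown camera id(s) in detections: {offenders}")
    records = []
    for row, t in zip(df.itertuples(index=False), ts):
        records.append(
            DetectionRecord(
                individual_id=row.individual_id,
                camera_id=row.camera_id,
                timestamp=t.to_pydatetime().replace(second=0, microsecond=0),
                sex=(getattr(row, "sex", "") or "unknown"),
                age_class=(getattr(row, "age_class", "") or "adult"),
                group_hint=getattr(row, "group_hint", "") or "",
            )
        )
    return records


def read_activity(path) -> pd.DataFrame:
    """Read the camera activity log (camera_id,active_from,active_to)."""
    df = pd.read_csv(path, dtype={"camera_id": str})
    _require_columns(df, ["camera_id", "active_from", "active_to"], str(path))
    df["active_from"] = pd.to_datetime(df["active_from"]).dt.date
    df["active_to"] = pd.to_datetime(df["active_to"]).dt.date
    if (df["active_to"] < df["active_from"]).any():
        raise ValidationError(f"{path}: activity range with end before start")
    return df


def read_habitat(path):
    """Read habitat polygons from GeoJSON; returns a shapely geometry."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [shapely_shape(f["geometry"]) for f in gj["features"]]
    elif gj.get("type") == "Feature":
        geoms = [shapely_shape(gj["geometry"])]
    else:
        geoms = [shapely_shape(gj)]
    return unary_union(geoms)


# ---------------------------------------------------------------------------
# occasions and effort
# ---------------------------------------------------------------------------

def build_occasions(study_start: date, study_end: date, occasion_days: int = 30) -> list[Occasion]:
    """Split [study_start, study_end) into consecutive half-open occasions.

    The final occasion may be shorter than ``occasion_days``.
    """
    if occasion_days <= 0:
        raise ParameterError("occasion_days must be positive")
    if study_start >= study_end:
        raise ParameterError("study_start must precede study_end")
    occasions = []
    cur = study_start
    while cur < study_end:
        nxt = min(cur + timedelta(days=occasion_days), study_end)
        occasions.append(Occasion(cur, nxt))
        cur = nxt
    return occasions


def _merge_ranges(ranges: list[tuple[date, date]]) -> list[tuple[date, date]]:
    """Merge overlapping/adjacent inclusive date ranges."""
    out: list[tuple[date, date]] = []
    for a, b in sorted(ranges):
        if out and a <= out[-1][1] + timedelta(days=1):
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def build_effort(activity: pd.DataFrame, occasions: Sequence[Occasion],
                 camera_ids: Sequence[str] | None = None) -> EffortMatrix:
    """Tally the fraction of each occasion each camera was filming.

    Activity ranges are inclusive dates; overlapping ranges for a camera
    are merged with a warning.  Cameras absent from the log get zero
    effort throughout.
    """
    if camera_ids is None:
        camera_ids = sorted(activity["camera_id"].unique())
    camera_ids = list(camera_ids)
    e = np.zeros((len(camera_ids), len(occasions)))
    by_cam = {cid: [] for cid in camera_ids}
    for row in activity.itertuples(index=False):
        if row.camera_id in by_cam:
            by_cam[row.camera_id].append((row.active_from, row.active_to))
    for k, cid in enumerate(camera_ids):
        ranges = sorted(by_cam[cid])
        if any(a2 <= b1 for (_, b1), (a2, _) in zip(ranges, ranges[1:])):
            warnings.warn(f"camera {cid}: overlapping activity ranges merged")
        merged = _merge_ranges(ranges)
        for s, occ in enumerate(occasions):
            active = 0
            for a, b in merged:
                lo = max(a, occ.start)
                hi = min(b, occ.end - timedelta(days=1))  # inclusive end
                if lo <= hi:
                    active += (hi - lo).days + 1
            e[k, s] = active / occ.days
    return EffortMatrix(camera_ids=camera_ids, occasions=list(occasions), e=np.clip(e, 0.0, 1.0))


# ---------------------------------------------------------------------------
# capture histories
# ---------------------------------------------------------------------------

def _dominant(values: list[str], default: str) -> str:
    vals = [v for v in values if v and v != "unknown"]
    if not vals:
        return default
    return pd.Series(vals).mode().iloc[0]


def build_capture_history(
    records: Sequence[DetectionRecord],
    cameras: Sequence[CameraTrap],
    occasions: Sequence[Occasion],
    effort: EffortMatrix,
    weaned_only: bool = True,
) -> CaptureHistory:
    """Collapse detection records into individual x detector x occasion counts.

    Only identified individuals enter the history; when ``weaned_only`` is
    set, detections of juveniles and infants are dropped (identification in
    the field is restricted to weaned animals, and the comparison methods
    exclude unweaned individuals too).  A detection at a camera/occasion
    with zero logged effort is a data inconsistency and raises.
    """
    cam_index = {c.camera_id: k for k, c in enumerate(cameras)}
    if effort.camera_ids != [c.camera_id for c in cameras]:
        raise ParameterError("effort matrix cameras do not match registry order")
    kept = [
        r for r in records
        if r.identified and (not weaned_only or r.age_class in WEANED_AGE_CLASSES)
    ]
    ids = sorted({r.individual_id for r in kept})
    idx = {i: j for j, i in enumerate(ids)}
    K, S = effort.e.shape
    y = np.zeros((len(ids), K, S), dtype=int)
    occ_starts = [o.start for o in occasions]
    for r in kept:
        if r.camera_id not in cam_index:
            raise ValidationError(f"detection at unknown camera {r.camera_id}")
        k = cam_index[r.camera_id]
        s = int(np.searchsorted(occ_starts, r.timestamp.date(), side="right")) - 1
        if s < 0 or not occasions[s].contains(r.timestamp):
            raise ValidationError(
                f"detection at {r.timestamp} outside the study occasions"
            )
        if effort.e[k, s] == 0:
            raise ValidationError(
                f"detection of {r.individual_id} at camera {r.camera_id} in "
                f"occasion {s} where logged effort is zero"
            )
        y[idx[r.individual_id], k, s] += 1
    by_id: dict[str, list[DetectionRecord]] = {i: [] for i in ids}
    for r in kept:
        by_id[r.individual_id].append(r)
    cov = pd.DataFrame(
        {
            "sex": [_dominant([r.sex for r in by_id[i]], "unknown") for i in ids],
            "group_hint": [_dominant([r.group_hint for r in by_id[i]], "") for i in ids],
        },
        index=pd.Index(ids, name="individual_id"),
    )
    return CaptureHistory(
        individual_ids=ids,
        cameras=list(cameras),
        occasions=list(occasions),
        effort=effort.e,
        y=y,
        covariates=cov,
    )


def parse_grid_cell(cell: str) -> tuple[int, int]:
    """Parse a grid-cell label of the form ``"<row>_<col>"``."""
    try:
        r, c = cell.split("_")
        return int(r), int(c)
    except Exception as exc:
        raise ParameterError(f"grid_cell {cell!r} is not of the form 'row_col'") from exc


def half_grid_subset(history: CaptureHistory, parity: int = 0) -> CaptureHistory:
    """Retain every second camera in a checkerboard pattern over grid cells.

    Cameras whose grid cell has (row + col) % 2 == ``parity`` are kept;
    individuals left with no detections are dropped.  Mirrors the
    sensitivity analysis of halving the camera array.
    """
    if parity not in (0, 1):
        raise ParameterError("parity must be 0 or 1")
    keep_k = []
    for k, cam in enumerate(history.cameras):
        if not cam.grid_cell:
            raise ParameterError(f"camera {cam.camera_id} has no grid_cell assignment")
        r, c = parse_grid_cell(cam.grid_cell)
        if (r + c) % 2 == parity:
            keep_k.append(k)
    y = history.y[:, keep_k, :]
    keep_i = np.flatnonzero(y.sum(axis=(1, 2)) > 0)
    ids = [history.individual_ids[i] for i in keep_i]
    return CaptureHistory(
        individual_ids=ids,
        cameras=[history.cameras[k] for k in keep_k],
        occasions=history.occasions,
        effort=history.effort[keep_k, :],
        y=y[keep_i],
        covariates=history.covariates.loc[ids],
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def identification_rate(n_identified: int, n_visits: int) -> float:
    """Identified fraction of camera visits, as a rounded percentage."""
    if n_visits <= 0:
        raise ParameterError("n_visits must be positive")
    return round(100.0 * n_identified / n_visits)


def identification_summary(records: Sequence[DetectionRecord]) -> dict:
    """Visit counts, identified counts and the identification rate (%)."""
    n_visits = len(records)
    n_id = sum(r.identified for r in records)
    return {
        "n_visits": n_visits,
        "n_identified": n_id,
        "rate_percent": identification_rate(n_id, n_visits) if n_visits else float("nan"),
    }
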