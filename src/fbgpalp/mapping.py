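"""Stiffness heat-map reconstruction from scattered palpation points.

Normalized stiffness scores live at the press coordinates of a session;
this module interpolates them onto a regular grid (piecewise-linear on the
Delaunay triangulation inside the convex hull — a linear interpolant never
overshoots, so scores stay within the session's [0, 1] band — with
nearest-neighbor extrapolation outside), locates stiff regions by
thresholding, and renders matrix/PNG outputs (red = stiff, blue = soft).

Coordinates are continuous, in mm, origin at the region-of-interest (ROI)
lower-left corner, x right / y up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.interpolate import griddata

from .stiffness import StiffnessRecord

__all__ = [
    "PalpationPoint",
    "PalpationSession",
    "StiffnessMap",
    "RegionSummary",
    "CollinearPointsError",
    "DuplicatePointError",
    "interpolate_map",
    "interpolate_line",
    "detect_stiff_region",
    "render_map",
    "read_manifest",
    "write_manifest",
]

DEFAULT_MAP_SHAPE = (50, 50)


class CollinearPointsError(ValueError):
    """All press points lie on one line: 2D contouring is refused."""


class DuplicatePointError(ValueError):
    """Duplicate press coordinates carry conflicting stiffness values."""


@dataclass(frozen=True)
class PalpationPoint:
    """One press location of a session manifest."""

    point_id: str
    x_rel: float
    y_rel: float
    contact_spectrum: str
    pressed_spectrum: str
    order: int = 0


@dataclass
class PalpationSession:
    """Ordered press points over a rectangular region of interest (mm)."""

    session_id: str
    roi: tuple[float, float]
    points: list[PalpationPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.points) < 1:
            raise ValueError("a session needs at least one point")
        ids = [p.point_id for p in self.points]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate point ids in session {self.session_id}")
        w, h = self.roi
        for p in self.points:
            if not (0 <= p.x_rel <= w and 0 <= p.y_rel <= h):
                raise ValueError(
                    f"point {p.point_id} at ({p.x_rel}, {p.y_rel}) outside "
                    f"ROI {w} x {h} mm"
                )


def write_manifest(session: PalpationSession, path) -> None:
    payload = {
        "session_id": session.session_id,
        "roi_mm": list(session.roi),
        "points": [
            {
                "point_id": p.point_id,
                "x_rel": p.x_rel,
                "y_rel": p.y_rel,
                "contact_spectrum": p.contact_spectrum,
                "pressed_spectrum": p.pressed_spectrum,
                "order": p.order,
            }
            for p in session.points
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def read_manifest(path) -> PalpationSession:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    try:
        points = [
            PalpationPoint(
                point_id=str(p["point_id"]),
                x_rel=float(p["x_rel"]),
                y_rel=float(p["y_rel"]),
                contact_spectrum=str(p["contact_spectrum"]),
                pressed_spectrum=str(p["pressed_spectrum"]),
                order=int(p.get("order", i)),
            )
            for i, p in enumerate(payload["points"])
        ]
        return PalpationSession(
            session_id=str(payload["session_id"]),
            roi=tuple(float(v) for v in payload["roi_mm"]),
            points=points,
        )
    except KeyError as exc:
        raise ValueError(f"{path}: manifest missing field {exc}") from None


@dataclass
class StiffnessMap:
    """Interpolated stiffness surface on a regular grid.

    ``values[i, j]`` is the stiffness at ``(grid_x[j], grid_y[i])`` (row =
    y, column = x, matching image conventions).
    """

    grid_x: np.ndarray
    grid_y: np.ndarray
    values: np.ndarray
    points: list[StiffnessRecord]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.grid_y), len(self.grid_x)):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({len(self.grid_y)}, {len(self.grid_x)})"
            )

    def sample(self, x: float | np.ndarray, y: float | np.ndarray) -> np.ndarray:
        """Evaluate the interpolant at arbitrary coordinates."""
        px, py, pv = _point_arrays(self.points)
        return _interp_scattered(px, py, pv, np.asarray(x, float), np.asarray(y, float))

    def argmax_xy(self) -> tuple[float, float]:
        """Coordinates of the maximum grid value (first on ties)."""
        i, j = np.unravel_index(int(np.argmax(self.values)), self.values.shape)
        return float(self.grid_x[j]), float(self.grid_y[i])


def _point_arrays(records: Sequence[StiffnessRecord]):
    x = np.array([r.x_rel for r in records], dtype=float)
    y = np.array([r.y_rel for r in records], dtype=float)
    v = np.array(
        [r.s_norm if r.s_norm is not None else r.S for r in records], dtype=float
    )
    return x, y, v


def _interp_scattered(px, py, pv, qx, qy):
    """Linear interpolation inside the hull, nearest-neighbor outside."""
    pts = np.column_stack([px, py])
    q = np.column_stack([np.ravel(qx), np.ravel(qy)])
    if len(pts) < 3:
        out = griddata(pts, pv, q, method="nearest")
    else:
        out = griddata(pts, pv, q, method="linear")
        hole = np.isnan(out)
        if hole.any():
            out[hole] = griddata(pts, pv, q[hole], method="nearest")
    return out.reshape(np.shape(qx))


def _check_duplicates(px, py, pv) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    seen: dict[tuple[float, float], float] = {}
    keep = []
    for i, (x, y, v) in enumerate(zip(px, py, pv)):
        key = (float(x), float(y))
        if key in seen:
            if not np.isclose(seen[key], v, rtol=0, atol=1e-12):
                raise DuplicatePointError(
                    f"duplicate coordinates {key} with conflicting values "
                    f"{seen[key]} and {v}"
                )
            continue
        seen[key] = float(v)
        keep.append(i)
    idx = np.asarray(keep, dtype=int)
    return px[idx], py[idx], pv[idx]


def interpolate_map(
    records: Sequence[StiffnessRecord],
    roi: Optional[tuple[float, float]] = None,
    shape: tuple[int, int] = DEFAULT_MAP_SHAPE,
    resolution_mm: Optional[float] = None,
) -> StiffnessMap:
    """Interpolate per-point stiffness onto a regular output grid.

    The grid spans the ROI when given, else the bounding box of the points;
    ``resolution_mm`` (grid spacing) overrides ``shape`` (default 50 x 50).
    Three or more non-collinear points give the piecewise-linear surface;
    one or two points fall back to nearest-neighbor.  Three or more points
    that are all collinear refuse 2D contouring (use
    :func:`interpolate_line` for a profile along the line).
    """
    if len(records) < 1:
        raise ValueError("no records to interpolate")
    px, py, pv = _point_arrays(records)
    px, py, pv = _check_duplicates(px, py, pv)

    if len(px) >= 3:
        coords = np.column_stack([px, py])
        spread = coords - coords.mean(axis=0)
        if np.linalg.matrix_rank(spread, tol=1e-9 * max(1.0, np.abs(spread).max())) < 2:
            raise CollinearPointsError(
                "press points are collinear: a 2D contour map is undefined; "
                "interpolate along the line instead (interpolate_line)"
            )

    if roi is not None:
        x_lo, x_hi = 0.0, float(roi[0])
        y_lo, y_hi = 0.0, float(roi[1])
    else:
        x_lo, x_hi = float(px.min()), float(px.max())
        y_lo, y_hi = float(py.min()), float(py.max())
        if x_hi == x_lo:
            x_hi = x_lo + 1.0
        if y_hi == y_lo:
            y_hi = y_lo + 1.0
    if resolution_mm is not None:
        gx = np.arange(x_lo, x_hi + resolution_mm / 2, resolution_mm)
        gy = np.arange(y_lo, y_hi + resolution_mm / 2, resolution_mm)
    else:
        gx = np.linspace(x_lo, x_hi, shape[1])
        gy = np.linspace(y_lo, y_hi, shape[0])
    qx, qy = np.meshgrid(gx, gy)
    values = _interp_scattered(px, py, pv, qx, qy)
    return StiffnessMap(grid_x=gx, grid_y=gy, values=values, points=list(records))


def interpolate_line(
    records: Sequence[StiffnessRecord], n: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """1D linear interpolation of stiffness along a collinear point set.

    Returns ``(t, values)`` where ``t`` is the arc-length coordinate (mm)
    along the line through the points.
    """
    px, py, pv = _point_arrays(records)
    px, py, pv = _check_duplicates(px, py, pv)
    if len(px) < 2:
        raise ValueError("need >= 2 points for a line profile")
    coords = np.column_stack([px, py])
    center = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - center)
    direction = vt[0]
    t = (coords - center) @ direction
    order = np.argsort(t)
    t_sorted, v_sorted = t[order], pv[order]
    tq = np.linspace(t_sorted[0], t_sorted[-1], n)
    return tq, np.interp(tq, t_sorted, v_sorted)


@dataclass(frozen=True)
class RegionSummary:
    """One connected stiff region of a thresholded map."""

    centroid_xy: tuple[float, float]
    bbox_xy: tuple[float, float, float, float]  # x_lo, y_lo, x_hi, y_hi
    area_fraction: float


def detect_stiff_region(
    stiffness_map: StiffnessMap, threshold: float = 0.5
) -> list[RegionSummary]:
    """Connected regions with value >= threshold * max, largest first.

    Returns an empty list when no grid cell clears the threshold (e.g.
    threshold > 1 on a normalized map).
    """
    values = stiffness_map.values
    if values.size == 0 or not np.any(np.isfinite(values)):
        raise ValueError("degenerate map: no finite values")
    cutoff = threshold * float(np.nanmax(values))
    mask = values >= cutoff
    if not mask.any():
        return []
    labels, n_regions = ndimage.label(mask)
    gx, gy = stiffness_map.grid_x, stiffness_map.grid_y
    out = []
    for lab in range(1, n_regions + 1):
        rows, cols = np.nonzero(labels == lab)
        cx = float(gx[cols].mean())
        cy = float(gy[rows].mean())
        bbox = (float(gx[cols].min()), float(gy[rows].min()),
                float(gx[cols].max()), float(gy[rows].max()))
        out.append(RegionSummary(
            centroid_xy=(cx, cy),
            bbox_xy=bbox,
            area_fraction=float(rows.size / values.size),
        ))
    out.sort(key=lambda r: r.area_fraction, reverse=True)
    return out


def render_map(
    stiffness_map: StiffnessMap,
    out_prefix,
    cmap: str = "RdYlBu_r",
    show_points: bool = True,
) -> tuple[Path, Path]:
    """Write the map as ``<prefix>_matrix.csv`` and ``<prefix>.png``.

    The CSV stores grid y-coordinates as the index and x-coordinates as
    columns, so the matrix round-trips exactly; the PNG uses a red-high /
    blue-low colormap matching the published heat-map convention.
    """
    if stiffness_map.values.size == 0:
        raise ValueError("empty map: nothing to render")
    import pandas as pd

    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = prefix.with_name(prefix.name + "_matrix.csv")
    png_path = prefix.with_name(prefix.name + ".png")

    df = pd.DataFrame(stiffness_map.values,
                      index=stiffness_map.grid_y, columns=stiffness_map.grid_x)
    df.to_csv(csv_path, float_format="%.12g")

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.2))
    mesh = ax.pcolormesh(stiffness_map.grid_x, stiffness_map.grid_y,
                         stiffness_map.values, cmap=cmap, shading="nearest")
    if show_points and stiffness_map.points:
        px, py, _ = _point_arrays(stiffness_map.points)
        ax.plot(px, py, "k.", ms=4)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_aspect("equal")
    fig.colorbar(mesh, ax=ax, label="relative stiffness")
    fig.tight_layout()
    fig.savefig(png_path, dpi=130)
    plt.close(fig)
    return csv_path, png_path
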