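"""Relative-stiffness statistic and probe-head calibration fits.

For each palpation point the absolute per-channel Bragg shifts are summed,

    S = |dl_1| + |dl_2| + |dl_3| + |dl_4|   [pm],

a non-vectorial first approximation of tissue stiffness under a constant
~2 mm press.  Within one session the values are min-max normalized so the
stiffest point maps to 1 and the softest to 0.  The module also fits the
probe's linear calibration relations (mean shift vs. indentation depth and
vs. Shore A target hardness) by ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .peaks import ShiftVector

__all__ = [
    "StiffnessRecord",
    "CalibrationCurve",
    "DegenerateSessionWarning",
    "summed_shift",
    "normalize_session",
    "fit_calibration",
    "make_record",
    "records_to_table",
    "write_stiffness_table",
    "read_stiffness_table",
]


class DegenerateSessionWarning(UserWarning):
    """All points in a session have equal S: no stiffness contrast."""


@dataclass(frozen=True)
class StiffnessRecord:
    """Per-point stiffness measurement within one palpation session."""

    point_id: str
    x_rel: float
    y_rel: float
    shifts: ShiftVector
    S: float
    s_norm: Optional[float] = None


def summed_shift(shifts: ShiftVector) -> float:
    """Sum of absolute per-channel Bragg shifts, in pm (S >= 0)."""
    values = shifts.as_array()
    if not np.all(np.isfinite(values)):
        raise ValueError(f"non-finite shifts: {values}")
    return float(np.sum(np.abs(values)))


def make_record(point_id: str, x_rel: float, y_rel: float,
                shifts: ShiftVector) -> StiffnessRecord:
    """Build a stiffness record with its summed statistic (s_norm unset)."""
    return StiffnessRecord(point_id=point_id, x_rel=x_rel, y_rel=y_rel,
                           shifts=shifts, S=summed_shift(shifts))


def normalize_session(records: Sequence[StiffnessRecord]) -> list[StiffnessRecord]:
    """Min-max normalize S across one session: stiffest -> 1, softest -> 0.

    Returns new records with ``s_norm = (S - S_min) / (S_max - S_min)``;
    the input order is irrelevant to the values.  A session without any
    contrast (all S equal) maps every point to 0.0 — uniformly "softest" is
    safer to report than NaN — and emits :class:`DegenerateSessionWarning`.
    Normalization scope is one session (one organ scan); scores are not
    comparable across sessions.
    """
    if len(records) < 2:
        raise ValueError(f"need >= 2 records to normalize, got {len(records)}")
    s = np.array([r.S for r in records], dtype=float)
    s_min, s_max = float(s.min()), float(s.max())
    if s_max == s_min:
        warnings.warn(
            "degenerate session: all summed shifts equal "
            f"({s_min} pm); assigning s_norm = 0 everywhere",
            DegenerateSessionWarning,
            stacklevel=2,
        )
        return [replace(r, s_norm=0.0) for r in records]
    return [
        replace(r, s_norm=float((r.S - s_min) / (s_max - s_min)))
        for r in records
    ]


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear calibration of mean Bragg shift against a probe stimulus.

    ``kind`` distinguishes the shift-vs-indentation-depth relation from the
    shift-vs-Shore-A-hardness relation.  ``support`` is the stimulus range
    covered by the calibration targets; downstream users should flag
    extrapolation outside it.
    """

    kind: str
    slope: float
    intercept: float
    r2: float
    support: tuple[float, float]

    def predict(self, x: float | np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def in_support(self, x: float) -> bool:
        return self.support[0] <= x <= self.support[1]


def fit_calibration(
    x: Sequence[float],
    y: Sequence[float],
    kind: str = "indentation-response",
) -> CalibrationCurve:
    """Ordinary least-squares line through calibration points.

    ``x`` is indentation depth (mm) or Shore A hardness; ``y`` is the mean
    Bragg shift (pm).  Requires >= 3 distinct-x points; the probe responds
    linearly over its working range, so no weighting is applied.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have the same length")
    if xa.size < 3:
        raise ValueError(f"need >= 3 calibration points, got {xa.size}")
    if np.unique(xa).size < 2:
        raise ValueError("calibration x values are constant")
    res = stats.linregress(xa, ya)
    return CalibrationCurve(
        kind=kind,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        support=(float(xa.min()), float(xa.max())),
    )


# ---------------------------------------------------------------------------
# Stiffness table I/O
# ---------------------------------------------------------------------------

def records_to_table(records: Sequence[StiffnessRecord]) -> pd.DataFrame:
    """Tabulate records as point_id,x_rel,y_rel,d1_pm..d4_pm,S_pm,s_norm."""
    rows = []
    for r in records:
        row = {"point_id": r.point_id, "x_rel": r.x_rel, "y_rel": r.y_rel}
        for cid, shift in zip(r.shifts.channel_ids, r.shifts.shifts_pm):
            row[f"d{cid}_pm"] = shift
        row["S_pm"] = r.S
        row["s_norm"] = np.nan if r.s_norm is None else r.s_norm
        rows.append(row)
    return pd.DataFrame(rows)


def write_stiffness_table(records: Sequence[StiffnessRecord], path) -> None:
    records_to_table(records).to_csv(path, index=False, float_format="%.10g")


def read_stiffness_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"point_id", "x_rel", "y_rel", "S_pm", "s_norm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
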