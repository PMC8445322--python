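"""Decay-curve readouts: normalization, slope A, remaining fraction.

The primary readout of the live-cell assay is the median GFP intensity in
endolysosomes (EL), corrected by subtracting the cytosolic median (diffuse
cleaved/background GFP) and normalized to the first frame. After a ~90 min
equilibration phase the decay is near-linear until ~360 min; the fitted
slope over that window ("slope A", per hour) and the remaining fraction
R(t) at fixed times are the per-movie summaries that conditions are
compared on, usually relative to a same-experiment control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DomainError, InsufficientDataError, NormalizationError

__all__ = [
    "DecayCurve",
    "ConditionSummary",
    "background_subtract_normalize",
    "fit_slope_A",
    "remaining_fraction",
    "summarize_replicates",
    "relative_to_control",
]

#: Default near-linear fit window (minutes): after equilibration, before plateau.
DEFAULT_FIT_WINDOW = (90.0, 360.0)


@dataclass
class DecayCurve:
    """Background-subtracted, first-frame-normalized EL intensity trace."""

    times_min: np.ndarray
    values: np.ndarray
    condition_label: str = ""
    slope_A: float | None = None  # per hour; set by fit_slope_A

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_min.shape != self.values.shape or self.times_min.ndim != 1:
            raise DomainError("times_min and values must be equal-length 1-D arrays")
        if np.any(np.diff(self.times_min) <= 0):
            raise DomainError("times must be strictly increasing")
        if abs(self.values[0] - 1.0) > 1e-6:
            raise NormalizationError(
                f"curve must be normalized to its first frame; values[0]={self.values[0]!r}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times_min,
                "value": self.values,
                "condition": self.condition_label,
            }
        )


def background_subtract_normalize(
    el_median: Sequence[float],
    cyto_median: Sequence[float],
    times_min: Sequence[float],
    condition_label: str = "",
) -> DecayCurve:
    """Subtract the cytosolic GFP background from the EL median and normalize.

    ``values[i] = (el[i] - cyto[i]) / (el[0] - cyto[0])``; the first frame is
    exactly 1. Negative corrected values (possible under noise) are kept, not
    clipped, to avoid bias; a warning notes them.
    """
    el = np.asarray(el_median, dtype=float)
    cy = np.asarray(cyto_median, dtype=float)
    if el.shape != cy.shape:
        raise DomainError("EL and cytosol series must have equal length")
    corrected = el - cy
    if not corrected[0] > 0:
        raise NormalizationError(
            f"first-frame corrected intensity must be > 0, got {corrected[0]!r}"
        )
    values = corrected / corrected[0]
    values[0] = 1.0  # exact by construction
    if np.any(corrected < 0):
        warnings.warn(
            f"{int(np.sum(corrected < 0))} corrected intensities are negative "
            "(noise below background); kept unclipped",
            stacklevel=2,
        )
    return DecayCurve(np.asarray(times_min, dtype=float), values, condition_label)


def fit_slope_A(
    curve: DecayCurve, window: tuple[float, float] = DEFAULT_FIT_WINDOW
) -> float:
    """Ordinary least-squares slope (per hour) of the curve inside ``window`` (minutes).

    Negative for decaying curves. The result is also stored on
    ``curve.slope_A``.
    """
    lo, hi = window
    mask = (curve.times_min >= lo) & (curve.times_min <= hi)
    if int(mask.sum()) < 3:
        raise InsufficientDataError(
            f"need >= 3 points in fit window [{lo}, {hi}] min, got {int(mask.sum())}"
        )
    t_h = curve.times_min[mask] / 60.0
    y = curve.values[mask]
    slope = float(np.polyfit(t_h, y, 1)[0])
    curve.slope_A = slope
    return slope


def remaining_fraction(curve: DecayCurve, t_query_min: float) -> float:
    """Normalized value at ``t_query_min``, linearly interpolated between frames."""
    t = curve.times_min
    if not t[0] <= t_query_min <= t[-1]:
        raise DomainError(
            f"t={t_query_min} min outside sampled range [{t[0]}, {t[-1]}]; "
            "extrapolation not supported"
        )
    return float(np.interp(t_query_min, t, curve.values))


@dataclass
class ConditionSummary:
    """Replicate-aggregated readouts for one experimental condition."""

    condition: str
    slope_A: float  # per hour, mean across replicates
    remaining_6h: float
    remaining_9h: float | None
    n_replicates: int
    sd_slope: float
    sd_remaining_6h: float
    slope_rel_control: float | None = None


def summarize_replicates(
    curves: Iterable[DecayCurve],
    condition: str,
    window: tuple[float, float] = DEFAULT_FIT_WINDOW,
) -> ConditionSummary:
    """Mean +/- SD of slope A and remaining fractions across replicate movies."""
    curves = list(curves)
    if not curves:
        raise DataError("no replicate curves supplied")
    slopes = np.array([fit_slope_A(c, window) for c in curves])
    r6 = np.array([remaining_fraction(c, min(360.0, c.times_min[-1])) for c in curves])
    r9 = [
        remaining_fraction(c, 540.0) if c.times_min[-1] >= 540.0 else np.nan
        for c in curves
    ]
    r9_arr = np.array(r9)
    have_9h = np.isfinite(r9_arr).any()
    ddof = 1 if len(curves) > 1 else 0
    return ConditionSummary(
        condition=condition,
        slope_A=float(slopes.mean()),
        remaining_6h=float(r6.mean()),
        remaining_9h=float(np.nanmean(r9_arr)) if have_9h else None,
        n_replicates=len(curves),
        sd_slope=float(slopes.std(ddof=ddof)),
        sd_remaining_6h=float(r6.std(ddof=ddof)),
    )


def relative_to_control(
    summaries: Sequence[ConditionSummary], control_label: str
) -> list[ConditionSummary]:
    """Fill ``slope_rel_control`` = slope_A / control slope_A; control maps to 1."""
    by_label = {s.condition: s for s in summaries}
    if control_label not in by_label:
        raise DataError(f"control condition {control_label!r} not present")
    ctrl = by_label[control_label].slope_A
    if abs(ctrl) < 1e-12:  # numerically flat control
        raise NormalizationError("control slope is zero; cannot normalize")
    for s in summaries:
        s.slope_rel_control = s.slope_A / ctrl
    return list(summaries)


def summaries_to_frame(summaries: Sequence[ConditionSummary]) -> pd.DataFrame:
    """Tabulate summaries with the documented column order."""
    return pd.DataFrame(
        {
            "condition": [s.condition for s in summaries],
            "slope_A_per_h": [s.slope_A for s in summaries],
            "slope_rel_control": [s.slope_rel_control for s in summaries],
            "remaining_6h": [s.remaining_6h for s in summaries],
            "remaining_9h": [s.remaining_9h for s in summaries],
            "n": [s.n_replicates for s in summaries],
            "sd": [s.sd_slope for s in summaries],
        }
    )
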