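"""Per-frame compartment segmentation of three-channel time-lapses.

Re-implementation of the batch quantification macro: each frame is split
into four mutually exclusive compartments —

* **EL** (endolysosomes) by thresholding the far-red lysosome probe channel,
* **N** (nuclei) by thresholding the red nuclear marker channel,
* **PM** (plasma membrane) by thresholding the GFP channel in the region
  outside N and EL,
* **CYTO** (cytosol), the remaining above-background cell area.

Thresholds for EL and PM are set on the first and last frame and linearly
interpolated for the frames between, tolerating slow drift in staining
intensity. Overlaps are resolved by the fixed precedence EL > N > PM >
CYTO. Thresholds are closed (``>=``) comparisons; pixels are (row, col),
0-based.

Thresholds may be given explicitly (reproducible batch mode) or derived
automatically with Otsu's method on the first and last frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .errors import DataError, DomainError

__all__ = [
    "ThresholdSpec",
    "CompartmentMasks",
    "interpolate_threshold",
    "auto_thresholds",
    "segment_compartments",
    "segment_stack",
    "measure_intensities",
]

COMPARTMENTS = ("EL", "N", "PM", "CYTO")
CHANNELS = ("gfp", "red", "lyso")


def interpolate_threshold(
    t_first: float, t_last: float, frame_idx: int, n_frames: int
) -> float:
    """Linear threshold interpolation between first- and last-frame values.

    ``t_first + (t_last - t_first) * frame_idx / (n_frames - 1)``;
    endpoints are exact.
    """
    if n_frames < 2:
        raise DomainError(f"n_frames must be >= 2, got {n_frames}")
    if not 0 <= frame_idx < n_frames:
        raise DomainError(f"frame_idx {frame_idx} outside [0, {n_frames})")
    if t_first < 0 or t_last < 0:
        raise DomainError("thresholds must be >= 0")
    if frame_idx == 0:
        return float(t_first)
    if frame_idx == n_frames - 1:
        return float(t_last)
    return float(t_first + (t_last - t_first) * frame_idx / (n_frames - 1))


@dataclass(frozen=True)
class ThresholdSpec:
    """First/last-frame thresholds per compartment channel.

    EL comes from the lysosome channel, N from the red channel (a single
    value suffices for the bright, stable nuclear marker), PM from the GFP
    channel. Interpolation between endpoints is linear.
    """

    el_first: float
    el_last: float
    nuc: float
    pm_first: float
    pm_last: float

    def __post_init__(self) -> None:
        for name in ("el_first", "el_last", "nuc", "pm_first", "pm_last"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise DomainError(f"threshold {name} must be finite and >= 0, got {v}")

    def el_at(self, frame_idx: int, n_frames: int) -> float:
        return interpolate_threshold(self.el_first, self.el_last, frame_idx, n_frames)

    def pm_at(self, frame_idx: int, n_frames: int) -> float:
        return interpolate_threshold(self.pm_first, self.pm_last, frame_idx, n_frames)


def _otsu_or_max(img: np.ndarray) -> float:
    flat = np.asarray(img, dtype=float)
    if flat.max() == flat.min():  # degenerate frame: threshold above everything
        return float(flat.max()) + 1.0
    return float(threshold_otsu(flat))


def auto_thresholds(stack: np.ndarray, cell_frac: float = 0.05) -> ThresholdSpec:
    """Otsu thresholds on the first and last frame of a (T, 3, H, W) stack.

    The PM threshold is computed on the GFP channel restricted to in-cell
    pixels (above ``cell_frac`` of the frame maximum) outside the
    first-pass EL and N masks, mirroring the interactive procedure of
    setting the PM threshold "outside nuclei and EL". If that region is
    flat (surface pool fully cleaved), the PM mask degrades to empty
    rather than swallowing the cytosol.
    """
    stack = _check_stack(stack)
    n = stack.shape[0]
    el_first = _otsu_or_max(stack[0, 2])
    el_last = _otsu_or_max(stack[-1, 2])
    nuc = _otsu_or_max(stack[0, 1])
    specs = []
    for idx, el_thr in ((0, el_first), (n - 1, el_last)):
        gfp = np.asarray(stack[idx, 0], dtype=float)
        outside = (
            (np.asarray(stack[idx, 2], dtype=float) < el_thr)
            & (np.asarray(stack[idx, 1], dtype=float) < nuc)
            & (gfp >= cell_frac * gfp.max())
        )
        region = gfp[outside]
        specs.append(_otsu_or_max(region) if region.size else gfp.max() + 1.0)
    return ThresholdSpec(
        el_first=el_first, el_last=el_last, nuc=nuc,
        pm_first=specs[0], pm_last=specs[1],
    )


@dataclass
class CompartmentMasks:
    """Mutually exclusive boolean masks for one frame."""

    frame_idx: int
    el: np.ndarray
    nuc: np.ndarray
    pm: np.ndarray
    cyto: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.el, self.nuc, self.pm, self.cyto)}
        if len(shapes) != 1:
            raise DomainError("masks must share one shape")
        overlap = (
            self.el.astype(int) + self.nuc.astype(int)
            + self.pm.astype(int) + self.cyto.astype(int)
        )
        if overlap.max(initial=0) > 1:
            raise DataError(f"masks overlap on frame {self.frame_idx}")

    def __getitem__(self, name: str) -> np.ndarray:
        return {"EL": self.el, "N": self.nuc, "PM": self.pm, "CYTO": self.cyto}[name]


def segment_compartments(
    gfp: np.ndarray,
    red: np.ndarray,
    lyso: np.ndarray,
    spec: ThresholdSpec,
    frame_idx: int,
    n_frames: int,
    cell_frac: float = 0.05,
    min_object_px: int = 0,
) -> CompartmentMasks:
    """Segment one frame into EL / N / PM / CYTO masks.

    ``cell_frac`` defines the above-background cell area used for CYTO: GFP
    pixels above ``cell_frac`` times the frame's GFP maximum. No
    morphological clean-up is applied unless ``min_object_px`` > 0 (EL
    objects smaller than that are dropped; the use is logged).
    """
    gfp = np.asarray(gfp, dtype=float)
    red = np.asarray(red, dtype=float)
    lyso = np.asarray(lyso, dtype=float)
    if not gfp.shape == red.shape == lyso.shape:
        raise DomainError("channel frames must share one shape")

    el = lyso >= spec.el_at(frame_idx, n_frames)
    if min_object_px > 0:
        el = remove_small_objects(el, min_size=min_object_px)
        warnings.warn(
            f"minimum EL object size {min_object_px} px applied on frame {frame_idx}",
            stacklevel=2,
        )
    nuc = (red >= spec.nuc) & ~el
    pm = (gfp >= spec.pm_at(frame_idx, n_frames)) & ~el & ~nuc
    cell = gfp >= cell_frac * gfp.max() if gfp.max() > 0 else np.zeros_like(el)
    cyto = cell & ~el & ~nuc & ~pm
    if not el.any():
        warnings.warn(f"empty EL mask on frame {frame_idx}", stacklevel=2)
    return CompartmentMasks(frame_idx=frame_idx, el=el, nuc=nuc, pm=pm, cyto=cyto)


def _check_stack(stack: np.ndarray) -> np.ndarray:
    stack = np.asarray(stack)
    if stack.ndim != 4 or stack.shape[1] != 3:
        raise DataError(
            f"expected a (T, 3, H, W) stack (gfp, red, lyso), got shape {stack.shape}"
        )
    if stack.shape[0] < 2:
        raise DataError("need at least 2 frames")
    return stack


def segment_stack(
    stack: np.ndarray,
    spec: ThresholdSpec | None = None,
    cell_frac: float = 0.05,
    min_object_px: int = 0,
) -> list[CompartmentMasks]:
    """Segment every frame of a (T, 3, H, W) stack; Otsu auto-thresholds if no spec."""
    stack = _check_stack(stack)
    if spec is None:
        spec = auto_thresholds(stack)
    n = stack.shape[0]
    return [
        segment_compartments(
            stack[i, 0], stack[i, 1], stack[i, 2], spec, i, n,
            cell_frac=cell_frac, min_object_px=min_object_px,
        )
        for i in range(n)
    ]


def measure_intensities(
    stack: np.ndarray,
    masks: Sequence[CompartmentMasks],
    frame_interval_s: float = 180.0,
) -> pd.DataFrame:
    """Mean/median intensity per frame x compartment x channel.

    Columns: ``frame, time_min, compartment, channel, mean, median, area_px``.
    Empty masks yield a recorded row with ``area_px`` 0 and missing
    statistics (NaN) rather than an error.
    """
    stack = _check_stack(stack)
    if len(masks) != stack.shape[0]:
        raise DataError("one CompartmentMasks per frame required")
    if frame_interval_s <= 0:
        raise DomainError("frame_interval_s must be > 0")
    records = []
    for i, m in enumerate(masks):
        t_min = i * frame_interval_s / 60.0
        for comp in COMPARTMENTS:
            sel = m[comp]
            area = int(sel.sum())
            for ci, ch in enumerate(CHANNELS):
                pix = np.asarray(stack[i, ci], dtype=float)[sel]
                records.append(
                    {
                        "frame": i,
                        "time_min": t_min,
                        "compartment": comp,
                        "channel": ch,
                        "mean": float(pix.mean()) if area else np.nan,
                        "median": float(np.median(pix)) if area else np.nan,
                        "area_px": area,
                    }
                )
    return pd.DataFrame.from_records(records)


def median_trace(
    table: pd.DataFrame, compartment: str, channel: str = "gfp"
) -> tuple[np.ndarray, np.ndarray]:
    """Extract (time_min, median) for one compartment/channel from an intensity table."""
    sub = table[(table["compartment"] == compartment) & (table["channel"] == channel)]
    sub = sub.sort_values("frame")
    return sub["time_min"].to_numpy(), sub["median"].to_numpy()
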