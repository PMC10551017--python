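"""Calcium fluorescence trace preprocessing.

The pipeline applied to every ROI trace, in order:

1. ``compute_dff`` — baseline normalisation, dF/F0 with F0 the mean of the
   first 10 frames;
2. ``smooth_trace`` — six-frame running mean over frames t-2 .. t+3;
3. ``remove_background`` — zero every value below a threshold defined as the
   trace median plus a small offset (0.02-0.05 in dF/F0 units);
4. ``minmax_normalize`` — rescale to [0, 1] (max -> 1, min -> 0).

Traces that are constant after background removal carry no pairwise
information; they are flagged *degenerate*, set to all-zeros, and excluded
from downstream correlation rather than producing NaN coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .exceptions import DegenerateBaselineError, InputError

__all__ = [
    "RawTraceSet",
    "PreprocessParams",
    "ProcessedTraceSet",
    "compute_dff",
    "smooth_trace",
    "remove_background",
    "minmax_normalize",
    "preprocess",
]

HOST = "host"
IMPLANT = "implant"


@dataclass
class RawTraceSet:
    """A set of per-ROI fluorescence time series with acquisition metadata.

    Parameters
    ----------
    traces
        Mapping ROI id -> 1-D fluorescence array ``F_t`` (arbitrary units).
        All traces must share a common length ``T >= 10`` and be finite.
    frame_interval_s
        Seconds per frame (default 1.29, confocal acquisition at
        1 frame / 1.29 s).
    compartment_of
        ROI id -> compartment label, typically ``"host"`` / ``"implant"``
        (or ``"upper"`` / ``"deep"`` for layered tissue).
    centroid_of
        Optional ROI id -> (x, y) centroid, unit given by ``centroid_unit``.
    """

    traces: Dict[int, np.ndarray]
    frame_interval_s: float = 1.29
    compartment_of: Dict[int, str] = field(default_factory=dict)
    centroid_of: Optional[Dict[int, Tuple[float, float]]] = None
    centroid_unit: str = "um"

    def __post_init__(self) -> None:
        self.traces = {int(k): np.asarray(v, dtype=float) for k, v in self.traces.items()}
        if not self.traces:
            raise InputError("trace set is empty")
        lengths = {v.shape[0] for v in self.traces.values()}
        if len(lengths) != 1:
            raise InputError(f"traces have differing lengths: {sorted(lengths)}")
        (t,) = lengths
        if t < 10:
            raise InputError(f"need at least 10 frames to define F0, got {t}")
        for k, v in self.traces.items():
            if v.ndim != 1:
                raise InputError(f"ROI {k}: trace must be 1-D")
            if not np.all(np.isfinite(v)):
                raise InputError(f"ROI {k}: trace contains non-finite values")

    @property
    def roi_ids(self):
        return sorted(self.traces)

    @property
    def n_frames(self) -> int:
        return next(iter(self.traces.values())).shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Traces as a DataFrame with a ``frame`` index and ``roi<k>`` columns."""
        df = pd.DataFrame({f"roi{k}": self.traces[k] for k in self.roi_ids})
        df.index.name = "frame"
        return df


@dataclass(frozen=True)
class PreprocessParams:
    """Tunable parameters of the four-stage preprocessing.

    ``threshold_offset`` is the additive constant delta on the trace median in
    the background-removal stage; the documented range is 0.02-0.05 and the
    default 0.035 is its midpoint.  ``smooth_window = (before, after)`` gives
    the asymmetric six-frame window (2 frames before, 3 after, plus the frame
    itself).  ``subtract_threshold`` switches background removal from
    zero-below-threshold (default) to subtracting the threshold.
    """

    f0_frames: int = 10
    smooth_window: Tuple[int, int] = (2, 3)
    threshold_offset: float = 0.035
    boundary_mode: str = "truncate"
    subtract_threshold: bool = False

    def __post_init__(self) -> None:
        if self.f0_frames < 1:
            raise InputError("f0_frames must be >= 1")
        if self.threshold_offset < 0:
            raise InputError("threshold_offset must be >= 0")
        if self.boundary_mode not in ("truncate", "reflect"):
            raise InputError(f"unknown boundary_mode {self.boundary_mode!r}")
        b, a = self.smooth_window
        if b < 0 or a < 0:
            raise InputError("smooth_window counts must be >= 0")


@dataclass
class ProcessedTraceSet:
    """Preprocessed traces in [0, 1] plus the parameters that produced them."""

    traces: Dict[int, np.ndarray]
    params: PreprocessParams
    degenerate_rois: frozenset
    frame_interval_s: float = 1.29
    compartment_of: Dict[int, str] = field(default_factory=dict)
    centroid_of: Optional[Dict[int, Tuple[float, float]]] = None
    centroid_unit: str = "um"

    @property
    def roi_ids(self):
        return sorted(self.traces)

    @property
    def usable_roi_ids(self):
        """Non-degenerate ROI ids, the ones entering correlation."""
        return [k for k in self.roi_ids if k not in self.degenerate_rois]

    @property
    def n_frames(self) -> int:
        return next(iter(self.traces.values())).shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({f"roi{k}": self.traces[k] for k in self.roi_ids})
        df.index.name = "frame"
        return df


def compute_dff(trace: np.ndarray, f0_frames: int = 10) -> np.ndarray:
    """Baseline-normalise a fluorescence trace: (F_t - F0) / F0.

    F0 is the mean fluorescence over the first ``f0_frames`` frames.
    Scale-invariant: ``compute_dff(a * F) == compute_dff(F)`` for a > 0.
    """
    x = np.asarray(trace, dtype=float)
    if x.shape[0] < f0_frames:
        raise InputError(f"trace length {x.shape[0]} < f0_frames {f0_frames}")
    f0 = float(np.mean(x[:f0_frames]))
    if f0 == 0.0:
        raise DegenerateBaselineError("F0 is zero; dF/F0 undefined")
    return (x - f0) / f0


def smooth_trace(
    dff: np.ndarray,
    window: Tuple[int, int] = (2, 3),
    boundary_mode: str = "truncate",
) -> np.ndarray:
    """Running mean over an asymmetric window of ``before + 1 + after`` frames.

    The default (2, 3) is the six-frame mean of frames t-2 .. t+3.  Frames
    near the trace ends, where the full window is unavailable, are handled by
    ``boundary_mode``: ``"truncate"`` averages only the in-range frames,
    ``"reflect"`` mirror-pads the trace first.
    """
    x = np.asarray(dff, dtype=float)
    before, after = window
    width = before + 1 + after
    if x.shape[0] < width:
        raise InputError(f"trace length {x.shape[0]} < window width {width}")
    if boundary_mode == "reflect":
        padded = np.pad(x, (before, after), mode="reflect")
        return np.convolve(padded, np.ones(width), mode="valid") / width
    if boundary_mode != "truncate":
        raise InputError(f"unknown boundary_mode {boundary_mode!r}")
    t = x.shape[0]
    cs = np.concatenate(([0.0], np.cumsum(x)))
    lo = np.maximum(np.arange(t) - before, 0)
    hi = np.minimum(np.arange(t) + after, t - 1)
    return (cs[hi + 1] - cs[lo]) / (hi - lo + 1)


def remove_background(
    smoothed: np.ndarray, offset: float = 0.035, subtract: bool = False
) -> np.ndarray:
    """Zero every value below the trace median plus ``offset``.

    The threshold is theta = median(trace) + offset.  Values below theta are
    set to 0; values at or above theta are kept unchanged, preserving
    transient amplitudes.  With ``subtract=True`` the threshold is instead
    subtracted from supra-threshold values.
    """
    if offset < 0:
        raise InputError("offset must be >= 0")
    x = np.asarray(smoothed, dtype=float)
    theta = float(np.median(x)) + offset
    out = np.where(x < theta, 0.0, x - theta if subtract else x)
    return out


def minmax_normalize(series: np.ndarray) -> Tuple[np.ndarray, bool]:
    """Rescale to [0, 1]: max -> 1, min -> 0.

    Returns ``(normalised, degenerate)``.  A constant series has no dynamic
    range; it is returned as all-zeros with ``degenerate=True`` so callers can
    exclude it from correlation.
    """
    x = np.asarray(series, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return np.zeros_like(x), True
    return (x - lo) / (hi - lo), False


def preprocess(raw: RawTraceSet, params: Optional[PreprocessParams] = None) -> ProcessedTraceSet:
    """Apply the full four-stage pipeline to every ROI of a raw trace set."""
    if params is None:
        params = PreprocessParams()
    out: Dict[int, np.ndarray] = {}
    degenerate = set()
    for roi in raw.roi_ids:
        try:
            dff = compute_dff(raw.traces[roi], params.f0_frames)
            sm = smooth_trace(dff, params.smooth_window, params.boundary_mode)
            bg = remove_background(sm, params.threshold_offset, params.subtract_threshold)
        except InputError as exc:
            raise InputError(f"ROI {roi}: {exc}") from exc
        norm, degen = minmax_normalize(bg)
        out[roi] = norm
        if degen:
            degenerate.add(roi)
    return ProcessedTraceSet(
        traces=out,
        params=params,
        degenerate_rois=frozenset(degenerate),
        frame_interval_s=raw.frame_interval_s,
        compartment_of=dict(raw.compartment_of),
        centroid_of=None if raw.centroid_of is None else dict(raw.centroid_of),
        centroid_unit=raw.centroid_unit,
    )
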