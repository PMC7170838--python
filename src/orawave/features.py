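"""Applanation-peak detection, the Monot1-2 statistic, and waveform descriptors.

The ORA applanation signal has two peaks (corneal inward and outward
flattening) separated by a trough.  Between the peaks the ideal signal
descends monotonically to the trough and then ascends monotonically to the
second peak.  **Monot1-2** quantifies departure from that profile: it is the
total retrogressive (anti-monotone) vertical movement between the peaks,

    monot12 = sum_{i=p1}^{trough-1} max(0, y[i+1] - y[i])
            + sum_{i=trough}^{p2-1}  max(0, y[i] - y[i+1]),

i.e. the summed rises during the expected descent plus the summed falls
during the expected ascent.  It is >= 0, translation invariant, positively
homogeneous of degree 1 in amplitude, and 0 iff the inter-peak segment is a
monotone V.

The classical waveform descriptors (h1, p1area, uslope1, Aindex, ...) are
computed by the vendor's unpublished algorithms; this module provides
documented surrogates that carry the same names and qualitative meaning but
make no claim of numerical agreement with the vendor software.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .errors import AssemblyError, FeatureError, PeakDetectionError
from .io import EyeCovariates

__all__ = [
    "PeakPair", "detect_applanation_peaks", "monot12",
    "surrogate_descriptors", "compute_features", "assemble_design_matrix",
    "DESCRIPTOR_NAMES", "DESIGN_COVARIATES", "EXCLUDED_DESCRIPTORS",
    "DesignMatrix",
]

#: Smoothing window (samples) for peak detection and the Aplhf residual.
SMOOTH_WINDOW = 9
#: Baseline = median of this many leading samples.
BASELINE_WINDOW = 50
#: Minimum separation (samples) between the two applanation peaks.
MIN_PEAK_SEPARATION = 40

#: The 37 vendor-named descriptors, in the published summary-table order.
DESCRIPTOR_NAMES: tuple[str, ...] = (
    "Aindex", "Bindex", "p1area", "p2area", "aspect1", "aspect2",
    "uslope1", "uslope2", "dslope1", "dslope2", "w1", "w2", "h1", "h2",
    "dive1", "dive2", "path1", "path2", "mslew1", "mslew2", "slew1", "slew2",
    "Aplhf", "p1area1", "p2area1", "aspect11", "aspect21", "uslope11",
    "uslope21", "dslope11", "dslope21", "w11", "w21", "h11", "h21",
    "path11", "path21",
)

#: Dropped from the regression design: exactly proportional to h1/h2.
EXCLUDED_DESCRIPTORS: tuple[str, ...] = ("h11", "h21")

#: Clinical covariates entering the design matrix, in order.
DESIGN_COVARIATES: tuple[str, ...] = ("age", "AL", "SERE", "CH", "CRF")


@dataclass(frozen=True)
class PeakPair:
    """Indices of applanation peak 1, the inter-peak trough, and peak 2."""

    p1: int
    trough: int
    p2: int

    def __post_init__(self) -> None:
        if not (0 <= self.p1 < self.trough < self.p2):
            raise ValueError(
                f"require 0 <= p1 < trough < p2, got {self.p1}, "
                f"{self.trough}, {self.p2}")


def _smooth(y: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    return uniform_filter1d(np.asarray(y, dtype=float), size=window,
                            mode="nearest")


def _parabolic_refine(sm: np.ndarray, idx: int, half: int = 7) -> int:
    """Re-localise a smoothed peak by fitting a parabola around it.

    Averages over ~2*half+1 samples, which stabilises the apex estimate
    against residual noise that survives the moving-average filter.
    """
    lo = max(0, idx - half)
    hi = min(len(sm), idx + half + 1)
    x = np.arange(lo, hi, dtype=float)
    c2, c1, _ = np.polyfit(x, sm[lo:hi], 2)
    if c2 >= 0:
        return idx
    vertex = -c1 / (2.0 * c2)
    if not (lo <= vertex <= hi - 1):
        return idx
    return int(round(vertex))


def _nearest_raw_maximum(y: np.ndarray, idx: int, radius: int = 5) -> int:
    """Nearest raw local maximum within ``radius`` of a smoothed peak index."""
    lo = max(1, idx - radius)
    hi = min(len(y) - 2, idx + radius)
    candidates = [i for i in range(lo, hi + 1)
                  if y[i] >= y[i - 1] and y[i] >= y[i + 1]]
    if not candidates:
        window = y[max(0, idx - radius):min(len(y), idx + radius + 1)]
        return max(0, idx - radius) + int(np.argmax(window))
    return min(candidates, key=lambda i: (abs(i - idx), i))


def detect_applanation_peaks(
    trace: Sequence[float],
    min_separation: int = MIN_PEAK_SEPARATION,
    smooth_window: int = SMOOTH_WINDOW,
) -> PeakPair:
    """Locate the two applanation peaks and the inter-peak trough.

    The trace is smoothed with a moving average; the two local maxima of
    highest prominence separated by at least ``min_separation`` samples are
    taken as the peaks, then each is snapped to the nearest raw local maximum
    within +/-5 samples.  The trough is the earliest minimum of the *raw*
    trace strictly between the peaks.

    Raises
    ------
    PeakDetectionError
        If fewer than two qualifying maxima exist (e.g. a monotone ramp).
    ValueError
        If the trace is shorter than the smoothing window.
    """
    y = np.asarray(trace, dtype=float)
    if y.ndim != 1 or len(y) < smooth_window:
        raise ValueError("trace must be 1-D and at least as long as the "
                         "smoothing window")
    sm = _smooth(y, smooth_window)
    peaks, props = find_peaks(sm, prominence=0.0)
    if len(peaks) < 2:
        raise PeakDetectionError(
            f"found {len(peaks)} candidate peaks; need two applanation peaks")
    order = np.argsort(props["prominences"])[::-1]
    primary = peaks[order[0]]
    partner = None
    for j in order[1:]:
        if abs(peaks[j] - primary) >= min_separation:
            partner = peaks[j]
            break
    if partner is None:
        raise PeakDetectionError(
            f"no second peak at least {min_separation} samples from the "
            f"dominant peak at {primary}")
    lo, hi = sorted((int(primary), int(partner)))
    p1 = _nearest_raw_maximum(y, _parabolic_refine(sm, lo))
    p2 = _nearest_raw_maximum(y, _parabolic_refine(sm, hi))
    if p2 - p1 < 2:
        raise PeakDetectionError("refined peaks collapsed onto each other")
    trough = p1 + 1 + int(np.argmin(y[p1 + 1:p2]))  # argmin -> earliest tie
    return PeakPair(p1, trough, p2)


def monot12(trace: Sequence[float], peaks: PeakPair,
            method: str = "increments") -> float:
    """Total retrogressive movement between the two applanation peaks.

    ``method="increments"`` (default) sums adverse vertical increments.
    ``method="arclength"`` instead sums the line-segment lengths
    ``hypot(1, dy)`` of the adverse steps — an alternative reading of
    "total length of retrogressive movement".
    """
    y = np.asarray(trace, dtype=float)
    if not (0 <= peaks.p1 < peaks.trough < peaks.p2 < len(y)):
        raise ValueError("PeakPair indices out of bounds for this trace")
    down = np.diff(y[peaks.p1:peaks.trough + 1])   # expected descent
    up = np.diff(y[peaks.trough:peaks.p2 + 1])     # expected ascent
    adverse_down = np.clip(down, 0.0, None)        # rises during descent
    adverse_up = np.clip(-up, 0.0, None)           # falls during ascent
    if method == "increments":
        return float(adverse_down.sum() + adverse_up.sum())
    if method == "arclength":
        return float(np.hypot(1.0, adverse_down[adverse_down > 0]).sum()
                     + np.hypot(1.0, adverse_up[adverse_up > 0]).sum())
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Surrogate descriptors
# ---------------------------------------------------------------------------

def _crossing(y: np.ndarray, level: float, peak: int, lo: int, hi: int,
              side: str) -> float:
    """Interpolated index where the trace crosses ``level`` on one flank.

    Walks away from ``peak`` until the trace drops below ``level``; clamps at
    the region boundary if it never does.
    """
    if side == "left":
        for i in range(peak, lo, -1):
            if y[i - 1] < level <= y[i]:
                return (i - 1) + (level - y[i - 1]) / (y[i] - y[i - 1])
        return float(lo)
    for i in range(peak, hi):
        if y[i + 1] < level <= y[i]:
            return i + (y[i] - level) / (y[i] - y[i + 1])
    return float(hi)


def _peak_metrics(y: np.ndarray, peak: int, lo: int, hi: int, baseline: float,
                  cut: float, slope_cuts: tuple[float, float]) -> Dict[str, float]:
    """Width/area/slope/path/slew/adverse-step metrics for one peak.

    ``cut`` is the height fraction defining the width/area/path level;
    ``slope_cuts`` are the two height fractions between which flank slopes
    are measured.
    """
    h = y[peak] - baseline
    level = baseline + cut * h
    xl = _crossing(y, level, peak, lo, hi, "left")
    xr = _crossing(y, level, peak, lo, hi, "right")
    width = max(xr - xl, 1.0)

    il, ir = int(np.ceil(xl)), int(np.floor(xr))
    above = np.clip(y[il:ir + 1] - level, 0.0, None)
    area = float(np.trapezoid(above)) if len(above) > 1 else 0.0
    path = int(np.sum(y[il:ir + 1] > level))

    lo_frac, hi_frac = slope_cuts
    lvl_lo = baseline + lo_frac * h
    lvl_hi = baseline + hi_frac * h
    x_lo_l = _crossing(y, lvl_lo, peak, lo, hi, "left")
    x_hi_l = _crossing(y, lvl_hi, peak, lo, hi, "left")
    x_hi_r = _crossing(y, lvl_hi, peak, lo, hi, "right")
    x_lo_r = _crossing(y, lvl_lo, peak, lo, hi, "right")
    dh = lvl_hi - lvl_lo
    uslope = dh / max(x_hi_l - x_lo_l, 0.5)
    dslope = dh / max(x_lo_r - x_hi_r, 0.5)

    # Flanks between the lower slope level and the peak.
    rise_lo = max(lo, int(np.floor(x_lo_l)))
    fall_hi = min(hi, int(np.ceil(x_lo_r)))
    rising = np.diff(y[rise_lo:peak + 1]) if peak > rise_lo else np.array([0.0])
    falling = np.diff(y[peak:fall_hi + 1]) if fall_hi > peak else np.array([0.0])
    slew = float(np.max(rising)) if len(rising) else 0.0
    seg = y[rise_lo:peak + 1]
    mslew = float(np.max(seg[3:] - seg[:-3])) if len(seg) > 3 else slew
    adverse = int(np.sum(rising < 0) + np.sum(falling > 0))

    return {"w": width, "area": area, "path": path, "uslope": uslope,
            "dslope": dslope, "slew": slew, "mslew": mslew, "adverse": adverse,
            "aspect": 10.0 * h / width}


def surrogate_descriptors(trace: Sequence[float], peaks: PeakPair,
                          baseline_window: int = BASELINE_WINDOW) -> Dict[str, float]:
    """The 37 vendor-named descriptors (surrogate definitions), as a mapping.

    Definitions (not the vendor's): baseline = median of the first
    ``baseline_window`` samples; h = peak height above baseline; dive =
    height above the inter-peak trough; widths/areas/paths use a 75% height
    cut (base set) or a 50% cut ("1"-suffixed set); flank slopes are mean
    slopes between the 25% and 75% (resp. 25% and 50%) levels; slew/mslew
    are the maximum 1-step and 3-step rises on the rising flank; Aindex and
    Bindex count down from 10 with each adverse step on the peak-1/peak-2
    flanks; Aplhf is 10x the power ratio of the window-9 high-frequency
    residual over the inter-peak segment; h11 and h21 are proportional to
    h1 and h2 (factor 2/3).
    """
    y = np.asarray(trace, dtype=float)
    baseline = float(np.median(y[:baseline_window]))
    out: Dict[str, float] = {}

    for tag, peak, lo, hi in (("1", peaks.p1, 0, peaks.trough),
                              ("2", peaks.p2, peaks.trough, len(y) - 1)):
        h = y[peak] - baseline
        if h <= 0:
            raise FeatureError(f"h{tag}: peak height not above baseline")
        base = _peak_metrics(y, peak, lo, hi, baseline, 0.75, (0.25, 0.75))
        alt = _peak_metrics(y, peak, lo, hi, baseline, 0.50, (0.25, 0.50))
        out[f"h{tag}"] = float(h)
        out[f"dive{tag}"] = float(y[peak] - y[peaks.trough])
        out[f"w{tag}"] = base["w"]
        out[f"p{tag}area"] = base["area"]
        out[f"uslope{tag}"] = base["uslope"]
        out[f"dslope{tag}"] = base["dslope"]
        out[f"aspect{tag}"] = base["aspect"]
        out[f"path{tag}"] = float(base["path"])
        out[f"slew{tag}"] = base["slew"]
        out[f"mslew{tag}"] = base["mslew"]
        out[f"w{tag}1"] = alt["w"]
        out[f"p{tag}area1"] = alt["area"]
        out[f"uslope{tag}1"] = alt["uslope"]
        out[f"dslope{tag}1"] = alt["dslope"]
        out[f"aspect{tag}1"] = alt["aspect"]
        out[f"path{tag}1"] = float(alt["path"])
        out[f"{'A' if tag == '1' else 'B'}index"] = \
            10.0 - min(10.0, float(base["adverse"]))

    out["h11"] = out["h1"] * (2.0 / 3.0)
    out["h21"] = out["h2"] * (2.0 / 3.0)

    seg = y[peaks.p1:peaks.p2 + 1]
    resid = seg - _smooth(y)[peaks.p1:peaks.p2 + 1]
    denom = float(np.sum((seg - seg.mean()) ** 2))
    out["Aplhf"] = 10.0 * float(np.sum(resid ** 2)) / denom if denom > 0 else 0.0

    return {name: float(out[name]) for name in DESCRIPTOR_NAMES}


def compute_features(trace: Sequence[float],
                     peaks: Optional[PeakPair] = None) -> Dict[str, float]:
    """Full feature set for one trace: the 37 descriptors plus ``monot12``."""
    if peaks is None:
        peaks = detect_applanation_peaks(trace)
    feats = surrogate_descriptors(trace, peaks)
    feats["monot12"] = monot12(trace, peaks)
    return feats


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

class DesignMatrix(NamedTuple):
    X: pd.DataFrame        # raw predictor columns, index = eye_id
    y: pd.Series           # PRAA (degrees)
    X_std: pd.DataFrame    # column-standardised copy of X


def assemble_design_matrix(
    features: Mapping[str, Mapping[str, float]],
    covariates: Sequence[EyeCovariates],
    include_keratometry: bool = False,
) -> DesignMatrix:
    """Predictor matrix + PRAA response for the regression stage.

    Columns (41 by default): age, AL, SERE, CH, CRF, the 35 descriptors
    excluding h11/h21 (proportional to h1/h2), and monot12 last.  Setting
    ``include_keratometry`` appends keratometry as an extra column.

    Raises
    ------
    AssemblyError
        Naming any eye with missing covariates or a missing PRAA response.
    """
    cov_by_eye = {c.eye_id: c for c in covariates}
    eyes = list(features)
    missing = [e for e in eyes if e not in cov_by_eye]
    if missing:
        raise AssemblyError(f"eyes missing covariates: {', '.join(missing)}")
    missing_praa = [e for e in eyes if cov_by_eye[e].PRAA is None]
    if missing_praa:
        raise AssemblyError(f"eyes missing PRAA: {', '.join(missing_praa)}")

    cov_cols = list(DESIGN_COVARIATES) + (
        ["keratometry"] if include_keratometry else [])
    desc_cols = [n for n in DESCRIPTOR_NAMES if n not in EXCLUDED_DESCRIPTORS]
    columns = cov_cols + desc_cols + ["monot12"]

    rows = []
    for eye in eyes:
        cov = cov_by_eye[eye]
        feat = features[eye]
        row = {c: float(getattr(cov, c)) for c in cov_cols}
        row.update({c: float(feat[c]) for c in desc_cols})
        row["monot12"] = float(feat["monot12"])
        rows.append(row)

    X = pd.DataFrame(rows, index=pd.Index(eyes, name="eye_id"),
                     columns=columns, dtype=float)
    y = pd.Series([float(cov_by_eye[e].PRAA) for e in eyes],
                  index=X.index, name="PRAA")
    std = X.std(ddof=0).replace(0.0, 1.0)
    X_std = (X - X.mean()) / std
    return DesignMatrix(X, y, X_std)
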