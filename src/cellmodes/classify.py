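"""Frame-wise behavioral classification from windowed mask dynamics.

Published criteria for telling mesenchymal, polygonal/bigonal and
amoeboid behavior apart are verbal (uni- vs multidirectional border
extension, directional vs non-directional centroid displacement, stable
vs unstable shape, spread vs poorly spread) and are judged over a
five-frame window (the two previous and two following frames).  This
module operationalizes them as a transparent thresholded rule set over
five window features:

``D``  directionality — net centroid displacement over the window
       divided by the path length, in [0, 1];
``X``  expansion anisotropy — circular resultant length of the
       directions (from the cell centroid) of the pixels newly occupied
       between consecutive aligned masks, pooled over the window's
       steps, in [0, 1];
``S``  shape stability — mean centroid-aligned Jaccard (intersection
       over union) of consecutive masks in the window, in [0, 1];
``A``  mean area (µm²) and ``PA`` mean perimeter/area (1/µm).

Masks are centroid-aligned before comparison so that translation does
not masquerade as border extension or shape change.  The decision
ladder (amoeboid instability checked first, since directed motion with
an unstable shape would otherwise partially satisfy the mesenchymal
clause):

1. AMO  if S < s_lo and D ≥ d_hi
2. MES  if D ≥ d_hi and X ≥ x_hi and S ≥ s_hi and A ≥ a_spread
3. POL  if D < d_hi and X < x_hi and S ≥ s_hi
4. UND  otherwise (or when features are undefined)

Raw per-frame labels are then smoothed by a width-3 categorical median
filter and runs shorter than ``debounce_min_run`` are absorbed into the
flanking state.  Thresholds are overridable and can be re-calibrated on
synthetic ground truth by grid search (:func:`calibrate_thresholds`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import STATES, UNDEFINED

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierThresholds:
    """Cutoffs of the decision ladder (unit-interval features, A in µm²)."""

    d_hi: float = 0.5
    x_hi: float = 0.5
    s_hi: float = 0.6
    s_lo: float = 0.35
    a_spread: float = 300.0
    debounce_min_run: int = 2

    def __post_init__(self):
        if not (0.0 <= self.s_lo < self.s_hi <= 1.0):
            raise ValueError("require 0 <= s_lo < s_hi <= 1")


@dataclass
class StateSequence:
    """Per-frame behavioral labels with provenance."""

    labels: np.ndarray                       # (n,) of {MES, POL, AMO, UND}
    source: str = "classified"               # or "ground_truth"
    features: pd.DataFrame | None = None     # window features, when classified

    def __len__(self):
        return len(self.labels)


# ---------------------------------------------------------------------------
# Window features
# ---------------------------------------------------------------------------

def _bbox_crop(a: np.ndarray, b: np.ndarray, pad: int = 5):
    """Crop two same-shape masks to the union bounding box.

    The pad must exceed the alignment-refinement search radius so that
    shifting a mask cannot push foreground out of the crop (which would
    shrink the union and distort the overlap score).
    """
    union = a | b
    rows = np.flatnonzero(union.any(axis=1))
    cols = np.flatnonzero(union.any(axis=0))
    if rows.size == 0:
        return a, b, (0, 0)
    r0, r1 = max(rows[0] - pad, 0), rows[-1] + pad + 1
    c0, c1 = max(cols[0] - pad, 0), cols[-1] + pad + 1
    return a[r0:r1, c0:c1], b[r0:r1, c0:c1], (r0, c0)


def _shift_int(mask: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Integer-shift a boolean mask with zero fill."""
    out = np.zeros_like(mask)
    h, w = mask.shape
    rs0, rs1 = max(dr, 0), min(h + dr, h)
    cs0, cs1 = max(dc, 0), min(w + dc, w)
    out[rs0:rs1, cs0:cs1] = mask[rs0 - dr:rs1 - dr, cs0 - dc:cs1 - dc]
    return out


def _shift_subpixel(mask: np.ndarray, dr: float, dc: float) -> np.ndarray:
    """Shift a boolean mask by a fractional offset (bilinear, zero fill)
    and re-binarize at the half level.

    Sub-pixel alignment matters: rounding to whole pixels leaves a
    residual translation whose leading-edge crescent would masquerade as
    unidirectional border extension in every moving cell.
    """
    from scipy import ndimage
    shifted = ndimage.shift(mask.astype(np.float32), (dr, dc), order=1,
                            mode="constant", cval=0.0, prefilter=False)
    return shifted >= 0.5


def _step_overlap(cur: np.ndarray, nxt: np.ndarray,
                  d_px: tuple[float, float], c_px: tuple[float, float]):
    """Aligned Jaccard and new-pixel circular resultant for one step.

    ``d_px`` is the centroid displacement (dx, dy) from cur to nxt and
    ``c_px`` the current-frame centroid, both in pixels.
    """
    cur_c, nxt_c, (r0, c0) = _bbox_crop(cur, nxt)
    aligned = _shift_subpixel(nxt_c, -d_px[1], -d_px[0])
    inter = int((cur_c & aligned).sum())
    union = int((cur_c | aligned).sum())
    jac = inter / union if union else np.nan
    # For the expansion map the centroid alignment is refined by a small
    # overlap-maximizing integer search: asymmetric growth itself drags
    # the centroid toward the new material, so pure centroid alignment
    # would manufacture a counter-directional rear crescent and cap the
    # resultant well below 1 even for perfectly one-sided extension.
    shifts = sorted(((dr, dc) for dr in range(-3, 4) for dc in range(-3, 4)),
                    key=lambda s: (s[0] * s[0] + s[1] * s[1]))
    best, best_shift = -1.0, (0, 0)
    for dr, dc in shifts:                    # smallest shift wins ties
        s = _shift_int(aligned, dr, dc)
        i = int((cur_c & s).sum())
        u = int((cur_c | s).sum())
        iou = i / u if u else 0.0
        if iou > best + 1e-12:
            best, best_shift = iou, (dr, dc)
    refined = _shift_int(aligned, *best_shift)
    # extension must clear the old boundary by more than one pixel:
    # rasterized (and segmented) outlines flicker by ±1 px along the whole
    # contour frame to frame, which would read as isotropic expansion
    from scipy import ndimage
    new = refined & ~ndimage.binary_dilation(cur_c, np.ones((3, 3), bool))
    rows, cols = np.nonzero(new)
    if rows.size == 0:
        return jac, 0.0, 0.0, 0
    ang = np.arctan2(rows + r0 - c_px[1], cols + c0 - c_px[0])
    return jac, float(np.cos(ang).sum()), float(np.sin(ang).sum()), rows.size


def _pair_features(masks: np.ndarray, centroids_px: np.ndarray):
    """Per consecutive pair: aligned Jaccard S_i and the new-pixel
    direction sums (cos, sin, count) feeding the window resultant."""
    n = len(masks)
    S = np.full(n - 1, np.nan)
    vec = np.zeros((n - 1, 3))
    for i in range(n - 1):
        if np.any(np.isnan(centroids_px[i])) or np.any(np.isnan(centroids_px[i + 1])):
            vec[i] = np.nan
            continue
        d = centroids_px[i + 1] - centroids_px[i]
        S[i], cs, sn, m = _step_overlap(masks[i] > 0, masks[i + 1] > 0,
                                        (d[0], d[1]), tuple(centroids_px[i]))
        vec[i] = (cs, sn, m)
    return S, vec


def window_features(masks: np.ndarray, features: pd.DataFrame,
                    pixel_size: float, half_window: int = 2,
                    min_new_pixels: int = 24) -> pd.DataFrame:
    """Window feature table (D, X, S, A, PA) for every frame of one track.

    ``features`` is the morphometrics table (``extract_features``) for the
    same stack.  Windows span frames [n−2, n+2], truncated at the track
    ends but never below three frames.
    """
    n = len(masks)
    if n < 3:
        raise ValueError("track must have at least 3 frames")
    cen = features[["x_um", "y_um"]].to_numpy() / pixel_size
    area = features["area_um2"].to_numpy()
    pa = features["pa_ratio"].to_numpy()
    S_pair, vec_pair = _pair_features(masks, cen)
    rows = []
    for t in range(n):
        lo = max(t - half_window, 0)
        hi = min(t + half_window, n - 1)
        while hi - lo + 1 < 3:          # keep >= 3 frames near track ends
            lo = max(lo - 1, 0)
            hi = min(hi + 1, n - 1)
        steps = np.diff(cen[lo:hi + 1], axis=0)
        if np.any(np.isnan(steps)):
            rows.append({"frame": t, "D": np.nan, "X": np.nan, "S": np.nan,
                         "A": np.nan, "PA": np.nan})
            continue
        path = np.linalg.norm(steps, axis=1).sum()
        net = np.linalg.norm(cen[hi] - cen[lo])
        D = net / path if path > 1e-9 else 0.0
        s_win = S_pair[lo:hi]
        S = float(np.nanmean(s_win)) if np.any(~np.isnan(s_win)) else np.nan
        # resultant pooled over all new pixels of the window's steps, so
        # steps with a handful of quantization-noise pixels cannot
        # masquerade as a unidirectional extension burst
        v = vec_pair[lo:hi]
        v = v[~np.isnan(v).any(axis=1)]
        n_new = v[:, 2].sum()
        # a handful of pixels is no appreciable extension at all — and
        # certainly not evidence of a unidirectional one
        X = float(np.hypot(v[:, 0].sum(), v[:, 1].sum()) / n_new) \
            if n_new >= min_new_pixels else 0.0
        rows.append({"frame": t, "D": float(D), "X": X, "S": S,
                     "A": float(np.nanmean(area[lo:hi + 1])),
                     "PA": float(np.nanmean(pa[lo:hi + 1]))})
    return pd.DataFrame(rows)


def extract_window_features(masks: np.ndarray, features: pd.DataFrame,
                            frame: int, pixel_size: float) -> pd.Series:
    """Window features for a single frame (row of :func:`window_features`)."""
    wf = window_features(masks, features, pixel_size)
    return wf.iloc[int(frame)]


# ---------------------------------------------------------------------------
# Decision ladder
# ---------------------------------------------------------------------------

def classify_frame(f, thr: ClassifierThresholds = ClassifierThresholds()) -> str:
    """Label one frame's window features via the decision ladder."""
    D, X, S, A = (float(f["D"]), float(f["X"]), float(f["S"]), float(f["A"]))
    if any(np.isnan(v) for v in (D, X, S, A)):
        return UNDEFINED
    if S < thr.s_lo and D >= thr.d_hi:
        return "AMO"
    if D >= thr.d_hi and X >= thr.x_hi and S >= thr.s_hi and A >= thr.a_spread:
        return "MES"
    if D < thr.d_hi and X < thr.x_hi and S >= thr.s_hi:
        return "POL"
    return UNDEFINED


def _classify_array(D, X, S, A, thr: ClassifierThresholds) -> np.ndarray:
    """Vectorized ladder over feature arrays."""
    labels = np.full(D.shape, UNDEFINED, dtype="U3")
    ok = ~(np.isnan(D) | np.isnan(X) | np.isnan(S) | np.isnan(A))
    amo = ok & (S < thr.s_lo) & (D >= thr.d_hi)
    mes = ok & ~amo & (D >= thr.d_hi) & (X >= thr.x_hi) & (S >= thr.s_hi) \
        & (A >= thr.a_spread)
    pol = ok & ~amo & ~mes & (D < thr.d_hi) & (X < thr.x_hi) & (S >= thr.s_hi)
    labels[amo], labels[mes], labels[pol] = "AMO", "MES", "POL"
    return labels


def _median3(labels: np.ndarray) -> np.ndarray:
    """Width-3 categorical median (majority-of-three) filter."""
    out = labels.copy()
    for i in range(1, len(labels) - 1):
        a, b, c = labels[i - 1], labels[i], labels[i + 1]
        if a == c and a != b:
            out[i] = a
    return out


def _runs(labels: np.ndarray):
    """Run-length encoding: list of (label, start, length)."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], start, i - start))
            start = i
    return runs


def _debounce(labels: np.ndarray, min_run: int) -> np.ndarray:
    """Absorb runs shorter than ``min_run`` into the flanking state.

    The replacement is the nearest *identified* flanking label
    (preceding preferred): UND marks ignorance, not a behavioral state,
    so a brief identified run flanked by UND is not erased into UND.
    """
    out = labels.copy()
    for _ in range(len(labels)):
        runs = _runs(out)
        if len(runs) <= 1:
            break
        short = [k for k, (_, _, ln) in enumerate(runs) if ln < min_run]
        if not short:
            break
        for k in short:
            lab, start, ln = runs[k]
            prev_lab = runs[k - 1][0] if k > 0 else None
            next_lab = runs[k + 1][0] if k + 1 < len(runs) else None
            if prev_lab is not None and prev_lab != UNDEFINED:
                repl = prev_lab
            elif next_lab is not None and next_lab != UNDEFINED:
                repl = next_lab
            elif prev_lab is not None:
                repl = prev_lab
            else:
                repl = next_lab
            if repl is not None and repl != lab:
                out[start:start + ln] = repl
                break
        else:
            break
    return out


def classify_track(masks: np.ndarray, features: pd.DataFrame,
                   thr: ClassifierThresholds = ClassifierThresholds(),
                   pixel_size: float = 1.0,
                   valid: np.ndarray | None = None) -> StateSequence:
    """Classify every frame of a track, then smooth and debounce.

    Frames flagged invalid by the inclusion criteria are forced to UND
    after smoothing so they never enter downstream statistics.
    """
    wf = window_features(masks, features, pixel_size)
    labels = _classify_array(wf["D"].to_numpy(), wf["X"].to_numpy(),
                             wf["S"].to_numpy(), wf["A"].to_numpy(), thr)
    labels = _median3(labels)
    labels = _debounce(labels, thr.debounce_min_run)
    if valid is not None:
        labels = labels.copy()
        labels[~np.asarray(valid, dtype=bool)] = UNDEFINED
    wf["label"] = labels
    return StateSequence(labels=labels, source="classified", features=wf)


# ---------------------------------------------------------------------------
# Calibration and inclusion criteria
# ---------------------------------------------------------------------------

def balanced_accuracy(truth: np.ndarray, predicted: np.ndarray) -> float:
    """Mean per-true-class recall over the classes present in ``truth``
    (UND predictions count as misses)."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    recalls = []
    for s in np.unique(truth):
        sel = truth == s
        recalls.append(float(np.mean(predicted[sel] == s)))
    return float(np.mean(recalls))


_DEFAULT_GRID = {
    "d_hi": (0.30, 0.40, 0.45, 0.50, 0.55, 0.60, 0.70),
    "x_hi": (0.10, 0.15, 0.20, 0.30, 0.40, 0.50, 0.60),
    "s_hi": (0.50, 0.60, 0.70),
    "s_lo": (0.25, 0.35, 0.45, 0.50, 0.55),
    "a_spread": (250.0, 300.0, 350.0),
}


def calibrate_thresholds(wf: pd.DataFrame, truth: np.ndarray,
                         grid: dict | None = None):
    """Grid-search ladder thresholds maximizing frame-wise balanced
    accuracy against ground-truth labels.

    Returns ``(ClassifierThresholds, achieved_balanced_accuracy)``.
    Deterministic given the grid; the default grid contains the default
    thresholds.  Raises on a single-state dataset (degenerate).
    """
    truth = np.asarray(truth)
    if np.unique(truth).size < 2:
        raise ValueError("calibration degenerate: dataset has a single state")
    grid = dict(_DEFAULT_GRID, **(grid or {}))
    D = wf["D"].to_numpy()
    X = wf["X"].to_numpy()
    S = wf["S"].to_numpy()
    A = wf["A"].to_numpy()
    best, best_thr = -1.0, None
    for d in grid["d_hi"]:
        for x in grid["x_hi"]:
            for sh in grid["s_hi"]:
                for sl in grid["s_lo"]:
                    if not sl < sh:
                        continue
                    for a in grid["a_spread"]:
                        thr = ClassifierThresholds(d, x, sh, sl, a)
                        acc = balanced_accuracy(
                            truth, _classify_array(D, X, S, A, thr))
                        if acc > best + 1e-12:
                            best, best_thr = acc, thr
    return best_thr, best


_warned_missing_annotations = False


def apply_inclusion_criteria(n_frames: int, annotations: pd.DataFrame | None,
                             individual: bool = True) -> np.ndarray:
    """Per-frame validity flags from annotation events.

    A frame is invalid when the cell is in contact with another cell, or
    dividing in that frame or either neighboring frame.  A cell that is
    not an individual is dropped entirely (all frames invalid).  With no
    annotations every frame is valid (warned once per process).
    """
    global _warned_missing_annotations
    valid = np.ones(int(n_frames), dtype=bool)
    if not individual:
        return np.zeros(int(n_frames), dtype=bool)
    if annotations is None:
        if not _warned_missing_annotations:
            logger.warning("no annotations provided; treating all frames as valid")
            _warned_missing_annotations = True
        return valid
    if len(annotations) != n_frames:
        raise ValueError("annotations length does not match track length")
    ann = annotations.sort_values("frame")
    contact = ann["contact"].to_numpy(dtype=bool)
    dividing = ann["dividing"].to_numpy(dtype=bool)
    spread = dividing.copy()
    spread[:-1] |= dividing[1:]
    spread[1:] |= dividing[:-1]
    return valid & ~contact & ~spread
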