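"""Per-frame speeds and signed turning angles from centroid series.

Speed at frame n is the displacement from frame n to n+1 divided by the
frame interval, in µm/min (undefined at the last frame).  The turning
angle at frame n is the signed angle from the displacement vector
(n−1 → n) to (n → n+1), counterclockwise-positive in the (x, y)
coordinate frame and wrapped to (−180°, 180°]; it is undefined at the
track ends and wherever either flanking displacement has zero length
(an undefined angle is reported as NaN rather than 0, which would bias
dispersion statistics).  Centroids are used as measured — no smoothing.
"""

from __future__ import annotations

import numpy as np


def compute_velocity(centroids_um: np.ndarray, dt_s: float) -> np.ndarray:
    """Per-frame speeds in µm/min; NaN at the last frame.

    Parameters
    ----------
    centroids_um : array of shape (n, 2)
        Per-frame (x, y) positions in µm.
    dt_s : float
        Frame interval in seconds.
    """
    if dt_s <= 0:
        raise ValueError("dt must be > 0")
    r = np.asarray(centroids_um, dtype=float)
    if r.ndim != 2 or r.shape[0] < 2 or r.shape[1] != 2:
        raise ValueError("need a (n>=2, 2) array of positions")
    steps = np.linalg.norm(np.diff(r, axis=0), axis=1)
    v = np.full(r.shape[0], np.nan)
    v[:-1] = steps / (dt_s / 60.0)
    return v


def compute_turning_angles(centroids_um: np.ndarray) -> np.ndarray:
    """Signed turning angles in degrees, wrapped to (−180, 180]; NaN at
    ends and at frames flanked by a zero-length displacement."""
    r = np.asarray(centroids_um, dtype=float)
    if r.ndim != 2 or r.shape[0] < 3 or r.shape[1] != 2:
        raise ValueError("need a (n>=3, 2) array of positions")
    d = np.diff(r, axis=0)                    # d[i] = r[i+1] - r[i]
    u, w = d[:-1], d[1:]                      # incoming, outgoing at frame i+1
    cross = u[:, 0] * w[:, 1] - u[:, 1] * w[:, 0]
    dot = (u * w).sum(axis=1)
    theta = np.degrees(np.arctan2(cross, dot))
    # atan2 returns [-180, 180]; fold the -180 branch onto +180
    theta[theta == -180.0] = 180.0
    zero = (np.linalg.norm(u, axis=1) == 0) | (np.linalg.norm(w, axis=1) == 0)
    theta[zero] = np.nan
    out = np.full(r.shape[0], np.nan)
    out[1:-1] = theta
    return out
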