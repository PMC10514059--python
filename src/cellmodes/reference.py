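"""Published reference statistics for WC256 carcinosarcoma cells.

Median/quartile descriptors per behavioral subpopulation and substrate
(rigid glass vs 40 kPa polyacrylamide), as published for the WC256
adherent subline.  These values parameterize the simulator presets and
serve as arithmetic anchors (IQR = Q3 − Q1, cross-condition differences)
in the test suite.  Units: velocity µm/min, turning angle degrees,
elongation dimensionless, area µm², perimeter/area 1/µm.
"""

from __future__ import annotations

import pandas as pd

_COLS = ("parameter", "group", "condition", "median", "q1", "q3", "iqr")

_ROWS = [
    ("velocity_um_min", "MES", "glass", 0.614, 0.372, 0.963, 0.591),
    ("velocity_um_min", "MES", "PA", 0.518, 0.289, 0.989, 0.700),
    ("velocity_um_min", "POL", "glass", 0.509, 0.311, 0.795, 0.484),
    ("velocity_um_min", "POL", "PA", 0.507, 0.306, 0.797, 0.492),
    ("velocity_um_min", "AMO", "glass", 1.325, 0.795, 2.186, 1.391),
    ("velocity_um_min", "AMO", "PA", 1.536, 0.899, 2.717, 1.818),
    ("velocity_um_min", "ALL", "glass", 0.607, 0.364, 0.988, 0.624),
    ("velocity_um_min", "ALL", "PA", 0.655, 0.365, 1.287, 0.922),
    ("turning_angle_deg", "MES", "glass", -15.4, -75.7, 28.6, 104.2),
    ("turning_angle_deg", "MES", "PA", -11.8, -68.9, 34.4, 103.3),
    ("turning_angle_deg", "POL", "glass", -37.9, -126.1, 39.8, 166.0),
    ("turning_angle_deg", "POL", "PA", -28.2, -121.3, 41.2, 162.5),
    ("turning_angle_deg", "AMO", "glass", -10.4, -49.1, 21.7, 70.9),
    ("turning_angle_deg", "AMO", "PA", -5.3, -29.6, 16.6, 46.2),
    ("turning_angle_deg", "ALL", "glass", -18.6, -91.2, 30.2, 121.4),
    ("turning_angle_deg", "ALL", "PA", -15.4, -75.7, 28.6, 104.2),
    ("elongation", "MES", "glass", 0.365, 0.258, 0.493, 0.235),
    ("elongation", "MES", "PA", 0.267, 0.169, 0.359, 0.190),
    ("elongation", "POL", "glass", 0.615, 0.484, 0.700, 0.216),
    ("elongation", "POL", "PA", 0.580, 0.445, 0.681, 0.236),
    ("elongation", "AMO", "glass", 0.357, 0.245, 0.462, 0.217),
    ("elongation", "AMO", "PA", 0.385, 0.287, 0.480, 0.193),
    ("elongation", "ALL", "glass", 0.436, 0.302, 0.601, 0.299),
    ("elongation", "ALL", "PA", 0.427, 0.288, 0.585, 0.297),
    ("area_um2", "MES", "glass", 478.9, 401.5, 566.0, 164.5),
    ("area_um2", "MES", "PA", 338.3, 274.6, 381.1, 106.5),
    ("area_um2", "POL", "glass", 503.9, 448.9, 568.2, 119.3),
    ("area_um2", "POL", "PA", 399.3, 323.1, 466.3, 143.3),
    ("area_um2", "AMO", "glass", 321.4, 290.9, 399.3, 108.4),
    ("area_um2", "AMO", "PA", 252.8, 226.1, 284.9, 58.8),
    ("area_um2", "ALL", "glass", 478.3, 401.0, 558.4, 157.4),
    ("area_um2", "ALL", "PA", 326.3, 259.9, 414.0, 154.2),
    ("pa_ratio", "MES", "glass", 0.142, 0.134, 0.153, 0.019),
    ("pa_ratio", "MES", "PA", 0.149, 0.141, 0.162, 0.021),
    ("pa_ratio", "POL", "glass", 0.158, 0.148, 0.170, 0.022),
    ("pa_ratio", "POL", "PA", 0.168, 0.157, 0.183, 0.026),
    ("pa_ratio", "AMO", "glass", 0.163, 0.157, 0.171, 0.014),
    ("pa_ratio", "AMO", "PA", 0.180, 0.169, 0.191, 0.022),
    ("pa_ratio", "ALL", "glass", 0.150, 0.138, 0.162, 0.024),
    ("pa_ratio", "ALL", "PA", 0.169, 0.155, 0.184, 0.029),
]

#: Published per-subpopulation quartiles (see module docstring).
REFERENCE_QUARTILES: pd.DataFrame = pd.DataFrame(_ROWS, columns=_COLS)

#: Published occurrence shares (% of frames), where stated exactly.
REFERENCE_OCCURRENCE_PCT = {
    ("glass", "POL"): 31.87,
    ("glass", "AMO"): 8.89,
    ("PA", "POL"): 44.38,
    ("PA", "AMO"): 23.17,
}

#: Published Pearson r between occupancy time series.
REFERENCE_SHARE_CORRELATIONS = {
    ("glass", "MES", "POL"): -0.8616,
    ("glass", "MES", "AMO"): 0.3330,
    ("glass", "POL", "AMO"): -0.4538,
    ("PA", "MES", "POL"): -0.5151,
    ("PA", "MES", "AMO"): 0.1249,
    ("PA", "POL", "AMO"): -0.8274,
}


def reference_row(parameter: str, group: str, condition: str) -> pd.Series:
    """Single reference row, e.g. ``reference_row("velocity_um_min",
    "MES", "glass")``."""
    sel = REFERENCE_QUARTILES[
        (REFERENCE_QUARTILES["parameter"] == parameter)
        & (REFERENCE_QUARTILES["group"] == group)
        & (REFERENCE_QUARTILES["condition"] == condition)]
    if len(sel) != 1:
        raise KeyError((parameter, group, condition))
    return sel.iloc[0]
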