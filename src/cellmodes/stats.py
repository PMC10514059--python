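"""Population-level heterogeneity statistics.

Durations (total time per behavioral state, summed across visits),
transition counts (after bridging short unidentified gaps), occurrence
shares with square-root-of-count errors, per-frame occupancy time
series, Pearson correlation between occupancy series, median/IQR
descriptive statistics, and two-sided Mann–Whitney comparisons with the
conventional star annotation (* p < 0.05, ** p < 0.01, *** p < 0.001).

Quantiles use the linear-interpolation rule (numpy default), recorded in
output metadata.  Unidentified (UND) gaps of at most ``bridge_max_und``
frames bridge a state visit for transition counting; longer gaps
terminate it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .params import STATES, UNDEFINED

ALL_LABELS = (*STATES, UNDEFINED)
QUANTILE_RULE = "linear_interpolation"


@dataclass(frozen=True)
class DescriptiveStats:
    median: float
    q1: float
    q3: float
    iqr: float
    n: int


@dataclass(frozen=True)
class ComparisonResult:
    u: float
    p: float
    stars: str
    n_a: int
    n_b: int


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    #: occupancy shares are compositional, hence statistically dependent;
    #: their correlation p-values must be read with that caveat
    dependent_series: bool = True


@dataclass
class TransitionTable:
    pair_counts: pd.DataFrame       # from, to, count
    per_cell: pd.DataFrame          # cell_id, n_transitions
    full_transitions: int           # MES→POL→AMO or reverse, via POL
    direct_mes_amo: int             # direct MES↔AMO switches


@dataclass
class StatsBundle:
    summary: pd.DataFrame           # per parameter × state-group × condition
    occurrence: pd.DataFrame
    occurrence_ts: pd.DataFrame
    transitions: pd.DataFrame
    durations: pd.DataFrame
    comparisons: pd.DataFrame
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Descriptive and comparative statistics
# ---------------------------------------------------------------------------

def describe(values) -> DescriptiveStats:
    """Median, quartiles and IQR (= Q3 − Q1) of a sample."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("cannot describe an empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return DescriptiveStats(float(med), float(q1), float(q3),
                            float(q3 - q1), int(v.size))


def stars_for_p(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "-"


def compare_groups(values_a, values_b) -> ComparisonResult:
    """Two-sided Mann–Whitney U comparison of two samples.

    Exact enumeration for small untied samples (both n ≤ 20), otherwise
    the tie-corrected normal approximation.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return ComparisonResult(float(res.statistic), float(res.pvalue),
                            stars_for_p(float(res.pvalue)), a.size, b.size)


def share_correlation(series_a, series_b) -> CorrelationResult:
    """Pearson correlation between two occupancy time series (two-sided
    p from the exact t transform)."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("series must be equal length >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("undefined correlation: a series has zero variance")
    r, p = sps.pearsonr(a, b)
    return CorrelationResult(float(r), float(p), int(a.size))


# ---------------------------------------------------------------------------
# Durations, transitions, occurrence
# ---------------------------------------------------------------------------

def subpopulation_durations(labels, dt_s: float) -> dict[str, float]:
    """Total time (hours) spent in each state, summed across visits."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty state sequence")
    return {s: float(np.sum(labels == s) * dt_s / 3600.0) for s in ALL_LABELS}


def _bridged_identified(labels: np.ndarray, bridge_max_und: int):
    """Segments of identified labels after bridging short UND gaps.

    Returns a list of label arrays; UND runs of length ≤ bridge_max_und
    are removed within a segment, longer runs split the sequence.
    """
    segments, current = [], []
    gap = 0
    for lab in labels:
        if lab == UNDEFINED:
            gap += 1
            continue
        if gap > bridge_max_und and current:
            segments.append(np.asarray(current))
            current = []
        gap = 0
        current.append(lab)
    if current:
        segments.append(np.asarray(current))
    return segments


def count_transitions(labels, bridge_max_und: int = 2,
                      cell_id: str = "cell") -> TransitionTable:
    """Ordered transition counts for one cell's label sequence.

    Also reports "full" MES→AMO (or reverse) passages through POL within
    a bridged segment, and direct MES↔AMO switches.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty state sequence")
    pairs: dict[tuple[str, str], int] = {}
    total = 0
    full = 0
    direct = 0
    for seg in _bridged_identified(labels, bridge_max_und):
        changes = seg[1:][seg[1:] != seg[:-1]]
        rle = [seg[0], *changes]
        for a, b in zip(rle[:-1], rle[1:]):
            pairs[(a, b)] = pairs.get((a, b), 0) + 1
            total += 1
            if {a, b} == {"MES", "AMO"}:
                direct += 1
        for a, b, c in zip(rle[:-2], rle[1:-1], rle[2:]):
            if b == "POL" and {a, c} == {"MES", "AMO"}:
                full += 1
    rows = [{"from": a, "to": b, "count": c} for (a, b), c in sorted(pairs.items())]
    pair_df = pd.DataFrame(rows, columns=["from", "to", "count"])
    per_cell = pd.DataFrame({"cell_id": [cell_id], "n_transitions": [total]})
    return TransitionTable(pair_df, per_cell, full, direct)


def occurrence(label_arrays) -> pd.DataFrame:
    """Occurrence table over all cells: per state, the frame count, the
    share of total frames, and square-root-of-count errors on both the
    count and the share scale."""
    all_labels = np.concatenate([np.asarray(a) for a in label_arrays])
    if all_labels.size == 0:
        raise ValueError("need at least one cell with frames")
    total = all_labels.size
    rows = []
    for s in ALL_LABELS:
        c = int(np.sum(all_labels == s))
        rows.append({"state": s, "count": c, "fraction": c / total,
                     "err_count": np.sqrt(c), "err_fraction": np.sqrt(c) / total})
    df = pd.DataFrame(rows)
    assert abs(df["fraction"].sum() - 1.0) < 1e-12
    df.attrs["total_frames"] = total
    return df


def occurrence_timeseries(label_arrays) -> pd.DataFrame:
    """Per-frame share of each state across cells (tracks frame-aligned).

    share[t, s] = #cells in state s at frame t / #cells observed at t;
    shares (including UND) sum to 1 in every frame.
    """
    arrays = [np.asarray(a) for a in label_arrays]
    n = max(a.size for a in arrays)
    rows = []
    for t in range(n):
        present = [a[t] for a in arrays if a.size > t]
        m = len(present)
        row = {"frame": t, "n_cells": m}
        for s in ALL_LABELS:
            row[s] = sum(1 for lab in present if lab == s) / m
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Aggregated report
# ---------------------------------------------------------------------------

_PARAMS = ("velocity_um_min", "turning_angle_deg", "elongation",
           "area_um2", "pa_ratio")


def duration_histogram(durations_h, n_frames: int, dt_s: float,
                       bin_h: float = 1.0) -> pd.DataFrame:
    """Histogram of per-cell total time in state, in 1-h bins with a
    closed top bin at the movie duration."""
    top = n_frames * dt_s / 3600.0
    edges = np.arange(0.0, top + bin_h, bin_h)
    edges[-1] = top + 1e-9
    vals = np.asarray([d for d in durations_h if d > 0])
    counts, _ = np.histogram(vals, bins=edges)
    return pd.DataFrame({"bin_lo_h": edges[:-1], "bin_hi_h": edges[1:],
                         "n_cells": counts})


def build_report(per_cell_frames: pd.DataFrame, dt_s: float,
                 bridge_max_und: int = 2) -> StatsBundle:
    """Assemble the full statistics bundle from a tidy per-frame table.

    ``per_cell_frames`` must have columns ``condition, cell_id, frame,
    label, velocity_um_min, turning_angle_deg, elongation, area_um2,
    pa_ratio`` (one row per valid frame).  UND frames are excluded from
    parameter statistics but retained in occurrence accounting.
    """
    df = per_cell_frames
    conditions = sorted(df["condition"].unique())
    if len(conditions) == 0:
        raise ValueError("no conditions present")

    summary_rows, comp_rows = [], []
    groups = [*[(s, (s,)) for s in STATES], ("ALL", STATES)]
    for param in _PARAMS:
        for gname, members in groups:
            samples = {}
            for cond in conditions:
                sel = df[(df["condition"] == cond) & df["label"].isin(members)]
                vals = sel[param].dropna().to_numpy()
                if vals.size:
                    samples[cond] = vals
                    d = describe(vals)
                    summary_rows.append({
                        "parameter": param, "group": gname, "condition": cond,
                        "median": d.median, "q1": d.q1, "q3": d.q3,
                        "iqr": d.iqr, "n": d.n})
            if len(samples) == 2:
                a, b = (samples[c] for c in conditions)
                comp = compare_groups(a, b)
                comp_rows.append({
                    "parameter": param, "group": gname,
                    "condition_a": conditions[0], "condition_b": conditions[1],
                    "u": comp.u, "p": comp.p, "stars": comp.stars})

    occ_rows, ts_rows, trans_rows, dur_rows = [], [], [], []
    for cond in conditions:
        sub = df[df["condition"] == cond]
        label_arrays = [g.sort_values("frame")["label"].to_numpy()
                        for _, g in sub.groupby("cell_id")]
        occ = occurrence(label_arrays).assign(condition=cond)
        occ_rows.append(occ)
        ts = occurrence_timeseries(label_arrays).assign(condition=cond)
        ts_rows.append(ts)
        for (cid, g) in sub.groupby("cell_id"):
            labels = g.sort_values("frame")["label"].to_numpy()
            tt = count_transitions(labels, bridge_max_und, cell_id=str(cid))
            for _, r in tt.pair_counts.iterrows():
                trans_rows.append({"condition": cond, "cell_id": cid,
                                   "from": r["from"], "to": r["to"],
                                   "count": int(r["count"])})
            durs = subpopulation_durations(labels, dt_s)
            for s in ALL_LABELS:
                dur_rows.append({"condition": cond, "cell_id": cid,
                                 "state": s, "hours": durs[s]})

    return StatsBundle(
        summary=pd.DataFrame(summary_rows),
        occurrence=pd.concat(occ_rows, ignore_index=True),
        occurrence_ts=pd.concat(ts_rows, ignore_index=True),
        transitions=pd.DataFrame(trans_rows,
                                 columns=["condition", "cell_id", "from",
                                          "to", "count"]),
        durations=pd.DataFrame(dur_rows),
        comparisons=pd.DataFrame(comp_rows,
                                 columns=["parameter", "group", "condition_a",
                                          "condition_b", "u", "p", "stars"]),
        meta={"quantile_rule": QUANTILE_RULE, "dt_s": dt_s,
              "bridge_max_und": bridge_max_und},
    )
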