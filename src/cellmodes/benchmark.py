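"""Seeded recovery benchmarks on synthetic ground truth.

These routines tie the whole pipeline together: simulate mask movies
with known Markov state sequences, classify every frame back, and score
recovery — frame-wise balanced accuracy (excluding frames within two
frames of a true transition, where the ±2-frame window necessarily
mixes states), per-cell transition-count agreement, and empirical
transition-matrix convergence.

Two track-level constants complement the frame-wise thresholds:

* ``BENCH_DEBOUNCE`` (5 frames = 7.5 min at 90 s): a label run shorter
  than the classification window span is treated as noise — behavioral
  states persist for tens of minutes, so nothing shorter than the
  window itself is trustworthy.
* classified-sequence transition counting bridges unidentified gaps up
  to ``debounce + window span − 1`` frames (8 by default): at a true
  transition the ±2-frame window mixes both states for up to five
  frames and the debouncer will not rescue runs below its floor, so
  transition-zone UND gaps are structural, not evidence of a visit
  ending.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .classify import (
    ClassifierThresholds,
    balanced_accuracy,
    calibrate_thresholds,
    classify_track,
    window_features,
)
from .morphometrics import extract_features
from .params import STATES, SimulationConfig, TransitionModel, glass_like, pa_like
from .simulate import simulate_cell, simulate_state_sequence
from .stats import count_transitions, occurrence

BENCH_DEBOUNCE = 5
_HALF_WINDOW = 2


def classified_bridge(thr: ClassifierThresholds) -> int:
    """UND-gap bridging length for classified sequences (see module
    docstring)."""
    return thr.debounce_min_run + 2 * _HALF_WINDOW - 1


def _analyze(cell, config: SimulationConfig, thr: ClassifierThresholds):
    feats = extract_features(cell.masks, config.pixel_size)
    seq = classify_track(cell.masks, feats, thr, pixel_size=config.pixel_size)
    return feats, seq


def calibrate_on_synthetic(seed: int, cells_per_state: int = 5,
                           n_frames: int = 70,
                           config: SimulationConfig | None = None
                           ) -> tuple[ClassifierThresholds, float]:
    """Grid-calibrate ladder thresholds on pure-state synthetic movies.

    One movie per (state, replicate) is rendered with a forced constant
    state sequence, so every behavioral class contributes the same
    number of unambiguous frames regardless of the transition model's
    stationary distribution.  Returns thresholds (with the track-level
    debounce floor applied) and the frame-wise balanced accuracy
    achieved on the calibration set.
    """
    from .simulate import render_movie
    config = config or glass_like()
    wfs, truths = [], []
    for si, state in enumerate(STATES):
        states = np.full(n_frames, state, dtype="U3")
        for i in range(cells_per_state):
            rng = np.random.default_rng(
                np.random.SeedSequence((seed, si, i)))
            _, masks = render_movie(states, config, rng)
            feats = extract_features(masks, config.pixel_size)
            wfs.append(window_features(masks, feats, config.pixel_size))
            truths.append(states)
    thr, acc = calibrate_thresholds(pd.concat(wfs, ignore_index=True),
                                    np.concatenate(truths))
    return dataclasses.replace(thr, debounce_min_run=BENCH_DEBOUNCE), acc


def run_recovery_benchmark(seed: int, n_cells: int = 50,
                           config: SimulationConfig | None = None) -> dict:
    """Classify the default 3-state benchmark and score recovery.

    Thresholds are calibrated on a separate synthetic set (seed offset
    by 101).  Returns balanced accuracy (transition-adjacent frames
    excluded), the fraction of cells whose recovered transition count is
    within ±1 of truth, and per-state classified occupancy.
    """
    base = config or glass_like()
    thr, _ = calibrate_on_synthetic(seed + 101, config=base)
    cfg = base.with_(n_cells=n_cells, rng_seed=seed)
    bridge = classified_bridge(thr)
    truth_all, pred_all = [], []
    n_within1 = 0
    labels_per_cell = []
    for i in range(cfg.n_cells):
        cell = simulate_cell(cfg, i)
        _, seq = _analyze(cell, cfg, thr)
        labels_per_cell.append(seq.labels)
        trans = np.flatnonzero(cell.states[1:] != cell.states[:-1])
        excl = np.zeros(len(cell.states), dtype=bool)
        for t in trans:
            excl[max(t - _HALF_WINDOW, 0):t + _HALF_WINDOW + 3] = True
        truth_all.append(cell.states[~excl])
        pred_all.append(seq.labels[~excl])
        n_true = count_transitions(cell.states).per_cell["n_transitions"].iloc[0]
        n_pred = count_transitions(seq.labels, bridge).per_cell[
            "n_transitions"].iloc[0]
        n_within1 += int(abs(int(n_true) - int(n_pred)) <= 1)
    occ = occurrence(labels_per_cell)
    return {
        "balanced_accuracy": balanced_accuracy(np.concatenate(truth_all),
                                               np.concatenate(pred_all)),
        "transitions_within1_fraction": n_within1 / cfg.n_cells,
        "occupancy": dict(zip(occ["state"], occ["fraction"])),
        "thresholds": thr,
        "n_cells": cfg.n_cells,
    }


def transition_matrix_recovery(seed: int, n_steps: int = 30_000,
                               model: TransitionModel | None = None) -> float:
    """Max-abs error between the empirical per-step transition matrix of
    one long simulated chain and the generating matrix T."""
    model = model or glass_like().transition_model
    labels = simulate_state_sequence(model, n_steps, seed)
    idx = {s: i for i, s in enumerate(model.states)}
    counts = np.zeros((len(model.states),) * 2)
    a = np.array([idx[s] for s in labels])
    np.add.at(counts, (a[:-1], a[1:]), 1)
    emp = counts / counts.sum(axis=1, keepdims=True)
    return float(np.max(np.abs(emp - model.T)))


def classified_occupancy_single(config: SimulationConfig, seed: int,
                                thr: ClassifierThresholds,
                                n_cells: int = 50) -> dict[str, float]:
    """Full-pipeline classified occupancy for one condition preset."""
    cfg = config.with_(n_cells=n_cells, rng_seed=seed)
    labels = []
    for i in range(cfg.n_cells):
        cell = simulate_cell(cfg, i)
        _, seq = _analyze(cell, cfg, thr)
        labels.append(seq.labels)
    occ = occurrence(labels)
    return dict(zip(occ["state"], occ["fraction"]))


def classified_occupancy(seed: int, n_cells: int = 50) -> dict[str, dict]:
    """Full-pipeline occupancy per condition for the two presets."""
    thr, _ = calibrate_on_synthetic(seed + 101)
    return {cfg.condition_label: classified_occupancy_single(cfg, seed, thr,
                                                             n_cells)
            for cfg in (glass_like(), pa_like())}


def pol_amo_switching_model(rate: float = 0.02) -> TransitionModel:
    """Two-state switching chain (POL↔AMO only; MES never visited)."""
    T = np.array([[1.0, 0.0, 0.0],
                  [0.0, 1.0 - rate, rate],
                  [0.0, rate, 1.0 - rate]])
    return TransitionModel(pi=np.array([0.0, 0.5, 0.5]), T=T)
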