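"""Domain parameter types for simulation and analysis.

The three behavioral states are:

``MES``
    mesenchymal — directed crawling of a spread, polarized cell whose
    leading-edge extension drives centroid displacement.
``POL``
    polygonal/bigonal (pooled) — spread, non-polarized cell extending
    protrusions in several (or two opposing) directions with chaotic
    centroid motion.
``AMO``
    amoeboid — fast, poorly spread cell with an unstable, blebby or
    pseudopodial outline.

``UND`` marks frames whose behavior cannot be identified; it is never a
simulated ground-truth state.

Two presets, :func:`glass_like` and :func:`pa_like`, encode the study
conditions for cells migrating on rigid glass versus a 40 kPa
polyacrylamide hydrogel: per-state speed, turning, area and elongation
statistics drawn from published quartiles for WC256 carcinosarcoma cells,
and transition propensities whose stationary distributions reproduce the
published subpopulation occupancies (mesenchymal-dominant on glass,
shifted toward polygonal/bigonal and amoeboid on the soft substrate).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

#: Ordered behavioral state labels (simulated ground-truth states).
STATES: tuple[str, str, str] = ("MES", "POL", "AMO")

#: Label for frames that fit no behavioral criterion.
UNDEFINED: str = "UND"


@dataclass(frozen=True)
class TransitionModel:
    """Per-frame Markov switching model over the behavioral states.

    Parameters
    ----------
    pi : array-like of shape (3,)
        Initial state distribution over ``STATES``.
    T : array-like of shape (3, 3)
        Row-stochastic matrix of per-step (one frame interval) transition
        probabilities; ``T[i, j]`` is P(next = j | current = i).
    states : sequence of str
        State labels; defaults to ``STATES``.
    """

    pi: np.ndarray
    T: np.ndarray
    states: tuple[str, ...] = STATES

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        T = np.asarray(self.T, dtype=float)
        k = len(self.states)
        if pi.shape != (k,) or T.shape != (k, k):
            raise ValueError(f"pi must be ({k},) and T ({k},{k}); got {pi.shape}, {T.shape}")
        if np.any(pi < 0) or np.any(T < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must sum to 1")
        if np.max(np.abs(T.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("each row of T must sum to 1")
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "T", T)

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of T for eigenvalue 1, normalized to sum 1."""
        w, v = np.linalg.eig(self.T.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        p = np.real(v[:, i])
        return p / p.sum()

    @staticmethod
    def from_rates(rates: Mapping[tuple[str, str], float],
                   pi: Sequence[float] | None = None) -> "TransitionModel":
        """Build a model from off-diagonal per-step switch probabilities.

        Diagonal entries are filled so rows sum to 1.  When ``pi`` is
        omitted the stationary distribution is used as the initial law.
        """
        k = len(STATES)
        T = np.zeros((k, k))
        idx = {s: i for i, s in enumerate(STATES)}
        for (a, b), p in rates.items():
            T[idx[a], idx[b]] = p
        np.fill_diagonal(T, 0.0)
        np.fill_diagonal(T, 1.0 - T.sum(axis=1))
        if np.any(np.diag(T) < 0):
            raise ValueError("off-diagonal rates exceed 1 in some row")
        m = TransitionModel(pi=np.full(k, 1.0 / k), T=T)
        if pi is None:
            pi = m.stationary_distribution()
        return TransitionModel(pi=np.asarray(pi, dtype=float), T=T)


@dataclass(frozen=True)
class MotionParams:
    """Per-state centroid-motion parameters.

    Speed is drawn per frame from a log-normal with the given median
    (µm/min) and log-scale spread; the heading turns each frame by a
    wrapped-normal angle with mean ``turning_drift_deg`` and spread
    ``turning_sigma_deg`` (degrees).
    """

    median_speed: float          # µm/min
    speed_sigma_log: float       # dimensionless log-scale spread
    turning_sigma_deg: float     # wrapped-normal sigma, degrees
    turning_drift_deg: float = 0.0

    def __post_init__(self):
        if self.median_speed <= 0:
            raise ValueError("median_speed must be > 0")
        if self.speed_sigma_log < 0 or self.turning_sigma_deg < 0:
            raise ValueError("spreads must be >= 0")


@dataclass(frozen=True)
class ShapeParams:
    """Per-state mask-shape parameters.

    The outline is a star-convex radial profile: a base ellipse at the
    state's target elongation, modulated by low-order Fourier boundary
    noise and by protrusion lobes (a single leading fan for MES, 2–5
    lobes for POL, transient bleb-like bumps for AMO).  ``shape_turnover``
    is the per-frame probability of re-sampling the protrusion pattern:
    high turnover produces the frame-to-frame instability characteristic
    of amoeboid cells.
    """

    median_area: float           # µm²
    area_sigma_log: float        # log-scale spread of area
    target_elongation: float     # ε = 1 − minor/major, in [0, 1)
    elongation_spread: float     # cell-to-cell s.d. of ε
    lobe_count: tuple[int, int]  # inclusive range of protrusion lobes
    lobe_amp: float              # lobe amplitude, fraction of base radius
    boundary_noise_amp: float    # Fourier boundary noise, fraction of radius
    shape_turnover: float        # per-frame resampling probability
    centroid_noise_um: float = 0.0   # shape-driven centroid scatter (µm)

    def __post_init__(self):
        if self.median_area <= 0:
            raise ValueError("median_area must be > 0")
        if not (0.0 <= self.target_elongation < 1.0):
            raise ValueError("target_elongation must be in [0, 1)")
        if not (0.0 <= self.shape_turnover <= 1.0):
            raise ValueError("shape_turnover must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Full recipe for one simulated condition.

    Defaults describe a 4-h movie at 90-s intervals (161 frames) for
    50 cells, imaged at 0.65 µm/px.
    """

    transition_model: TransitionModel
    motion: Mapping[str, MotionParams]
    shapes: Mapping[str, ShapeParams]
    n_cells: int = 50
    n_frames: int = 161
    dt: float = 90.0             # s
    pixel_size: float = 0.65     # µm/px
    condition_label: str = "glass"
    canvas: tuple[int, int] = (360, 360)
    margin: int = 45             # px kept clear of the canvas border
    contact_rate: float = 0.0    # per-frame probability of a contact event
    division_rate: float = 0.0   # per-movie probability of one division event
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_frames < 5:
            raise ValueError("n_frames must be >= 5 (classification window)")
        if self.dt <= 0 or self.pixel_size <= 0:
            raise ValueError("dt and pixel_size must be > 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for s in STATES:
            if s not in self.motion or s not in self.shapes:
                raise ValueError(f"missing motion/shape params for state {s}")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _glass_motion() -> dict[str, MotionParams]:
    # Speed medians and log-spreads from published per-state quartiles on
    # glass; turning sigma = IQR / 1.349 (normal-quantile relation), drift
    # = published median turning angle.
    return {
        "MES": MotionParams(0.614, 0.705, 77.2, -15.4),
        "POL": MotionParams(0.509, 0.50, 123.1, -37.9),
        "AMO": MotionParams(1.325, 0.750, 52.6, -10.4),
    }


def _pa_motion() -> dict[str, MotionParams]:
    return {
        "MES": MotionParams(0.518, 0.912, 76.6, -11.8),
        "POL": MotionParams(0.507, 0.50, 120.5, -28.2),
        "AMO": MotionParams(1.536, 0.820, 34.2, -5.3),
    }


def _glass_shapes() -> dict[str, ShapeParams]:
    return {
        "MES": ShapeParams(478.9, 0.254, 0.365, 0.10, (1, 1), 0.90, 0.05, 0.20, 0.05),
        "POL": ShapeParams(503.9, 0.175, 0.615, 0.10, (2, 5), 0.35, 0.05, 0.02, 0.42),
        "AMO": ShapeParams(321.4, 0.235, 0.357, 0.10, (3, 7), 0.80, 0.85, 0.92, 0.05),
    }


def _pa_shapes() -> dict[str, ShapeParams]:
    return {
        "MES": ShapeParams(338.3, 0.243, 0.267, 0.10, (1, 1), 0.90, 0.05, 0.20, 0.05),
        "POL": ShapeParams(399.3, 0.272, 0.580, 0.10, (2, 5), 0.35, 0.05, 0.02, 0.42),
        "AMO": ShapeParams(252.8, 0.171, 0.385, 0.10, (3, 7), 0.80, 0.85, 0.92, 0.05),
    }


def glass_like(**overrides) -> SimulationConfig:
    """Condition preset for cells on rigid glass: mesenchymal-dominant
    occupancy (~58/33/9 % MES/POL/AMO at stationarity) with MES↔POL as
    the most frequent transition and direct MES↔AMO switches seen in only
    a few percent of cells per movie."""
    model = TransitionModel.from_rates({
        ("MES", "POL"): 0.0060, ("POL", "MES"): 0.01055,
        ("POL", "AMO"): 0.0025, ("AMO", "POL"): 0.00917,
        ("MES", "AMO"): 0.0002, ("AMO", "MES"): 0.00129,
    })
    cfg = SimulationConfig(transition_model=model, motion=_glass_motion(),
                           shapes=_glass_shapes(), condition_label="glass")
    return cfg.with_(**overrides) if overrides else cfg


def pa_like(**overrides) -> SimulationConfig:
    """Condition preset for cells on a 40 kPa polyacrylamide substrate:
    occupancy shifted toward polygonal/bigonal and amoeboid states
    (~26/48/26 % at stationarity) with POL↔AMO as the most frequent
    transition."""
    model = TransitionModel.from_rates({
        ("MES", "POL"): 0.0080, ("POL", "MES"): 0.00433,
        ("POL", "AMO"): 0.0060, ("AMO", "POL"): 0.01108,
        ("MES", "AMO"): 0.0002, ("AMO", "MES"): 0.0002,
    })
    cfg = SimulationConfig(transition_model=model, motion=_pa_motion(),
                           shapes=_pa_shapes(), condition_label="PA40kPa")
    return cfg.with_(**overrides) if overrides else cfg
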