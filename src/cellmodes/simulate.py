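"""Synthetic single-cell mask movies with known behavioral ground truth.

Each simulated cell is driven by a per-frame Markov chain over the three
behavioral states.  The centroid follows a persistent random walk whose
per-state speed is log-normal (parameterized by its median) and whose
heading turns by a wrapped-normal angle each frame.  The outline is a
star-convex radial profile: a base ellipse modulated by low-order Fourier
boundary noise and state-specific protrusions —

* MES: a leading fan of bumps ahead of the (smoothed) heading whose
  amplitude ramps up and resets, emulating protrusion–attachment cycles;
  the body orientation tracks the heading slowly.
* POL: 2–5 lobes at fixed directions breathing slowly in phase, giving
  multidirectional border extension with little net centroid
  displacement; the measured centroid additionally scatters around the
  motion track (shape-driven centroid noise, largest for this state).
* AMO: a small body whose boundary modes and bumps are re-sampled nearly
  every frame (``shape_turnover`` high), producing the frame-to-frame
  shape instability of blebbing/pseudopodial cells.

The polygon is affinely corrected — once per state visit, against a
nominal protrusion pattern — so its moment-equivalent ellipse sits on
the per-cell target elongation and area, which keeps the downstream
morphometric distributions on the configured per-state targets while
letting the per-frame protrusion dynamics express freely.  Where a
state has shape-driven centroid noise, the intrinsic walk speed is
reduced (via the Rice-distribution median) so that the *measured*
per-frame speed median stays on the configured value.

Trajectories that would leave the canvas margin are reflected (folded)
back inside, with a log warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import draw, measure

from .params import STATES, MotionParams, ShapeParams, SimulationConfig, TransitionModel

logger = logging.getLogger(__name__)

_N_PHI = 180
_PHI = np.linspace(0.0, 2.0 * np.pi, _N_PHI, endpoint=False)
_LOBE_KAPPA = 10.0          # angular concentration of protrusion lobes/blebs
_FAN_KAPPA = 8.0            # angular concentration of the leading-fan bumps
_FAN_SPREAD = 25.0          # half-width (deg) of leading-fan bump offsets
_ORIENT_EMA = 0.02          # per-frame body re-orientation rate toward heading


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# Markov chain and track
# ---------------------------------------------------------------------------

def simulate_state_sequence(model: TransitionModel, n_frames: int,
                            rng_seed) -> np.ndarray:
    """Sample a state-label sequence of length ``n_frames`` from the chain.

    The first state is drawn from ``model.pi``; each subsequent state
    from the row of ``model.T`` for the current state.  Deterministic
    given the seed.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = _rng(rng_seed)
    k = len(model.states)
    idx = np.empty(n_frames, dtype=np.int64)
    idx[0] = rng.choice(k, p=model.pi)
    for t in range(1, n_frames):
        idx[t] = rng.choice(k, p=model.T[idx[t - 1]])
    return np.asarray(model.states, dtype="U3")[idx]


def simulate_track(states: np.ndarray, motion: dict[str, MotionParams],
                   dt_s: float, rng_seed, return_headings: bool = False):
    """Persistent-random-walk centroid path (µm) for a state sequence.

    The step from frame n to n+1 uses the state at frame n: step length
    = speed·dt with speed drawn log-normally around the state's median
    speed; the heading turns by a wrapped-normal angle with the state's
    drift and spread.
    """
    states = np.asarray(states)
    if states.size == 0:
        raise ValueError("states must be nonempty")
    if dt_s <= 0:
        raise ValueError("dt must be > 0")
    rng = _rng(rng_seed)
    n = states.size
    pos = np.zeros((n, 2))
    headings = np.zeros(n)
    heading = rng.uniform(0.0, 360.0)
    for t in range(n - 1):
        m = motion[str(states[t])]
        speed = m.median_speed * np.exp(m.speed_sigma_log * rng.standard_normal())
        heading = heading + m.turning_drift_deg \
            + m.turning_sigma_deg * rng.standard_normal()
        heading = (heading + 180.0) % 360.0 - 180.0
        step = speed * (dt_s / 60.0)
        rad = np.radians(heading)
        pos[t + 1] = pos[t] + step * np.array([np.cos(rad), np.sin(rad)])
        headings[t] = heading
    headings[n - 1] = headings[n - 2] if n > 1 else heading
    if return_headings:
        return pos, headings
    return pos


def _fold(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (triangle-wave folding)."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    return lo + np.where(y <= span, y, 2.0 * span - y)


# ---------------------------------------------------------------------------
# Shape engine
# ---------------------------------------------------------------------------

def _polygon_geometry(xy: np.ndarray):
    """Area, centroid and central second moments of a polygon (Green's
    theorem); vertices (n, 2) as (x, y), CCW positive area."""
    x, y = xy[:, 0], xy[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cr = x * y1 - x1 * y
    area = 0.5 * cr.sum()
    cx = ((x + x1) * cr).sum() / (6.0 * area)
    cy = ((y + y1) * cr).sum() / (6.0 * area)
    ixx = ((x * x + x * x1 + x1 * x1) * cr).sum() / 12.0
    iyy = ((y * y + y * y1 + y1 * y1) * cr).sum() / 12.0
    ixy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cr).sum() / 24.0
    sxx = ixx / area - cx * cx
    syy = iyy / area - cy * cy
    sxy = ixy / area - cx * cy
    return area, (cx, cy), (sxx, syy, sxy)


class _ShapeEngine:
    """Per-cell stateful outline generator (one instance per movie).

    The affine correction that puts the moment ellipse on the per-cell
    target elongation and area is calibrated once per state visit (on a
    nominal protrusion pattern) and then held fixed, so that per-frame
    protrusion dynamics — the signal the classifier reads — express
    naturally instead of being cancelled frame by frame.
    """

    _AREA_AR_PHI = 0.99     # slow per-frame area modulation
    _AREA_AR_SD = 0.25      # fraction of the state's area log-spread

    def __init__(self, shapes: dict[str, ShapeParams], pixel_size: float,
                 rng: np.random.Generator):
        self.shapes = shapes
        self.ps = pixel_size
        self.rng = rng
        self.state: str | None = None
        self.orient = rng.uniform(-180.0, 180.0)
        self.ar_area = 0.0
        self.cell_area: dict[str, float] = {}
        self.cell_eps: dict[str, float] = {}

    # -- protrusion patterns -------------------------------------------------
    def _enter_state(self, state: str):
        sp = self.shapes[state]
        rng = self.rng
        if state not in self.cell_area:
            self.cell_area[state] = sp.median_area * np.exp(
                0.8 * sp.area_sigma_log * rng.standard_normal())
            self.cell_eps[state] = float(np.clip(
                sp.target_elongation + sp.elongation_spread * rng.standard_normal(),
                0.0, 0.88))
        self.state = state
        if state == "MES":
            self._fan_offsets = rng.uniform(-_FAN_SPREAD, _FAN_SPREAD, size=3)
            self._fan_amps = rng.uniform(0.6, 1.0, size=3)
            self._fan_phase = int(rng.integers(0, 6))
        elif state == "POL":
            k = int(rng.integers(sp.lobe_count[0], sp.lobe_count[1] + 1))
            base = rng.uniform(0.0, 360.0)
            jitter = 4.0 if k == 2 else 10.0    # bigonal lobes stay antipodal
            self._lobe_angles = (base + np.arange(k) * 360.0 / k
                                 + rng.uniform(-jitter, jitter, size=k))
            # lobes breathe slowly and in phase: the border advances in
            # several directions at once, a fraction of a pixel per frame
            self._breath_period = float(rng.uniform(14.0, 24.0))
            self._breath_phase = float(rng.uniform(0.0, 1.0))
            self._t = 0
        else:  # AMO
            self._resample_blebs()
        self._resample_noise()
        self._calibrate()

    def _resample_noise(self):
        rng = self.rng
        ks = np.arange(2, 7)
        amps = rng.uniform(0.5, 1.0, size=ks.size) / ks
        amps *= self.shapes[self.state].boundary_noise_amp / \
            np.sqrt(0.5 * (amps ** 2).sum())
        self._noise_k = ks
        self._noise_amp = amps
        self._noise_phase = rng.uniform(0.0, 2.0 * np.pi, size=ks.size)

    def _resample_blebs(self):
        rng = self.rng
        k = int(rng.integers(self.shapes["AMO"].lobe_count[0],
                             self.shapes["AMO"].lobe_count[1] + 1))
        self._bleb_angles = rng.uniform(0.0, 360.0, size=k)
        self._bleb_amps = rng.uniform(0.3, 1.0, size=k) * \
            self.shapes["AMO"].lobe_amp
        # the apparent cell axis of a blebbing cell flips with the bleb
        # pattern; its elongation scatters around the state median
        self._amo_orient = rng.uniform(0.0, 360.0)
        eps0 = self.cell_eps.get("AMO", self.shapes["AMO"].target_elongation)
        self._amo_eps = float(np.clip(
            eps0 + 0.20 * rng.standard_normal(), 0.05, 0.78))

    # -- per-frame update ----------------------------------------------------
    def step(self, state: str, heading_deg: float) -> None:
        if state != self.state:
            self._enter_state(state)
        sp = self.shapes[state]
        rng = self.rng
        phi = self._AREA_AR_PHI
        self.ar_area = phi * self.ar_area + np.sqrt(1 - phi ** 2) * \
            self._AREA_AR_SD * sp.area_sigma_log * rng.standard_normal()
        if state == "POL":
            # body orientation drifts on its own, decoupled from heading
            self.orient += rng.normal(0.0, 1.5)
            self._t += 1
            if rng.random() < sp.shape_turnover:
                j = rng.integers(len(self._lobe_angles))
                self._lobe_angles[j] = rng.uniform(0.0, 360.0)
        else:
            delta = (heading_deg - self.orient + 180.0) % 360.0 - 180.0
            self.orient += _ORIENT_EMA * delta
            if state == "MES":
                # protrusion-attachment cycle: the fan extends a little
                # further every frame until it collapses and a fresh fan
                # starts in a (slightly) new direction
                # phases run 0..5 (ramp 0.2→1.0) with an optional early
                # collapse near the top, so the stationary phase law stays
                # near-uniform and the mid-ramp calibration unbiased
                self._fan_phase += 1
                if self._fan_phase >= 6 or (self._fan_phase >= 4 and
                                            rng.random() < sp.shape_turnover):
                    self._fan_phase = 0
                    self._fan_offsets = rng.uniform(-_FAN_SPREAD, _FAN_SPREAD, size=3)
                    self._fan_amps = rng.uniform(0.6, 1.0, size=3)
            else:  # AMO
                if rng.random() < sp.shape_turnover:
                    self._resample_blebs()
                    self._resample_noise()

    # -- rendering -----------------------------------------------------------
    def _raw_outline(self, state: str, nominal: bool = False) -> np.ndarray:
        """Uncorrected polygon (µm) around the origin.  With ``nominal``
        the time-varying protrusion amplitudes are set to mid-cycle
        values (used to calibrate the per-visit affine correction)."""
        sp = self.shapes[state]
        area0 = self.cell_area[state]
        eps0 = self.cell_eps[state]
        rho = 1.0 / (1.0 - eps0)
        b = np.sqrt(area0 / (np.pi * rho))
        a = rho * b
        th = _PHI - np.radians(self.orient)
        r = a * b / np.sqrt((b * np.cos(th)) ** 2 + (a * np.sin(th)) ** 2)
        noise = np.zeros(_N_PHI)
        for k, amp, ph in zip(self._noise_k, self._noise_amp, self._noise_phase):
            noise += amp * np.cos(k * _PHI + ph)
        lobes = np.zeros(_N_PHI)
        if state == "MES":
            ramp = 0.6 if nominal else 0.2 + 0.8 * min(self._fan_phase / 5.0, 1.0)
            for off, amp in zip(self._fan_offsets, self._fan_amps):
                d = _PHI - np.radians(self.orient + off)
                lobes += sp.lobe_amp * amp * ramp * \
                    np.exp(_FAN_KAPPA * (np.cos(d) - 1.0))
        elif state == "POL":
            amp = 0.55 if nominal else 0.55 + 0.45 * np.sin(
                2 * np.pi * (self._t / self._breath_period + self._breath_phase))
            for ang in self._lobe_angles:
                d = _PHI - np.radians(ang)
                lobes += sp.lobe_amp * amp * np.exp(_LOBE_KAPPA * (np.cos(d) - 1.0))
        else:  # AMO
            for ang, amp in zip(self._bleb_angles, self._bleb_amps):
                d = _PHI - np.radians(ang)
                lobes += amp * np.exp(_LOBE_KAPPA * (np.cos(d) - 1.0))
        r = r * np.clip(1.0 + noise, 0.25, None) * (1.0 + lobes)
        return np.column_stack([r * np.cos(_PHI), r * np.sin(_PHI)])

    def _apply_affine(self, xy: np.ndarray, corr: np.ndarray,
                      scale: float) -> np.ndarray:
        """Apply the frozen body-frame correction matrix at the current
        orientation, then a uniform scale; return re-centered vertices."""
        _, (cx, cy), _ = _polygon_geometry(xy)
        p = xy - (cx, cy)
        th = np.radians(self.orient)
        rot = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
        q = (p @ rot.T) @ corr.T
        p = (q @ rot) * scale
        _, (cx, cy), _ = _polygon_geometry(p)
        return p - (cx, cy)

    def _whiten_outline(self, xy: np.ndarray) -> np.ndarray:
        """Map the polygon's second moments exactly onto the target
        ellipse (elongation along the current orientation, target area).

        Used for the amoeboid state, whose transient bleb patterns have
        anisotropy along arbitrary axes that a fixed axis-aligned
        stretch cannot normalize.
        """
        state = self.state
        _, (cx, cy), (sxx, syy, sxy) = _polygon_geometry(xy)
        p = xy - (cx, cy)
        C = np.array([[sxx, sxy], [sxy, syy]])
        w, V = np.linalg.eigh(C)
        w = np.clip(w, 1e-12, None)
        inv_sqrt = V @ np.diag(w ** -0.5) @ V.T
        rho = 1.0 / (1.0 - self._amo_eps)
        th = np.radians(self._amo_orient)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        target_half = R @ np.diag([np.sqrt(rho), np.sqrt(1.0 / rho)]) @ R.T
        p = p @ (target_half @ inv_sqrt).T
        area, (cx, cy), _ = _polygon_geometry(p)
        p = (p - (cx, cy)) * np.sqrt(self.cell_area[state] / abs(area))
        return p

    def _calibrate(self):
        """Fix the per-visit body-frame correction matrix and scale so a
        nominal-pattern outline hits the cell's target elongation (full
        covariance whitening, cross moments included) and area exactly."""
        state = self.state
        xy = self._raw_outline(state, nominal=True)
        _, (cx, cy), _ = _polygon_geometry(xy)
        p = xy - (cx, cy)
        th = np.radians(self.orient)
        rot = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
        q = p @ rot.T
        _, _, (sxx, syy, sxy) = _polygon_geometry(q)
        C = np.array([[sxx, sxy], [sxy, syy]])
        w, V = np.linalg.eigh(C)
        w = np.clip(w, 1e-12, None)
        inv_sqrt = V @ np.diag(w ** -0.5) @ V.T
        rho = 1.0 / (1.0 - self.cell_eps[state])
        self._corr = np.diag([np.sqrt(rho), np.sqrt(1.0 / rho)]) @ inv_sqrt
        area, _, _ = _polygon_geometry(self._apply_affine(xy, self._corr, 1.0))
        self._scale = float(np.sqrt(self.cell_area[state] / abs(area)))

    def outline_px(self, state: str) -> np.ndarray:
        """Centered polygon vertices (x, y) in pixels for the current frame."""
        xy = self._raw_outline(state)
        if state == "AMO":
            return self._whiten_outline(xy) * np.exp(self.ar_area / 2.0) / self.ps
        scale = self._scale * np.exp(self.ar_area / 2.0)
        return self._apply_affine(xy, self._corr, scale) / self.ps


def _rasterize(xy_px: np.ndarray, centroid_px: tuple[float, float],
               canvas: tuple[int, int]) -> np.ndarray:
    rows = xy_px[:, 1] + centroid_px[1]
    cols = xy_px[:, 0] + centroid_px[0]
    rr, cc = draw.polygon(rows, cols, shape=canvas)
    mask = np.zeros(canvas, dtype=bool)
    mask[rr, cc] = True
    labels, n = measure.label(mask, connectivity=2, return_num=True)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == np.argmax(counts)
    return mask


def render_mask(state: str, centroid_px: tuple[float, float], heading_deg: float,
                shape: ShapeParams, pixel_size: float = 1.0,
                canvas: tuple[int, int] = (256, 256), rng_seed=0) -> np.ndarray:
    """Render one binary mask for a cell in ``state`` at ``centroid_px``.

    One-shot functional form of the stateful engine; successive frames of
    a movie should instead be rendered through :func:`simulate_cell` so
    the protrusion pattern persists between frames.
    """
    rng = _rng(rng_seed)
    engine = _ShapeEngine({s: shape for s in STATES}, pixel_size, rng)
    engine.step(state, heading_deg)
    return _rasterize(engine.outline_px(state), centroid_px, canvas)


# ---------------------------------------------------------------------------
# Whole experiments
# ---------------------------------------------------------------------------

@dataclass
class CellMovie:
    """One simulated cell: mask stack plus ground truth and annotations."""

    cell_id: str
    states: np.ndarray          # (n,) ground-truth labels
    track_um: np.ndarray        # (n, 2) simulated centroid path, µm
    masks: np.ndarray | None    # (n, H, W) bool
    annotations: pd.DataFrame   # frame, contact, dividing
    individual: bool = True


@dataclass
class SimulatedDataset:
    cells: list[CellMovie]
    config: SimulationConfig


def _intrinsic_speed_median(measured_um_min: float, sigma_j_um: float,
                            dt_s: float) -> float:
    """Walk-speed median whose mask-measured counterpart, after adding
    iid centroid scatter of s.d. ``sigma_j_um`` per axis per frame, has
    the requested median (per-frame displacement is Rice-distributed)."""
    if sigma_j_um <= 0:
        return measured_um_min
    from scipy.optimize import brentq
    from scipy.stats import rice
    tau = sigma_j_um * np.sqrt(2.0)      # s.d. of the jitter *difference*
    dt_min = dt_s / 60.0
    step_target = measured_um_min * dt_min
    floor = float(rice.median(1e-9, scale=tau))
    if step_target <= floor * 1.02:
        return 0.05 * measured_um_min    # jitter alone exceeds the target
    f = lambda s: float(rice.median(s / tau, scale=tau)) - step_target
    s = brentq(f, 1e-9, step_target)
    return s / dt_min


def render_movie(states: np.ndarray, config: SimulationConfig,
                 rng_seed) -> tuple[np.ndarray, np.ndarray]:
    """Render a mask movie for a given state sequence.

    Simulates the centroid walk (with the Rice-median speed
    compensation for states with shape-driven centroid scatter), folds
    it into the canvas margin, and renders every frame through the
    stateful shape engine.  Returns ``(track_um, masks)`` where the
    track is the simulated (jitter-free) centroid path.
    """
    rng = _rng(rng_seed)
    states = np.asarray(states)
    n = states.size
    from dataclasses import replace as _replace
    motion_eff = {
        s: _replace(m, median_speed=_intrinsic_speed_median(
            m.median_speed, config.shapes[s].centroid_noise_um, config.dt))
        for s, m in config.motion.items()}
    track, _ = simulate_track(states, motion_eff, config.dt, rng,
                              return_headings=True)
    h, w = config.canvas
    ps = config.pixel_size
    pos_px = track / ps
    pos_px = pos_px - pos_px[0] + np.array([w / 2.0, h / 2.0])
    lo = float(config.margin)
    folded = np.column_stack([
        _fold(pos_px[:, 0], lo, w - 1.0 - lo),
        _fold(pos_px[:, 1], lo, h - 1.0 - lo),
    ])
    if not np.allclose(folded, pos_px):
        logger.warning("trajectory reflected at canvas margin")
    pos_px = folded
    # headings recomputed on the folded path so masks face actual motion
    d = np.diff(pos_px, axis=0)
    head = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    head = np.append(head, head[-1] if head.size else 0.0)
    engine = _ShapeEngine(dict(config.shapes), ps, rng)
    masks = np.zeros((n, h, w), dtype=bool)
    for t in range(n):
        s = str(states[t])
        engine.step(s, float(head[t]))
        jit = rng.normal(0.0, config.shapes[s].centroid_noise_um / ps, size=2)
        masks[t] = _rasterize(engine.outline_px(s), pos_px[t] + jit, (h, w))
    return pos_px * ps, masks


def simulate_cell(config: SimulationConfig, index: int) -> CellMovie:
    """Simulate one cell movie; the per-cell seed derives deterministically
    from ``(config.rng_seed, index)``."""
    rng = np.random.default_rng(np.random.SeedSequence((config.rng_seed, index)))
    states = simulate_state_sequence(config.transition_model, config.n_frames, rng)
    track_um, masks = render_movie(states, config, rng)
    contact = rng.random(config.n_frames) < config.contact_rate
    dividing = np.zeros(config.n_frames, dtype=bool)
    if rng.random() < config.division_rate:
        dividing[rng.integers(config.n_frames)] = True
    ann = pd.DataFrame({"frame": np.arange(config.n_frames),
                        "contact": contact, "dividing": dividing})
    return CellMovie(cell_id=f"cell_{index:03d}", states=states,
                     track_um=track_um, masks=masks, annotations=ann)


def iter_cells(config: SimulationConfig):
    """Yield cells one at a time (memory-light alternative to
    :func:`simulate_experiment` for large benchmarks)."""
    for i in range(config.n_cells):
        yield simulate_cell(config, i)


def simulate_experiment(config: SimulationConfig, outdir=None,
                        keep_masks: bool = True) -> SimulatedDataset:
    """Simulate ``config.n_cells`` independent movies.

    When ``outdir`` is given, writes per-cell multi-page TIFFs (uint8,
    0/255), ``truth.csv`` (cell_id, frame, state, x_um, y_um),
    ``annotations.csv`` and a ``manifest.yaml`` echoing the full config.
    """
    from . import io as cio
    cells = []
    for i in range(config.n_cells):
        cell = simulate_cell(config, i)
        cells.append(cell if keep_masks else
                     CellMovie(cell.cell_id, cell.states, cell.track_um,
                               None, cell.annotations))
        if outdir is not None:
            cio.write_cell_tiff(outdir, cell, config)
    ds = SimulatedDataset(cells=cells, config=config)
    if outdir is not None:
        cio.write_dataset_tables(outdir, ds)
    return ds
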