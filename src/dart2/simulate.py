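"""Agent-based synthetic two-choice assay.

Flies in a 150 mm tube are modeled as a biased random walk along the
tube axis.  Position updates follow the Euler discretization

    x[t + dt] = x[t] + kappa * (1 - exp(-t / tau)) * dt + sigma * sqrt(dt) * xi

with reflecting boundaries at the tube ends.  ``kappa`` is the drift
speed away from the odorant (positive = toward the solvent end, i.e.
aversion), ramped in with time constant ``tau`` to emulate the gradual
build-up of avoidance over the first ~20 min of an assay; ``sigma`` is
the diffusive motility; ``xi`` is standard Gaussian noise.  Crowding is
modeled as a pairwise soft-core repulsion: flies closer than the
exclusion distance ``d_ex`` push each other apart by half the overlap,
a displacement that decays linearly to zero at ``d_ex``.  At high
occupancy this packs the aversive end and forces part of the group back
toward the odorant, reproducing the slight drop in average CoM seen
with 32-64 flies per tube.  A per-replicate jitter on the drift
(``drift_jitter``) represents tube-to-tube variability in odor loading
and handling; it bounds from below the replicate-to-replicate variance
of the mean CoM, so that variance stops improving beyond ~8-16 flies.

The stationary density of the (jitter- and crowding-free) walk on
[0, L] is exponential, p(x) proportional to exp(2*kappa*x/sigma^2), which
gives a closed form for the steady-state mean CoM and is used by
:func:`estimate_drift` to recover ``kappa`` from observed traces.

A single seed governs initial positions, dynamics noise and the
per-replicate drift jitter through spawned substreams, so identical
configurations reproduce identical trajectories bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .tracking import TubeGeometry

PATTERN_SUPPORT: dict[str, Tuple[float, float]] = {
    "homogeneous": (0.0, 1.0),
    "right_cluster": (0.9, 1.0),
    "left_cluster": (0.0, 0.1),
    "right_bias": (0.5, 1.0),
    "left_bias": (0.0, 0.5),
    "slight_right_bias": (0.5, 0.75),
    "slight_left_bias": (0.25, 0.5),
}
"""Supports (normalized, odorant end = 0) of the canonical fly
distributions used to anchor the CoM scale: clusters occupy the outer
tenth of the tube, biases one half, slight biases the inner quarter of
one half."""


@dataclass(frozen=True)
class AssaySimConfig:
    """Parameters of one synthetic assay tube.

    Attributes
    ----------
    n_flies:
        Flies per tube (1-64 in the calibration sweeps).
    duration_s, fps:
        Recording length and frame rate; a 60 min assay at 1 frame/s is
        the default.
    tube_length_mm:
        Tube length (odorant cap at 0 mm).
    drift_mm_s:
        Drift speed ``kappa``; positive values move flies toward the
        solvent end (aversion).
    onset_tau_s:
        Time constant of the exponential ramp with which the drift turns
        on after odor application.
    diffusion_mm_sqrt_s:
        Diffusive motility ``sigma`` in mm per sqrt-second.
    crowding_radius_mm:
        Soft exclusion distance ``d_ex``; 0 disables crowding.
    drift_jitter_mm_s:
        SD of the per-replicate (per-tube) perturbation added to the
        drift; models odor-loading and handling variability shared by
        all flies in a tube.
    seed:
        Master seed; identical configs give identical trajectories.
    """

    n_flies: int = 16
    duration_s: float = 3600.0
    fps: float = 1.0
    tube_length_mm: float = 150.0
    drift_mm_s: float = 0.25
    onset_tau_s: float = 420.0
    diffusion_mm_sqrt_s: float = 4.5
    crowding_radius_mm: float = 3.0
    drift_jitter_mm_s: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_flies) != self.n_flies or self.n_flies < 1:
            raise ValueError(f"n_flies must be an integer >= 1, got {self.n_flies}")
        for name in (
            "duration_s",
            "fps",
            "tube_length_mm",
            "drift_mm_s",
            "onset_tau_s",
            "diffusion_mm_sqrt_s",
            "crowding_radius_mm",
            "drift_jitter_mm_s",
        ):
            val = getattr(self, name)
            if not math.isfinite(float(val)):
                raise ValueError(f"{name} must be finite, got {val!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.tube_length_mm <= 0:
            raise ValueError("tube_length_mm must be positive")
        if self.onset_tau_s <= 0:
            raise ValueError("onset_tau_s must be positive")
        if self.diffusion_mm_sqrt_s < 0:
            raise ValueError("diffusion must be non-negative")
        if self.crowding_radius_mm < 0:
            raise ValueError("crowding_radius_mm must be non-negative")
        if self.drift_jitter_mm_s < 0:
            raise ValueError("drift_jitter_mm_s must be non-negative")

    @property
    def n_frames(self) -> int:
        """Number of recorded frames: duration_s * fps + 1 (frame at t=0)."""
        return int(round(self.duration_s * self.fps)) + 1


@dataclass(frozen=True)
class FlyTrajectory:
    """Per-fly position paths: one row per fly, one column per frame (mm)."""

    positions: np.ndarray
    times: np.ndarray
    tube_length_mm: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.float64)
        t = np.asarray(self.times, dtype=np.float64)
        if pos.ndim != 2 or t.ndim != 1 or pos.shape[1] != t.size:
            raise ValueError("positions must be (n_flies, n_frames) matching times")
        if pos.size and (pos.min() < -1e-9 or pos.max() > self.tube_length_mm + 1e-9):
            raise ValueError("positions must lie within [0, tube_length_mm]")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "times", t)

    @property
    def n_flies(self) -> int:
        return int(self.positions.shape[0])

    def com_values(self) -> np.ndarray:
        """Point-mass normalized CoM per frame (mean position / length)."""
        return self.positions.mean(axis=0) / self.tube_length_mm


@dataclass(frozen=True)
class CanonicalPattern:
    """A named canonical spatial distribution with sampled positions."""

    name: str
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.name not in PATTERN_SUPPORT:
            raise ValueError(
                f"unknown pattern {self.name!r}; known: {sorted(PATTERN_SUPPORT)}"
            )
        pos = np.asarray(self.positions, dtype=np.float64)
        lo, hi = PATTERN_SUPPORT[self.name]
        if pos.size and (pos.min() < lo or pos.max() > hi):
            raise ValueError(f"positions escape the {self.name!r} support [{lo}, {hi}]")
        object.__setattr__(self, "positions", pos)


def canonical_positions(name: str, n: int, seed: int = 0) -> CanonicalPattern:
    """Draw ``n`` normalized positions uniformly from a named support.

    The vocabulary (``homogeneous``, ``left/right_cluster``,
    ``left/right_bias``, ``slight_left/right_bias``) mirrors the sample
    distributions used to anchor the CoM scale; see
    :data:`PATTERN_SUPPORT` for the supports.
    """
    if name not in PATTERN_SUPPORT:
        raise ValueError(f"unknown pattern {name!r}; known: {sorted(PATTERN_SUPPORT)}")
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = PATTERN_SUPPORT[name]
    rng = np.random.default_rng(seed)
    return CanonicalPattern(name=name, positions=rng.uniform(lo, hi, size=n))


def _reflect(x: np.ndarray, L: float) -> np.ndarray:
    x = np.abs(x)
    return L - np.abs(L - x)


def _crowding_push(x: np.ndarray, d_ex: float) -> np.ndarray:
    """Summed pairwise soft-core displacements along the last axis.

    Each pair closer than ``d_ex`` pushes both members apart by half the
    overlap; coincident flies (distance exactly 0) exert no force and
    are separated by the dynamics noise on the next step.
    """
    diff = x[..., :, None] - x[..., None, :]
    overlap = d_ex - np.abs(diff)
    np.clip(overlap, 0.0, None, out=overlap)
    return 0.5 * (overlap * np.sign(diff)).sum(axis=-1)


def _simulate_batch(
    config: AssaySimConfig, n_replicates: int, keep_positions: bool
) -> Tuple[np.ndarray, Optional[np.ndarray], np.ndarray]:
    """Run ``n_replicates`` independent tubes with the same parameters.

    Returns ``(times, positions or None, com)`` where ``positions`` has
    shape (reps, n_flies, n_frames) and ``com`` (reps, n_frames).
    Replicates share nothing but the parameter values; each has its own
    initial positions, dynamics noise and drift jitter, all derived from
    ``config.seed`` through spawned substreams.
    """
    ss_init, ss_dyn, ss_jit = np.random.SeedSequence(config.seed).spawn(3)
    rng_init = np.random.default_rng(ss_init)
    rng_dyn = np.random.default_rng(ss_dyn)
    rng_jit = np.random.default_rng(ss_jit)

    n = int(config.n_flies)
    L = float(config.tube_length_mm)
    dt = 1.0 / config.fps
    n_steps = config.n_frames - 1
    sig_dt = config.diffusion_mm_sqrt_s * math.sqrt(dt)
    d_ex = config.crowding_radius_mm

    kappa = config.drift_mm_s + config.drift_jitter_mm_s * rng_jit.standard_normal(n_replicates)
    kappa = kappa[:, None]  # broadcast over flies

    x = rng_init.uniform(0.0, L, size=(n_replicates, n))
    com = np.empty((n_replicates, n_steps + 1))
    com[:, 0] = x.mean(axis=1) / L
    positions = None
    if keep_positions:
        positions = np.empty((n_replicates, n, n_steps + 1))
        positions[:, :, 0] = x

    tau = config.onset_tau_s
    for k in range(1, n_steps + 1):
        t_prev = (k - 1) * dt
        ramp = 1.0 - math.exp(-t_prev / tau)
        x = x + kappa * ramp * dt + sig_dt * rng_dyn.standard_normal((n_replicates, n))
        x = _reflect(x, L)
        if d_ex > 0.0 and n > 1:
            x = x + _crowding_push(x, d_ex)
            np.clip(x, 0.0, L, out=x)
        com[:, k] = x.mean(axis=1) / L
        if keep_positions:
            positions[:, :, k] = x  # type: ignore[index]

    times = np.arange(n_steps + 1) * dt
    return times, positions, com


def simulate_trajectories(config: AssaySimConfig) -> FlyTrajectory:
    """Simulate one tube and return the full per-fly position paths."""
    times, positions, _ = _simulate_batch(config, n_replicates=1, keep_positions=True)
    assert positions is not None
    return FlyTrajectory(positions=positions[0], times=times, tube_length_mm=config.tube_length_mm)


def simulate_com_series(config: AssaySimConfig, n_replicates: int = 1) -> Tuple[np.ndarray, np.ndarray]:
    """Simulate replicate tubes, returning only the point-mass CoM traces.

    Returns ``(times, com)`` with ``com`` of shape (n_replicates,
    n_frames).  Equivalent to tracking each replicate with an ideal
    point-mass tracker; avoids materializing full position arrays for
    large sweeps.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    times, _, com = _simulate_batch(config, n_replicates, keep_positions=False)
    return times, com


def stationary_mean_com(drift_mm_s: float, diffusion_mm_sqrt_s: float, tube_length_mm: float) -> float:
    """Mean normalized CoM of the stationary drift-diffusion density.

    The stationary density on [0, L] is proportional to
    ``exp(2 * kappa * x / sigma^2)``; its normalized mean is
    ``e^y/(e^y - 1) - 1/y`` with ``y = 2 * kappa * L / sigma^2``.
    """
    if diffusion_mm_sqrt_s <= 0:
        raise ValueError("diffusion must be positive")
    y = 2.0 * drift_mm_s * tube_length_mm / diffusion_mm_sqrt_s**2
    if abs(y) < 1e-9:
        return 0.5
    return float(math.exp(y) / math.expm1(y) - 1.0 / y)


def estimate_drift(
    steady_state_mean_com: float,
    diffusion_mm_sqrt_s: float,
    tube_length_mm: float,
) -> float:
    """Invert the stationary mean CoM for the drift speed ``kappa``.

    Assumes independent flies (no crowding) and a known motility
    ``sigma``.  The observed steady-state mean (e.g. a window average
    over the plateau of the trace, averaged over replicates) determines
    the shape parameter ``y`` of the stationary exponential density,
    hence ``kappa = y * sigma^2 / (2 * L)``.
    """
    c = float(steady_state_mean_com)
    if not 0.0 < c < 1.0:
        raise ValueError("steady-state mean CoM must lie strictly inside (0, 1)")
    if abs(c - 0.5) < 1e-12:
        return 0.0

    def f(y: float) -> float:
        if abs(y) < 1e-9:
            return 0.5 - c
        return math.exp(y) / math.expm1(y) - 1.0 / y - c

    y = brentq(f, -700.0, 700.0, xtol=1e-12)
    return float(y * diffusion_mm_sqrt_s**2 / (2.0 * tube_length_mm))


def render_frames(
    traj: FlyTrajectory,
    geometry: TubeGeometry,
    fly_radius_px: int = 3,
    fly_intensity: int = 220,
    background: int = 30,
    noise_sd: float = 4.0,
    seed: int = 0,
    frame_height: int = 40,
    frame_width: Optional[int] = None,
    row_mode: str = "uniform",
) -> np.ndarray:
    """Render a trajectory as an 8-bit grayscale frame stack.

    Each fly is drawn as a disc of ``fly_radius_px`` at the frame column
    mapped from its lengthwise position; only the lengthwise coordinate
    carries signal, so the transverse row is either placed uniformly at
    random (``row_mode="uniform"``) or assigned to disjoint transverse
    lanes (``row_mode="lanes"``).  With uniform rows, flies that come
    within a disc diameter of each other can occlude: their discs merge
    into one blob and the pixel-weighted CoM is then down-weighted for
    that pair, exactly as occluding real flies are.  Lane placement
    guarantees non-overlapping discs (it requires a frame tall enough
    for ``n_flies`` lanes) and is what makes the render-then-track
    roundtrip accurate to within one fly radius.

    Additive Gaussian noise of ``noise_sd`` is applied; configurations
    whose fly/background contrast is less than 10 noise SDs are rejected
    because flies could then not be separated from background by a fixed
    threshold.  A threshold at ``(fly_intensity + background) / 2``
    recovers the flies.
    """
    from skimage.draw import disk

    if fly_radius_px < 1:
        raise ValueError("fly_radius_px must be >= 1")
    contrast = abs(float(fly_intensity) - float(background))
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if contrast < 10.0 * max(noise_sd, 1e-12):
        raise ValueError(
            f"fly_intensity {fly_intensity} and background {background} are separated by "
            f"{contrast} gray levels but the noise SD is {noise_sd}; flies would be "
            "indistinguishable from background (need contrast >= 10 * noise_sd)"
        )
    W = frame_width if frame_width is not None else geometry.c1 + 1 + geometry.c0
    if geometry.c1 >= W:
        raise ValueError("frame_width must exceed the tube span")
    H = int(frame_height)
    if H < 2 * fly_radius_px + 2:
        raise ValueError("frame_height too small for the fly radius")

    if row_mode not in ("uniform", "lanes"):
        raise ValueError(f"row_mode must be 'uniform' or 'lanes', got {row_mode!r}")
    rng = np.random.default_rng(seed)
    L = geometry.length_px
    n_frames = traj.times.size
    u = traj.positions / traj.tube_length_mm
    off = np.rint(np.clip(u, 0.0, 1.0) * (L - 1)).astype(np.int64)
    if geometry.odorant_end == "low":
        cols = geometry.c0 + off
    else:
        cols = geometry.c1 - off
    # A fly's body cannot protrude past the tube caps: clamp disc centers
    # one radius inside the span.  Every fly then contributes a full disc,
    # so no fly is down-weighted in the pixel CoM by boundary clipping,
    # and the displacement is at most one radius for flies at the caps.
    if L <= 2 * fly_radius_px:
        raise ValueError("tube span too narrow for the fly radius")
    cols = np.clip(cols, geometry.c0 + fly_radius_px, geometry.c1 - fly_radius_px)

    lane_h = 2 * fly_radius_px + 1
    if row_mode == "lanes":
        n_lanes = (H - 1) // lane_h
        if traj.n_flies > n_lanes:
            raise ValueError(
                f"frame_height {H} offers only {n_lanes} non-overlapping lanes for "
                f"radius {fly_radius_px}; need {traj.n_flies}"
            )

    stack = np.empty((n_frames, H, W), dtype=np.uint8)
    lo_row, hi_row = fly_radius_px, H - 1 - fly_radius_px
    for f in range(n_frames):
        img = np.full((H, W), float(background))
        if row_mode == "lanes" and traj.n_flies > 0:
            lanes = rng.permutation((H - 1) // lane_h)[: traj.n_flies]
            rows = fly_radius_px + lanes * lane_h
        else:
            rows = rng.integers(lo_row, hi_row + 1, size=max(traj.n_flies, 1))
        for i in range(traj.n_flies):
            rr, cc = disk((int(rows[i]), int(cols[i, f])), fly_radius_px + 0.5, shape=(H, W))
            img[rr, cc] = float(fly_intensity)
        if noise_sd > 0:
            img += noise_sd * rng.standard_normal((H, W))
        stack[f] = np.clip(img, 0, 255).astype(np.uint8)
    return stack


def suggested_threshold(fly_intensity: float, background: float) -> float:
    """Midpoint threshold separating rendered flies from background."""
    return (float(fly_intensity) + float(background)) / 2.0


def mirrored_config(config: AssaySimConfig) -> AssaySimConfig:
    """The physically mirrored assay: drift (and jitter effect) negated."""
    return replace(config, drift_mm_s=-config.drift_mm_s)
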