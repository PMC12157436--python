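"""Brownian-motion prior over candidate tracks and its conditionals.

The motion model is a Gaussian random walk: the initial position of each
candidate is uniform over the field of view, and each per-frame increment
is ``Normal(0, s)`` per axis with ``s = msd_per_frame / 2`` (2-D mean
squared displacement per frame interval; ``MSD = 4 * D * dt``).

The mean squared displacement carries an inverse-gamma prior, which is
conjugate to the Gaussian increments: with ``n`` scalar increments of
summed square ``ss``, the conditional is
``InverseGamma(shape + n/2, scale + ss)`` — the factor-of-two from the
Gaussian exponent cancels against ``s = MSD/2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MotionParams",
    "Priors",
    "CandidateSet",
    "log_motion_prior",
    "sample_tracks_prior",
    "bridge_conditional",
    "msd_conditional_params",
]


@dataclass(frozen=True)
class MotionParams:
    """Diffusive motion scale: 2-D mean squared displacement per frame (nm^2)."""

    msd_per_frame_nm2: float

    def __post_init__(self) -> None:
        if not self.msd_per_frame_nm2 > 0:
            raise ValueError("msd_per_frame_nm2 must be strictly positive")

    @property
    def step_var_nm2(self) -> float:
        """Per-axis variance of one frame increment."""
        return self.msd_per_frame_nm2 / 2.0


@dataclass(frozen=True)
class Priors:
    """Hyperparameters of the track / load / MSD priors.

    fov_bounds is ``((x_lo, x_hi), (y_lo, y_hi))`` in nm; initial positions
    are uniform over this rectangle.
    """

    msd_shape: float
    msd_scale_nm2: float
    load_prob: float
    fov_bounds: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        if not self.msd_shape > 0:
            raise ValueError("msd_shape must be positive")
        if not self.msd_scale_nm2 > 0:
            raise ValueError("msd_scale_nm2 must be positive")
        if not 0.0 <= self.load_prob <= 1.0:
            raise ValueError("load_prob must be in [0, 1]")
        (x_lo, x_hi), (y_lo, y_hi) = self.fov_bounds
        if not (x_hi > x_lo and y_hi > y_lo):
            raise ValueError("fov_bounds must be a non-degenerate rectangle")

    @property
    def fov_area_nm2(self) -> float:
        (x_lo, x_hi), (y_lo, y_hi) = self.fov_bounds
        return (x_hi - x_lo) * (y_hi - y_lo)

    @property
    def msd_prior_mean_nm2(self) -> float:
        if self.msd_shape <= 1:
            return float("inf")
        return self.msd_scale_nm2 / (self.msd_shape - 1.0)

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Whether (x, y) points lie inside the field of view."""
        xy = np.asarray(xy, dtype=float)
        (x_lo, x_hi), (y_lo, y_hi) = self.fov_bounds
        return (
            (xy[..., 0] >= x_lo)
            & (xy[..., 0] <= x_hi)
            & (xy[..., 1] >= y_lo)
            & (xy[..., 1] <= y_hi)
        )


def fov_for_frame(frame_shape: tuple[int, int], pixel_size_nm: float):
    """Field-of-view rectangle covering an I x J pixel frame."""
    n_i, n_j = frame_shape
    return ((0.0, n_i * pixel_size_nm), (0.0, n_j * pixel_size_nm))


@dataclass
class CandidateSet:
    """K candidate tracks over N frames with binary loads.

    ``positions`` has shape (N, K, 2) in nm; ``loads`` is a (K,) 0/1 vector.
    Only loaded (active) candidates contribute photons; inactive ones are
    placeholders that still follow the motion prior.
    """

    positions: np.ndarray
    loads: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.loads = np.asarray(self.loads, dtype=np.int8)
        if self.positions.ndim != 3 or self.positions.shape[-1] != 2:
            raise ValueError("positions must have shape (n_frames, n_candidates, 2)")
        if self.loads.shape != (self.positions.shape[1],):
            raise ValueError("loads must be a (n_candidates,) vector")
        if not np.all((self.loads == 0) | (self.loads == 1)):
            raise ValueError("loads must be binary")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_candidates(self) -> int:
        return self.positions.shape[1]

    @property
    def n_active(self) -> int:
        return int(self.loads.sum())

    def active_positions(self) -> np.ndarray:
        """Positions of loaded candidates, shape (N, M, 2)."""
        return self.positions[:, self.loads.astype(bool), :]

    def copy(self) -> "CandidateSet":
        return CandidateSet(self.positions.copy(), self.loads.copy())


def log_motion_prior(candidates: CandidateSet, motion: MotionParams, priors: Priors) -> float:
    """Log-density of all K candidate tracks under the motion prior.

    Uniform-FOV initial term (with indicator) plus Gaussian increment terms;
    inactive candidates are included — they follow the same prior.
    """
    pos = candidates.positions
    n_frames, n_cand = pos.shape[0], pos.shape[1]
    if not np.all(priors.contains(pos[0])):
        return float("-inf")
    total = -n_cand * np.log(priors.fov_area_nm2)
    if n_frames > 1:
        s = motion.step_var_nm2
        steps = np.diff(pos, axis=0)  # (N-1, K, 2)
        n_inc = steps.size
        total += -0.5 * n_inc * np.log(2.0 * np.pi * s) - np.sum(steps**2) / (2.0 * s)
    return float(total)


def sample_tracks_prior(
    n_candidates: int,
    n_frames: int,
    motion: MotionParams,
    priors: Priors,
    rng: np.random.Generator,
    initial_margin: float = 0.0,
) -> np.ndarray:
    """Forward-simulate candidate tracks from the motion prior.

    ``initial_margin`` (fraction in [0, 0.5)) shrinks the uniform initial
    rectangle towards the FOV centre, e.g. 0.1 keeps starts within the
    central 80% — used by the simulator to limit edge truncation.

    Returns positions of shape (n_frames, n_candidates, 2).
    """
    if n_candidates < 1 or n_frames < 1:
        raise ValueError("n_candidates and n_frames must be >= 1")
    if not 0.0 <= initial_margin < 0.5:
        raise ValueError("initial_margin must be in [0, 0.5)")
    (x_lo, x_hi), (y_lo, y_hi) = priors.fov_bounds
    mx = initial_margin * (x_hi - x_lo)
    my = initial_margin * (y_hi - y_lo)
    start = np.column_stack(
        [
            rng.uniform(x_lo + mx, x_hi - mx, size=n_candidates),
            rng.uniform(y_lo + my, y_hi - my, size=n_candidates),
        ]
    )
    positions = np.empty((n_frames, n_candidates, 2))
    positions[0] = start
    if n_frames > 1:
        sd = np.sqrt(motion.step_var_nm2)
        steps = rng.normal(0.0, sd, size=(n_frames - 1, n_candidates, 2))
        positions[1:] = start + np.cumsum(steps, axis=0)
    return positions


def bridge_conditional(x_prev, x_next, motion: MotionParams):
    """Gaussian conditional of one frame's position given its neighbours.

    Exact conditional of the random walk: with both neighbours the position
    is ``Normal((x_prev + x_next)/2, s/2)`` per axis; with a single
    neighbour it is ``Normal(neighbour, s)`` (the flat initial prior is
    absorbed).  Pass ``None`` for an absent neighbour.

    Returns ``(mean, per_axis_var)``.
    """
    s = motion.step_var_nm2
    if x_prev is not None and x_next is not None:
        return (np.asarray(x_prev, dtype=float) + np.asarray(x_next, dtype=float)) / 2.0, s / 2.0
    if x_prev is not None:
        return np.asarray(x_prev, dtype=float).copy(), s
    if x_next is not None:
        return np.asarray(x_next, dtype=float).copy(), s
    raise ValueError("at least one neighbour must be present")


def msd_conditional_params(candidates: CandidateSet, priors: Priors) -> tuple[float, float]:
    """Inverse-gamma conditional for the MSD given all candidate tracks.

    shape' = shape + K*(N-1)*d/2,  scale' = scale + sum of squared scalar
    increments (both axes, all candidates).  With per-axis step variance
    ``s = MSD/2`` each increment contributes ``exp(-delta^2 / MSD)``, so the
    squared increments enter the scale without a factor of 1/2.
    """
    pos = candidates.positions
    if pos.shape[0] < 2:
        return priors.msd_shape, priors.msd_scale_nm2
    steps = np.diff(pos, axis=0)
    if not np.all(np.isfinite(steps)):
        raise ValueError("non-finite increments")
    shape = priors.msd_shape + steps.size / 2.0
    scale = priors.msd_scale_nm2 + float(np.sum(steps**2))
    return shape, scale
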