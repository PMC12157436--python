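"""Detection-level accuracy: diffraction-limited matching and detection ratio.

Per frame, estimated positions are matched one-to-one to ground-truth
positions by an optimal assignment that minimises total distance among the
pairs closer than one matching radius (the diffraction limit by default).
Estimates farther than the radius from every truth position are spurious;
unmatched truths are misses.  The detection ratio is total correct
detections over total truth positions, pooled over frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .optics import OpticsConfig

__all__ = [
    "MatchResult",
    "diffraction_limit",
    "match_frame_detections",
    "detection_ratio",
]


def diffraction_limit(optics: OpticsConfig) -> float:
    """Matching radius in nm: lambda / (2 NA)."""
    return optics.emission_wavelength_nm / (2.0 * optics.numerical_aperture)


@dataclass
class MatchResult:
    """Outcome of matching estimates to truths (one frame or pooled)."""

    n_truth: int
    n_est: int
    n_correct: int
    n_spurious: int
    matched_pairs: list = field(default_factory=list)  # (truth_idx, est_idx, dist)

    def __post_init__(self) -> None:
        assert self.n_correct <= self.n_truth
        assert self.n_correct <= self.n_est
        assert self.n_spurious == self.n_est - self.n_correct

    @property
    def n_missed(self) -> int:
        return self.n_truth - self.n_correct

    @property
    def match_distances(self) -> np.ndarray:
        return np.array([d for _, _, d in self.matched_pairs])

    def merge(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(
            n_truth=self.n_truth + other.n_truth,
            n_est=self.n_est + other.n_est,
            n_correct=self.n_correct + other.n_correct,
            n_spurious=self.n_spurious + other.n_spurious,
            matched_pairs=self.matched_pairs + other.matched_pairs,
        )


def match_frame_detections(
    truth_positions: np.ndarray, est_positions: np.ndarray, radius: float
) -> MatchResult:
    """Optimal one-to-one matching of one frame's detections.

    Pairs farther apart than ``radius`` are inadmissible.  Among admissible
    assignments the match count is maximised first, then total distance
    minimised (achieved by pricing inadmissible pairs above any admissible
    total).
    """
    truth = np.atleast_2d(np.asarray(truth_positions, dtype=float))
    est = np.atleast_2d(np.asarray(est_positions, dtype=float))
    if truth.size == 0:
        truth = truth.reshape(0, 2)
    if est.size == 0:
        est = est.reshape(0, 2)
    if not (np.all(np.isfinite(truth)) and np.all(np.isfinite(est))):
        raise ValueError("positions must be finite")
    n_t, n_e = len(truth), len(est)
    if n_t == 0 or n_e == 0:
        return MatchResult(n_truth=n_t, n_est=n_e, n_correct=0, n_spurious=n_e)

    dist = np.linalg.norm(truth[:, None, :] - est[None, :, :], axis=-1)
    feasible = dist <= radius
    big = dist[feasible].sum() + radius * (min(n_t, n_e) + 1) + 1.0
    cost = np.where(feasible, dist, big)
    rows, cols = linear_sum_assignment(cost)
    pairs = [
        (int(r), int(c), float(dist[r, c]))
        for r, c in zip(rows, cols)
        if feasible[r, c]
    ]
    n_correct = len(pairs)
    return MatchResult(
        n_truth=n_t,
        n_est=n_e,
        n_correct=n_correct,
        n_spurious=n_e - n_correct,
        matched_pairs=pairs,
    )


def detection_ratio(truth_tracks, est_tracks, radius: float):
    """Pooled detection ratio over frames.

    Parameters
    ----------
    truth_tracks, est_tracks : (N, M, 2) arrays or length-N sequences of
        (M_n, 2) arrays of positions in nm.
    radius : matching radius in nm.

    Returns
    -------
    ratio : float in [0, 1]
    result : pooled :class:`MatchResult` (spurious count included; the
        metric is conventionally reported only when it is zero).
    """
    truth_frames = [np.asarray(f, dtype=float) for f in truth_tracks]
    est_frames = [np.asarray(f, dtype=float) for f in est_tracks]
    if len(truth_frames) != len(est_frames):
        raise ValueError(
            f"frame count mismatch: {len(truth_frames)} truth vs {len(est_frames)} estimated"
        )
    total = MatchResult(n_truth=0, n_est=0, n_correct=0, n_spurious=0)
    for t_frame, e_frame in zip(truth_frames, est_frames):
        total = total.merge(match_frame_detections(t_frame, e_frame, radius))
    if total.n_truth == 0:
        raise ValueError("no ground-truth positions to score against")
    return total.n_correct / total.n_truth, total
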