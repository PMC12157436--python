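"""Checkerboard Metropolis-within-Gibbs sampler over candidate tracks.

One sweep updates, in order:

1. track positions at even frame indices, then at odd frame indices
   (checkerboard phases: given one parity the other parity's positions are
   conditionally independent across frames, so frames within a phase may be
   updated in any order — or in parallel — with identical results);
2. the binary loads, each from its exact Bernoulli conditional
   (skipped in parametric mode);
3. the mean squared displacement, from its conjugate inverse-gamma
   conditional;
4. optionally the scalar background rate and brightness, by random-walk
   Metropolis-Hastings on the log scale.

Track proposals are drawn from the prior bridge conditional given the
(fixed) opposite-parity neighbours, so the Gaussian prior factors cancel
and the acceptance probability reduces to the single-frame likelihood
ratio; the only surviving prior factor is the field-of-view indicator on
the first frame.  Inactive candidates have likelihood ratio 1 and are
refreshed from the prior with acceptance exactly 1.

Reproducibility: every stochastic event draws from its own counter-based
random stream keyed by (seed, iteration, kind, candidate, frame), so
results are bit-identical regardless of the order in which frames within a
phase are processed, and a checkpointed chain resumes exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter, maximum_filter

from .likelihood import (
    CameraEMCCD,
    CameraSPAD,
    ImageStack,
    axis_masses,
    frame_loglike,
    pixel_edges,
    stack_loglike,
)
from .motion import (
    CandidateSet,
    MotionParams,
    Priors,
    log_motion_prior,
    msd_conditional_params,
    sample_tracks_prior,
)
from .optics import OpticsConfig

__all__ = [
    "STREAMS",
    "Substreams",
    "SamplerConfig",
    "ChainState",
    "PosteriorSamples",
    "update_tracks_phase",
    "update_loads",
    "update_msd",
    "sweep",
    "run_chain",
    "posterior_summary",
    "posterior_mean_tracks",
    "detect_initial_tracks",
]

# Stream kinds for the counter-based substreams.
STREAMS = {
    "init": 0,
    "track_even": 1,
    "track_odd": 2,
    "loads": 3,
    "msd": 4,
    "background": 5,
    "brightness": 6,
    "data": 7,  # reserved for model self-simulation (sampler validation)
}

_PHASE_STREAM = {"even": STREAMS["track_even"], "odd": STREAMS["track_odd"]}


class Substreams:
    """Counter-based per-event random streams derived from one master seed."""

    def __init__(self, seed: int):
        self.seed = int(seed)

    def rng(self, iteration: int, stream: int, candidate: int = 0, frame: int = 0):
        bitgen = np.random.Philox(
            key=np.uint64(self.seed & 0xFFFFFFFFFFFFFFFF),
            counter=[int(iteration), int(stream), int(candidate), int(frame)],
        )
        return np.random.Generator(bitgen)


@dataclass(frozen=True)
class SamplerConfig:
    """Chain length, mode flags, model scalars and the master seed."""

    n_iterations: int
    n_candidates: int
    brightness: float
    background_rate: float
    burn_in: int = 0
    thin: int = 1
    seed: int = 0
    parametric_mode: bool = False
    infer_background: bool = False
    infer_brightness: bool = False
    proposal: str = "bridge"  # "bridge" | "random_walk"
    rw_scale_nm: float = 30.0
    init: str = "prior"  # "prior" | "detect"
    msd_init_nm2: Optional[float] = None
    scalar_proposal_scale: float = 0.1  # log-scale RW for background/brightness
    scalar_prior_shape: float = 2.0  # Gamma prior shape for inferred scalars

    def __post_init__(self) -> None:
        if self.burn_in > self.n_iterations:
            raise ValueError("burn_in must be <= n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be >= 1")
        if self.brightness < 0 or self.background_rate < 0:
            raise ValueError("brightness and background_rate must be nonnegative")
        if self.proposal not in ("bridge", "random_walk"):
            raise ValueError("proposal must be 'bridge' or 'random_walk'")
        if self.init not in ("prior", "detect"):
            raise ValueError("init must be 'prior' or 'detect'")


@dataclass
class ChainState:
    """One Gibbs state plus cached expected-photon field and log-likelihoods.

    The caches (axis masses ``ux``/``uy``, field ``u`` and per-frame
    log-likelihood) are preallocated on the first :meth:`refresh_cache` and
    mutated in place thereafter.
    """

    candidates: CandidateSet
    motion: MotionParams
    background_rate: float
    brightness: float
    iteration: int = 0
    ux: Optional[np.ndarray] = None  # (N, I, K)
    uy: Optional[np.ndarray] = None  # (N, J, K)
    u: Optional[np.ndarray] = None  # (N, I, J)
    ll_frames: Optional[np.ndarray] = None  # (N,)

    def copy(self) -> "ChainState":
        return ChainState(
            candidates=self.candidates.copy(),
            motion=self.motion,
            background_rate=self.background_rate,
            brightness=self.brightness,
            iteration=self.iteration,
            ux=None if self.ux is None else self.ux.copy(),
            uy=None if self.uy is None else self.uy.copy(),
            u=None if self.u is None else self.u.copy(),
            ll_frames=None if self.ll_frames is None else self.ll_frames.copy(),
        )

    def refresh_cache(self, stack: ImageStack, camera, optics: OpticsConfig) -> None:
        """Recompute all caches from scratch (allocating once, reusing after)."""
        pos = self.candidates.positions
        n_frames, n_cand = pos.shape[0], pos.shape[1]
        n_i, n_j = stack.frame_shape
        var = optics.psf_variance_nm2
        delta = optics.pixel_size_nm
        if self.ux is None:
            self.ux = np.empty((n_frames, n_i, n_cand))
            self.uy = np.empty((n_frames, n_j, n_cand))
            self.u = np.empty((n_frames, n_i, n_j))
            self.ll_frames = np.empty(n_frames)
        self.ux[...] = axis_masses(pos[..., 0], pixel_edges(n_i, delta), var)
        self.uy[...] = axis_masses(pos[..., 1], pixel_edges(n_j, delta), var)
        self._rebuild_field()
        _, per_frame = stack_loglike(stack.values, self.u, camera)
        self.ll_frames[...] = per_frame

    def _rebuild_field(self) -> None:
        b = self.candidates.loads.astype(float)
        self.u[...] = self.background_rate
        if self.brightness > 0 and b.any():
            uxb = self.ux * b  # zero out inactive columns
            self.u += self.brightness * (uxb @ self.uy.transpose(0, 2, 1))

    def audit_cache(self, stack: ImageStack, camera, optics: OpticsConfig) -> float:
        """Max |cached - fresh| per-frame log-likelihood discrepancy."""
        fresh = self.copy()
        fresh.refresh_cache(stack, camera, optics)
        return float(np.max(np.abs(fresh.ll_frames - self.ll_frames)))

    def total_loglike(self) -> float:
        return float(self.ll_frames.sum())


def _log_load_prior(loads: np.ndarray, gamma: float) -> float:
    m = int(loads.sum())
    k = loads.size
    if gamma in (0.0, 1.0):
        ok = (m == 0) if gamma == 0.0 else (m == k)
        return 0.0 if ok else float("-inf")
    return m * math.log(gamma) + (k - m) * math.log1p(-gamma)


def _log_invgamma_pdf(x: float, shape: float, scale: float) -> float:
    if x <= 0:
        return float("-inf")
    return (
        shape * math.log(scale)
        - math.lgamma(shape)
        - (shape + 1.0) * math.log(x)
        - scale / x
    )


def log_posterior(state: ChainState, priors: Priors) -> float:
    """Unnormalised log-posterior of the current state (cached likelihood)."""
    lp = state.total_loglike()
    lp += log_motion_prior(state.candidates, state.motion, priors)
    lp += _log_load_prior(state.candidates.loads, priors.load_prob)
    lp += _log_invgamma_pdf(
        state.motion.msd_per_frame_nm2, priors.msd_shape, priors.msd_scale_nm2
    )
    return lp


# ---------------------------------------------------------------------------
# Track updates


def _phase_frames(n_frames: int, phase: str) -> np.ndarray:
    if phase == "even":
        return np.arange(0, n_frames, 2)
    if phase == "odd":
        return np.arange(1, n_frames, 2)
    raise ValueError(f"phase must be 'even' or 'odd', got {phase!r}")


def _neighbours(pos: np.ndarray, n: int, m: int):
    n_frames = pos.shape[0]
    x_prev = pos[n - 1, m] if n > 0 else None
    x_next = pos[n + 1, m] if n < n_frames - 1 else None
    return x_prev, x_next


def _bridge_moments(x_prev, x_next, step_var: float):
    if x_prev is not None and x_next is not None:
        return (x_prev + x_next) / 2.0, step_var / 2.0
    if x_prev is not None:
        return x_prev, step_var
    return x_next, step_var


def update_tracks_phase(
    state: ChainState,
    stack: ImageStack,
    camera,
    optics: OpticsConfig,
    priors: Priors,
    config: SamplerConfig,
    streams: Substreams,
    iteration: int,
    phase: str,
    frame_order: Optional[np.ndarray] = None,
) -> ChainState:
    """Metropolis update of every frame of the given parity, per candidate.

    Candidates are processed sequentially (the likelihood couples them);
    frames within a phase are independent and may be visited in any order
    (``frame_order``) with bit-identical results.
    """
    frames = _phase_frames(state.candidates.n_frames, phase)
    if frame_order is not None:
        frame_order = np.asarray(frame_order)
        if sorted(frame_order.tolist()) != frames.tolist():
            raise ValueError("frame_order must be a permutation of the phase's frames")
        frames = frame_order
    stream = _PHASE_STREAM[phase]

    pos = state.candidates.positions
    loads = state.candidates.loads
    step_var = state.motion.step_var_nm2
    var = optics.psf_variance_nm2
    delta = optics.pixel_size_nm
    n_i, n_j = stack.frame_shape
    edges_x = pixel_edges(n_i, delta)
    edges_y = pixel_edges(n_j, delta)
    h = state.brightness
    (x_lo, x_hi), (y_lo, y_hi) = priors.fov_bounds
    single_frame = state.candidates.n_frames == 1

    for m in range(state.candidates.n_candidates):
        active = bool(loads[m]) and h > 0
        for n in frames:
            rng = streams.rng(iteration, stream, m, int(n))
            x_prev, x_next = _neighbours(pos, n, m)
            if single_frame:
                proposal = np.array(
                    [rng.uniform(x_lo, x_hi), rng.uniform(y_lo, y_hi)]
                )
                log_prior_ratio = 0.0
            elif config.proposal == "bridge":
                mean, pvar = _bridge_moments(x_prev, x_next, step_var)
                proposal = mean + math.sqrt(pvar) * rng.standard_normal(2)
                log_prior_ratio = 0.0
            else:  # symmetric random walk: prior ratio survives
                proposal = pos[n, m] + config.rw_scale_nm * rng.standard_normal(2)
                mean, pvar = _bridge_moments(x_prev, x_next, step_var)
                d_new = proposal - mean
                d_old = pos[n, m] - mean
                log_prior_ratio = float(
                    (d_old @ d_old - d_new @ d_new) / (2.0 * pvar)
                )
            accept_u = rng.random()

            # flat-FOV prior indicator applies to the first frame only
            if n == 0 and not single_frame:
                if not (
                    x_lo <= proposal[0] <= x_hi and y_lo <= proposal[1] <= y_hi
                ):
                    continue

            if not active:
                if log_prior_ratio != 0.0 and math.log(accept_u) >= log_prior_ratio:
                    continue
                pos[n, m] = proposal
                state.ux[n, :, m] = axis_masses(proposal[:1], edges_x, var)[:, 0]
                state.uy[n, :, m] = axis_masses(proposal[1:], edges_y, var)[:, 0]
                continue

            px_new = axis_masses(proposal[:1], edges_x, var)[:, 0]
            py_new = axis_masses(proposal[1:], edges_y, var)[:, 0]
            u_new = state.u[n] + h * (
                np.outer(px_new, py_new)
                - np.outer(state.ux[n, :, m], state.uy[n, :, m])
            )
            np.maximum(u_new, state.background_rate, out=u_new)  # clamp fp dust
            ll_new = frame_loglike(stack.values[n], u_new, camera)
            ll_old = state.ll_frames[n]
            if ll_new == ll_old:  # covers the -inf/-inf corner
                log_alpha = log_prior_ratio
            else:
                log_alpha = ll_new - ll_old + log_prior_ratio
            if log_alpha >= 0.0 or math.log(accept_u) < log_alpha:
                pos[n, m] = proposal
                state.ux[n, :, m] = px_new
                state.uy[n, :, m] = py_new
                state.u[n] = u_new
                state.ll_frames[n] = ll_new
    return state


# ---------------------------------------------------------------------------
# Load updates


def _candidate_field(state: ChainState, m: int) -> np.ndarray:
    """Photon contribution of candidate m over all frames, (N, I, J)."""
    return state.brightness * (
        state.ux[:, :, m][:, :, None] * state.uy[:, :, m][:, None, :]
    )


def update_loads(
    state: ChainState,
    stack: ImageStack,
    camera,
    priors: Priors,
    streams: Substreams,
    iteration: int,
) -> ChainState:
    """Draw each load from its exact Bernoulli conditional, sequentially."""
    gamma = priors.load_prob
    loads = state.candidates.loads
    for m in range(state.candidates.n_candidates):
        rng = streams.rng(iteration, STREAMS["loads"], m)
        coin = rng.random()
        if gamma == 1.0:
            target = 1
        elif gamma == 0.0:
            target = 0
        else:
            contrib = _candidate_field(state, m)
            if loads[m]:
                u_on = state.u
                u_off = state.u - contrib
                np.maximum(u_off, state.background_rate, out=u_off)
            else:
                u_off = state.u
                u_on = state.u + contrib
            ll_on, pf_on = stack_loglike(stack.values, u_on, camera)
            ll_off, pf_off = stack_loglike(stack.values, u_off, camera)
            if ll_on == ll_off:  # includes -inf twice
                p_on = gamma
            elif ll_on == float("-inf"):
                p_on = 0.0
            elif ll_off == float("-inf"):
                p_on = 1.0
            else:
                p_on = gamma / (gamma + (1.0 - gamma) * math.exp(ll_off - ll_on))
            target = 1 if coin < p_on else 0
            if target != loads[m]:
                if target:
                    state.u[...] = u_on
                    state.ll_frames[...] = pf_on
                else:
                    state.u[...] = u_off
                    state.ll_frames[...] = pf_off
            loads[m] = target
            continue
        # degenerate prior branch
        if target != loads[m]:
            contrib = _candidate_field(state, m)
            if target:
                state.u += contrib
            else:
                state.u -= contrib
                np.maximum(state.u, state.background_rate, out=state.u)
            _, per_frame = stack_loglike(stack.values, state.u, camera)
            state.ll_frames[...] = per_frame
        loads[m] = target
    return state


# ---------------------------------------------------------------------------
# Scalar updates


def update_msd(
    state: ChainState, priors: Priors, streams: Substreams, iteration: int
) -> ChainState:
    """Draw the MSD from its conjugate inverse-gamma conditional."""
    shape, scale = msd_conditional_params(state.candidates, priors)
    rng = streams.rng(iteration, STREAMS["msd"])
    gamma_draw = rng.gamma(shape, 1.0 / scale)
    state.motion = MotionParams(msd_per_frame_nm2=1.0 / gamma_draw)
    return state


def _scalar_mh(
    state: ChainState,
    stack: ImageStack,
    camera,
    config: SamplerConfig,
    streams: Substreams,
    iteration: int,
    which: str,
) -> ChainState:
    """Log-scale random-walk MH on the background rate or brightness.

    Gamma prior with shape ``scalar_prior_shape`` and mean equal to the
    configured initial value; the log-normal proposal contributes a
    Jacobian factor new/old which combines with the prior into
    ``shape * (log new - log old) - rate * (new - old)``.
    """
    current = state.background_rate if which == "background" else state.brightness
    if current <= 0:
        return state  # cannot move a zero scalar multiplicatively
    rng = streams.rng(iteration, STREAMS[which])
    z = rng.standard_normal()
    accept_u = rng.random()
    proposed = current * math.exp(config.scalar_proposal_scale * z)
    shape = config.scalar_prior_shape
    prior_mean = (
        config.background_rate if which == "background" else config.brightness
    )
    rate = shape / prior_mean
    if which == "background":
        u_new = state.u + (proposed - current)
    else:
        u_new = state.background_rate + (proposed / current) * (
            state.u - state.background_rate
        )
    ll_new_total, per_frame = stack_loglike(stack.values, u_new, camera)
    log_alpha = (
        ll_new_total
        - state.total_loglike()
        + shape * (math.log(proposed) - math.log(current))
        - rate * (proposed - current)
    )
    if log_alpha >= 0.0 or math.log(accept_u) < log_alpha:
        state.u[...] = u_new
        state.ll_frames[...] = per_frame
        if which == "background":
            state.background_rate = proposed
        else:
            state.brightness = proposed
    return state


# ---------------------------------------------------------------------------
# Sweep and chain


def sweep(
    state: ChainState,
    stack: ImageStack,
    camera,
    optics: OpticsConfig,
    priors: Priors,
    config: SamplerConfig,
    streams: Substreams,
    iteration: int,
) -> ChainState:
    """One full Gibbs iteration: tracks (two phases), loads, MSD, scalars."""
    for phase in ("even", "odd"):
        update_tracks_phase(
            state, stack, camera, optics, priors, config, streams, iteration, phase
        )
    if not config.parametric_mode:
        update_loads(state, stack, camera, priors, streams, iteration)
    update_msd(state, priors, streams, iteration)
    if config.infer_background:
        _scalar_mh(state, stack, camera, config, streams, iteration, "background")
    if config.infer_brightness:
        _scalar_mh(state, stack, camera, config, streams, iteration, "brightness")
    state.iteration = iteration + 1
    return state


@dataclass
class PosteriorSamples:
    """Thinned chain output plus the per-iteration log-posterior trace."""

    iterations: np.ndarray  # (S,)
    loads: np.ndarray  # (S, K)
    tracks: np.ndarray  # (S, N, K, 2) nm
    msd: np.ndarray  # (S,) nm^2 per frame
    background: np.ndarray  # (S,)
    brightness: np.ndarray  # (S,)
    log_posterior: np.ndarray  # (S,)
    log_posterior_trace: np.ndarray  # (n_iterations,)
    config: SamplerConfig
    final_state: Optional[ChainState] = None

    def __len__(self) -> int:
        return len(self.iterations)

    @property
    def n_active(self) -> np.ndarray:
        """Emitter count M per sample."""
        return self.loads.sum(axis=1)

    def extend(self, other: "PosteriorSamples") -> "PosteriorSamples":
        return PosteriorSamples(
            iterations=np.concatenate([self.iterations, other.iterations]),
            loads=np.concatenate([self.loads, other.loads]),
            tracks=np.concatenate([self.tracks, other.tracks]),
            msd=np.concatenate([self.msd, other.msd]),
            background=np.concatenate([self.background, other.background]),
            brightness=np.concatenate([self.brightness, other.brightness]),
            log_posterior=np.concatenate([self.log_posterior, other.log_posterior]),
            log_posterior_trace=np.concatenate(
                [self.log_posterior_trace, other.log_posterior_trace]
            ),
            config=other.config,
            final_state=other.final_state,
        )


def _initial_state(
    stack: ImageStack,
    camera,
    optics: OpticsConfig,
    priors: Priors,
    config: SamplerConfig,
    streams: Substreams,
) -> ChainState:
    msd0 = config.msd_init_nm2
    if msd0 is None:
        msd0 = (
            priors.msd_prior_mean_nm2
            if math.isfinite(priors.msd_prior_mean_nm2)
            else priors.msd_scale_nm2
        )
    motion = MotionParams(msd_per_frame_nm2=msd0)
    k = config.n_candidates
    n = stack.n_frames
    if config.init == "detect":
        positions, loads = detect_initial_tracks(
            stack, camera, optics, priors, k, motion, streams.rng(0, STREAMS["init"])
        )
    else:
        rng = streams.rng(0, STREAMS["init"])
        positions = sample_tracks_prior(k, n, motion, priors, rng)
        # conservative start: all loads off, except a degenerate gamma = 1
        # prior under which that state has probability zero
        fill = 1 if priors.load_prob == 1.0 else 0
        loads = np.full(k, fill, dtype=np.int8)
    if config.parametric_mode:
        loads = np.ones(k, dtype=np.int8)
    state = ChainState(
        candidates=CandidateSet(positions, loads),
        motion=motion,
        background_rate=config.background_rate,
        brightness=config.brightness,
    )
    state.refresh_cache(stack, camera, optics)
    return state


def run_chain(
    stack: ImageStack,
    camera,
    optics: OpticsConfig,
    priors: Priors,
    config: SamplerConfig,
    init_state: Optional[ChainState] = None,
) -> PosteriorSamples:
    """Run the Gibbs chain and collect thinned posterior samples.

    Pass a previously returned ``final_state`` as ``init_state`` to resume a
    checkpointed chain: the continuation is bit-identical to the
    uninterrupted run (samples from the resumed stretch are returned; use
    :meth:`PosteriorSamples.extend` to splice).
    """
    stack.validate_for_camera(camera)
    streams = Substreams(config.seed)
    if init_state is None:
        state = _initial_state(stack, camera, optics, priors, config, streams)
    else:
        state = init_state.copy()
        state.refresh_cache(stack, camera, optics)

    rec_iter, rec_loads, rec_tracks = [], [], []
    rec_msd, rec_bg, rec_h, rec_lp = [], [], [], []
    trace = []
    for it in range(state.iteration, config.n_iterations):
        sweep(state, stack, camera, optics, priors, config, streams, it)
        lp = log_posterior(state, priors)
        if math.isnan(lp):
            raise FloatingPointError(
                f"NaN log-posterior at iteration {it}: "
                f"msd={state.motion.msd_per_frame_nm2}, "
                f"M={state.candidates.n_active}, "
                f"ll={state.ll_frames}"
            )
        trace.append(lp)
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            rec_iter.append(it)
            rec_loads.append(state.candidates.loads.copy())
            rec_tracks.append(state.candidates.positions.copy())
            rec_msd.append(state.motion.msd_per_frame_nm2)
            rec_bg.append(state.background_rate)
            rec_h.append(state.brightness)
            rec_lp.append(lp)

    k = config.n_candidates
    n = stack.n_frames
    return PosteriorSamples(
        iterations=np.asarray(rec_iter, dtype=int),
        loads=(
            np.asarray(rec_loads, dtype=np.int8)
            if rec_loads
            else np.empty((0, k), dtype=np.int8)
        ),
        tracks=(
            np.asarray(rec_tracks) if rec_tracks else np.empty((0, n, k, 2))
        ),
        msd=np.asarray(rec_msd),
        background=np.asarray(rec_bg),
        brightness=np.asarray(rec_h),
        log_posterior=np.asarray(rec_lp),
        log_posterior_trace=np.asarray(trace),
        config=config,
        final_state=state,
    )


# ---------------------------------------------------------------------------
# Initialisation and summaries


def detect_initial_tracks(
    stack: ImageStack,
    camera,
    optics: OpticsConfig,
    priors: Priors,
    n_candidates: int,
    motion: MotionParams,
    rng: np.random.Generator,
):
    """Data-driven initial tracks: bright maxima of the time-averaged frame.

    The time-averaged image is converted to approximate photon counts,
    smoothed at the PSF scale, and its strongest local maxima (with a
    minimum mutual separation of one PSF sigma) become constant candidate
    tracks with loads switched on; remaining candidates are drawn from the
    prior with loads off.  This only seeds the chain — the sampler prunes
    or refines from here.
    """
    mean_frame = stack.values.astype(float).mean(axis=0)
    if isinstance(camera, CameraEMCCD):
        photons = (mean_frame - camera.offset) / camera.em_gain
    else:
        photons = mean_frame
    sigma_px = optics.psf_sigma_nm / optics.pixel_size_nm
    smooth = gaussian_filter(photons, sigma=sigma_px, mode="nearest")
    is_max = (smooth == maximum_filter(smooth, size=3, mode="nearest"))
    peaks = np.argwhere(is_max)
    order = np.argsort(smooth[is_max])[::-1]
    peaks = peaks[order]

    min_sep_px = max(1.0, sigma_px)
    chosen: list[np.ndarray] = []
    for p in peaks:
        if len(chosen) >= n_candidates:
            break
        if all(np.hypot(*(p - q)) >= min_sep_px for q in chosen):
            chosen.append(p)

    n = stack.n_frames
    delta = optics.pixel_size_nm
    positions = np.empty((n, n_candidates, 2))
    loads = np.zeros(n_candidates, dtype=np.int8)
    (x_lo, x_hi), (y_lo, y_hi) = priors.fov_bounds
    for m, p in enumerate(chosen):
        xy = (np.asarray(p, dtype=float) + 0.5) * delta
        xy[0] = min(max(xy[0], x_lo), x_hi)
        xy[1] = min(max(xy[1], y_lo), y_hi)
        positions[:, m, :] = xy
        loads[m] = 1
    n_fill = n_candidates - len(chosen)
    if n_fill:
        positions[:, len(chosen):, :] = sample_tracks_prior(
            n_fill, n, motion, priors, rng
        )
    return positions, loads


def posterior_mean_tracks(samples: PosteriorSamples) -> np.ndarray:
    """Posterior-mean active tracks conditioned on the modal emitter count.

    Candidates are matched across samples by optimal assignment of their
    time-mean positions to those of the first qualifying sample.  Returns an
    (N, M, 2) array with M the modal emitter count.
    """
    summary = posterior_summary(samples)
    return summary["mean_tracks"]


def posterior_summary(samples: PosteriorSamples) -> dict:
    """Marginal summaries: M histogram, MSD mean/CI, matched track bands."""
    from scipy.optimize import linear_sum_assignment

    if len(samples) == 0:
        raise ValueError("no posterior samples to summarise")
    m_values = samples.n_active
    counts = np.bincount(m_values, minlength=samples.loads.shape[1] + 1)
    modal_m = int(np.argmax(counts))

    msd_summary = {
        "mean": float(samples.msd.mean()),
        "sd": float(samples.msd.std(ddof=1)) if len(samples) > 1 else 0.0,
        "ci90": (
            float(np.quantile(samples.msd, 0.05)),
            float(np.quantile(samples.msd, 0.95)),
        ),
    }

    keep = np.flatnonzero(m_values == modal_m)
    if modal_m == 0 or keep.size == 0:
        mean_tracks = np.empty((samples.tracks.shape[1], 0, 2))
        aligned = np.empty((0, samples.tracks.shape[1], 0, 2))
    else:
        per_sample = []
        for s in keep:
            active = samples.loads[s].astype(bool)
            per_sample.append(samples.tracks[s][:, active, :])  # (N, M, 2)
        ref_means = per_sample[0].mean(axis=0)  # (M, 2)
        aligned_list = []
        for tr in per_sample:
            cur_means = tr.mean(axis=0)
            cost = np.linalg.norm(
                ref_means[:, None, :] - cur_means[None, :, :], axis=-1
            )
            rows, cols = linear_sum_assignment(cost)
            perm = np.empty_like(cols)
            perm[rows] = cols
            aligned_list.append(tr[:, perm, :])
        aligned = np.asarray(aligned_list)  # (S', N, M, 2)
        mean_tracks = aligned.mean(axis=0)

    if aligned.shape[0] == 0:
        track_bands = {"mean": mean_tracks, "lo90": mean_tracks, "hi90": mean_tracks}
    else:
        track_bands = {
            "mean": mean_tracks,
            "lo90": np.quantile(aligned, 0.05, axis=0),
            "hi90": np.quantile(aligned, 0.95, axis=0),
        }

    return {
        "m_counts": counts,
        "modal_m": modal_m,
        "msd": msd_summary,
        "mean_tracks": mean_tracks,
        "track_bands": track_bands,
        "n_samples": len(samples),
    }
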