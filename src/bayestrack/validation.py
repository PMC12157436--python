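"""Sampler self-validation experiments.

These routines exercise the whole inference stack against independent
oracles: joint-distribution (forward vs successive-conditional) testing on
a tiny binary-detector model, exact enumeration of load configurations,
and end-to-end parameter recovery on simulated movies.  They are used by
the test suite and the acceptance report script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluate import detection_ratio, diffraction_limit
from .likelihood import (
    CameraSPAD,
    ImageStack,
    expected_photons_batched,
    stack_loglike,
)
from .motion import (
    CandidateSet,
    MotionParams,
    Priors,
    fov_for_frame,
    sample_tracks_prior,
)
from .optics import OpticsConfig
from .sampler import (
    STREAMS,
    ChainState,
    SamplerConfig,
    Substreams,
    posterior_summary,
    run_chain,
    sweep,
    update_loads,
)
from .simulate import make_preset, simulate_movie

__all__ = [
    "effective_sample_size",
    "geweke_experiment",
    "load_enumeration_experiment",
    "recovery_experiment",
]


def effective_sample_size(x: np.ndarray) -> float:
    """ESS from the Geyer initial-positive-sequence autocorrelation sum."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1 :] / n
    if acov[0] == 0:
        return float(n)
    rho = acov / acov[0]
    tau = 1.0
    for k in range(1, n - 1, 2):
        gamma = rho[k] + rho[k + 1]
        if gamma < 0:
            break
        tau += 2.0 * gamma
    return n / max(tau, 1.0)


@dataclass(frozen=True)
class _TinyModel:
    """Small binary-detector model shared by the validation experiments."""

    optics: OpticsConfig = OpticsConfig(1.45, 1.515, 665.0, 133.0)
    size: int = 8
    n_frames: int = 5
    n_candidates: int = 2
    brightness: float = 2.5
    background_rate: float = 0.2
    msd_shape: float = 10.0
    msd_scale_nm2: float = 18_000.0
    load_prob: float = 0.5

    @property
    def priors(self) -> Priors:
        return Priors(
            msd_shape=self.msd_shape,
            msd_scale_nm2=self.msd_scale_nm2,
            load_prob=self.load_prob,
            fov_bounds=fov_for_frame((self.size, self.size), self.optics.pixel_size_nm),
        )

    @property
    def config(self) -> SamplerConfig:
        return SamplerConfig(
            n_iterations=1,
            n_candidates=self.n_candidates,
            brightness=self.brightness,
            background_rate=self.background_rate,
        )

    def prior_draw(self, rng: np.random.Generator):
        priors = self.priors
        msd = 1.0 / rng.gamma(priors.msd_shape, 1.0 / priors.msd_scale_nm2)
        motion = MotionParams(msd)
        loads = (rng.random(self.n_candidates) < priors.load_prob).astype(np.int8)
        pos = sample_tracks_prior(
            self.n_candidates, self.n_frames, motion, priors, rng
        )
        return pos, loads, motion

    def render(self, positions, loads, rng: np.random.Generator) -> ImageStack:
        field = expected_photons_batched(
            positions,
            loads,
            self.brightness,
            self.background_rate,
            self.optics,
            (self.size, self.size),
        )
        w = (rng.random(field.u.shape) < -np.expm1(-field.u)).astype(np.uint8)
        return ImageStack(w, self.optics.pixel_size_nm, 0.033)


def _test_functions(pos, loads, msd) -> np.ndarray:
    # MSD, emitter count, mean coordinate, mean squared coordinate (scaled)
    return np.array([msd, loads.sum(), pos.mean(), (pos**2).mean() / 1e6])


def geweke_experiment(n_samples: int, seed: int, model: _TinyModel | None = None):
    """Joint-distribution test of the full sweep kernel.

    Compares forward prior simulation against a successive-conditional chain
    (resimulate data given the state, then one Gibbs sweep given the data)
    on test functions {MSD, M, mean position, mean squared position}.

    Returns a dict with per-function z-scores (autocorrelation-corrected).
    """
    model = model or _TinyModel()
    priors = model.priors
    camera = CameraSPAD()

    rng_f = np.random.default_rng(seed)
    fwd = np.empty((n_samples, 4))
    for s in range(n_samples):
        pos, loads, motion = model.prior_draw(rng_f)
        fwd[s] = _test_functions(pos, loads, motion.msd_per_frame_nm2)

    streams = Substreams(seed + 1)
    rng0 = np.random.default_rng(seed + 2)
    pos, loads, motion = model.prior_draw(rng0)
    state = ChainState(
        candidates=CandidateSet(pos, loads),
        motion=motion,
        background_rate=model.background_rate,
        brightness=model.brightness,
    )
    succ = np.empty((n_samples, 4))
    for it in range(n_samples):
        rng_data = streams.rng(it, STREAMS["data"])
        stack = model.render(
            state.candidates.positions, state.candidates.loads, rng_data
        )
        state.refresh_cache(stack, camera, model.optics)
        sweep(
            state, stack, camera, model.optics, priors, model.config, streams, it
        )
        succ[it] = _test_functions(
            state.candidates.positions,
            state.candidates.loads,
            state.motion.msd_per_frame_nm2,
        )

    names = ["msd", "n_active", "mean_position", "mean_sq_position"]
    result = {}
    for i, name in enumerate(names):
        se_f = fwd[:, i].std(ddof=1) / np.sqrt(n_samples)
        n_eff = effective_sample_size(succ[:, i])
        se_s = succ[:, i].std(ddof=1) / np.sqrt(n_eff)
        result[name] = {
            "z": float((fwd[:, i].mean() - succ[:, i].mean()) / np.hypot(se_f, se_s)),
            "forward_mean": float(fwd[:, i].mean()),
            "successive_mean": float(succ[:, i].mean()),
            "ess": float(n_eff),
        }
    return result


def load_enumeration_experiment(
    n_scans: int, seed: int, model: _TinyModel | None = None
):
    """Gibbs load updates vs brute-force enumeration on a 2-candidate toy.

    Tracks, MSD and data are held fixed; only the loads move.  Returns the
    empirical configuration frequencies, the enumerated exact posterior over
    the 2^K configurations, and batch-means standard errors.
    """
    model = model or _TinyModel(n_frames=2, brightness=3.0, load_prob=0.4)
    priors = model.priors
    camera = CameraSPAD()
    rng = np.random.default_rng(seed)
    pos, _, motion = model.prior_draw(rng)
    stack = model.render(pos, np.ones(model.n_candidates, dtype=np.int8), rng)

    k = model.n_candidates
    # exact enumeration of all load configurations
    log_posts = np.empty(2**k)
    gamma = priors.load_prob
    for idx in range(2**k):
        loads = np.array([(idx >> m) & 1 for m in range(k)], dtype=np.int8)
        field = expected_photons_batched(
            pos, loads, model.brightness, model.background_rate,
            model.optics, (model.size, model.size),
        )
        ll, _ = stack_loglike(stack.values, field.u, camera)
        m = loads.sum()
        log_posts[idx] = ll + m * np.log(gamma) + (k - m) * np.log1p(-gamma)
    exact = np.exp(log_posts - log_posts.max())
    exact /= exact.sum()

    # Gibbs scans over the loads only
    state = ChainState(
        candidates=CandidateSet(pos, np.zeros(k, dtype=np.int8)),
        motion=motion,
        background_rate=model.background_rate,
        brightness=model.brightness,
    )
    state.refresh_cache(stack, camera, model.optics)
    streams = Substreams(seed + 1)
    visits = np.zeros((n_scans, 2**k), dtype=np.int8)
    for it in range(n_scans):
        update_loads(state, stack, camera, priors, streams, it)
        idx = int(sum(int(b) << m for m, b in enumerate(state.candidates.loads)))
        visits[it, idx] = 1

    freqs = visits.mean(axis=0)
    # batch-means standard errors to account for scan-to-scan correlation
    n_batches = 100
    batch = visits[: (n_scans // n_batches) * n_batches].reshape(
        n_batches, -1, 2**k
    ).mean(axis=1)
    se = batch.std(axis=0, ddof=1) / np.sqrt(n_batches)
    return {"freqs": freqs, "exact": exact, "se": se}


def recovery_experiment(
    seed: int,
    n_replicates: int = 10,
    n_particles: int = 3,
    frame_size: int = 32,
    background_rate: float = 10.0,
    n_iterations: int = 1200,
    burn_in: int = 400,
    n_candidates: int = 6,
):
    """End-to-end parameter recovery on simulated EMCCD movies.

    For each replicate: simulate a movie (reference acquisition optics,
    0.1 um^2/s diffusion, 80 concentric-pixel photons), run the sampler and
    report the modal emitter count, the detection ratio of the
    posterior-mean tracks at one diffraction limit, the spurious count, and
    the 90% credible interval for the diffusion coefficient.
    """
    results = []
    for rep in range(n_replicates):
        preset = make_preset(
            "background-sweep",
            level=background_rate,
            frame_size=frame_size,
            n_particles=n_particles,
            seed=seed + 1000 * rep,
        )
        truth, stack = simulate_movie(preset)
        priors = Priors(
            msd_shape=2.0,
            msd_scale_nm2=2.0e4,
            load_prob=n_particles / n_candidates,
            fov_bounds=fov_for_frame(stack.frame_shape, stack.pixel_size_nm),
        )
        config = SamplerConfig(
            n_iterations=n_iterations,
            burn_in=burn_in,
            thin=2,
            n_candidates=n_candidates,
            brightness=truth.brightness,
            background_rate=background_rate,
            seed=seed + 1000 * rep + 1,
            init="detect",
        )
        samples = run_chain(stack, preset.camera, preset.optics, priors, config)
        summary = posterior_summary(samples)
        mean_tracks = summary["mean_tracks"]
        radius = diffraction_limit(preset.optics)
        truth_frames = [truth.tracks[n] for n in range(preset.n_frames)]
        est_frames = [mean_tracks[n] for n in range(preset.n_frames)]
        ratio, match = detection_ratio(truth_frames, est_frames, radius)

        dt = preset.exposure_s
        d_samples = samples.msd / (4.0 * dt) * 1e-6  # nm^2/frame -> um^2/s
        d_lo, d_hi = np.quantile(d_samples, [0.05, 0.95])
        results.append(
            {
                "modal_m": summary["modal_m"],
                "true_m": n_particles,
                "detection_ratio": float(ratio),
                "n_spurious": int(match.n_spurious),
                "d_ci90": (float(d_lo), float(d_hi)),
                "d_true": preset.diffusion_um2_s,
                "d_covered": bool(d_lo <= preset.diffusion_um2_s <= d_hi),
            }
        )
    return results
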