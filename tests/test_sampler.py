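import math

import numpy as np
import pytest
from scipy.stats import invgamma, kstest

from bayestrack import (
    CameraSPAD,
    CandidateSet,
    ChainState,
    ImageStack,
    MotionParams,
    PosteriorSamples,
    SamplerConfig,
    Substreams,
    expected_photons_batched,
    posterior_summary,
    run_chain,
    simulate_movie,
    sweep,
    update_loads,
    update_msd,
    update_tracks_phase,
)
from bayestrack.likelihood import stack_loglike
from bayestrack.sampler import STREAMS, _phase_frames, log_posterior
from bayestrack.simulate import SimulationPreset, make_preset

from conftest import make_priors


def small_spad_problem(seed=5, n_frames=4, size=8, k=1, h=3.0, bg=0.3):
    """A tiny SPAD movie plus a matching initial chain state."""
    preset = make_preset(
        "background-sweep", frame_size=size, n_frames=n_frames, n_particles=k, seed=seed
    )
    preset = SimulationPreset(
        **{
            **preset.__dict__,
            "camera": CameraSPAD(),
            "center_pixel_photons": h,
            "background_rate": bg,
        }
    )
    truth, stack = simulate_movie(preset)
    priors = make_priors(frame_shape=(size, size), msd_scale_nm2=preset.msd_per_frame_nm2)
    state = ChainState(
        candidates=CandidateSet(truth.tracks.copy(), np.ones(k, dtype=np.int8)),
        motion=MotionParams(preset.msd_per_frame_nm2),
        background_rate=bg,
        brightness=truth.brightness,
    )
    state.refresh_cache(stack, preset.camera, preset.optics)
    return preset, truth, stack, priors, state


def default_config(**kw):
    defaults = dict(
        n_iterations=10, n_candidates=1, brightness=50.0, background_rate=0.3, seed=3
    )
    defaults.update(kw)
    return SamplerConfig(**defaults)


# ---------------------------------------------------------------------------
# track updates


def test_inactive_candidate_always_accepts(optics):
    preset, truth, stack, priors, state = small_spad_problem()
    state.candidates.loads[:] = 0
    state.refresh_cache(stack, preset.camera, preset.optics)
    before = state.candidates.positions.copy()
    streams = Substreams(99)
    cfg = default_config()
    for phase in ("even", "odd"):
        update_tracks_phase(
            state, stack, preset.camera, preset.optics, priors, cfg, streams, 0, phase
        )
    # every non-first frame moved (acceptance 1; frame 0 may reject only via FOV)
    moved = np.any(state.candidates.positions != before, axis=(1, 2))
    assert moved[1:].all()
    # likelihood untouched
    assert state.audit_cache(stack, preset.camera, preset.optics) < 1e-9


def test_zero_brightness_behaves_like_inactive():
    preset, truth, stack, priors, state = small_spad_problem(h=3.0)
    state.brightness = 0.0
    state.refresh_cache(stack, preset.camera, preset.optics)
    before = state.candidates.positions.copy()
    streams = Substreams(4)
    cfg = default_config()
    update_tracks_phase(
        state, stack, preset.camera, preset.optics, priors, cfg, streams, 0, "odd"
    )
    frames = _phase_frames(4, "odd")
    assert np.all(state.candidates.positions[frames] != before[frames])


def test_phase_frames_partition():
    assert _phase_frames(7, "even").tolist() == [0, 2, 4, 6]
    assert _phase_frames(7, "odd").tolist() == [1, 3, 5]
    with pytest.raises(ValueError):
        _phase_frames(7, "diagonal")


def test_each_frame_touched_once_per_sweep(monkeypatch):
    preset, truth, stack, priors, state = small_spad_problem(n_frames=6)
    touched = []
    import bayestrack.sampler as sm

    orig = sm._bridge_moments

    def spy(x_prev, x_next, step_var):
        touched.append(1)
        return orig(x_prev, x_next, step_var)

    monkeypatch.setattr(sm, "_bridge_moments", spy)
    streams = Substreams(1)
    cfg = default_config()
    for phase in ("even", "odd"):
        update_tracks_phase(
            state, stack, preset.camera, preset.optics, priors, cfg, streams, 0, phase
        )
    assert len(touched) == 6  # one proposal per frame per candidate


def test_frame_order_within_phase_is_irrelevant():
    preset, truth, stack, priors, state = small_spad_problem(n_frames=8)
    cfg = default_config()
    s1 = state.copy()
    s2 = state.copy()
    streams = Substreams(cfg.seed)
    update_tracks_phase(
        s1, stack, preset.camera, preset.optics, priors, cfg, streams, 0, "even"
    )
    update_tracks_phase(
        s2,
        stack,
        preset.camera,
        preset.optics,
        priors,
        cfg,
        streams,
        0,
        "even",
        frame_order=np.array([6, 0, 4, 2]),
    )
    np.testing.assert_array_equal(s1.candidates.positions, s2.candidates.positions)
    np.testing.assert_array_equal(s1.ll_frames, s2.ll_frames)


def test_bad_frame_order_rejected():
    preset, truth, stack, priors, state = small_spad_problem()
    cfg = default_config()
    with pytest.raises(ValueError):
        update_tracks_phase(
            state,
            stack,
            preset.camera,
            preset.optics,
            priors,
            cfg,
            Substreams(0),
            0,
            "even",
            frame_order=np.array([1, 3]),
        )


def test_single_frame_dataset_updates_from_uniform():
    preset, truth, stack, priors, state = small_spad_problem(n_frames=1)
    cfg = default_config()
    streams = Substreams(11)
    for it in range(20):
        update_tracks_phase(
            state, stack, preset.camera, preset.optics, priors, cfg, streams, it, "even"
        )
    assert np.all(priors.contains(state.candidates.positions[0]))
    assert state.audit_cache(stack, preset.camera, preset.optics) < 1e-9


def test_single_frame_posterior_matches_grid():
    # N=1: the track posterior is likelihood x flat prior on one frame,
    # which we can normalise on a dense grid and compare marginals against.
    # weak signal keeps the posterior broad so the uniform independence
    # proposal mixes fast enough for a KS comparison
    preset, truth, stack, priors, state = small_spad_problem(
        seed=21, n_frames=1, size=8, h=0.5, bg=0.05
    )
    cfg = default_config()
    streams = Substreams(42)
    xs = []
    for it in range(100_000):
        update_tracks_phase(
            state, stack, preset.camera, preset.optics, priors, cfg, streams, it, "even"
        )
        # thinning by 10 leaves ~1% residual dependence at ~0.37 acceptance
        if it >= 500 and it % 10 == 0:
            xs.append(state.candidates.positions[0, 0].copy())
    xs = np.asarray(xs)

    grid = np.linspace(0.0, 8 * 133.0, 161)
    gx, gy = np.meshgrid(grid, grid, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel()], axis=-1)[None, :, :]  # (1, G, 2)
    log_dens = np.empty(pts.shape[1])
    for idx in range(pts.shape[1]):
        field = expected_photons_batched(
            pts[:, idx : idx + 1, :],
            [1],
            state.brightness,
            state.background_rate,
            preset.optics,
            (8, 8),
        )
        log_dens[idx], _ = stack_loglike(stack.values, field.u, preset.camera)
    dens = np.exp(log_dens - log_dens.max()).reshape(len(grid), len(grid))

    from scipy.integrate import cumulative_trapezoid

    for axis, name in ((0, "x"), (1, "y")):
        marg = dens.sum(axis=1 - axis)
        cdf = cumulative_trapezoid(marg, grid, initial=0.0)
        cdf /= cdf[-1]
        stat = kstest(xs[:, axis], lambda v: np.interp(v, grid, cdf)).statistic
        assert stat < 0.02, f"axis {name}: KS={stat:.4f}"


# ---------------------------------------------------------------------------
# load updates


def test_zero_brightness_load_probability_is_gamma():
    preset, truth, stack, priors, state = small_spad_problem(k=1)
    state.brightness = 0.0
    state.refresh_cache(stack, preset.camera, preset.optics)
    streams = Substreams(17)
    draws = []
    for it in range(4000):
        update_loads(state, stack, preset.camera, priors, streams, it)
        draws.append(int(state.candidates.loads[0]))
    p_hat = np.mean(draws)
    se = math.sqrt(0.5 * 0.5 / len(draws))
    assert p_hat == pytest.approx(priors.load_prob, abs=4 * se)


def test_gamma_one_forces_all_loads_on():
    preset, truth, stack, priors, state = small_spad_problem(k=2)
    priors1 = make_priors(load_prob=1.0, msd_scale_nm2=priors.msd_scale_nm2)
    state.candidates.loads[:] = 0
    state.refresh_cache(stack, preset.camera, preset.optics)
    update_loads(state, stack, preset.camera, priors1, Substreams(0), 0)
    assert state.candidates.loads.tolist() == [1, 1]
    assert state.audit_cache(stack, preset.camera, preset.optics) < 1e-8


def test_gamma_zero_forces_all_loads_off():
    preset, truth, stack, priors, state = small_spad_problem(k=2)
    priors0 = make_priors(load_prob=0.0, msd_scale_nm2=priors.msd_scale_nm2)
    update_loads(state, stack, preset.camera, priors0, Substreams(0), 0)
    assert state.candidates.loads.tolist() == [0, 0]
    assert state.audit_cache(stack, preset.camera, preset.optics) < 1e-8


def test_load_flip_keeps_cache_consistent():
    preset, truth, stack, priors, state = small_spad_problem(k=2, h=4.0)
    streams = Substreams(23)
    for it in range(50):
        update_loads(state, stack, preset.camera, priors, streams, it)
        assert state.audit_cache(stack, preset.camera, preset.optics) < 1e-8


# ---------------------------------------------------------------------------
# MSD updates


def test_msd_prior_only_when_single_frame():
    preset, truth, stack, priors, state = small_spad_problem(n_frames=1)
    streams = Substreams(3)
    draws = np.array(
        [
            update_msd(state, priors, streams, it).motion.msd_per_frame_nm2
            for it in range(10_000)
        ]
    )
    ref = invgamma(a=priors.msd_shape, scale=priors.msd_scale_nm2)
    # moment check on the median (mean diverges for shape=2)
    med = np.median(draws)
    assert med == pytest.approx(ref.median(), rel=0.05)
    assert kstest(draws, ref.cdf).statistic < 0.02


def test_msd_posterior_mean_matches_invgamma_moment():
    preset, truth, stack, priors, state = small_spad_problem(n_frames=6, k=2)
    from bayestrack.motion import msd_conditional_params

    shape, scale = msd_conditional_params(state.candidates, priors)
    streams = Substreams(31)
    draws = np.array(
        [
            update_msd(state, priors, streams, it).motion.msd_per_frame_nm2
            for it in range(10_000)
        ]
    )
    expected_mean = scale / (shape - 1)
    expected_sd = math.sqrt(scale**2 / ((shape - 1) ** 2 * (shape - 2)))
    se = expected_sd / math.sqrt(len(draws))
    assert draws.mean() == pytest.approx(expected_mean, abs=4 * se)


def test_msd_posterior_tighter_for_degenerate_tracks():
    preset, truth, stack, priors, state = small_spad_problem(n_frames=5)
    from bayestrack.motion import msd_conditional_params

    state.candidates.positions[:] = state.candidates.positions[0]
    shape, scale = msd_conditional_params(state.candidates, priors)
    assert shape > priors.msd_shape
    assert scale == pytest.approx(priors.msd_scale_nm2)


# ---------------------------------------------------------------------------
# sweep / run_chain contracts


def test_sweep_deterministic_given_seed():
    preset, truth, stack, priors, state = small_spad_problem(n_frames=6, k=2)
    cfg = default_config(n_candidates=2)
    s1, s2 = state.copy(), state.copy()
    for s in (s1, s2):
        streams = Substreams(cfg.seed)
        for it in range(3):
            sweep(s, stack, preset.camera, preset.optics, priors, cfg, streams, it)
    np.testing.assert_array_equal(s1.candidates.positions, s2.candidates.positions)
    np.testing.assert_array_equal(s1.candidates.loads, s2.candidates.loads)
    assert s1.motion == s2.motion


def test_sweep_cache_audit_invariant():
    preset, truth, stack, priors, state = small_spad_problem(n_frames=6, k=2, h=5.0)
    cfg = default_config(n_candidates=2)
    streams = Substreams(cfg.seed)
    for it in range(30):
        sweep(state, stack, preset.camera, preset.optics, priors, cfg, streams, it)
        assert state.audit_cache(stack, preset.camera, preset.optics) < 1e-6


def test_sweep_reuses_preallocated_workspace():
    preset, truth, stack, priors, state = small_spad_problem(n_frames=6)
    cfg = default_config()
    streams = Substreams(0)
    ids = (id(state.u), id(state.ux), id(state.uy), id(state.ll_frames))
    for it in range(5):
        sweep(state, stack, preset.camera, preset.optics, priors, cfg, streams, it)
    assert (id(state.u), id(state.ux), id(state.uy), id(state.ll_frames)) == ids


def test_run_chain_empty_when_burnin_equals_iterations():
    preset, truth, stack, priors, state = small_spad_problem()
    cfg = default_config(n_iterations=5, burn_in=5)
    samples = run_chain(stack, preset.camera, preset.optics, priors, cfg)
    assert len(samples) == 0
    assert samples.log_posterior_trace.shape == (5,)


def test_run_chain_sample_count_and_stamps():
    preset, truth, stack, priors, state = small_spad_problem()
    cfg = default_config(n_iterations=21, burn_in=5, thin=3)
    samples = run_chain(stack, preset.camera, preset.optics, priors, cfg)
    assert len(samples) == math.ceil((21 - 5) / 3)
    assert np.all(np.diff(samples.iterations) == 3)


def test_checkpoint_resume_bit_identical():
    preset, truth, stack, priors, state = small_spad_problem(n_frames=6, k=2)
    cfg_full = default_config(n_iterations=40, burn_in=0, n_candidates=2)
    full = run_chain(stack, preset.camera, preset.optics, priors, cfg_full)

    cfg_half = default_config(n_iterations=20, burn_in=0, n_candidates=2)
    first = run_chain(stack, preset.camera, preset.optics, priors, cfg_half)
    second = run_chain(
        stack,
        preset.camera,
        preset.optics,
        priors,
        cfg_full,
        init_state=first.final_state,
    )
    spliced = first.extend(second)
    np.testing.assert_array_equal(spliced.tracks, full.tracks)
    np.testing.assert_array_equal(spliced.loads, full.loads)
    np.testing.assert_array_equal(spliced.msd, full.msd)
    np.testing.assert_array_equal(
        spliced.log_posterior_trace, full.log_posterior_trace
    )


def test_parametric_mode_keeps_loads_fixed():
    preset, truth, stack, priors, state = small_spad_problem(k=2)
    cfg = default_config(
        n_iterations=15, n_candidates=2, parametric_mode=True, init="prior"
    )
    samples = run_chain(stack, preset.camera, preset.optics, priors, cfg)
    assert np.all(samples.loads == 1)


def test_parametric_equals_gamma_one_nonparametric_bitwise():
    # With gamma = 1 the load update is a deterministic no-op, so the two
    # modes consume identical track/msd substreams and must agree exactly.
    preset, truth, stack, priors, state = small_spad_problem(k=2, n_frames=6)
    priors1 = make_priors(load_prob=1.0, msd_scale_nm2=priors.msd_scale_nm2)
    cfg_p = default_config(
        n_iterations=25, n_candidates=2, parametric_mode=True, init="prior", seed=9
    )
    cfg_np = default_config(
        n_iterations=25, n_candidates=2, parametric_mode=False, init="prior", seed=9
    )
    sp = run_chain(stack, preset.camera, preset.optics, priors1, cfg_p)
    snp = run_chain(stack, preset.camera, preset.optics, priors1, cfg_np)
    np.testing.assert_array_equal(sp.tracks, snp.tracks)
    np.testing.assert_array_equal(sp.msd, snp.msd)
    np.testing.assert_array_equal(sp.loads, snp.loads)


def test_run_chain_rejects_nonbinary_spad_stack():
    preset, truth, stack, priors, state = small_spad_problem()
    bad = ImageStack(
        np.full_like(stack.values, 7), stack.pixel_size_nm, stack.exposure_s
    )
    cfg = default_config()
    with pytest.raises(ValueError):
        run_chain(bad, preset.camera, preset.optics, priors, cfg)


# ---------------------------------------------------------------------------
# posterior summaries


def _toy_samples(k=3, n=4, s=50, seed=0, msd_draws=None):
    rng = np.random.default_rng(seed)
    loads = np.ones((s, k), dtype=np.int8)
    tracks = rng.normal(500, 5, size=(s, n, k, 2)) + np.arange(k)[None, None, :, None] * 800
    msd = msd_draws if msd_draws is not None else rng.uniform(1e3, 2e3, size=s)
    return PosteriorSamples(
        iterations=np.arange(s),
        loads=loads,
        tracks=tracks,
        msd=np.asarray(msd),
        background=np.zeros(s),
        brightness=np.zeros(s),
        log_posterior=np.zeros(s),
        log_posterior_trace=np.zeros(s),
        config=default_config(n_candidates=k),
    )


def test_summary_identical_samples_zero_width():
    samples = _toy_samples(s=20)
    samples.tracks[:] = samples.tracks[0]
    samples.msd[:] = 1234.0
    summary = posterior_summary(samples)
    assert summary["msd"]["ci90"] == (1234.0, 1234.0)
    np.testing.assert_allclose(
        summary["track_bands"]["lo90"], summary["track_bands"]["hi90"]
    )


def test_summary_msd_ci_matches_invgamma_quantiles():
    rng = np.random.default_rng(7)
    ref = invgamma(a=12.0, scale=30_000.0)
    draws = ref.rvs(size=20_000, random_state=rng)
    summary = posterior_summary(_toy_samples(s=20_000, msd_draws=draws))
    lo, hi = summary["msd"]["ci90"]
    assert lo == pytest.approx(ref.ppf(0.05), rel=0.02)
    assert hi == pytest.approx(ref.ppf(0.95), rel=0.02)


def test_summary_invariant_to_sample_permutation():
    samples = _toy_samples(s=40)
    perm = np.random.default_rng(1).permutation(40)
    shuffled = PosteriorSamples(
        iterations=samples.iterations,
        loads=samples.loads[perm],
        tracks=samples.tracks[perm],
        msd=samples.msd[perm],
        background=samples.background[perm],
        brightness=samples.brightness[perm],
        log_posterior=samples.log_posterior[perm],
        log_posterior_trace=samples.log_posterior_trace,
        config=samples.config,
    )
    a = posterior_summary(samples)
    b = posterior_summary(shuffled)
    assert a["modal_m"] == b["modal_m"]
    np.testing.assert_allclose(a["mean_tracks"], b["mean_tracks"], atol=1e-9)
    assert a["msd"]["mean"] == pytest.approx(b["msd"]["mean"])


def test_summary_requires_samples():
    empty = _toy_samples(s=1)
    empty = PosteriorSamples(
        iterations=np.empty(0, dtype=int),
        loads=np.empty((0, 2), dtype=np.int8),
        tracks=np.empty((0, 3, 2, 2)),
        msd=np.empty(0),
        background=np.empty(0),
        brightness=np.empty(0),
        log_posterior=np.empty(0),
        log_posterior_trace=np.empty(0),
        config=default_config(),
    )
    with pytest.raises(ValueError):
        posterior_summary(empty)


def test_log_posterior_finite_on_valid_state():
    preset, truth, stack, priors, state = small_spad_problem()
    lp = log_posterior(state, priors)
    assert np.isfinite(lp)
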