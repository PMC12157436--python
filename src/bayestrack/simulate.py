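"""Synthetic-movie generation through the same forward model as inference.

Ground-truth Brownian tracks are rendered through the pixel-integrated
Gaussian PSF and the chosen camera model, so parameter-recovery experiments
are well-posed: what the simulator draws is exactly what the likelihood
assumes (EMCCD frames are additionally clipped at zero and quantised to
integer ADU, a deliberate slight mismatch tolerated by the Gaussian
likelihood).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from .likelihood import (
    CameraEMCCD,
    CameraSPAD,
    ImageStack,
    PhotonField,
    erf_strip_integral,
    expected_photons_batched,
)
from .motion import MotionParams, Priors, fov_for_frame, sample_tracks_prior
from .optics import DEFAULT_OPTICS, OpticsConfig

__all__ = [
    "SimulationPreset",
    "GroundTruth",
    "calibrate_brightness",
    "simulate_ground_truth",
    "render_stack",
    "make_preset",
    "simulate_movie",
]

Camera = Union[CameraEMCCD, CameraSPAD]


@dataclass(frozen=True)
class SimulationPreset:
    """Complete recipe for one synthetic movie."""

    optics: OpticsConfig
    camera: Camera
    n_frames: int
    frame_size: int
    n_particles: int
    diffusion_um2_s: float
    exposure_s: float
    center_pixel_photons: float
    background_rate: float
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_frames, self.frame_size, self.n_particles) < 1:
            raise ValueError("counts must be >= 1")
        if self.center_pixel_photons < 0 or self.background_rate < 0:
            raise ValueError("photon rates must be nonnegative")
        if self.diffusion_um2_s < 0 or self.exposure_s <= 0:
            raise ValueError("invalid motion parameters")

    @property
    def msd_per_frame_nm2(self) -> float:
        """2-D MSD per frame: 4 * D * dt, in nm^2."""
        return 4.0 * self.diffusion_um2_s * self.exposure_s * 1e6

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frame_size, self.frame_size


@dataclass
class GroundTruth:
    """Simulated truth: tracks, calibrated brightness and expected fields."""

    preset: SimulationPreset
    tracks: np.ndarray  # (N, M, 2) nm
    brightness: float
    background_rate: float
    field: PhotonField


def calibrate_brightness(target_center_photons: float, optics: OpticsConfig) -> float:
    """Brightness scale h giving ``target`` photons at the concentric pixel.

    For an in-focus particle centred on a pixel, the pixel's expected signal
    is ``h * f**2`` with ``f`` the 1-D Gaussian mass of one pixel-wide strip
    centred on the particle; invert that.
    """
    if target_center_photons < 0:
        raise ValueError("target photon count must be nonnegative")
    half = optics.pixel_size_nm / 2.0
    f = float(erf_strip_integral(0.0, -half, half, optics.psf_variance_nm2))
    if f <= 0:
        raise ValueError("degenerate optics: zero central-pixel mass")
    return target_center_photons / (f * f)


def simulate_ground_truth(preset: SimulationPreset) -> GroundTruth:
    """Draw Brownian tracks and compute the expected-photon field.

    Initial positions are uniform over the central 80% of the field of view
    (to limit edge truncation); regeneration from the same preset is
    bit-identical.
    """
    rng = np.random.Generator(
        np.random.Philox(key=np.uint64(preset.seed & 0xFFFFFFFFFFFFFFFF))
    )
    motion = MotionParams(
        msd_per_frame_nm2=max(preset.msd_per_frame_nm2, 1e-12)
    )
    priors = Priors(
        msd_shape=2.0,
        msd_scale_nm2=max(preset.msd_per_frame_nm2, 1e-12),
        load_prob=1.0,
        fov_bounds=fov_for_frame(preset.frame_shape, preset.optics.pixel_size_nm),
    )
    tracks = sample_tracks_prior(
        preset.n_particles,
        preset.n_frames,
        motion,
        priors,
        rng,
        initial_margin=0.1,
    )
    if preset.diffusion_um2_s == 0:
        tracks[1:] = tracks[0]
    h = calibrate_brightness(preset.center_pixel_photons, preset.optics)
    field = expected_photons_batched(
        tracks,
        np.ones(preset.n_particles, dtype=np.int8),
        h,
        preset.background_rate,
        preset.optics,
        preset.frame_shape,
    )
    return GroundTruth(
        preset=preset,
        tracks=tracks,
        brightness=h,
        background_rate=preset.background_rate,
        field=field,
    )


def render_stack(
    truth: GroundTruth, camera: Optional[Camera] = None, rng=None
) -> ImageStack:
    """Render noisy frames from the expected-photon field.

    SPAD pixels are Bernoulli(1 - exp(-u)); EMCCD pixels are Gaussian with
    the same mean/variance the likelihood assumes, then clipped at zero and
    rounded to integer ADU.
    """
    preset = truth.preset
    if camera is None:
        camera = preset.camera
    if rng is None:
        rng = np.random.Generator(
            np.random.Philox(
                key=np.uint64(preset.seed & 0xFFFFFFFFFFFFFFFF), counter=[1, 0, 0, 0]
            )
        )
    u = truth.field.u
    if isinstance(camera, CameraSPAD):
        hit_prob = -np.expm1(-u)
        values = (rng.random(u.shape) < hit_prob).astype(np.uint8)
    else:
        draw = rng.normal(camera.mean(u), np.sqrt(camera.variance(u)))
        values = np.clip(np.rint(draw), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return ImageStack(
        values=values,
        pixel_size_nm=preset.optics.pixel_size_nm,
        exposure_s=preset.exposure_s,
    )


def simulate_movie(preset: SimulationPreset) -> tuple[GroundTruth, ImageStack]:
    """Convenience wrapper: ground truth plus a rendered stack."""
    truth = simulate_ground_truth(preset)
    return truth, render_stack(truth)


def make_preset(
    variant: str,
    level: Optional[float] = None,
    frame_size: int = 128,
    n_frames: int = 10,
    n_particles: int = 10,
    seed: int = 0,
) -> SimulationPreset:
    """Reference EMCCD presets mirroring the package's benchmark scenarios.

    ``variant='background-sweep'``: 80 photons at the concentric pixel,
    ``level`` sets the background (photons/pixel/frame, default 10).
    ``variant='emission-sweep'``: background fixed at 60 photons/pixel/frame,
    ``level`` sets the concentric-pixel photons (default 80).
    Optics: NA 1.45, n 1.515, 665 nm emission, 133 nm pixels, 33 ms
    exposure, EMCCD offset and gain 100; particles diffuse at 0.1 um^2/s.
    ``frame_size`` overrides geometry only (densities preserved by caller
    choice of ``n_particles``).
    """
    camera = CameraEMCCD(offset=100.0, em_gain=100.0, read_noise_sd=2.0)
    common = dict(
        optics=DEFAULT_OPTICS,
        camera=camera,
        n_frames=n_frames,
        frame_size=frame_size,
        n_particles=n_particles,
        diffusion_um2_s=0.1,
        exposure_s=0.033,
        seed=seed,
    )
    if variant == "background-sweep":
        return SimulationPreset(
            center_pixel_photons=80.0,
            background_rate=10.0 if level is None else float(level),
            **common,
        )
    if variant == "emission-sweep":
        return SimulationPreset(
            center_pixel_photons=80.0 if level is None else float(level),
            background_rate=60.0,
            **common,
        )
    raise ValueError(
        f"unknown variant {variant!r}; expected 'background-sweep' or 'emission-sweep'"
    )
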