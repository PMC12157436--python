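"""Expected-photon fields and detector likelihoods.

The emission model is separable: the expected photon count at pixel
``(i, j)`` of frame ``n`` is

    u[n, i, j] = background + h * sum_m b_m * Px[n, i, m] * Py[n, j, m]

where ``Px``/``Py`` hold the 1-D Gaussian probability masses of each
particle over pixel columns/rows (computed with the error function), ``h``
is the particle brightness and ``b_m`` the binary loads.  The batched path
evaluates the sum as one matrix product per frame; a deliberately naive
per-pixel loop is kept as a verification oracle.

Coordinate convention: positions are continuous (x, y) in nm; pixel
``(i, j)`` covers the half-open square ``[i*D, (i+1)*D) x [j*D, (j+1)*D)``
with ``D`` the pixel pitch, ``x`` along the ``i`` (first pixel) axis and
``y`` along the ``j`` axis.  Stacks are indexed ``[n, i, j]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .optics import OpticsConfig, psf_sigma

__all__ = [
    "CameraEMCCD",
    "CameraSPAD",
    "ImageStack",
    "PhotonField",
    "erf_strip_integral",
    "pixel_edges",
    "axis_masses",
    "expected_photons_batched",
    "expected_photons_serial_oracle",
    "loglike_spad",
    "loglike_emccd",
    "frame_loglike",
    "stack_loglike",
]


@dataclass(frozen=True)
class CameraEMCCD:
    """Gaussian read-out model for an electron-multiplying CCD.

    A pixel receiving ``u`` expected photons reads out
    ``Normal(offset + em_gain * u, excess_noise_factor_sq * em_gain**2 * u
    + read_noise_sd**2)`` in ADU.  The excess-noise factor squared defaults
    to 2, the high-gain limit of the EM register.
    """

    offset: float = 100.0
    em_gain: float = 100.0
    read_noise_sd: float = 2.0
    excess_noise_factor_sq: float = 2.0

    def __post_init__(self) -> None:
        if not self.em_gain > 0:
            raise ValueError("em_gain must be positive")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be nonnegative")
        if self.excess_noise_factor_sq < 1:
            raise ValueError("excess_noise_factor_sq must be >= 1")

    def mean(self, u):
        return self.offset + self.em_gain * np.asarray(u, dtype=float)

    def variance(self, u):
        return (
            self.excess_noise_factor_sq * self.em_gain**2 * np.asarray(u, dtype=float)
            + self.read_noise_sd**2
        )


@dataclass(frozen=True)
class CameraSPAD:
    """Binary single-photon avalanche diode array: P(hit) = 1 - exp(-u)."""


@dataclass
class ImageStack:
    """Recorded movie: (N, I, J) per-pixel measurements plus acquisition metadata.

    Values are ADU for an EMCCD read-out or {0, 1} for a SPAD array.
    """

    values: np.ndarray
    pixel_size_nm: float
    exposure_s: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must have shape (n_frames, I, J)")
        if not np.all(np.isfinite(self.values.astype(float))):
            raise ValueError("values must be finite")
        if not (self.pixel_size_nm > 0 and self.exposure_s > 0):
            raise ValueError("pixel_size_nm and exposure_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.values.shape[1], self.values.shape[2]

    def validate_for_camera(self, camera) -> None:
        """Reject stacks inconsistent with the camera model (e.g. non-binary SPAD)."""
        if isinstance(camera, CameraSPAD):
            vals = np.unique(self.values)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(
                    f"SPAD stacks must contain only 0/1 values; found {vals[:8]}"
                )


@dataclass
class PhotonField:
    """Expected photons per pixel per frame plus the scalars that built it."""

    u: np.ndarray  # (N, I, J), photons
    background_rate: float  # photons / pixel / frame
    brightness: float  # photons (scale factor h)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 3:
            raise ValueError("u must have shape (n_frames, I, J)")
        if self.background_rate < 0:
            raise ValueError("background_rate must be nonnegative")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("u must be finite")
        if np.any(self.u < self.background_rate - 1e-12):
            raise ValueError("u must be >= background_rate everywhere")


def erf_strip_integral(center, lo, hi, variance):
    """Mass of a 1-D Gaussian N(center, variance) over the strip [lo, hi].

    Vectorised over all arguments; uses the normal CDF (``ndtr``) so the
    result is accurate in both tails.
    """
    variance = np.asarray(variance, dtype=float)
    if np.any(variance <= 0):
        raise ValueError("variance must be strictly positive")
    sd = np.sqrt(variance)
    return ndtr((np.asarray(hi) - center) / sd) - ndtr((np.asarray(lo) - center) / sd)


def pixel_edges(n_pixels: int, pixel_size_nm: float) -> np.ndarray:
    """Edge coordinates (nm) of ``n_pixels`` contiguous pixels from 0."""
    return np.arange(n_pixels + 1, dtype=float) * pixel_size_nm


def axis_masses(coords: np.ndarray, edges: np.ndarray, variance: float) -> np.ndarray:
    """Gaussian pixel-strip masses for many particles along one axis.

    Parameters
    ----------
    coords : (..., M) positions in nm along the axis.
    edges : (P+1,) pixel edges in nm.
    variance : scalar PSF variance in nm^2.

    Returns
    -------
    (..., P, M) array of per-pixel probability masses.
    """
    coords = np.asarray(coords, dtype=float)
    sd = np.sqrt(variance)
    # CDF at all edges: (..., P+1, M)
    z = (edges[..., :, None] - coords[..., None, :]) / sd
    cdf = ndtr(z)
    return np.diff(cdf, axis=-2)


def expected_photons_batched(
    positions: np.ndarray,
    loads: np.ndarray,
    brightness: float,
    background_rate: float,
    optics: OpticsConfig,
    frame_shape: tuple[int, int],
) -> PhotonField:
    """Expected-photon field from the active candidates, via batched matmul.

    Parameters
    ----------
    positions : (N, K, 2) candidate positions in nm (x, y).
    loads : (K,) binary activity indicators.
    brightness : photons contributed by a particle, as the scale factor h.
    background_rate : photons / pixel / frame, added uniformly.
    optics : acquisition optics (PSF width, pixel pitch).
    frame_shape : (I, J) pixel counts along x and y.
    """
    if brightness < 0:
        raise ValueError("brightness must be nonnegative")
    if background_rate < 0:
        raise ValueError("background_rate must be nonnegative")
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 3 or positions.shape[-1] != 2:
        raise ValueError("positions must have shape (n_frames, n_candidates, 2)")
    loads = np.asarray(loads)
    n_frames = positions.shape[0]
    n_i, n_j = frame_shape

    active = np.flatnonzero(loads)
    u = np.full((n_frames, n_i, n_j), float(background_rate))
    if active.size and brightness > 0:
        var = optics.psf_variance_nm2
        delta = optics.pixel_size_nm
        px = axis_masses(positions[:, active, 0], pixel_edges(n_i, delta), var)
        py = axis_masses(positions[:, active, 1], pixel_edges(n_j, delta), var)
        # (N, I, M) @ (N, M, J) -> (N, I, J), batched over frames
        u += brightness * (px @ py.transpose(0, 2, 1))
    return PhotonField(u=u, background_rate=background_rate, brightness=brightness)


def expected_photons_serial_oracle(
    positions: np.ndarray,
    loads: np.ndarray,
    brightness: float,
    background_rate: float,
    optics: OpticsConfig,
    frame_shape: tuple[int, int],
) -> PhotonField:
    """Per-pixel triple-loop reference for :func:`expected_photons_batched`.

    Intentionally slow; used only to verify the batched path on small
    instances.
    """
    if brightness < 0 or background_rate < 0:
        raise ValueError("brightness and background_rate must be nonnegative")
    positions = np.asarray(positions, dtype=float)
    n_frames = positions.shape[0]
    n_i, n_j = frame_shape
    var = optics.psf_variance_nm2
    delta = optics.pixel_size_nm
    u = np.empty((n_frames, n_i, n_j))
    active = [m for m in range(positions.shape[1]) if loads[m]]
    for n in range(n_frames):
        for i in range(n_i):
            for j in range(n_j):
                total = background_rate
                for m in active:
                    x, y = positions[n, m]
                    mass_x = erf_strip_integral(x, i * delta, (i + 1) * delta, var)
                    mass_y = erf_strip_integral(y, j * delta, (j + 1) * delta, var)
                    total += brightness * mass_x * mass_y
                u[n, i, j] = total
    return PhotonField(u=u, background_rate=background_rate, brightness=brightness)


def loglike_spad(w, u):
    """Bernoulli log-likelihood of binary measurements: P(1) = 1 - exp(-u).

    ``w == 0`` contributes exactly ``-u``; ``w == 1`` uses ``log(-expm1(-u))``
    for stability at small ``u``.  ``w = 1`` with ``u = 0`` yields ``-inf``.
    """
    w = np.asarray(w)
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("expected photon counts must be nonnegative")
    with np.errstate(divide="ignore"):
        hit = np.log(-np.expm1(-u))
    return np.where(w == 0, -u, hit)


def loglike_emccd(w, u, camera: CameraEMCCD):
    """Gaussian read-out log-density of ADU measurements given photons ``u``."""
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("expected photon counts must be nonnegative")
    var = camera.variance(u)
    if np.any(var <= 0):
        raise ValueError(
            "total read-out variance must be positive; set read_noise_sd > 0 "
            "when u can reach zero"
        )
    resid = np.asarray(w, dtype=float) - camera.mean(u)
    return -0.5 * (np.log(2.0 * np.pi * var) + resid * resid / var)


def _pixel_loglike(w, u, camera):
    if isinstance(camera, CameraSPAD):
        return loglike_spad(w, u)
    if isinstance(camera, CameraEMCCD):
        return loglike_emccd(w, u, camera)
    raise TypeError(f"unsupported camera model: {camera!r}")


def frame_loglike(w_frame, u_frame, camera) -> float:
    """Log-likelihood of one frame (sum over its pixels)."""
    return float(np.sum(_pixel_loglike(w_frame, u_frame, camera)))


def stack_loglike(values, field, camera):
    """Total and per-frame log-likelihood of a full stack.

    Parameters
    ----------
    values : (N, I, J) measurements (ADU or binary).
    field : :class:`PhotonField` or an (N, I, J) array of expected photons.
    camera : :class:`CameraEMCCD` or :class:`CameraSPAD`.

    Returns
    -------
    total : float (may be ``-inf``; never NaN)
    per_frame : (N,) array of frame subtotals.
    """
    u = field.u if isinstance(field, PhotonField) else np.asarray(field, dtype=float)
    values = np.asarray(values)
    if values.shape != u.shape:
        raise ValueError(f"shape mismatch: data {values.shape} vs field {u.shape}")
    per_pixel = _pixel_loglike(values, u, camera)
    per_frame = per_pixel.reshape(per_pixel.shape[0], -1).sum(axis=1)
    return float(per_frame.sum()), per_frame
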