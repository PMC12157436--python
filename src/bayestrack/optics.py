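"""Optical configuration and the Gaussian-PSF width rule."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class OpticsConfig:
    """Acquisition optics for a widefield fluorescence movie.

    Lengths are in nanometres throughout the package.  The lateral PSF is
    approximated by an isotropic 2-D Gaussian whose standard deviation is
    ``psf_sigma_factor * emission_wavelength_nm / numerical_aperture``
    (in-focus approximation); the factor is configurable so alternative
    width rules, e.g. z-dependent ones, can be plugged in upstream.
    """

    numerical_aperture: float
    refractive_index: float
    emission_wavelength_nm: float
    pixel_size_nm: float
    psf_sigma_factor: float = 0.21

    def __post_init__(self) -> None:
        for name in (
            "numerical_aperture",
            "refractive_index",
            "emission_wavelength_nm",
            "pixel_size_nm",
            "psf_sigma_factor",
        ):
            value = getattr(self, name)
            if not (value > 0):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.numerical_aperture >= self.refractive_index:
            raise ValueError(
                "numerical_aperture must be smaller than refractive_index "
                f"({self.numerical_aperture} >= {self.refractive_index})"
            )

    @property
    def psf_sigma_nm(self) -> float:
        return psf_sigma(self)

    @property
    def psf_variance_nm2(self) -> float:
        s = psf_sigma(self)
        return s * s


def psf_sigma(optics: OpticsConfig) -> float:
    """Lateral Gaussian-PSF standard deviation in nm for in-focus emitters."""
    return optics.psf_sigma_factor * optics.emission_wavelength_nm / optics.numerical_aperture


# Reference acquisition parameters used by the bundled simulator presets.
DEFAULT_OPTICS = OpticsConfig(
    numerical_aperture=1.45,
    refractive_index=1.515,
    emission_wavelength_nm=665.0,
    pixel_size_nm=133.0,
)
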