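"""Image formation: emission, photobleaching, PSF splatting, EMCCD readout.

Each illuminated substep every active fluorophore emits a photon packet
whose mean is I(x,y,z) · N_ph(0,0,0) · Δt per tag; individual photons land
on the detector at the molecule position plus a 2D Gaussian offset whose
FWHM follows the defocus law FWHM(z) = γ_obj·(z - z_f)² + FWHM_f.  Substeps
are summed into one photon image per camera frame, which is then converted
to counts by a per-pixel stochastic EMCCD gain and additive Gaussian
background noise, saturating at 16 bits.

Emission-number fluctuation follows a flat (linear-RNG) law of total width
sqrt(N) around the mean; a Poisson option is available via
``CameraSpec.photon_noise = "poisson"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import CameraSpec, OpticsSpec

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
U16_MAX = np.iinfo(np.uint16).max


def psf_fwhm_um(z_um, optics: OpticsSpec):
    """Image FWHM of a fluorophore at height z: quadratic growth with defocus."""
    dz = np.asarray(z_um, dtype=float) - optics.z_focus_um
    return optics.gamma_obj_per_um * dz * dz + optics.psf_fwhm_nm * 1e-3


def diffraction_limited_fwhm_nm(lambda_nm: float, na: float) -> float:
    """In-focus PSF size estimate FWHM = 0.6·λ/NA."""
    return 0.6 * lambda_nm / na


def emitted_photons(mean_photons: np.ndarray, camera: CameraSpec,
                    rng: np.random.Generator) -> np.ndarray:
    """Integer photon packets with the configured fluctuation law.

    ``uniform``: flat over [mean - sqrt(mean)/2, mean + sqrt(mean)/2]
    (total spread sqrt(N)); ``poisson``: standard shot noise.
    """
    mean = np.asarray(mean_photons, dtype=float)
    if camera.photon_noise == "poisson":
        return rng.poisson(mean).astype(np.int64)
    half = 0.5 * np.sqrt(mean)
    n = np.rint(mean + rng.uniform(-1.0, 1.0, size=mean.shape) * half)
    return np.maximum(n, 0.0).astype(np.int64)


def bleach_step(tags_active: np.ndarray, intensity: np.ndarray,
                r_bleach: float, dt_s: float,
                rng: np.random.Generator) -> np.ndarray:
    """One photobleaching substep: each active tag independently survives
    with probability 1 - R_bleach·Δt·I(x,y,z).  Bleached tags never recover.
    Returns the updated (copied) tag matrix."""
    tags = np.asarray(tags_active, dtype=bool).copy()
    if r_bleach <= 0 or tags.size == 0:
        return tags
    p = np.clip(r_bleach * dt_s * np.asarray(intensity, dtype=float), 0.0, 1.0)
    hit = rng.random(tags.shape) < p[:, None]
    return tags & ~hit


def splat_photons(photon_image: np.ndarray, x_um: np.ndarray, y_um: np.ndarray,
                  n_photons: np.ndarray, fwhm_um: np.ndarray,
                  pixel_um: float, rng: np.random.Generator) -> int:
    """Deposit photons around each emitter position; returns the number of
    photons that fell outside the frame (dropped).

    Per-photon sampling: every photon gets an independent Gaussian (x, y)
    offset with the emitter's defocus-dependent FWHM, then lands in the
    containing pixel (row = y, col = x).
    """
    n_photons = np.asarray(n_photons, dtype=np.int64)
    total = int(n_photons.sum())
    if total == 0:
        return 0
    x0 = np.repeat(np.asarray(x_um, dtype=float), n_photons)
    y0 = np.repeat(np.asarray(y_um, dtype=float), n_photons)
    sigma = np.repeat(np.asarray(fwhm_um, dtype=float) * FWHM_TO_SIGMA,
                      n_photons)
    px = np.floor((x0 + rng.normal(size=total) * sigma) / pixel_um).astype(np.int64)
    py = np.floor((y0 + rng.normal(size=total) * sigma) / pixel_um).astype(np.int64)
    h, w = photon_image.shape
    ok = (px >= 0) & (px < w) & (py >= 0) & (py < h)
    np.add.at(photon_image, (py[ok], px[ok]), 1)
    return int(total - ok.sum())


def finalize_frame(photon_image: np.ndarray, camera: CameraSpec,
                   rng: np.random.Generator) -> np.ndarray:
    """Convert an accumulated photon image to EMCCD counts.

    counts = round(photons × N(gain, σ_gain)⁺) + N(offset, noise RMS),
    clipped at zero and saturated to uint16.
    """
    photons = np.asarray(photon_image, dtype=float)
    g = np.maximum(rng.normal(camera.gain, camera.sigma_gain, photons.shape), 0.0) \
        if camera.sigma_gain > 0 else camera.gain
    counts = np.rint(photons * g)
    if camera.noise_rms > 0:
        counts = counts + np.rint(
            rng.normal(camera.offset, camera.noise_rms, photons.shape))
    elif camera.offset:
        counts = counts + round(camera.offset)
    return np.clip(counts, 0, U16_MAX).astype(np.uint16)


@dataclass
class FrameStack:
    """Rendered camera frames plus per-frame acquisition metadata."""

    frames: np.ndarray                       # (T, H, W) uint16
    times_s: np.ndarray                      # frame start times
    illuminated: np.ndarray                  # bool per frame
    z_focus_um: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.z_focus_um is None:
            self.z_focus_um = np.zeros(len(self.frames))

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def recorded(self) -> np.ndarray:
        """Frames actually exposed (the time-lapse record)."""
        return self.frames[self.illuminated]

    @property
    def recorded_times_s(self) -> np.ndarray:
        return self.times_s[self.illuminated]
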