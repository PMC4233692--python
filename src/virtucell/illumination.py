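"""3D illumination intensity fields and the temporal gating schedule.

All fields are normalised to 1 at the field centre on the coverslip
(z = 0 for epi/TIRF, the focal plane for confocal); the absolute photon
scale lives in the camera spec.  Supported modes:

* ``epi`` — TEM00 laser beam: 2D Gaussian in (x, y), constant in z.
* ``tirf`` — same lateral profile times exp(-z/d) with the evanescent
  penetration depth d = λ0 / (4π·sqrt(n3²·sin²θ - n1²)).
* ``confocal`` — laterally uniform (scanned), with the axial hyperbolic
  fall-off I(z) = I(z_f) · S_zf / (S_zf + π·(tanθ·|z - z_f|)²).
"""

from __future__ import annotations

import math

import numpy as np

from .config import ConfigurationError, IlluminationSpec

_4LN2 = 4.0 * math.log(2.0)


def epi_intensity(x_um, y_um, z_um, spec: IlluminationSpec,
                  centre_um: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Relative epi-illumination intensity; independent of z."""
    dx = np.asarray(x_um, dtype=float) - centre_um[0]
    dy = np.asarray(y_um, dtype=float) - centre_um[1]
    r2 = dx * dx + dy * dy
    out = np.exp(-_4LN2 * r2 / spec.beam_fwhm_um ** 2)
    if spec.diaphragm_radius_um is not None:
        out = np.where(r2 <= spec.diaphragm_radius_um ** 2, out, 0.0)
    return out


def tirf_penetration_depth_nm(lambda0_nm: float, angle_deg: float,
                              n1: float, n3: float) -> float:
    """Evanescent-field 1/e depth d in nm; diverges at the critical angle."""
    theta = math.radians(angle_deg)
    s = n3 * n3 * math.sin(theta) ** 2 - n1 * n1
    if s <= 0:
        raise ConfigurationError(
            f"incidence angle {angle_deg}° is not totally internally "
            f"reflected (critical angle "
            f"{math.degrees(math.asin(n1 / n3)):.2f}°)")
    return lambda0_nm / (4.0 * math.pi * math.sqrt(s))


def tirf_intensity(x_um, y_um, z_um, spec: IlluminationSpec,
                   centre_um: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Relative TIRF intensity: lateral epi profile × exp(-z/d)."""
    t = spec.tirf
    d_um = tirf_penetration_depth_nm(t.lambda0_nm, t.angle_deg, t.n1, t.n3) * 1e-3
    z = np.asarray(z_um, dtype=float)
    return epi_intensity(x_um, y_um, z_um, spec, centre_um) * np.exp(-z / d_um)


def confocal_intensity(x_um, y_um, z_um, spec: IlluminationSpec,
                       z_focus_um: float = 0.0,
                       centre_um: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Relative confocal illumination: laterally uniform, axially hyperbolic."""
    c = spec.confocal
    if c.szf_um2 <= 0:
        raise ConfigurationError("focused spot size must be > 0")
    dz = np.abs(np.asarray(z_um, dtype=float) - z_focus_um)
    tan_t = math.tan(math.radians(c.cone_half_angle_deg))
    return c.szf_um2 / (c.szf_um2 + math.pi * (tan_t * dz) ** 2)


def illumination_gate(frame_index: int, spec: IlluminationSpec) -> bool:
    """Deterministic on/off state of a frame under the gating schedule.

    One exposed frame leads every period of ``period_frames`` frames; the
    mean on-fraction over a period is ``duty_ratio`` when period_frames is
    round(1/duty_ratio).
    """
    if spec.duty_ratio >= 1.0 or spec.period_frames <= 1:
        return True
    n_on = max(1, int(round(spec.duty_ratio * spec.period_frames)))
    return (frame_index % spec.period_frames) < n_on


class IlluminationField:
    """Mode dispatch bound to one configuration (field centre, focus)."""

    def __init__(self, spec: IlluminationSpec,
                 centre_um: tuple[float, float] = (0.0, 0.0),
                 z_focus_um: float = 0.0):
        self.spec = spec
        self.centre_um = centre_um
        self.z_focus_um = z_focus_um
        if spec.mode == "tirf":   # validate the angle eagerly
            tirf_penetration_depth_nm(spec.tirf.lambda0_nm, spec.tirf.angle_deg,
                                      spec.tirf.n1, spec.tirf.n3)

    def intensity(self, pos_um: np.ndarray) -> np.ndarray:
        pos = np.atleast_2d(pos_um)
        x, y, z = pos[:, 0], pos[:, 1], pos[:, 2]
        if self.spec.mode == "epi":
            return epi_intensity(x, y, z, self.spec, self.centre_um)
        if self.spec.mode == "tirf":
            return tirf_intensity(x, y, z, self.spec, self.centre_um)
        return confocal_intensity(x, y, z, self.spec, self.z_focus_um,
                                  self.centre_um)

    def gate(self, frame_index: int) -> bool:
        return illumination_gate(frame_index, self.spec)
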