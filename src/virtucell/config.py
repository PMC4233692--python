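"""Domain types, default parameters and configuration I/O.

Internal unit conventions: lengths in micrometres (µm), time in seconds,
emission in photons.  Fields whose *names* carry a unit suffix (``id_nm``,
``pixel_size_nm`` ...) hold that unit in configuration documents and are
converted where they are consumed.

The defaults reproduce a typical single-molecule TIRF experiment on a
10 × 10 × 10 µm cell imaged at 33 fps with a 100×/1.45 NA objective:
100 nm pixels, 250 nm PSF, 6000 photons s⁻¹ per fluorophore at the field
centre, photobleaching rate 0.5 s⁻¹, EMCCD gain 5 over a 2-count RMS noise
floor, and a 100 µm FWHM illuminating beam (TIRF incidence 64°).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

AVOGADRO = 6.02214076e23

#: face index -> (normal axis, side) where side 0 is the plane at coordinate 0
#: and side 1 the plane at the far edge.  Face 0 is the coverslip plane z = 0.
FACES: tuple[tuple[int, int], ...] = (
    (2, 0),  # z = 0 (coverslip)
    (2, 1),  # z = Lz
    (1, 0),  # y = 0
    (1, 1),  # y = Ly
    (0, 0),  # x = 0
    (0, 1),  # x = Lx
)

#: face index -> the two in-plane (tangent) axes, in ascending axis order
FACE_TANGENTS: tuple[tuple[int, int], ...] = tuple(
    tuple(a for a in (0, 1, 2) if a != normal) for normal, _ in FACES
)


class ConfigurationError(ValueError):
    """Raised for invalid or inconsistent simulation parameters."""


@dataclass
class CellGeometry:
    """Parallelepiped cell resting on the coverslip plane z = 0."""

    lx_um: float = 10.0
    ly_um: float = 10.0
    lz_um: float = 10.0

    def __post_init__(self) -> None:
        if min(self.lx_um, self.ly_um, self.lz_um) <= 0:
            raise ConfigurationError("cell edges must be positive")

    @property
    def edges(self) -> np.ndarray:
        return np.array([self.lx_um, self.ly_um, self.lz_um])

    @property
    def volume_um3(self) -> float:
        return self.lx_um * self.ly_um * self.lz_um

    def face_area_um2(self, face: int) -> float:
        ta, tb = FACE_TANGENTS[face]
        e = self.edges
        return float(e[ta] * e[tb])

    @property
    def total_face_area_um2(self) -> float:
        return float(sum(self.face_area_um2(f) for f in range(6)))

    def contains(self, pos: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        pos = np.atleast_2d(pos)
        lo = pos >= -atol
        hi = pos <= self.edges + atol
        return np.all(lo & hi, axis=1)


@dataclass
class BindingRule:
    """One reaction channel: this class may bind molecules of ``partner``."""

    partner: str
    r_bind: float = 0.0        # s^-1, multiplies the average interaction time
    r_diss: float = 0.0        # s^-1, zero-order dissociation
    id_nm: float = 5.0         # interaction distance (reaction diameter)

    def __post_init__(self) -> None:
        if self.r_bind < 0 or self.r_diss < 0:
            raise ConfigurationError("binding/dissociation rates must be >= 0")
        if self.id_nm <= 0:
            raise ConfigurationError("interaction distance must be > 0")


@dataclass
class MoleculeClassSpec:
    """Parameters of one molecular species.

    Abundance is given in exactly one of three forms: an explicit ``count``,
    a cytoplasmic ``concentration_nM`` or a membrane ``density_per_um2``.
    ``n_tags = 0`` declares a dark (non-fluorescent) class, e.g. unlabelled
    binding targets.
    """

    name: str
    compartment: str = "membrane"          # cytoplasm | membrane | static
    d_um2_s: float = 0.0
    count: Optional[int] = None
    concentration_nM: Optional[float] = None
    density_per_um2: Optional[float] = None
    n_tags: int = 1
    tag_colour_nm: float = 532.0
    bindings: list[BindingRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.compartment not in ("cytoplasm", "membrane", "static"):
            raise ConfigurationError(f"unknown compartment {self.compartment!r}")
        if self.d_um2_s < 0:
            raise ConfigurationError("diffusion coefficient must be >= 0")
        if not 0 <= self.n_tags <= 8:
            raise ConfigurationError("n_tags must be in 0..8")
        n_forms = sum(v is not None for v in
                      (self.count, self.concentration_nM, self.density_per_um2))
        if n_forms != 1:
            raise ConfigurationError(
                f"class {self.name!r}: exactly one abundance form required")
        self.bindings = [BindingRule(**b) if isinstance(b, dict) else b
                         for b in self.bindings]

    @property
    def fluorescent(self) -> bool:
        return self.n_tags > 0


def abundance_to_count(spec: MoleculeClassSpec, geom: CellGeometry) -> int:
    """Number of molecules implied by the class abundance.

    Concentration applies to the cell volume (nM × N_A × V), density to the
    summed area of all six faces.
    """
    if spec.count is not None:
        if spec.count < 0:
            raise ConfigurationError("count must be >= 0")
        return int(spec.count)
    if spec.concentration_nM is not None:
        if spec.concentration_nM < 0:
            raise ConfigurationError("concentration must be >= 0")
        volume_l = geom.volume_um3 * 1e-15
        return int(round(spec.concentration_nM * 1e-9 * AVOGADRO * volume_l))
    assert spec.density_per_um2 is not None
    if spec.density_per_um2 < 0:
        raise ConfigurationError("density must be >= 0")
    return int(round(spec.density_per_um2 * geom.total_face_area_um2))


@dataclass
class TirfSpec:
    angle_deg: float = 64.0
    lambda0_nm: float = 532.0
    n1: float = 1.33           # aqueous medium
    n3: float = 1.52           # glass

    @property
    def critical_angle_deg(self) -> float:
        return float(np.degrees(np.arcsin(self.n1 / self.n3)))


@dataclass
class ConfocalSpec:
    szf_um2: float = 0.05          # focused spot area at the focal plane
    cone_half_angle_deg: float = 60.0


@dataclass
class IlluminationSpec:
    """Illumination geometry plus the temporal (gating) schedule.

    ``duty_ratio`` < 1 runs gated time-lapse: one exposed frame every
    ``period_frames`` frames, the rest dark (no emission, no bleaching).
    """

    mode: str = "epi"              # epi | tirf | confocal
    beam_fwhm_um: float = 100.0
    tirf: TirfSpec = field(default_factory=TirfSpec)
    confocal: ConfocalSpec = field(default_factory=ConfocalSpec)
    diaphragm_radius_um: Optional[float] = None
    duty_ratio: float = 1.0
    period_frames: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("epi", "tirf", "confocal"):
            raise ConfigurationError(f"unknown illumination mode {self.mode!r}")
        if not 0 < self.duty_ratio <= 1:
            raise ConfigurationError("duty ratio must be in (0, 1]")
        if isinstance(self.tirf, dict):
            self.tirf = TirfSpec(**self.tirf)
        if isinstance(self.confocal, dict):
            self.confocal = ConfocalSpec(**self.confocal)


@dataclass
class OpticsSpec:
    pixel_size_nm: float = 100.0
    psf_fwhm_nm: float = 250.0       # in-focus single-fluorophore image FWHM
    gamma_obj_per_um: float = 0.6    # defocus FWHM growth, µm of FWHM per µm²
    z_focus_um: float = 0.0
    gamma_pinhole_per_um2: float = 1.0   # confocal pinhole rejection

    def __post_init__(self) -> None:
        if self.psf_fwhm_nm <= 0:
            raise ConfigurationError("PSF FWHM must be > 0")
        if self.gamma_obj_per_um < 0:
            raise ConfigurationError("defocus coefficient must be >= 0")

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm * 1e-3


@dataclass
class CameraSpec:
    frame_px: Optional[tuple[int, int]] = None   # (H, W); None -> cover cell
    photons_per_s: float = 6000.0    # per fluorophore at the field centre, z=0
    r_bleach: float = 0.5            # s^-1 at unit illumination intensity
    noise_rms: float = 2.0           # background counts per pixel
    offset: float = 0.0
    gain: float = 5.0                # EMCCD mean multiplicative gain
    gain_spread: Optional[float] = None   # sigma of the per-pixel gain; None -> gain/4
    photon_noise: str = "uniform"    # uniform (width sqrt(N)) | poisson

    def __post_init__(self) -> None:
        for v in (self.photons_per_s, self.r_bleach, self.noise_rms, self.gain):
            if v < 0:
                raise ConfigurationError("camera parameters must be >= 0")
        if self.photon_noise not in ("uniform", "poisson"):
            raise ConfigurationError("photon_noise must be 'uniform' or 'poisson'")
        if self.frame_px is not None:
            self.frame_px = tuple(int(v) for v in self.frame_px)

    @property
    def sigma_gain(self) -> float:
        return self.gain / 4.0 if self.gain_spread is None else self.gain_spread


@dataclass
class MembraneFeatureMap:
    """Optional membrane heterogeneity: barrier fences and viscous rafts.

    Barriers are grid lines of pitch ``barrier_pitch_um`` crossed with
    probability ``barrier_permeability`` per attempt; rafts are square
    patches of ``raft_size_um`` separated by ``raft_gap_um`` inside which
    mobility is multiplied by ``raft_mobility_ratio``.
    """

    barrier_pitch_um: Optional[float] = None
    barrier_permeability: float = 1.0
    raft_size_um: Optional[float] = None
    raft_gap_um: Optional[float] = None
    raft_mobility_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.barrier_pitch_um is not None and self.barrier_pitch_um <= 0:
            raise ConfigurationError("barrier pitch must be > 0")
        if not 0 <= self.barrier_permeability <= 1:
            raise ConfigurationError("permeability must be in [0, 1]")
        if self.raft_size_um is not None:
            if self.raft_size_um <= 0 or (self.raft_gap_um or 0) < 0:
                raise ConfigurationError("invalid raft geometry")
            if not 0 < self.raft_mobility_ratio <= 1:
                raise ConfigurationError("raft mobility ratio must be in (0, 1]")

    @property
    def has_barriers(self) -> bool:
        return self.barrier_pitch_um is not None and self.barrier_permeability < 1

    @property
    def has_rafts(self) -> bool:
        return self.raft_size_um is not None and self.raft_mobility_ratio < 1


@dataclass
class RateChange:
    """Scheduled mid-run change of the kinetic rates of one reaction rule."""

    time_s: float
    class_name: str
    partner: str
    r_bind: Optional[float] = None
    r_diss: Optional[float] = None


@dataclass
class SimulationConfig:
    geometry: CellGeometry = field(default_factory=CellGeometry)
    classes: list[MoleculeClassSpec] = field(default_factory=list)
    fps: float = 33.0
    substeps_per_frame: int = 10
    duration_s: float = 10.0
    seed: int = 0
    illumination: IlluminationSpec = field(default_factory=IlluminationSpec)
    optics: OpticsSpec = field(default_factory=OpticsSpec)
    camera: CameraSpec = field(default_factory=CameraSpec)
    membrane_features: MembraneFeatureMap = field(default_factory=MembraneFeatureMap)
    rate_changes: list[RateChange] = field(default_factory=list)
    truth_every: int = 1             # record ground truth every N substeps
    render: bool = True              # False -> kinetics/ground truth only
    equilibration_s: float = 0.0     # dark settling period before imaging

    def __post_init__(self) -> None:
        for name, cls in (("geometry", CellGeometry),
                          ("illumination", IlluminationSpec),
                          ("optics", OpticsSpec),
                          ("camera", CameraSpec),
                          ("membrane_features", MembraneFeatureMap)):
            v = getattr(self, name)
            if isinstance(v, dict):
                setattr(self, name, cls(**v))
        self.classes = [MoleculeClassSpec(**c) if isinstance(c, dict) else c
                        for c in self.classes]
        self.rate_changes = [RateChange(**r) if isinstance(r, dict) else r
                             for r in self.rate_changes]
        if self.fps <= 0 or self.substeps_per_frame < 1:
            raise ConfigurationError("fps and substeps_per_frame must be positive")
        if self.duration_s < 0 or self.equilibration_s < 0:
            raise ConfigurationError("durations must be >= 0")
        if self.truth_every < 1:
            raise ConfigurationError("truth_every must be >= 1")
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate class names")
        for c in self.classes:
            for b in c.bindings:
                if b.partner not in names:
                    raise ConfigurationError(
                        f"class {c.name!r} binds unknown partner {b.partner!r}")

    @property
    def dt_s(self) -> float:
        """Model (substep) time step; dt × substeps_per_frame = 1/fps."""
        return 1.0 / (self.fps * self.substeps_per_frame)

    @property
    def n_frames(self) -> int:
        """Frames over the full run (equilibration frames stay dark)."""
        return int(round((self.duration_s + self.equilibration_s) * self.fps))

    @property
    def frame_shape(self) -> tuple[int, int]:
        if self.camera.frame_px is not None:
            return self.camera.frame_px
        pix = self.optics.pixel_size_um
        return (int(np.ceil(self.geometry.ly_um / pix)),
                int(np.ceil(self.geometry.lx_um / pix)))

    @property
    def field_centre_um(self) -> tuple[float, float]:
        """Illumination/field centre (cell centred in the field of view)."""
        return (self.geometry.lx_um / 2.0, self.geometry.ly_um / 2.0)

    def class_named(self, name: str) -> MoleculeClassSpec:
        for c in self.classes:
            if c.name == name:
                return c
        raise KeyError(name)


def default_config() -> SimulationConfig:
    """Default two-class experiment: cytoplasmic molecules (D = 5 µm² s⁻¹,
    2 nM) plus membrane molecules (D = 0.3 µm² s⁻¹, 1 µm⁻²), no reactions."""
    return SimulationConfig(
        classes=[
            MoleculeClassSpec(name="cytoplasmic", compartment="cytoplasm",
                              d_um2_s=5.0, concentration_nM=2.0),
            MoleculeClassSpec(name="membrane", compartment="membrane",
                              d_um2_s=0.3, density_per_um2=1.0),
        ])


# ---------------------------------------------------------------------------
# serialisation

def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def config_to_dict(config: SimulationConfig) -> dict:
    return _to_plain(config)


def config_from_dict(data: dict) -> SimulationConfig:
    return SimulationConfig(**data)


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: not a mapping")
    return config_from_dict(data)


# ---------------------------------------------------------------------------
# RNG management

@dataclass
class RngStreams:
    """Independent per-module generators split from one root seed, so that
    e.g. camera noise can be varied without perturbing the trajectories."""

    motion: np.random.Generator
    interactions: np.random.Generator
    imaging: np.random.Generator
    placement: np.random.Generator

    @classmethod
    def from_seed(cls, seed: int) -> "RngStreams":
        ss = np.random.SeedSequence(int(seed))
        children = ss.spawn(4)
        return cls(*(np.random.default_rng(c) for c in children))
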