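import dataclasses

import numpy as np
import pytest

from virtucell import engine, presets, tracking
from virtucell.config import (CellGeometry, IlluminationSpec,
                              MoleculeClassSpec, SimulationConfig)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def geom():
    return CellGeometry()


@pytest.fixture
def small_membrane_config():
    """A fast 2-second membrane run used by several engine tests."""
    return SimulationConfig(
        classes=[MoleculeClassSpec(name="membrane", compartment="membrane",
                                   d_um2_s=0.3, density_per_um2=1.0)],
        illumination=IlluminationSpec(mode="tirf"),
        duration_s=2.0, seed=7)


@pytest.fixture(scope="session")
def s4_flat_run():
    """One 10 s free-membrane-diffusion run under a flat beam, shared by the
    pipeline tests (session-scoped: simulated once)."""
    cfg = presets.scenario_preset("S4", duration_s=10.0, seed=1)
    cfg = dataclasses.replace(
        cfg, illumination=dataclasses.replace(cfg.illumination,
                                              beam_fwhm_um=200.0))
    return engine.run(cfg)


def pipeline_tracks(result, d_expect=0.3, **kw):
    cfg = result.config
    gate = tracking.linking_gate_px(d_expect, 1.0 / cfg.fps,
                                    cfg.optics.pixel_size_um)
    return tracking.track_movie(result.stack.recorded, cfg.optics,
                                max_disp_px=gate,
                                noise_rms=cfg.camera.noise_rms, **kw)
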