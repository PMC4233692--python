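"""Run outputs (TIFF stacks, CSV tables, manifest) and test fixtures.

Outputs of a run are written as: one multi-page 16-bit grayscale TIFF per
colour channel (``movie.tif`` or ``movie_chN.tif``), the ground-truth
trajectory table and event log as UTF-8 CSV with unit-bearing headers, and
a JSON manifest echoing the full configuration, seed and SHA-256 checksums
of every file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from . import motion
from .config import CameraSpec, OpticsSpec, config_to_dict
from .engine import RunResult
from .imaging import finalize_frame, splat_photons

FIXTURE_NAMES = ("single_spot", "two_spots", "blank_noise",
                 "five_track_movie")


@dataclass
class RunManifest:
    seed: int
    software: str
    config: dict
    files: dict[str, str]          # relative path -> sha256

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(result: RunResult, out_dir, truth_every: int = 1,
                  basename: str = "movie") -> RunManifest:
    """Write TIFF stack(s), ground-truth CSV, event CSV and manifest.

    Files are written to temporary names and renamed on success; a failure
    removes the partial outputs.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        if result.stacks and len(result.stacks[0].frames):
            multi = len(result.stacks) > 1
            for ch, stack in enumerate(result.stacks):
                name = f"{basename}_ch{ch}.tif" if multi else f"{basename}.tif"
                path = out / name
                tmp = path.with_suffix(".tif.part")
                tifffile.imwrite(tmp, stack.frames, photometric="minisblack")
                tmp.rename(path)
                written.append(path)

        truth_path = out / "ground_truth.csv"
        df = result.truth.to_dataframe(every=truth_every)
        with open(truth_path, "w") as fh:
            fh.write("# virtucell ground truth; positions in um, time in s\n")
            df.to_csv(fh, index=False)
        written.append(truth_path)

        events_path = out / "events.csv"
        with open(events_path, "w") as fh:
            fh.write("# virtucell event log; time in s, separation in nm\n")
            result.events.to_csv(fh, index=False)
        written.append(events_path)

        manifest = RunManifest(
            seed=result.config.seed, software=f"virtucell {__version__}",
            config=config_to_dict(result.config),
            files={p.name: _sha256(p) for p in written})
        man_path = out / "manifest.json"
        man_path.write_text(manifest.to_json())
        return manifest
    except BaseException:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def read_stack(path) -> np.ndarray:
    """Load a multi-page TIFF as a (T, H, W) array."""
    arr = tifffile.imread(path)
    return arr[None] if arr.ndim == 2 else arr


# ---------------------------------------------------------------------------
# deterministic fixtures for tracking tests

def _render_point_movie(positions_um: np.ndarray, n_frames: int,
                        optics: OpticsSpec, camera: CameraSpec,
                        rng: np.random.Generator,
                        shape=(40, 40), photons_per_frame: float = 182.0,
                        ) -> np.ndarray:
    """Render a movie of point emitters from a (T, N, 2) position array."""
    frames = np.zeros((n_frames,) + shape, dtype=np.uint16)
    fwhm = optics.psf_fwhm_nm * 1e-3
    for f in range(n_frames):
        img = np.zeros(shape, dtype=np.int64)
        pos = positions_um[f]
        n_ph = rng.poisson(photons_per_frame, size=len(pos))
        splat_photons(img, pos[:, 0], pos[:, 1], n_ph,
                      np.full(len(pos), fwhm), optics.pixel_size_um, rng)
        frames[f] = finalize_frame(img, camera, rng)
    return frames


def make_fixture(name: str, seed: int = 0) -> dict:
    """Small deterministic movies with known ground truth.

    ``single_spot``  — 50 frames, one static in-focus molecule (SNR ≈ 15).
    ``two_spots``    — 50 frames, two static molecules 2 µm apart.
    ``blank_noise``  — 50 noise-only frames at the default 2-count RMS.
    ``five_track_movie`` — 60 frames, five walkers at D = 0.1 µm² s⁻¹.

    Returns {"frames", "truth_um", "optics", "camera", "fps"}.
    """
    rng = np.random.default_rng(seed)
    optics = OpticsSpec()
    camera = CameraSpec()
    fps = 33.0
    shape = (40, 40)
    if name == "single_spot":
        n = 50
        truth = np.tile(np.array([[2.0, 2.0]]), (n, 1, 1))
        frames = _render_point_movie(truth, n, optics, camera, rng, shape)
    elif name == "two_spots":
        n = 50
        truth = np.tile(np.array([[1.0, 1.0], [3.0, 3.0]]), (n, 1, 1))
        frames = _render_point_movie(truth, n, optics, camera, rng, shape)
    elif name == "blank_noise":
        n = 50
        truth = np.zeros((n, 0, 2))
        frames = np.stack([
            finalize_frame(np.zeros(shape, dtype=np.int64), camera, rng)
            for _ in range(n)])
    elif name == "five_track_movie":
        n, d = 60, 0.1
        start = rng.uniform(0.8, 3.2, size=(5, 2))
        steps = motion.gaussian_step(rng, d, 1.0 / fps, 2, size=5 * (n - 1))
        steps = steps.reshape(n - 1, 5, 2)
        truth = np.concatenate([start[None], start[None] + np.cumsum(
            steps, axis=0)], axis=0)
        frames = _render_point_movie(truth, n, optics, camera, rng, shape)
    else:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return {"frames": frames, "truth_um": truth, "optics": optics,
            "camera": camera, "fps": fps}
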