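"""Brownian displacement rules.

Free molecules take independent Gaussian steps per axis with per-dimension
variance 2·D·Δt (so MSD is 2nDΔt in n dimensions).  Cytoplasmic walkers are
confined to the cell volume by specular reflection; membrane walkers live on
the faces of the parallelepiped and wrap onto the adjoining face when a step
overshoots an edge, preserving the excess path length.  Optional membrane
features modulate the walk: fence-like barrier grids crossed with a fixed
permeability per attempt, and viscous raft patches that scale D.

Bound pairs move as one object: a single displacement is drawn at the pair
mobility D_pair = D_a / (1 + D_a/D_b) (membrane pairs), or at the membrane
partner's D when a cytoplasmic molecule rides on a membrane one.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .config import FACES, FACE_TANGENTS, CellGeometry, MembraneFeatureMap


def gaussian_step(rng: np.random.Generator, d_um2_s: float, dt_s: float,
                  ndim: int, size: Optional[int] = None) -> np.ndarray:
    """Displacement vector(s) with independent N(0, 2·D·Δt) components."""
    if d_um2_s < 0 or dt_s <= 0:
        raise ValueError("need D >= 0 and dt > 0")
    rmsd = math.sqrt(2.0 * d_um2_s * dt_s)
    shape = (ndim,) if size is None else (size, ndim)
    if rmsd == 0.0:
        return np.zeros(shape)
    return rng.normal(0.0, rmsd, size=shape)


def pair_mobility(da: float, db: float) -> float:
    """Mobility of a bound pair of membrane molecules.

    D_pair = D_a / (1 + D_a/D_b); symmetric in its arguments, D/2 for a
    homodimer, and 0 if either partner is immobile.
    """
    if da < 0 or db < 0:
        raise ValueError("mobilities must be >= 0")
    if da == 0.0 or db == 0.0:
        return 0.0
    return da * db / (da + db)


def reflect_into_box(pos: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Fold positions back into [0, L] per axis by specular reflection.

    The fold L - |(x mod 2L) - L| implements any number of wall bounces at
    once, so steps larger than the cell still land inside.
    """
    period = 2.0 * edges
    return edges - np.abs(np.mod(pos, period) - edges)


def step_cytoplasm(pos: np.ndarray, d_um2_s: np.ndarray | float, dt_s: float,
                   geom: CellGeometry, rng: np.random.Generator) -> np.ndarray:
    """Advance 3D walkers one substep inside the cell volume."""
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    d = np.broadcast_to(np.asarray(d_um2_s, dtype=float), pos.shape[:1])
    rmsd = np.sqrt(2.0 * d * dt_s)
    step = rng.normal(size=pos.shape) * rmsd[:, None]
    return reflect_into_box(pos + step, geom.edges)


# ---------------------------------------------------------------------------
# membrane walk

def in_raft(u: np.ndarray, v: np.ndarray,
            features: MembraneFeatureMap) -> np.ndarray:
    """Raft membership of face-tangent coordinates (u, v).

    Rafts tile each face periodically: a ``raft_size`` square at the origin
    of every (size + gap) cell.
    """
    if not features.has_rafts:
        return np.zeros(np.shape(u), dtype=bool)
    size = features.raft_size_um
    period = size + (features.raft_gap_um or 0.0)
    return (np.mod(u, period) < size) & (np.mod(v, period) < size)


def _apply_barriers_axis(x0: np.ndarray, x1: np.ndarray, pitch: float,
                         permeability: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Resolve barrier-line crossings along one tangent axis.

    Each grid-line crossing of the segment x0→x1 is a Bernoulli(permeability)
    trial; a refused crossing reflects the remaining path off the line.
    Handled line by line so multi-compartment jumps are legal only if every
    intervening line is passed.
    """
    x = np.array(x1, dtype=float)
    cur = np.array(x0, dtype=float)
    for _ in range(64):  # worst-case multi-line walk; steps are ≪ pitch in practice
        k0 = np.floor(cur / pitch)
        k1 = np.floor(x / pitch)
        moving = k1 != k0
        if not np.any(moving):
            break
        idx = np.nonzero(moving)[0]
        direction = np.sign(x[idx] - cur[idx])
        # first line hit along the direction of travel
        line = np.where(direction > 0, (k0[idx] + 1) * pitch, k0[idx] * pitch)
        passed = rng.random(idx.size) < permeability
        # refused: reflect the remainder of the path about the line
        refl = idx[~passed]
        x[refl] = 2.0 * line[~passed] - x[refl]
        # guard against landing exactly on the line after reflection
        cur[refl] = line[~passed] - direction[~passed] * 1e-12
        # accepted: advance the running point just past the line
        acc = idx[passed]
        cur[acc] = line[passed] + direction[passed] * 1e-12
    return x


def _wrap_faces(pos: np.ndarray, face: np.ndarray,
                edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Carry overshooting membrane walkers onto the adjoining face.

    The out-of-range tangent coordinate is clamped at the shared edge and the
    excess path length continues on the neighbouring face along what was the
    origin face's normal axis.  Corners resolve the larger overshoot first
    (ties: x before y before z).  Scalar loop: offenders are rare because
    typical steps are tens of nm on 10 µm faces.
    """
    pos = pos.copy()
    face = face.copy()
    tangents = FACE_TANGENTS

    def excess(p, f):
        out = []
        for a in tangents[f]:
            if p[a] < 0.0:
                out.append((a, -p[a], 0))
            elif p[a] > edges[a]:
                out.append((a, p[a] - edges[a], 1))
        return out

    candidates = []
    for i in range(pos.shape[0]):
        f = face[i]
        ta, tb = tangents[f]
        if (pos[i, ta] < 0.0 or pos[i, ta] > edges[ta]
                or pos[i, tb] < 0.0 or pos[i, tb] > edges[tb]):
            candidates.append(i)

    for i in candidates:
        p = pos[i]
        f = int(face[i])
        for _ in range(64):
            out = excess(p, f)
            if not out:
                break
            # largest overshoot first; ties broken by axis order (x, y, z)
            a, e, side = max(out, key=lambda t: (t[1], -t[0]))
            normal, nside = FACES[f]
            p[a] = edges[a] if side == 1 else 0.0
            # continue along the old normal axis, moving into the domain
            p[normal] = e if nside == 0 else edges[normal] - e
            # safety: an excess longer than the new face folds back
            if p[normal] < 0.0 or p[normal] > edges[normal]:
                period = 2.0 * edges[normal]
                p[normal] = edges[normal] - abs(
                    (p[normal] % period) - edges[normal])
            f = _face_index(a, side)
        face[i] = f
        pos[i] = p
    return pos, face


def _face_index(axis: int, side: int) -> int:
    return FACES.index((axis, side))


def step_membrane(pos: np.ndarray, face: np.ndarray,
                  d_um2_s: np.ndarray | float, dt_s: float,
                  geom: CellGeometry, rng: np.random.Generator,
                  features: Optional[MembraneFeatureMap] = None,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Advance 2D membrane walkers one substep over the parallelepiped faces.

    Raft membership is decided at the start position; barrier trials act on
    the segment between old and new tangent coordinates.
    """
    pos = np.atleast_2d(np.asarray(pos, dtype=float)).copy()
    face = np.asarray(face, dtype=np.int64).copy()
    n = pos.shape[0]
    if n == 0:
        return pos, face
    d = np.broadcast_to(np.asarray(d_um2_s, dtype=float), (n,)).copy()
    edges = geom.edges

    # gather tangent coordinates
    tang = np.asarray(FACE_TANGENTS)[face]          # (n, 2) axis ids
    rows = np.arange(n)
    u = pos[rows, tang[:, 0]]
    v = pos[rows, tang[:, 1]]

    if features is not None and features.has_rafts:
        slow = in_raft(u, v, features)
        d = np.where(slow, d * features.raft_mobility_ratio, d)

    rmsd = np.sqrt(2.0 * d * dt_s)
    du = rng.normal(size=n) * rmsd
    dv = rng.normal(size=n) * rmsd
    u1, v1 = u + du, v + dv

    if features is not None and features.has_barriers:
        pitch = features.barrier_pitch_um
        p = features.barrier_permeability
        u1 = _apply_barriers_axis(u, u1, pitch, p, rng)
        v1 = _apply_barriers_axis(v, v1, pitch, p, rng)

    pos[rows, tang[:, 0]] = u1
    pos[rows, tang[:, 1]] = v1
    return _wrap_faces(pos, face, edges)
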