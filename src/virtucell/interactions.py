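"""Binding and dissociation kinetics via average interaction times (AIT).

Instead of resolving every collision with sub-microsecond time steps, each
candidate pair is assigned the expected time it would spend within the
interaction distance (ID) during one model step, computed from the free
diffusion propagator.  With the pair separation x at the start of a step and
combined mobility D = D_A + D_B, the probability density of finding the
partner at the origin after time t is the d-dimensional Gaussian kernel

    G_d(x, t) = (4πDt)^(-d/2) · exp(-x² / 4Dt),

and the AIT is the time integral over the step of G_d times the interaction
measure — ID in 1D, the interaction area IA = πr² in 2D, the interaction
volume IV = 4/3·πr³ in 3D, with r = ID/2.  Binding fires with probability
P_bind = AIT·R_bind (clipped to [0, 1]); bound pairs dissociate with
P_diss = R_diss·Δt.  AIT values are precomputed on a 1 nm grid and looked
up by integer separation; a table depends only on (D, ID, Δt, d), so rate
changes never force a rebuild.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
from scipy.spatial import cKDTree

AIT_NEGLIGIBLE_PBIND = 1e-6      # drop pairs whose P_bind falls below this
AIT_MAX_RANGE_NM = 2000          # hard cap on the tabulated separation


def interaction_measure(id_nm: float, ndim: int) -> float:
    """ID (µm), IA (µm²) or IV (µm³) for r = ID/2."""
    id_um = id_nm * 1e-3
    r = id_um / 2.0
    if ndim == 1:
        return id_um
    if ndim == 2:
        return math.pi * r * r
    if ndim == 3:
        return 4.0 / 3.0 * math.pi * r ** 3
    raise ValueError("ndim must be 1, 2 or 3")


def green_density(x_um, t_s, d_um2_s: float, ndim: int, id_nm: float):
    """Probability weight of finding the partner within the interaction
    measure at separation x after time t of free relative diffusion."""
    if np.any(np.asarray(t_s) <= 0):
        raise ValueError("t must be > 0")
    if d_um2_s <= 0:
        raise ValueError("D must be > 0")
    x = np.asarray(x_um, dtype=float)
    t = np.asarray(t_s, dtype=float)
    norm = (4.0 * math.pi * d_um2_s * t) ** (-ndim / 2.0)
    return norm * np.exp(-x * x / (4.0 * d_um2_s * t)) * interaction_measure(id_nm, ndim)


def compute_ait(x_um, d_um2_s: float, id_nm: float, dt_s: float, ndim: int,
                n_nodes: int = 200) -> np.ndarray | float:
    """Average interaction time for separation(s) x over one step of length dt.

    Discrete integration of :func:`green_density` over (0, dt] on a
    logarithmic time grid (the integrand is near-singular at small t for
    small x); the result is clipped to [0, dt], and x = 0 is pinned to dt
    (a coincident pair is taken to interact for the whole step).
    """
    scalar = np.isscalar(x_um) or np.ndim(x_um) == 0
    x = np.atleast_1d(np.asarray(x_um, dtype=float))
    t = np.geomspace(dt_s * 1e-6, dt_s, n_nodes)
    g = green_density(x[:, None], t[None, :], d_um2_s, ndim, id_nm)
    ait = np.trapezoid(g, t, axis=1)
    ait = np.clip(ait, 0.0, dt_s)
    ait[x == 0.0] = dt_s
    return float(ait[0]) if scalar else ait


@dataclass
class AITTable:
    """AIT tabulated on a 1 nm separation grid for one reacting class pair."""

    d_um2_s: float               # combined mobility D_A + D_B
    id_nm: float
    dt_s: float
    ndim: int
    values_s: np.ndarray = field(repr=False)   # index = separation in nm

    @classmethod
    def build(cls, d_um2_s: float, id_nm: float, dt_s: float, ndim: int,
              max_nm: int = AIT_MAX_RANGE_NM) -> "AITTable":
        x_um = np.arange(max_nm + 1) * 1e-3
        values = np.asarray(compute_ait(x_um, d_um2_s, id_nm, dt_s, ndim))
        return cls(d_um2_s=d_um2_s, id_nm=id_nm, dt_s=dt_s, ndim=ndim,
                   values_s=values)

    def key(self) -> tuple:
        return (self.d_um2_s, self.id_nm, self.dt_s, self.ndim)

    def cutoff_nm(self, r_bind: float,
                  threshold: float = AIT_NEGLIGIBLE_PBIND) -> int:
        """Largest separation worth testing for a given binding rate."""
        if r_bind <= 0:
            return 0
        keep = np.nonzero(self.values_s * r_bind >= threshold)[0]
        return int(keep[-1]) if keep.size else 0

    def ait_at(self, dist_um: np.ndarray) -> np.ndarray:
        """Nearest-nm lookup; separations beyond the table are 0."""
        idx = np.rint(np.asarray(dist_um) * 1e3).astype(np.int64)
        out = np.zeros(idx.shape, dtype=float)
        ok = (idx >= 0) & (idx < self.values_s.size)
        out[ok] = self.values_s[idx[ok]]
        return out

    def to_text(self, path) -> None:
        """Two-column export (distance_nm, ait_s) for inspection."""
        np.savetxt(path, np.column_stack(
            [np.arange(self.values_s.size), self.values_s]),
            fmt=("%d", "%.8e"), header="distance_nm ait_s")


def build_ait_table(d_um2_s: float, id_nm: float, dt_s: float,
                    ndim: int) -> AITTable:
    """Convenience wrapper around :meth:`AITTable.build`."""
    return AITTable.build(d_um2_s, id_nm, dt_s, ndim)


class AITTableCache:
    """Build-once store keyed by (D, ID, dt, d); rate changes reuse tables."""

    def __init__(self) -> None:
        self._tables: dict[tuple, AITTable] = {}
        self.builds = 0

    def get(self, d_um2_s: float, id_nm: float, dt_s: float,
            ndim: int) -> AITTable:
        key = (float(d_um2_s), float(id_nm), float(dt_s), int(ndim))
        if key not in self._tables:
            self._tables[key] = AITTable.build(*key)
            self.builds += 1
        return self._tables[key]


def candidate_pairs(pos_a: np.ndarray, pos_b: np.ndarray,
                    cutoff_um: float,
                    exclude_self: bool = False) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All index pairs (i into pos_a, j into pos_b) with separation <= cutoff.

    Uses a k-d tree; equivalent to the O(N²) scan.  With ``exclude_self``
    (same-class reactions where pos_a is pos_b) each unordered pair is
    reported once, i < j.
    """
    na, nb = len(pos_a), len(pos_b)
    if na == 0 or nb == 0 or cutoff_um <= 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy(), np.empty(0, dtype=float)
    if exclude_self:
        tree = cKDTree(pos_a)
        pairs = tree.query_pairs(cutoff_um, output_type="ndarray")
        if pairs.size == 0:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty.copy(), np.empty(0, dtype=float)
        i, j = pairs[:, 0], pairs[:, 1]
        dist = np.linalg.norm(pos_a[i] - pos_a[j], axis=1)
        return i.astype(np.int64), j.astype(np.int64), dist
    tree_b = cKDTree(pos_b)
    tree_a = cKDTree(pos_a)
    coo = tree_a.sparse_distance_matrix(tree_b, cutoff_um,
                                        output_type="coo_matrix")
    return (coo.row.astype(np.int64), coo.col.astype(np.int64),
            np.asarray(coo.data, dtype=float))


def attempt_bindings(i_idx: np.ndarray, j_idx: np.ndarray, dist_um: np.ndarray,
                     table: AITTable, r_bind: float,
                     free_i: np.ndarray, free_j: np.ndarray,
                     rng: np.random.Generator) -> list[tuple[int, int, float]]:
    """Bernoulli binding trials, closest pairs first, first success wins.

    ``free_i``/``free_j`` are mutable boolean site masks indexed like the
    respective populations; successful events clear both flags so each
    molecule binds at most one partner per step (and ever, until it
    dissociates).  Returns (i, j, separation_um) events.
    """
    if i_idx.size == 0 or r_bind <= 0:
        return []
    p = np.clip(table.ait_at(dist_um) * r_bind, 0.0, 1.0)
    order = np.argsort(dist_um, kind="stable")
    draws = rng.random(i_idx.size)
    events: list[tuple[int, int, float]] = []
    for k in order:
        if p[k] <= 0.0:
            continue
        i, j = int(i_idx[k]), int(j_idx[k])
        if not (free_i[i] and free_j[j]):
            continue
        if draws[k] < p[k]:
            free_i[i] = False
            free_j[j] = False
            events.append((i, j, float(dist_um[k])))
    return events


def attempt_dissociations(pair_index: np.ndarray, r_diss: float, dt_s: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Indices (into ``pair_index``) of pairs that dissociate this step,
    each with probability min(R_diss·Δt, 1)."""
    if pair_index.size == 0 or r_diss <= 0:
        return np.empty(0, dtype=np.int64)
    p = min(r_diss * dt_s, 1.0)
    hit = rng.random(pair_index.size) < p
    return np.nonzero(hit)[0].astype(np.int64)
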