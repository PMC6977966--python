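"""Solvent-accessible surface area by Shrake–Rupley sphere sampling.

Each atom is inflated by the probe radius (1.4 Å water) and covered with a
deterministic golden-spiral point lattice; the accessible fraction of each
sphere gives the per-atom area. Deterministic for a given point count.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .geometry import sphere_points

PROBE_RADIUS = 1.4  # Å
DEFAULT_N_POINTS = 256


def sasa_per_atom(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    subset: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom SASA (Å²) of atoms ``subset`` occluded by the full set.

    ``subset`` (indices) defaults to all atoms. Occlusion always uses every
    atom in ``coords``, so evaluating a subset is exact, not an
    approximation.
    """
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    n = coords.shape[0]
    if subset is None:
        subset = np.arange(n)
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    rmax = float(radii.max()) if n else 0.0
    out = np.zeros(len(subset))
    for k, i in enumerate(subset):
        ri = radii[i] + probe
        pts = coords[i] + ri * unit
        # any neighbor close enough to possibly cover a point?
        neigh = tree.query_ball_point(coords[i], ri + rmax + probe)
        neigh = [j for j in neigh if j != i]
        if neigh:
            nc = coords[neigh]
            nr = radii[np.asarray(neigh)] + probe
            d2 = np.sum(
                (pts[:, None, :] - nc[None, :, :]) ** 2, axis=2
            )
            buried = np.any(d2 < (nr**2)[None, :], axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        out[k] = 4.0 * np.pi * ri * ri * frac
    return out


def total_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> float:
    return float(np.sum(sasa_per_atom(coords, radii, probe, n_points)))
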