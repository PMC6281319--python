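"""Cell-shape and marker polarity metrics.

- roundness index: minor/major axis ratio of a cell (1 = spherical; the
  wild-type progenitor population is elongated towards the tip, ~0.45);
- Golgi a/b ratio: a = distance cell centre → foot (the cell's contact
  point on the tip), b = distance Golgi → foot; smaller values mean the
  Golgi lies farther from the tip (polarised distally);
- foci far fraction: percentage of marker foci (desmin-like) farther than
  a cutoff (default 5 µm) from the tip surface;
- neighbour composition: per focal cell of type A, the ratio of type-B to
  type-A neighbours within a touch distance;
- heterotypic tip contacts: per tip domain, the count of type-B cells
  touching the tip surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


@dataclass
class PolarityRecord:
    cell_id: int
    length_um: float
    width_um: float
    roundness: float
    a_um: float
    b_um: float
    golgi_ratio: float


def roundness_index(length: float, width: float) -> float:
    """Width-to-length (minor/major) axis ratio; 1 for a sphere.

    Axes are ordered internally, so argument order does not matter.
    """
    if length <= 0 or width <= 0:
        raise ValueError("cell extents must be > 0")
    major, minor = max(length, width), min(length, width)
    return minor / major


def golgi_polarization(center: np.ndarray, golgi: np.ndarray,
                       foot: np.ndarray) -> float:
    """Golgi a/b ratio: |centre − foot| / |Golgi − foot|.

    Smaller values indicate the Golgi lies farther from the tip than the
    cell centre (distal polarisation).  Returns NaN (flagged undefined)
    when the Golgi coincides with the foot.
    """
    center = np.asarray(center, dtype=float)
    golgi = np.asarray(golgi, dtype=float)
    foot = np.asarray(foot, dtype=float)
    a = float(np.linalg.norm(center - foot))
    b = float(np.linalg.norm(golgi - foot))
    if b == 0:
        return float("nan")
    return a / b


def cell_axes_from_mask(mask: np.ndarray,
                        voxel_size: Sequence[float] = (1.0, 1.0, 1.0),
                        ) -> tuple[float, float]:
    """(length, width) of a segmented cell from principal axes of its voxel
    cloud; for a solid ellipsoid the semi-axis along eigenvector i is
    sqrt(5 λ_i) of the coordinate covariance."""
    mask = np.asarray(mask) > 0
    if not np.any(mask):
        raise ValueError("empty cell mask")
    coords = np.column_stack(np.nonzero(mask)).astype(float)
    coords *= np.asarray(voxel_size, dtype=float)
    cov = np.cov(coords, rowvar=False)
    lam = np.sort(np.linalg.eigvalsh(cov))[::-1]
    lam = np.clip(lam, 0.0, None)
    length = 2.0 * np.sqrt(5.0 * lam[0])
    width = 2.0 * np.sqrt(5.0 * lam[1])
    return float(length), float(width)


def foci_far_fraction(distances: np.ndarray, cutoff: float = 5.0) -> float:
    """Percentage of foci farther than ``cutoff`` µm from the tip surface."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty foci set")
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    return 100.0 * float(np.mean(d > cutoff))


def foci_distances(foci_positions: np.ndarray, tip_surface) -> np.ndarray:
    """Euclidean point-to-surface distances for a foci point set."""
    from .geometry import points_to_surface_distance
    return points_to_surface_distance(foci_positions, tip_surface)


def neighbor_composition(positions: np.ndarray, types: Sequence[str],
                         focal_type: str = "A", other_type: str = "B",
                         touch_distance: float = 0.5,
                         cell_diameter: float = 8.0) -> pd.DataFrame:
    """Per focal cell of ``focal_type``: (#other-type neighbours) /
    (#focal-type neighbours).

    Cells are treated as spheres of ``cell_diameter``; two cells touch when
    their centre distance is at most ``cell_diameter + touch_distance``.
    The ratio is NaN (flagged) when a cell has no focal-type neighbours.
    """
    positions = np.asarray(positions, dtype=float)
    types = np.asarray(types)
    if positions.shape[0] != types.shape[0]:
        raise ValueError("positions and types must align")
    known = set(types.tolist())
    if not known <= {focal_type, other_type}:
        raise ValueError(f"untyped cells present: {sorted(known - {focal_type, other_type})}")
    tree = cKDTree(positions)
    radius = cell_diameter + touch_distance
    rows = []
    for i in np.flatnonzero(types == focal_type):
        nbrs = [j for j in tree.query_ball_point(positions[i], radius)
                if j != i]
        n_same = sum(types[j] == focal_type for j in nbrs)
        n_other = len(nbrs) - n_same
        ratio = n_other / n_same if n_same > 0 else float("nan")
        rows.append((i, n_same, n_other, ratio))
    return pd.DataFrame(rows, columns=["cell_index", "n_focal_neighbors",
                                       "n_other_neighbors", "ratio"])


def heterotypic_tip_contacts(positions: np.ndarray, types: Sequence[str],
                             tip_surfaces: Sequence[object],
                             contact_type: str = "B",
                             touch_distance: float = 0.5,
                             cell_radius: float = 4.0) -> pd.DataFrame:
    """Per tip domain, count of ``contact_type`` cells whose membrane lies
    within ``touch_distance`` of the tip surface."""
    if len(tip_surfaces) == 0:
        raise ValueError("no tip domains given")
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    types = np.asarray(types)
    rows = []
    for k, tip in enumerate(tip_surfaces):
        if len(positions) == 0:
            rows.append((k, 0))
            continue
        from .geometry import points_to_surface_distance
        d = points_to_surface_distance(positions, tip)
        membrane = np.clip(d - cell_radius, 0.0, None)
        sel = (types == contact_type) & (membrane <= touch_distance)
        rows.append((k, int(np.sum(sel))))
    return pd.DataFrame(rows, columns=["tip_domain", "n_contacts"])


def polarity_table(cell_table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell polarity records from a scene marker snapshot (columns
    x/y/z_um, foot_*, golgi_*, length_um, width_um)."""
    rows = []
    for _, r in cell_table.iterrows():
        center = np.array([r.x_um, r.y_um, r.z_um])
        foot = np.array([r.foot_x, r.foot_y, r.foot_z])
        golgi = np.array([r.golgi_x, r.golgi_y, r.golgi_z])
        a = float(np.linalg.norm(center - foot))
        b = float(np.linalg.norm(golgi - foot))
        rows.append(PolarityRecord(
            cell_id=int(r.cell_id), length_um=float(r.length_um),
            width_um=float(r.width_um),
            roundness=roundness_index(r.length_um, r.width_um),
            a_um=a, b_um=b,
            golgi_ratio=golgi_polarization(center, golgi, foot)).__dict__)
    return pd.DataFrame(rows)
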