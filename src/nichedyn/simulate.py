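"""Synthetic nephrogenic-niche scene generator.

Builds ground-truthed 3D+t movies of a nephrogenic niche: a hemispherical
ureteric-tip dome that translates (whole-tissue drift) and dilates (growth),
capped by nephron-progenitor cells whose attachment to the tip surface
follows a two-state Markov chain, with cell division and out-of-frame
censoring, membrane-reporter jitter on the observed positions, and polarised
marker tables (Golgi offset along the cell axis, desmin foci near the tip,
an interspersed interstitial-like second cell type).

Status codes follow the live-imaging convention used throughout the package:

    1 = attached, 2 = unattached, 3 = cell division,
    4 = cell death, 5 = out of frame.

Division is a single-frame event after which the cell re-enters the detached
state and a daughter track is spawned.  Codes 4 and 5 are absorbing; the
generator itself never emits 4 (no death rate is parameterised) but the full
code set is honoured downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Optional

import numpy as np
import pandas as pd

ATTACHED, DETACHED, DIVISION, DEATH, OUT_OF_FRAME = 1, 2, 3, 4, 5
UNBORN = 0  # pre-birth padding in full-length status arrays (daughters)

_PROB_FIELDS = ("p_detach", "p_attach", "p_divide", "p_exit",
                "initial_attached_fraction", "desmin_near_fraction",
                "secondary_near_fraction")
_NONNEG_FIELDS = ("frame_interval", "tip_radius", "tip_growth_rate",
                  "membrane_jitter_sd", "cell_radius", "attach_depth",
                  "detach_gap", "step_sd_attached", "step_sd_detached",
                  "axis_ratio_sd", "golgi_offset_sd")


@dataclass(frozen=True)
class SceneParameters:
    """Full parameterisation of one synthetic niche movie.

    Lengths are in µm, rates per frame, the frame interval in minutes.
    ``golgi_offset`` is signed along the cell's radial axis: positive values
    place the Golgi distal to the cell centre (away from the tip).
    """

    n_cells: int = 30
    n_frames: int = 98
    frame_interval: float = 10.0
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 3.0)  # (dx, dy, dz)
    tip_radius: float = 20.0
    tip_growth_rate: float = 0.05
    drift_velocity: tuple[float, float, float] = (0.2, 0.0, 0.0)
    p_detach: float = 0.005
    p_attach: float = 0.2
    p_divide: float = 0.001
    p_exit: float = 0.001
    membrane_jitter_sd: float = 0.5
    golgi_offset: float = 2.0
    golgi_offset_sd: float = 0.5
    desmin_near_fraction: float = 0.8
    seed: int = 0
    # cell geometry / motion
    cell_radius: float = 4.0
    attach_depth: float = 1.0          # membrane overlap with the tip shell
    detach_gap: float = 6.0            # max membrane gap when detached
    detach_gap_min: float = 2.0        # min membrane gap when detached
    step_sd_attached: float = 0.02     # tangential angular walk, radians
    step_sd_detached: float = 0.8      # radial/tangential walk, µm
    max_polar_deg: float = 75.0        # cells stay on the dome cap
    min_cell_spacing: float = 3.0
    initial_attached_fraction: float = 1.0
    # cell shape and markers
    cell_axis_ratio: float = 0.45      # width/length, true mean
    axis_ratio_sd: float = 0.05
    cell_length: float = 12.0
    n_foci: int = 100
    n_secondary: int = 30
    secondary_near_fraction: float = 0.1
    marker_frame: int = 10
    image_margin: float = 10.0

    def __post_init__(self) -> None:
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        for name in _NONNEG_FIELDS:
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v!r}")
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames!r}")
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells!r}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size entries must be > 0, got {self.voxel_size!r}")
        if self.tip_radius <= 0:
            raise ValueError(f"tip_radius must be > 0, got {self.tip_radius!r}")

    def with_seed(self, seed: int) -> "SceneParameters":
        return replace(self, seed=int(seed))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["voxel_size"] = list(self.voxel_size)
        d["drift_velocity"] = list(self.drift_velocity)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneParameters":
        d = dict(d)
        if "voxel_size" in d:
            d["voxel_size"] = tuple(d["voxel_size"])
        if "drift_velocity" in d:
            d["drift_velocity"] = tuple(d["drift_velocity"])
        return cls(**d)


def control_like(**overrides) -> SceneParameters:
    """Preset emulating stably attached (control-like) progenitor behaviour:
    rare detachment, distal Golgi, elongated cells, deep tip contacts."""
    base = dict(p_detach=0.005, p_attach=0.2, golgi_offset=2.0,
                cell_axis_ratio=0.45, attach_depth=1.0,
                desmin_near_fraction=0.8, secondary_near_fraction=0.1,
                initial_attached_fraction=1.0)
    base.update(overrides)
    return SceneParameters(**base)


def mutant_like(**overrides) -> SceneParameters:
    """Preset emulating the frequently switching (mutant-like) regime:
    10x detachment rate, unpolarised Golgi, rounder cells, shallower
    contacts, interstitial-like cells infiltrating near the tip."""
    base = dict(p_detach=0.05, p_attach=0.2, golgi_offset=0.0,
                cell_axis_ratio=0.565, attach_depth=0.55,
                desmin_near_fraction=0.4, secondary_near_fraction=0.4,
                initial_attached_fraction=0.5)
    base.update(overrides)
    return SceneParameters(**base)


PRESETS = {"control_like": control_like, "mutant_like": mutant_like}


@dataclass
class TipSphere:
    """Analytic tip geometry at one frame: a hemispherical dome (cap side
    +z) of the sphere |p - center| = radius.  Cells live on the cap, so
    their distance to the tip surface is the spherical distance."""

    center: np.ndarray
    radius: float
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def surface_distance(self, points: np.ndarray) -> np.ndarray:
        """Unsigned distance from points (N,3) or (3,) to the sphere."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return np.abs(np.linalg.norm(p - self.center, axis=1) - self.radius)

    def signed_height(self, points: np.ndarray) -> np.ndarray:
        """Signed distance above (+) / below (-) the sphere surface."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return np.linalg.norm(p - self.center, axis=1) - self.radius

    def foot_point(self, points: np.ndarray) -> np.ndarray:
        """Nearest point on the sphere (the cell's 'foot' on the tip)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        d = p - self.center
        n = np.linalg.norm(d, axis=1, keepdims=True)
        n = np.where(n == 0, 1.0, n)
        return self.center + d / n * self.radius

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        inside = np.linalg.norm(p - self.center, axis=1) <= self.radius
        cap = (p - self.center) @ self.axis >= 0
        return inside & cap


def simulate_status_chain(p_detach: float, p_attach: float, p_divide: float,
                          p_exit: float, n_frames: int, initial_state: int,
                          seed: Optional[int] = None,
                          rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Simulate one cell's per-frame attachment status sequence.

    The attached/unattached backbone is a two-state Markov chain; each frame
    the cell may instead leave the field (code 5, absorbing) or divide
    (code 3, a single-frame event after which the cell is detached).  Event
    precedence per frame: exit, then division, then attach/detach switching.

    Returns an integer array of length ``n_frames`` with codes in {1,2,3,5}.
    """
    for name, p in (("p_detach", p_detach), ("p_attach", p_attach),
                    ("p_divide", p_divide), ("p_exit", p_exit)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {p!r}")
    if initial_state not in (ATTACHED, DETACHED):
        raise ValueError(f"initial_state must be 1 or 2, got {initial_state!r}")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    codes = np.empty(n_frames, dtype=np.int64)
    codes[0] = initial_state
    for f in range(1, n_frames):
        prev = codes[f - 1]
        if prev in (DEATH, OUT_OF_FRAME):
            codes[f] = prev
            continue
        state = DETACHED if prev == DIVISION else prev
        if rng.random() < p_exit:
            codes[f] = OUT_OF_FRAME
        elif rng.random() < p_divide:
            codes[f] = DIVISION
        elif state == ATTACHED:
            codes[f] = DETACHED if rng.random() < p_detach else ATTACHED
        else:
            codes[f] = ATTACHED if rng.random() < p_attach else DETACHED
    return codes


@dataclass
class SimCell:
    """One simulated cell: true and observed positions plus ground truth."""

    cell_id: int
    parent_id: Optional[int]
    birth_frame: int
    frames: np.ndarray                 # frames with a recorded position
    true_positions: np.ndarray         # (n, 3) µm
    observed_positions: np.ndarray     # (n, 3) µm, membrane-jittered
    status: np.ndarray                 # full-length codes, padded 5 after exit


@dataclass
class NicheScene:
    """A generated niche movie plus all ground truth needed to verify the
    downstream analysis: per-frame tip geometry, per-cell tracks (true and
    jittered), true status sequences, and marker tables."""

    params: SceneParameters
    tip_centers: np.ndarray            # (n_frames, 3)
    tip_radii: np.ndarray              # (n_frames,)
    cells: list[SimCell]
    cell_table: pd.DataFrame           # per-cell shape + marker snapshot
    foci: pd.DataFrame                 # desmin-like foci (x,y,z, dist_tip)
    secondary: pd.DataFrame            # interstitial-like cells
    origin: np.ndarray                 # µm coordinates of voxel (0,0,0)
    image_shape: tuple[int, int, int]  # (nz, ny, nx)

    def tip(self, frame: int) -> TipSphere:
        return TipSphere(self.tip_centers[frame], float(self.tip_radii[frame]))

    @property
    def n_frames(self) -> int:
        return self.params.n_frames

    def tracks_dataframe(self, observed: bool = True) -> pd.DataFrame:
        """Long-format track table (cell_id, frame, x_um, y_um, z_um,
        status_true, parent_id)."""
        rows = []
        for c in self.cells:
            pos = c.observed_positions if observed else c.true_positions
            for i, f in enumerate(c.frames):
                rows.append((c.cell_id, int(f), pos[i, 0], pos[i, 1], pos[i, 2],
                             int(c.status[f]),
                             -1 if c.parent_id is None else c.parent_id))
        return pd.DataFrame(rows, columns=["cell_id", "frame", "x_um", "y_um",
                                           "z_um", "status_true", "parent_id"])

    def status_matrix(self) -> pd.DataFrame:
        """Per-cell full-length status sequences as a (cell, frame) frame."""
        data = {c.cell_id: c.status for c in self.cells}
        return pd.DataFrame(data).T.rename_axis("cell_id")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


def _random_cap_direction(rng: np.random.Generator, max_polar: float) -> np.ndarray:
    """Uniform direction on the spherical cap polar angle <= max_polar."""
    cos_min = np.cos(max_polar)
    cos_t = rng.uniform(cos_min, 1.0)
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t ** 2))
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return np.array([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def _clamp_polar(u: np.ndarray, max_polar: float) -> np.ndarray:
    """Pull a direction back inside the cap if the walk left it."""
    u = _unit(u)
    polar = np.arccos(np.clip(u[2], -1.0, 1.0))
    if polar <= max_polar:
        return u
    # rotate towards +z in the plane spanned by u and z
    horiz = np.array([u[0], u[1], 0.0])
    h = np.linalg.norm(horiz)
    if h == 0:
        return np.array([0.0, 0.0, 1.0])
    horiz /= h
    return np.sin(max_polar) * horiz + np.array([0.0, 0.0, np.cos(max_polar)])


def generate_scene(params: SceneParameters) -> NicheScene:
    """Generate a full synthetic niche movie.

    Deterministic under (params, seed).  Cells start on the tip cap with a
    minimum spacing; attached cells perform a small tangential walk with the
    membrane overlapping the tip shell by ``attach_depth``; detached cells
    random-walk in a shell ``detach_gap_min``–``detach_gap`` above the
    surface.  Divisions spawn daughter tracks; exits censor a track.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n_frames = p.n_frames
    max_polar = np.deg2rad(p.max_polar_deg)

    drift = np.asarray(p.drift_velocity, dtype=float)
    frames_idx = np.arange(n_frames)
    tip_radii = p.tip_radius + p.tip_growth_rate * frames_idx
    # place the tip so the whole movie fits in a nonnegative voxel box
    extent = tip_radii[-1] + p.cell_radius + p.detach_gap + p.image_margin
    start = np.array([extent, extent, 0.0])
    tip_centers = start[None, :] + drift[None, :] * frames_idx[:, None]

    # --- initial placement with minimum spacing (rejection sampling)
    dirs: list[np.ndarray] = []
    min_cos = None
    if p.min_cell_spacing > 0:
        # chord distance on the attachment shell -> angular separation
        shell_r = tip_radii[0] + p.cell_radius - p.attach_depth
        min_cos = 1.0 - 0.5 * (p.min_cell_spacing / shell_r) ** 2
    attempts = 0
    while len(dirs) < p.n_cells and attempts < 20000:
        attempts += 1
        u = _random_cap_direction(rng, max_polar)
        if min_cos is not None and any(float(u @ v) > min_cos for v in dirs):
            continue
        dirs.append(u)
    if len(dirs) < p.n_cells:
        raise ValueError(
            "could not place n_cells on the tip cap at min_cell_spacing; "
            "increase tip_radius or reduce n_cells/min_cell_spacing")

    # --- status chains, then motion conditioned on the chain
    cells: list[SimCell] = []
    next_id = p.n_cells

    def attach_radius(f: int) -> float:
        return tip_radii[f] + p.cell_radius - p.attach_depth

    def run_cell(cell_id: int, parent_id: Optional[int], birth: int,
                 u0: np.ndarray, gap0: float, initial_state: int) -> None:
        nonlocal next_id
        status = np.full(n_frames, UNBORN, dtype=np.int64)
        chain = simulate_status_chain(p.p_detach, p.p_attach, p.p_divide,
                                      p.p_exit, n_frames - birth,
                                      initial_state, rng=rng)
        status[birth:] = chain
        u, gap = u0.copy(), gap0
        frames, true_pos = [], []
        for f in range(birth, n_frames):
            code = status[f]
            if code == OUT_OF_FRAME:
                break
            if code == ATTACHED:
                step = rng.normal(0.0, p.step_sd_attached, size=3)
                u = _clamp_polar(u + step, max_polar)
                gap = -p.attach_depth
            elif code == DETACHED:
                if gap < 0:  # just detached: push off the surface
                    gap = rng.uniform(p.detach_gap_min, p.detach_gap)
                else:
                    gap = float(np.clip(gap + rng.normal(0.0, p.step_sd_detached),
                                        p.detach_gap_min, p.detach_gap))
                ang = rng.normal(0.0, p.step_sd_detached / tip_radii[f], size=3)
                u = _clamp_polar(u + ang, max_polar)
            else:  # DIVISION: hold position this frame, spawn a daughter
                pass
            r = tip_radii[f] + p.cell_radius + gap
            pos = tip_centers[f] + r * u
            frames.append(f)
            true_pos.append(pos)
            if code == DIVISION and f + 1 < n_frames:
                d_u = _clamp_polar(u + rng.normal(0.0, 0.08, size=3), max_polar)
                d_gap = rng.uniform(p.detach_gap_min, p.detach_gap)
                daughter_id = next_id
                next_id += 1
                run_cell(daughter_id, cell_id, f + 1, d_u, d_gap, DETACHED)
        true_pos = np.asarray(true_pos, dtype=float).reshape(len(frames), 3)
        jitter = rng.normal(0.0, p.membrane_jitter_sd, size=true_pos.shape) \
            if p.membrane_jitter_sd > 0 else np.zeros_like(true_pos)
        cells.append(SimCell(cell_id=cell_id, parent_id=parent_id,
                             birth_frame=birth,
                             frames=np.asarray(frames, dtype=np.int64),
                             true_positions=true_pos,
                             observed_positions=true_pos + jitter,
                             status=status))

    n_attached = int(round(p.initial_attached_fraction * p.n_cells))
    for i, u0 in enumerate(dirs):
        if i < n_attached:
            run_cell(i, None, 0, u0, -p.attach_depth, ATTACHED)
        else:
            gap0 = rng.uniform(p.detach_gap_min, p.detach_gap)
            run_cell(i, None, 0, u0, gap0, DETACHED)
    cells.sort(key=lambda c: c.cell_id)

    # --- marker snapshot at marker_frame
    mf = min(p.marker_frame, n_frames - 1)
    tip_mf = TipSphere(tip_centers[mf], float(tip_radii[mf]))
    rows = []
    for c in cells:
        if mf not in c.frames:
            continue
        i = int(np.searchsorted(c.frames, mf))
        center = c.true_positions[i]
        foot = tip_mf.foot_point(center)[0]
        axis = _unit(center - foot)
        off = rng.normal(p.golgi_offset, p.golgi_offset_sd)
        golgi = center + off * axis
        ratio = float(np.clip(rng.normal(p.cell_axis_ratio, p.axis_ratio_sd),
                              0.05, 1.0))
        length = max(rng.normal(p.cell_length, 1.0), 2.0)
        rows.append((c.cell_id, int(c.status[mf]), *center, *foot, *golgi,
                     length, ratio * length))
    cell_table = pd.DataFrame(rows, columns=[
        "cell_id", "status", "x_um", "y_um", "z_um",
        "foot_x", "foot_y", "foot_z", "golgi_x", "golgi_y", "golgi_z",
        "length_um", "width_um"])

    # --- desmin-like foci: a desmin_near_fraction within 5 µm of the tip
    n_near = int(round(p.desmin_near_fraction * p.n_foci))
    foci_rows = []
    for k in range(p.n_foci):
        u = _random_cap_direction(rng, max_polar)
        if k < n_near:
            d = rng.uniform(0.2, 4.8)
        else:
            d = rng.uniform(5.2, 15.0)
        pos = tip_mf.center + (tip_mf.radius + d) * u
        foci_rows.append((*pos, d))
    foci = pd.DataFrame(foci_rows, columns=["x_um", "y_um", "z_um", "dist_tip_um"])

    # --- interstitial-like secondary cells
    n_near2 = int(round(p.secondary_near_fraction * p.n_secondary))
    sec_rows = []
    for k in range(p.n_secondary):
        u = _random_cap_direction(rng, max_polar)
        if k < n_near2:
            d = rng.uniform(0.0, 0.4)      # touching the tip
        else:
            d = rng.uniform(2.0 * p.cell_radius, 2.0 * p.cell_radius + 12.0)
        pos = tip_mf.center + (tip_mf.radius + d) * u
        sec_rows.append((*pos, d, k < n_near2))
    secondary = pd.DataFrame(sec_rows,
                             columns=["x_um", "y_um", "z_um", "dist_tip_um",
                                      "near_tip"])

    # --- image geometry
    vx, vy, vz = p.voxel_size
    size = 2.0 * extent + np.abs(drift) * (n_frames - 1) * np.array([1.0, 1.0, 1.0])
    zmax = tip_radii[-1] + p.cell_radius + p.detach_gap + p.image_margin \
        + max(0.0, drift[2] * (n_frames - 1))
    nx = int(np.ceil(size[0] / vx)) + 1
    ny = int(np.ceil(size[1] / vy)) + 1
    nz = int(np.ceil(zmax / vz)) + 1
    origin = np.array([0.0, 0.0, 0.0])

    return NicheScene(params=p, tip_centers=tip_centers, tip_radii=tip_radii,
                      cells=cells, cell_table=cell_table, foci=foci,
                      secondary=secondary, origin=origin,
                      image_shape=(nz, ny, nx))


def render_image_stack(scene: NicheScene, frame: int) -> dict[str, np.ndarray]:
    """Render one frame to labelled voxel volumes, axis order (z, y, x).

    Returns a dict with:

    - ``tip_mask``    bool, the hemispherical tip dome;
    - ``cell_labels`` uint16, solid cell spheres labelled ``cell_id + 1``
      (channels are independent; tip and cell volumes overlap only within
      the thin contact shell where attached membranes appose the tip);
    - ``nuclei``      float, a unit point source at each cell centre voxel;
    - ``foci``        float, point sources at desmin-like foci.

    Rendering is deterministic: re-rendering a frame reproduces identical
    volumes.
    """
    if not (0 <= frame < scene.n_frames):
        raise ValueError(f"frame {frame} out of range [0, {scene.n_frames})")
    p = scene.params
    nz, ny, nx = scene.image_shape
    vx, vy, vz = p.voxel_size
    zs = np.arange(nz) * vz
    ys = np.arange(ny) * vy
    xs = np.arange(nx) * vx
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")

    tip = scene.tip(frame)
    cx, cy, cz = tip.center
    dist2 = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2
    tip_mask = (dist2 <= tip.radius ** 2) & (Z >= cz)

    cell_labels = np.zeros((nz, ny, nx), dtype=np.uint16)
    nuclei = np.zeros((nz, ny, nx), dtype=float)
    for c in scene.cells:
        if frame not in c.frames:
            continue
        i = int(np.searchsorted(c.frames, frame))
        center = c.true_positions[i]
        r = p.cell_radius
        # local crop for speed
        zi0 = max(int((center[2] - r) / vz) - 1, 0)
        zi1 = min(int((center[2] + r) / vz) + 2, nz)
        yi0 = max(int((center[1] - r) / vy) - 1, 0)
        yi1 = min(int((center[1] + r) / vy) + 2, ny)
        xi0 = max(int((center[0] - r) / vx) - 1, 0)
        xi1 = min(int((center[0] + r) / vx) + 2, nx)
        sl = (slice(zi0, zi1), slice(yi0, yi1), slice(xi0, xi1))
        d2 = ((X[sl] - center[0]) ** 2 + (Y[sl] - center[1]) ** 2
              + (Z[sl] - center[2]) ** 2)
        cell_labels[sl][d2 <= r ** 2] = c.cell_id + 1
        iz = int(round(center[2] / vz))
        iy = int(round(center[1] / vy))
        ix = int(round(center[0] / vx))
        if 0 <= iz < nz and 0 <= iy < ny and 0 <= ix < nx:
            nuclei[iz, iy, ix] += 1.0

    foci = np.zeros((nz, ny, nx), dtype=float)
    for _, row in scene.foci.iterrows():
        iz = int(round(row.z_um / vz))
        iy = int(round(row.y_um / vy))
        ix = int(round(row.x_um / vx))
        if 0 <= iz < nz and 0 <= iy < ny and 0 <= ix < nx:
            foci[iz, iy, ix] += 1.0

    return {"tip_mask": tip_mask, "cell_labels": cell_labels,
            "nuclei": nuclei, "foci": foci}
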