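"""Track drift correction, triangulation smoothing, and windowing.

Raw 3D+t tracks of niche cells ride on the whole-tissue motion of the
growing kidney; subtracting a per-frame drift series (estimated from a
stationary reference such as the tip centroid) leaves cell-intrinsic
motion.  Membrane-reporter tracking adds high-frequency jitter on top of
the true cell-centre path; the triangulation pass replaces the track by
midpoints of consecutive raw positions, which cancels frame-to-frame
zig-zag while preserving the underlying direction of travel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class CellTrack:
    """One cell's time-indexed 3D positions (µm).

    ``frames`` are strictly increasing consecutive integers (no gaps before
    censoring); ``positions`` is the matching (n, 3) array.
    """

    cell_id: int
    frames: np.ndarray
    positions: np.ndarray
    parent_id: Optional[int] = None
    censored: bool = False
    censor_frame: Optional[int] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.frames) != len(self.positions):
            raise ValueError("frames and positions must have equal length")
        if len(self.frames) > 1:
            d = np.diff(self.frames)
            if np.any(d != 1):
                raise ValueError("frames must be consecutive integers")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def is_empty(self) -> bool:
        return len(self.frames) == 0

    def path_length(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.positions, axis=0),
                                           axis=1)))


@dataclass
class DriftSeries:
    """Per-frame cumulative translation (µm) mapping raw to corrected
    coordinates; the frame-0 vector is zero by construction."""

    frames: np.ndarray
    cumulative: np.ndarray  # (n, 3), displacement of the reference vs frame 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.cumulative = np.asarray(self.cumulative, dtype=float).reshape(-1, 3)
        if len(self.frames) != len(self.cumulative):
            raise ValueError("frames and cumulative must have equal length")
        if len(self.frames) and not np.allclose(self.cumulative[0], 0.0):
            raise ValueError("frame-0 drift vector must be zero")

    def per_frame(self) -> np.ndarray:
        """Frame-to-frame drift increments (first row zero)."""
        inc = np.zeros_like(self.cumulative)
        if len(self.cumulative) > 1:
            inc[1:] = np.diff(self.cumulative, axis=0)
        return inc

    def at(self, frames: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.frames, frames)
        if (np.any(idx >= len(self.frames))
                or np.any(self.frames[np.clip(idx, 0, len(self.frames) - 1)]
                          != frames)):
            missing = set(np.atleast_1d(frames)) - set(self.frames.tolist())
            raise ValueError(f"drift series does not cover frames {sorted(missing)}")
        return self.cumulative[idx]

    def negated(self) -> "DriftSeries":
        return DriftSeries(self.frames.copy(), -self.cumulative)


def estimate_drift(reference_positions: np.ndarray,
                   frames: Optional[np.ndarray] = None) -> DriftSeries:
    """Estimate tissue drift from a per-frame reference (e.g. tip centroid).

    The cumulative translation at frame f is the reference displacement
    from frame 0, so subtracting it renders the reference stationary.
    """
    ref = np.asarray(reference_positions, dtype=float)
    if ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("reference_positions must be (n_frames, 3)")
    if not np.all(np.isfinite(ref)):
        raise ValueError("reference positions must be finite at every frame")
    if frames is None:
        frames = np.arange(len(ref))
    return DriftSeries(frames, ref - ref[0])


def estimate_drift_global(tracks: list[CellTrack]) -> DriftSeries:
    """Fallback drift reference: per-frame mean step of all tracks,
    accumulated from frame 0 over the union of track frames."""
    if not tracks:
        raise ValueError("no tracks given")
    f0 = min(int(t.frames[0]) for t in tracks if not t.is_empty)
    f1 = max(int(t.frames[-1]) for t in tracks if not t.is_empty)
    frames = np.arange(f0, f1 + 1)
    inc = np.zeros((len(frames), 3))
    for i, f in enumerate(frames[1:], start=1):
        steps = []
        for t in tracks:
            j = np.searchsorted(t.frames, f)
            if j < len(t.frames) and t.frames[j] == f and j > 0:
                steps.append(t.positions[j] - t.positions[j - 1])
        if steps:
            inc[i] = np.mean(steps, axis=0)
    return DriftSeries(frames, np.cumsum(inc, axis=0))


def apply_drift_correction(track: CellTrack, drift: DriftSeries) -> CellTrack:
    """Subtract the cumulative drift at each track frame.

    Exactly invertible: applying ``drift.negated()`` restores the raw track.
    """
    if track.is_empty:
        return track
    corr = track.positions - drift.at(track.frames)
    return replace(track, positions=corr)


def triangulate_track(track: CellTrack, passes: int = 1) -> CellTrack:
    """Smooth a track by consecutive-pair midpoints.

    Each pass maps positions p_i -> (p_i + p_{i+1}) / 2 assigned to frame i,
    dropping the final frame; by the triangle inequality the total path
    length never increases.  ``passes`` iterates the construction.
    """
    if passes < 1:
        raise ValueError("passes must be >= 1")
    if track.n_frames < passes + 1:
        raise ValueError(
            f"track needs at least {passes + 1} frames for {passes} pass(es), "
            f"has {track.n_frames}")
    pos = track.positions
    frames = track.frames
    for _ in range(passes):
        pos = 0.5 * (pos[:-1] + pos[1:])
        frames = frames[:-1]
    return replace(track, frames=frames.copy(), positions=pos)


def analysis_window(track: CellTrack, first: int = 10,
                    last: int = 97) -> CellTrack:
    """Restrict a track to the analysed frame range [first, last].

    The default window discards the first 10 frames (setup artefacts) and
    keeps frames 10–97 (870 min at a 10-min interval).  An empty result is
    allowed and marked censored.
    """
    if first > last:
        raise ValueError(f"first ({first}) must be <= last ({last})")
    keep = (track.frames >= first) & (track.frames <= last)
    if not np.any(keep):
        return replace(track, frames=np.empty(0, dtype=np.int64),
                       positions=np.empty((0, 3)), censored=True,
                       censor_frame=first)
    return replace(track, frames=track.frames[keep],
                   positions=track.positions[keep])


def tracks_from_dataframe(df: pd.DataFrame,
                          position_cols: tuple[str, str, str] = ("x_um", "y_um", "z_um"),
                          ) -> list[CellTrack]:
    """Build CellTracks from a long-format table (cell_id, frame, x, y, z)."""
    out = []
    for cell_id, g in df.sort_values(["cell_id", "frame"]).groupby("cell_id"):
        parent = None
        if "parent_id" in g.columns:
            pv = int(g["parent_id"].iloc[0])
            parent = None if pv < 0 else pv
        out.append(CellTrack(cell_id=int(cell_id),
                             frames=g["frame"].to_numpy(),
                             positions=g[list(position_cols)].to_numpy(),
                             parent_id=parent))
    return out


def tracks_to_dataframe(tracks: list[CellTrack]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for i, f in enumerate(t.frames):
            rows.append((t.cell_id, int(f), *t.positions[i],
                         -1 if t.parent_id is None else t.parent_id))
    return pd.DataFrame(rows, columns=["cell_id", "frame", "x_um", "y_um",
                                       "z_um", "parent_id"])
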