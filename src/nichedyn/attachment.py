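"""Attachment-state classification and transition scoring.

Each cell-frame is coded 1 (attached), 2 (unattached), 3 (cell division),
4 (cell death) or 5 (out of frame).  A cell counts as attached when its
membrane lies within ``attach_distance`` of the tip surface.  Cells that
die or leave the field inside the analysis window are excluded, and each
remaining cell is scored for the number of frame-to-frame status changes
within codes 1–3 — the headline dynamics statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import ATTACHED, DETACHED, DIVISION, DEATH, OUT_OF_FRAME, UNBORN
from .tracks import CellTrack

ACTIVE_CODES = (ATTACHED, DETACHED, DIVISION)


@dataclass
class StatusSequence:
    """Per-frame attachment status codes for one cell."""

    cell_id: int
    frames: np.ndarray
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if len(self.frames) != len(self.codes):
            raise ValueError("frames and codes must have equal length")
        bad = set(self.codes.tolist()) - {1, 2, 3, 4, 5}
        if bad:
            raise ValueError(f"invalid status codes {sorted(bad)}")
        # censoring: nothing but same-code padding may follow a 4 or 5
        for absorbing in (DEATH, OUT_OF_FRAME):
            idx = np.flatnonzero(self.codes == absorbing)
            if len(idx) and np.any(self.codes[idx[0]:] != absorbing):
                raise ValueError(
                    f"code {absorbing} is absorbing; only padding may follow")

    def window(self, first: int, last: int) -> "StatusSequence":
        keep = (self.frames >= first) & (self.frames <= last)
        return StatusSequence(self.cell_id, self.frames[keep], self.codes[keep])

    def is_censored(self) -> bool:
        return bool(np.any(np.isin(self.codes, (DEATH, OUT_OF_FRAME))))


def _surface_distance(surface, points: np.ndarray) -> np.ndarray:
    """Point-to-surface distance for an analytic tip or a triangle mesh."""
    from .geometry import points_to_surface_distance
    return points_to_surface_distance(points, surface)


def classify_status(track: CellTrack, tip_surfaces: Mapping[int, object],
                    attach_distance: float = 1.0, cell_radius: float = 4.0,
                    division_frames: Iterable[int] = (),
                    death_frames: Iterable[int] = (),
                    censor_frames: Iterable[int] = ()) -> StatusSequence:
    """Classify each track frame as attached/unattached against the tip.

    A frame is attached (1) when the minimum membrane-to-surface distance
    — centre-to-surface distance minus ``cell_radius``, floored at zero —
    is at most ``attach_distance``; otherwise unattached (2).  Event
    annotations override: ``division_frames`` → 3 at those frames;
    ``death_frames``/``censor_frames`` → absorbing 4/5 from the earliest
    such frame onwards (a frame with no surface available is treated as a
    censor frame rather than interpolated).
    """
    if attach_distance < 0:
        raise ValueError(f"attach_distance must be >= 0, got {attach_distance!r}")
    if cell_radius < 0:
        raise ValueError(f"cell_radius must be >= 0, got {cell_radius!r}")
    division = set(int(f) for f in division_frames)
    death = set(int(f) for f in death_frames)
    censor = set(int(f) for f in censor_frames)
    for f in track.frames:
        if int(f) not in tip_surfaces and int(f) not in (death | censor):
            censor.add(int(f))

    codes = np.empty(track.n_frames, dtype=np.int64)
    absorbed = None
    for i, f in enumerate(track.frames.tolist()):
        if absorbed is not None:
            codes[i] = absorbed
            continue
        if f in death:
            codes[i] = absorbed = DEATH
        elif f in censor:
            codes[i] = absorbed = OUT_OF_FRAME
        elif f in division:
            codes[i] = DIVISION
        else:
            d_center = _surface_distance(tip_surfaces[f], track.positions[i])[0]
            membrane = max(float(d_center) - cell_radius, 0.0)
            codes[i] = ATTACHED if membrane <= attach_distance else DETACHED
    return StatusSequence(track.cell_id, track.frames.copy(), codes)


def filter_eligible(sequences: Sequence[StatusSequence],
                    ) -> tuple[list[StatusSequence], int]:
    """Drop cells that died or moved out of frame; returns (kept, n_excluded)."""
    kept = [s for s in sequences if not s.is_censored()]
    return kept, len(sequences) - len(kept)


def count_transitions(codes: Sequence[int] | np.ndarray) -> int:
    """Number of adjacent unequal code pairs with both codes in {1, 2, 3}.

    Pairs involving death (4) or out-of-frame (5) never count.
    """
    codes = np.asarray(codes, dtype=np.int64)
    if codes.size == 0:
        raise ValueError("empty status sequence")
    a, b = codes[:-1], codes[1:]
    active = np.isin(a, ACTIVE_CODES) & np.isin(b, ACTIVE_CODES)
    return int(np.sum(active & (a != b)))


def attachment_fraction(sequences: Sequence[StatusSequence],
                        frame: int) -> float:
    """Fraction of cells attached (code 1) among cells coded 1 or 2 at
    ``frame``."""
    n1 = n12 = 0
    for s in sequences:
        idx = np.flatnonzero(s.frames == frame)
        if len(idx) == 0:
            continue
        c = int(s.codes[idx[0]])
        if c in (ATTACHED, DETACHED):
            n12 += 1
            n1 += int(c == ATTACHED)
    if n12 == 0:
        raise ValueError(f"no eligible cells defined at frame {frame}")
    return n1 / n12


def per_cell_attached_fraction(seq: StatusSequence) -> float:
    """Fraction of a cell's 1-or-2 frames spent attached."""
    c = seq.codes
    n12 = np.sum(np.isin(c, (ATTACHED, DETACHED)))
    if n12 == 0:
        raise ValueError("sequence has no attached/unattached frames")
    return float(np.sum(c == ATTACHED) / n12)


def group_transition_summary(sequences_by_group: Mapping[str, Sequence[StatusSequence]],
                             initial_state_frame: Optional[int] = None,
                             ) -> pd.DataFrame:
    """Per-group mean ± SEM transition counts over eligible cells.

    With ``initial_state_frame`` set (conventionally the first analysed
    frame, 10), groups are additionally stratified by whether each cell was
    attached or unattached at that frame.
    """
    rows = []
    for group, seqs in sequences_by_group.items():
        if len(seqs) == 0:
            raise ValueError(f"group {group!r} is empty")
        eligible, _ = filter_eligible(list(seqs))
        if not eligible:
            raise ValueError(f"group {group!r} has no eligible cells")
        strata: dict[str, list[int]] = {}
        for s in eligible:
            counts = count_transitions(s.codes)
            label = "all"
            if initial_state_frame is not None:
                idx = np.flatnonzero(s.frames == initial_state_frame)
                if len(idx) == 0:
                    continue
                c0 = int(s.codes[idx[0]])
                label = "attached" if c0 == ATTACHED else "unattached"
            strata.setdefault(label, []).append(counts)
            if initial_state_frame is not None:
                strata.setdefault("all", []).append(counts)
        for label, vals in sorted(strata.items()):
            arr = np.asarray(vals, dtype=float)
            sem = (arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
            rows.append((group, label, len(arr), arr.mean(), sem))
    return pd.DataFrame(rows, columns=["group", "initial_state", "n",
                                       "mean_transitions", "sem"])


def sequences_to_dataframe(sequences: Sequence[StatusSequence]) -> pd.DataFrame:
    rows = [(s.cell_id, int(f), int(c))
            for s in sequences for f, c in zip(s.frames, s.codes)]
    return pd.DataFrame(rows, columns=["cell_id", "frame", "code"])


def sequences_from_scene(scene, window: Optional[tuple[int, int]] = None,
                         ) -> list[StatusSequence]:
    """Ground-truth StatusSequences from a generated scene (born frames
    only), optionally restricted to an analysis window."""
    out = []
    for c in scene.cells:
        mask = c.status != UNBORN
        frames = np.flatnonzero(mask)
        seq = StatusSequence(c.cell_id, frames, c.status[frames])
        if window is not None:
            seq = seq.window(*window)
        if len(seq.frames):
            out.append(seq)
    return out
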