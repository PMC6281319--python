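"""Per-cell motility statistics on processed tracks.

Displacement is the net start-to-end distance, path length the summed step
lengths, velocity the path length per unit time, and the meandering index
the ratio displacement / path length (1 for perfectly straight motion,
0 for a closed loop).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tracks import CellTrack


@dataclass
class MotilityRecord:
    cell_id: int
    displacement_um: float
    path_um: float
    duration_min: float
    velocity_um_min: float
    meandering: float


def track_motility(track: CellTrack, frame_interval: float = 10.0) -> MotilityRecord:
    """Compute displacement, path length, velocity and meandering for one
    track.  Requires at least two frames."""
    if track.n_frames < 2:
        raise ValueError("motility needs a track with >= 2 frames")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    disp = float(np.linalg.norm(track.positions[-1] - track.positions[0]))
    path = track.path_length()
    duration = (track.n_frames - 1) * frame_interval
    velocity = path / duration
    meandering = disp / path if path > 0 else 1.0
    return MotilityRecord(track.cell_id, disp, path, duration, velocity,
                          meandering)


def motility_table(tracks: Sequence[CellTrack],
                   frame_interval: float = 10.0) -> pd.DataFrame:
    recs = [track_motility(t, frame_interval) for t in tracks
            if t.n_frames >= 2]
    return pd.DataFrame([r.__dict__ for r in recs])


def motility_group_compare(records_by_group: Mapping[str, pd.DataFrame],
                           metrics: Sequence[str] = ("displacement_um",
                                                     "velocity_um_min",
                                                     "meandering"),
                           ) -> pd.DataFrame:
    """Per-metric two-group comparison (means, SEM, fold, Welch p)."""
    from .report import compare_groups
    groups = list(records_by_group)
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    a, b = groups
    rows = []
    for m in metrics:
        va = records_by_group[a][m].to_numpy(dtype=float)
        vb = records_by_group[b][m].to_numpy(dtype=float)
        cmp_ = compare_groups(va, vb, labels=(a, b), metric=m)
        rows.append(cmp_.as_row())
    return pd.DataFrame(rows)
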