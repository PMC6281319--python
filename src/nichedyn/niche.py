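"""Per-niche summary metrics and comparative arithmetic.

A niche is one ureteric branch tip plus its cap of nephron progenitors.
Summaries count progenitors and tip cells, measure cap/tip volumes from
labelled voxels, and histogram the developing nephron structures attached
to each tip by stage (renal vesicle, comma/S-shaped body, stage 4+).
Fold changes and percent reductions reproduce the reporting conventions
used for group means (1 decimal place for folds, nearest integer for
percentages, full precision alongside).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

NEPHRON_STAGES = ("RV", "comma_s", "stage4plus")


@dataclass
class NicheSummary:
    niche_id: int
    n_progenitors: int
    cap_volume_um3: float
    n_tip_cells: Optional[int] = None
    tip_volume_um3: Optional[float] = None
    nephrons_attached: int = 0
    nephron_stage_histogram: dict = field(
        default_factory=lambda: {s: 0 for s in NEPHRON_STAGES})
    stages_provided: bool = False

    def __post_init__(self) -> None:
        if self.n_progenitors < 0 or self.cap_volume_um3 < 0:
            raise ValueError("counts and volumes must be >= 0")


def label_volume(mask: np.ndarray, voxel_size: Sequence[float]) -> float:
    """Labelled-voxel volume in µm³ (voxel count × voxel volume)."""
    voxel = np.asarray(voxel_size, dtype=float)
    return float(np.count_nonzero(mask) * np.prod(voxel))


def summarize_niche(progenitor_marker, cap_region,
                    voxel_size: Sequence[float] = (1.0, 1.0, 1.0),
                    niche_id: int = 0,
                    tip_mask: Optional[np.ndarray] = None,
                    tip_nuclei=None,
                    nephron_stages: Optional[Sequence[str]] = None,
                    smoothing_sigma: float = 0.5,
                    min_separation: float = 2.0) -> NicheSummary:
    """Summarise one niche from labels/markers.

    ``progenitor_marker`` is a point list (n, 3) in µm or an intensity
    volume; ``cap_region`` a mask or an object with ``contains``.  Volumes
    are labelled-voxel counts × voxel volume.  Nephron staging is accepted
    as categorical input only.  Raises when a required label is missing.
    """
    from .geometry import count_cells_in_region
    if progenitor_marker is None:
        raise ValueError("missing required label: progenitor_marker")
    if cap_region is None:
        raise ValueError("missing required label: cap_region")
    n_prog = count_cells_in_region(progenitor_marker, cap_region,
                                   smoothing_sigma=smoothing_sigma,
                                   voxel_size=voxel_size,
                                   min_separation=min_separation)
    if hasattr(cap_region, "contains"):
        cap_vol = getattr(cap_region, "volume", float("nan"))
        cap_vol = float(cap_vol() if callable(cap_vol) else cap_vol)
        if np.isnan(cap_vol):
            cap_vol = 0.0
    else:
        cap_vol = label_volume(cap_region, voxel_size)

    n_tip = None
    tip_vol = None
    if tip_mask is not None:
        tip_vol = label_volume(tip_mask, voxel_size)
        if tip_nuclei is not None:
            n_tip = count_cells_in_region(tip_nuclei, tip_mask,
                                          smoothing_sigma=smoothing_sigma,
                                          voxel_size=voxel_size,
                                          min_separation=min_separation)

    hist = {s: 0 for s in NEPHRON_STAGES}
    provided = nephron_stages is not None
    n_neph = 0
    if provided:
        for s in nephron_stages:
            if s not in hist:
                raise ValueError(f"unknown nephron stage label {s!r}")
            hist[s] += 1
            n_neph += 1
    return NicheSummary(niche_id=niche_id, n_progenitors=n_prog,
                        cap_volume_um3=cap_vol, n_tip_cells=n_tip,
                        tip_volume_um3=tip_vol, nephrons_attached=n_neph,
                        nephron_stage_histogram=hist, stages_provided=provided)


def fold_change(mean_a: float, mean_b: float) -> tuple[float, float]:
    """Fold change mean_b / mean_a, returned as (full precision, 1 d.p.)."""
    if mean_a == 0:
        raise ValueError("reference mean must be nonzero")
    fc = mean_b / mean_a
    return fc, round(fc, 1)


def percent_reduction(mean_ref: float, mean_alt: float) -> tuple[float, int]:
    """Percent reduction 100 · (ref − alt) / ref, as (full precision,
    nearest integer)."""
    if mean_ref == 0:
        raise ValueError("reference mean must be nonzero")
    pr = 100.0 * (mean_ref - mean_alt) / mean_ref
    return pr, int(round(pr))


def nephrons_per_tip(tip_to_nephrons: Mapping[int, Sequence[str]],
                     ) -> tuple[float, dict[str, int]]:
    """Mean developing-nephron count per tip plus the stage histogram."""
    if len(tip_to_nephrons) == 0:
        raise ValueError("empty tip table")
    hist = {s: 0 for s in NEPHRON_STAGES}
    counts = []
    for tip_id, stages in tip_to_nephrons.items():
        counts.append(len(stages))
        for s in stages:
            if s not in hist:
                raise ValueError(f"unknown nephron stage label {s!r}")
            hist[s] += 1
    return float(np.mean(counts)), hist


def summaries_to_dataframe(summaries: Sequence[NicheSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"niche_id": s.niche_id, "n_progenitors": s.n_progenitors,
               "cap_volume_um3": s.cap_volume_um3,
               "n_tip_cells": s.n_tip_cells,
               "tip_volume_um3": s.tip_volume_um3,
               "nephrons_attached": s.nephrons_attached}
        row.update({f"stage_{k}": v for k, v in s.nephron_stage_histogram.items()})
        rows.append(row)
    return pd.DataFrame(rows)
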