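"""Group statistics and pipeline orchestration.

Two-group comparisons use Welch's unequal-variance t-test by default (a
pooled-variance option is provided), reported with per-group means, SEM
(sd/sqrt(n)), fold change, and the conventional significance tiers
(ns p>0.05, * p<0.05, ** p<0.01, *** p<0.001).  No multiple-testing
correction is applied.

``run_pipeline`` executes the full chain — simulate → track processing →
attachment classification → contact areas → motility → polarity → niche
metrics → group comparison — for a control-like and a mutant-like cohort,
writing CSV tables and a JSON summary with provenance (config hash, seed).
``replicate_study`` repeats the cohort contrast over many seeds for
calibration-style summaries; it measures contact areas per cell with the
closed-form sphere-cap estimator on observed positions, which the geometry
tests validate against the mesh route.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import simulate as sim
from .attachment import (classify_status, count_transitions, filter_eligible,
                         attachment_fraction, per_cell_attached_fraction,
                         group_transition_summary, sequences_to_dataframe)
from .geometry import sphere_cap_contact_area
from .motility import motility_table
from .niche import fold_change
from .polarity import polarity_table, foci_far_fraction
from .tracks import (CellTrack, analysis_window, apply_drift_correction,
                     estimate_drift, triangulate_track, tracks_to_dataframe)

log = logging.getLogger("nichedyn")


def significance_tier(p: float) -> str:
    if not (0.0 <= p <= 1.0) and not np.isnan(p):
        raise ValueError(f"p-value out of range: {p!r}")
    if np.isnan(p) or p > 0.05:
        return "ns"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    return "*"


@dataclass
class GroupComparison:
    """Two-group summary: means, SEM, fold change, t-test p, tier."""

    metric: str
    labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    sems: tuple[float, float]
    fold: float
    p_value: float
    tier: str
    test: str = "welch"

    def as_row(self) -> dict:
        return {"metric": self.metric,
                "group_a": self.labels[0], "group_b": self.labels[1],
                "n_a": self.n[0], "n_b": self.n[1],
                "mean_a": self.means[0], "mean_b": self.means[1],
                "sem_a": self.sems[0], "sem_b": self.sems[1],
                "fold_change": self.fold, "p_value": self.p_value,
                "tier": self.tier, "test": self.test}


def _sem(x: np.ndarray) -> float:
    return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0


def compare_groups(values_a: Sequence[float], values_b: Sequence[float],
                   labels: tuple[str, str] = ("control", "mutant"),
                   metric: str = "", equal_var: bool = False) -> GroupComparison:
    """Welch (default) or pooled two-sample two-sided t-test with summary
    statistics.  Requires n >= 2 finite values per group."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 finite values")
    import warnings
    with warnings.catch_warnings():
        # zero-variance groups are legitimate here and handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, equal_var=equal_var)
    p = float(res.pvalue)
    if np.isnan(p):  # zero variance in both groups with equal means
        p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    mean_a, mean_b = float(a.mean()), float(b.mean())
    fold = mean_b / mean_a if mean_a != 0 else float("inf")
    return GroupComparison(metric=metric, labels=labels,
                           n=(len(a), len(b)), means=(mean_a, mean_b),
                           sems=(_sem(a), _sem(b)), fold=fold, p_value=p,
                           tier=significance_tier(p),
                           test="pooled" if equal_var else "welch")


# ---------------------------------------------------------------------------
# cohort analysis on one generated scene

def analyze_scene(scene: sim.NicheScene, attach_distance: float = 1.0,
                  contact_distance: float = 0.5,
                  window: tuple[int, int] = (10, 97),
                  passes: int = 1) -> dict:
    """Run the measurement chain on one scene's *observed* data.

    Tracks are drift-corrected against the tip centroid, windowed, and
    triangulated; attachment status is classified geometrically per frame
    with division/censoring annotations taken from the event record;
    transitions are scored on eligible cells; per-cell contact areas use
    the sphere-cap estimator on observed positions at the marker frame.
    """
    p = scene.params
    first, last = window
    last = min(last, p.n_frames - 1)
    tips = {f: scene.tip(f) for f in range(p.n_frames)}
    drift = estimate_drift(scene.tip_centers)

    raw_tracks, corrected, sequences = [], [], []
    n_excluded = 0
    for c in scene.cells:
        t = CellTrack(cell_id=c.cell_id, frames=c.frames,
                      positions=c.observed_positions, parent_id=c.parent_id)
        raw_tracks.append(t)
        # a death/exit event at or before the window end censors the cell
        # (its track simply ends, so the event frame itself carries no
        # position and must be consulted directly)
        cens = np.flatnonzero(np.isin(c.status, (sim.DEATH, sim.OUT_OF_FRAME)))
        if len(cens) and cens[0] <= last:
            n_excluded += 1
            continue
        division = np.flatnonzero(c.status == sim.DIVISION).tolist()
        seq = classify_status(t, tips, attach_distance=attach_distance,
                              cell_radius=p.cell_radius,
                              division_frames=division)
        seq = seq.window(first, last)
        if len(seq.frames):
            sequences.append(seq)
        tw = analysis_window(apply_drift_correction(t, drift), first, last)
        if tw.n_frames >= passes + 1:
            corrected.append(triangulate_track(tw, passes=passes))

    eligible, _ = filter_eligible(sequences)
    transitions = pd.DataFrame(
        [(s.cell_id, count_transitions(s.codes)) for s in eligible],
        columns=["cell_id", "n_transitions"])
    attached_frac = pd.DataFrame(
        [(s.cell_id, per_cell_attached_fraction(s)) for s in eligible],
        columns=["cell_id", "attached_fraction"])
    try:
        frac_first = attachment_fraction(eligible, first)
    except ValueError:
        frac_first = float("nan")

    # per-cell contact area: mean sphere-cap estimate over the frames the
    # cell is classified attached within the window
    areas = []
    by_id = {c.cell_id: c for c in scene.cells}
    for s in eligible:
        att_frames = s.frames[s.codes == sim.ATTACHED]
        if len(att_frames) == 0:
            continue
        c = by_id[s.cell_id]
        vals = []
        for f in att_frames.tolist():
            i = int(np.searchsorted(c.frames, f))
            d = float(np.linalg.norm(c.observed_positions[i]
                                     - scene.tip_centers[f]))
            vals.append(sphere_cap_contact_area(
                p.cell_radius, d, float(scene.tip_radii[f]), contact_distance))
        areas.append((s.cell_id, float(np.mean(vals))))
    contact = pd.DataFrame(areas, columns=["cell_id", "contact_area_um2"])

    motility = motility_table(corrected, frame_interval=p.frame_interval)
    polarity = polarity_table(scene.cell_table)
    far_pct = foci_far_fraction(scene.foci["dist_tip_um"].to_numpy(), cutoff=5.0)

    return {"tracks": raw_tracks, "corrected_tracks": corrected,
            "sequences": eligible, "n_excluded": n_excluded,
            "transitions": transitions, "attached_fraction": attached_frac,
            "attachment_fraction_first_frame": frac_first,
            "contact_areas": contact, "motility": motility,
            "polarity": polarity, "foci_far_pct": far_pct}


_COHORT_METRICS = (
    ("n_transitions", "transitions", "n_transitions"),
    ("attached_fraction", "attached_fraction", "attached_fraction"),
    ("contact_area_um2", "contact_areas", "contact_area_um2"),
    ("roundness", "polarity", "roundness"),
    ("golgi_ratio", "polarity", "golgi_ratio"),
    ("velocity_um_min", "motility", "velocity_um_min"),
    ("displacement_um", "motility", "displacement_um"),
    ("meandering", "motility", "meandering"),
)


def compare_cohorts(result_a: dict, result_b: dict,
                    labels: tuple[str, str] = ("control", "mutant"),
                    ) -> pd.DataFrame:
    rows = []
    for metric, table, col in _COHORT_METRICS:
        va = result_a[table][col].to_numpy(dtype=float)
        vb = result_b[table][col].to_numpy(dtype=float)
        if len(va) < 2 or len(vb) < 2:
            continue
        rows.append(compare_groups(va, vb, labels=labels, metric=metric).as_row())
    return pd.DataFrame(rows)


def replicate_study(n_replicates: int = 100, base_seed: int = 0,
                    n_cells: int = 30, n_frames: int = 98,
                    window: tuple[int, int] = (10, 97),
                    control_kwargs: Optional[dict] = None,
                    mutant_kwargs: Optional[dict] = None) -> pd.DataFrame:
    """Repeat the control-like vs mutant-like cohort contrast over seeds.

    Returns one row per replicate with per-group means, fold changes and
    Welch p-values for transitions, attached fraction, contact area,
    roundness and Golgi ratio.
    """
    rows = []
    ck = dict(n_cells=n_cells, n_frames=n_frames)
    ck.update(control_kwargs or {})
    mk = dict(n_cells=n_cells, n_frames=n_frames)
    mk.update(mutant_kwargs or {})
    for rep in range(n_replicates):
        sc = sim.generate_scene(sim.control_like(**ck, seed=base_seed + 2 * rep))
        sm = sim.generate_scene(sim.mutant_like(**mk, seed=base_seed + 2 * rep + 1))
        ra = analyze_scene(sc, window=window)
        rb = analyze_scene(sm, window=window)
        cmp_df = compare_cohorts(ra, rb)
        row = {"replicate": rep}
        for _, r in cmp_df.iterrows():
            m = r["metric"]
            row[f"{m}_control"] = r["mean_a"]
            row[f"{m}_mutant"] = r["mean_b"]
            row[f"{m}_fold"] = r["fold_change"]
            row[f"{m}_p"] = r["p_value"]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full pipeline

DEFAULT_CONFIG: dict = {
    "scene": {
        "groups": {"control": {"preset": "control_like"},
                   "mutant": {"preset": "mutant_like"}},
        "n_cells": 30,
        "n_frames": 98,
    },
    "thresholds": {"attach_distance": 1.0, "contact_distance": 0.5,
                   "min_area": 0.5},
    "window": [10, 97],
    "passes": 1,
    "seed": 0,
}


def _config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: Optional[Mapping] = None,
                 out_dir: Optional[str | Path] = None,
                 seed: Optional[int] = None) -> dict:
    """Execute the full analysis chain for every configured group and write
    CSV tables plus a JSON summary with provenance.

    Any stage failure raises an error naming the stage; outputs written by
    earlier stages are retained.
    """
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if config:
        for k, v in config.items():
            if isinstance(v, Mapping) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    if seed is not None:
        cfg["seed"] = int(seed)
    window = tuple(cfg["window"])
    thresholds = cfg["thresholds"]
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    results: dict[str, dict] = {}
    scene_cfg = cfg["scene"]
    group_items = list(scene_cfg["groups"].items())
    for gi, (name, gcfg) in enumerate(group_items):
        stage = f"simulate[{name}]"
        try:
            preset = sim.PRESETS[gcfg.get("preset", "control_like")]
            overrides = {k: v for k, v in gcfg.items() if k != "preset"}
            overrides.setdefault("n_cells", scene_cfg.get("n_cells", 30))
            overrides.setdefault("n_frames", scene_cfg.get("n_frames", 98))
            params = preset(**overrides, seed=int(cfg["seed"]) + gi)
            log.info("stage %s: seed=%d", stage, params.seed)
            scene = sim.generate_scene(params)
        except Exception as e:
            raise RuntimeError(f"stage {stage} failed: {e}") from e
        stage = f"analyze[{name}]"
        try:
            res = analyze_scene(scene,
                                attach_distance=thresholds["attach_distance"],
                                contact_distance=thresholds["contact_distance"],
                                window=window, passes=int(cfg["passes"]))
        except Exception as e:
            raise RuntimeError(f"stage {stage} failed: {e}") from e
        res["scene"] = scene
        results[name] = res
        if out is not None:
            tracks_to_dataframe(res["tracks"]).to_csv(
                out / f"tracks_raw_{name}.csv", index=False)
            tracks_to_dataframe(res["corrected_tracks"]).to_csv(
                out / f"tracks_processed_{name}.csv", index=False)
            sequences_to_dataframe(res["sequences"]).to_csv(
                out / f"status_{name}.csv", index=False)
            for key in ("transitions", "attached_fraction", "contact_areas",
                        "motility", "polarity"):
                res[key].to_csv(out / f"{key}_{name}.csv", index=False)

    summary: dict = {"config_hash": _config_hash(cfg), "seed": cfg["seed"],
                     "groups": {}}
    for name, res in results.items():
        summary["groups"][name] = {
            "n_cells_eligible": int(len(res["transitions"])),
            "n_excluded": int(res["n_excluded"]),
            "mean_transitions": float(res["transitions"]["n_transitions"].mean()),
            "attachment_fraction_first_frame":
                float(res["attachment_fraction_first_frame"]),
            "mean_contact_area_um2":
                float(res["contact_areas"]["contact_area_um2"].mean())
                if len(res["contact_areas"]) else float("nan"),
            "mean_roundness": float(res["polarity"]["roundness"].mean()),
            "mean_golgi_ratio": float(res["polarity"]["golgi_ratio"].mean()),
            "foci_far_pct": float(res["foci_far_pct"]),
        }
    if len(results) == 2:
        (na, ra), (nb, rb) = results.items()
        stage = "compare"
        try:
            comparisons = compare_cohorts(ra, rb, labels=(na, nb))
        except Exception as e:
            raise RuntimeError(f"stage {stage} failed: {e}") from e
        summary["comparisons"] = comparisons.to_dict(orient="records")
        t_fold, t_fold_1dp = fold_change(
            summary["groups"][na]["mean_transitions"],
            summary["groups"][nb]["mean_transitions"])
        summary["transition_fold_change"] = t_fold
        summary["transition_fold_change_1dp"] = t_fold_1dp
        if out is not None:
            comparisons.to_csv(out / "comparisons.csv", index=False)
    if out is not None:
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
    summary["results"] = results
    return summary
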