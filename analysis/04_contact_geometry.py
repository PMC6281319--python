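#!/usr/bin/env python
"""Reconstruct cell and tip surfaces from a rendered frame and measure
per-cell contact areas.

Meshes the tip (1 µm blur, 1 µm detail) and each attached cell (0.3 µm
detail) from a small isotropic-voxel scene, extracts surface–surface
contact patches (0.5 µm contact distance, 0.5 µm² noise filter) and
compares the meshed areas against the closed-form sphere-cap values.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import nichedyn as nd

SEED = 20183
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "contacts"
    out.mkdir(parents=True, exist_ok=True)
    params = nd.SceneParameters(
        n_cells=4, n_frames=12, tip_radius=12.0, voxel_size=(0.4, 0.4, 0.4),
        drift_velocity=(0.0, 0.0, 0.0), tip_growth_rate=0.0,
        p_detach=0.0, p_divide=0.0, p_exit=0.0, membrane_jitter_sd=0.0,
        image_margin=6.0, max_polar_deg=45.0, min_cell_spacing=8.5,
        seed=SEED)
    scene = nd.generate_scene(params)
    frame = 10
    vols = nd.render_image_stack(scene, frame)
    tip = scene.tip(frame)

    rows = []
    for c in scene.cells:
        i = int(np.searchsorted(c.frames, frame))
        cell_surf = nd.build_surface(vols["cell_labels"] == c.cell_id + 1,
                                     voxel_size=params.voxel_size[::-1],
                                     blur_sigma=0.0, detail=0.3)
        patches = nd.contact_patches(cell_surf, tip, contact_distance=0.5,
                                     min_area=0.5, cell_id=c.cell_id)
        mesh_area = sum(p.area_um2 for p in patches)
        d = float(np.linalg.norm(c.true_positions[i] - tip.center))
        analytic = nd.sphere_cap_contact_area(params.cell_radius, d,
                                              tip.radius, 0.5)
        rows.append((c.cell_id, mesh_area, analytic,
                     100 * abs(mesh_area - analytic) / analytic))
    table = pd.DataFrame(rows, columns=["cell_id", "mesh_area_um2",
                                        "analytic_area_um2", "error_pct"])
    table.to_csv(out / "contact_areas.csv", index=False)
    print(table.to_string(index=False))
    print(f"mean |error| vs sphere-cap oracle: {table.error_pct.mean():.1f}%")


if __name__ == "__main__":
    main()
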