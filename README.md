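# nichedyn

Quantification of nephron-progenitor behaviour in the nephrogenic niche of
the developing kidney, driven by a ground-truthed synthetic scene
simulator.

## The problem

Nephron progenitors (Six2⁺ mesenchymal cells) cap each ureteric branch tip
and anchor themselves to the tip epithelium through membranous
protrusions.  Live imaging of explanted kidneys shows that healthy
progenitors hold stable attachments — detaching briefly only to divide —
while perturbed progenitors cycle through rounds of detachment and
reattachment, disperse from the cap, intermix with Foxd1⁺ interstitial
progenitors and differentiate prematurely.  Quantifying this behaviour
requires a chain of measurements over 3D+t microscopy: tissue-drift
correction and membrane-jitter smoothing of manual cell tracks, per-frame
attachment-state classification, transition scoring, cell–epithelium
contact-area reconstruction, motility statistics, polarity indices and
niche-level counts.

Raw movies for such studies are rarely shareable, so `nichedyn` pairs the
full measurement chain with a synthetic niche simulator whose ground truth
makes every stage verifiable: each measurement can be checked against the
parameters that generated the data.  The package is aimed at developmental
biologists and image analysts who want a tested, scriptable version of
this workflow.

## Model and statistics

- **Scene model.** The tip is a hemispherical dome of radius R(f) = R₀ +
  g·f translating at a drift velocity v; progenitors sit on the cap and
  switch between *attached* (membrane apposed to the tip) and *unattached*
  states by a two-state Markov chain with per-frame probabilities
  p_detach and p_attach, plus single-frame division events (after which
  the cell is detached and a daughter track spawns) and absorbing
  out-of-frame exits.  Observed positions are the true centres plus
  isotropic Gaussian membrane jitter.  Frames are 10 min apart, z-step
  3 µm, movies ≈98 frames.
- **Status codes.** 1 = attached, 2 = unattached, 3 = cell division,
  4 = cell death, 5 = out of frame.  Cells with a 4 or 5 inside the
  analysed window (frames 10–97) are excluded.  The headline statistic is
  the per-cell count of frame-to-frame status changes within codes 1–3.
- **Track processing.** Drift correction subtracts the cumulative
  displacement of a reference (tip centroid) so residual motion is
  cell-intrinsic; triangulation replaces the track by midpoints of
  consecutive positions, (pᵢ + pᵢ₊₁)/2, which cancels membrane zig-zag and
  never increases path length.
- **Contact geometry.** Label volumes are meshed (Gaussian blur, isotropic
  "detail" resampling, marching cubes); contacts are connected components
  of cell-surface triangles within 0.5 µm of the tip surface, filtered at
  0.5 µm²; a closed-form sphere-cap area (2πr·h) serves as the analytic
  oracle and as a fast per-cell estimator.
- **Motility & polarity.** displacement |p_last − p_first|, path length
  Σ|Δp|, velocity path/duration, meandering displacement/path; roundness =
  width/length; Golgi polarity a/b with a = |centre−foot|, b =
  |Golgi−foot| (smaller ⇒ Golgi distal to the tip); desmin-focus
  dispersion as the % of foci > 5 µm from the tip.
- **Reporting.** Group means ± SEM, fold changes (1 d.p.) and percent
  reductions (nearest integer), Welch two-sided t-tests with the usual
  tiers (ns, *, **, ***).

## Worked example

The numbered scripts under `analysis/` run the full study on simulated
cohorts (a stable "control-like" preset, p_detach = 0.005, and a
switching "mutant-like" preset, p_detach = 0.05, p_attach = 0.2; 30 cells,
98 frames).  `python analysis/03_attachment_dynamics.py` prints:

```
  group initial_state  n  mean_transitions      sem
control           all 29          0.724138 0.226869
 mutant           all 29          7.551724 0.456443
 mutant      attached 21          7.571429 0.571429
 mutant    unattached  8          7.500000 0.755929
mutant-like cells switch status 10.4x more often than control-like cells
```

Control-like cells barely change status (they detach essentially only to
divide) while mutant-like cells average ~7.5 changes over the 14.5 h
window, whether they start attached or detached.  The cohort comparison
(`analysis/05_motility_polarity.py`) shows the full phenotype panel —
lower attachment fraction, smaller contact areas, rounder cells, higher
Golgi a/b ratio, higher velocity, and no significant difference in
meandering:

```
    n_transitions  0.937500  7.258065     7.741935 2.021320e-15  ***
attached_fraction  0.963797  0.775037     0.804150 2.118176e-12  ***
 contact_area_um2 32.852957 22.397371     0.681746 6.303992e-41  ***
        roundness  0.434952  0.578339     1.329659 8.762303e-14  ***
      golgi_ratio  0.588443  1.069849     1.818101 4.022281e-15  ***
  velocity_um_min  0.078331  0.105057     1.341205 2.727132e-16  ***
  displacement_um  7.223476  9.400943     1.301443 3.749766e-03   **
       meandering  0.114605  0.118286     1.032119 7.964282e-01   ns
```

A library one-liner for the same comparison:

```python
import nichedyn as nd
summary = nd.run_pipeline(out_dir="out", seed=0)
```

## Layout

```
src/nichedyn/      library: simulate, tracks, attachment, geometry,
                   motility, polarity, niche, report, io, cli
analysis/          numbered drivers reproducing the study, step by step
tests/             pytest suite (unit, property and acceptance tests)
scripts/           acceptance.py
docs/methods.md    models, assumptions, parameter choices, limitations
```

A `nichedyn` CLI (`simulate`, `track`, `motility`, `metrics`, `run`)
wraps the library for shell use.
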