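# bundlekit

Colonies of matrix-producing bacteria can spread over surfaces without
flagella: at the colony edge, chains of pole-to-pole attached cells organize
into tightly aligned multicellular bundles whose growing filaments buckle,
fold into loops, and push the colony front outward. `bundlekit` implements a
desk-scale computational account of this mechanism for people studying
collective motility and multicellular organization in rod-shaped bacteria:

* a **stochastic filament model** — elongation, division, and bending-energy
  turning of a pinned cell chain in a 1 x 1 arena — that reproduces
  loop-driven front migration and how it responds to cell length and bending
  rigidity;
* the **micrograph statistics** used to characterize such bundles from
  segmented images: neighborhood alignment of cell segments, two-channel
  observed/expected co-expression ratios, pole-localization transect profiles,
  and loop-folding angle distributions;
* a **synthetic-data generator** that produces every input with known ground
  truth, so the whole pipeline is testable without microscopy data.

## The model in brief

A filament of N cells starts as a straight line at the bottom of the unit
square, with both ends pinned. Per step one random cell either elongates
(rate ~ Uniform(0, G), pushing a random neighbor away; cells longer than S
divide into two equal daughters without moving any node) or attempts to turn:
the pole shared with a random neighbor is rotated by beta ~ Normal(0, B) and
the move is adopted — only if it lowers the bending energy

    V = (pi - alpha1)^2 + (pi - alpha2)^2

(alpha1, alpha2 = angles with the left/right neighbor, pi = aligned) — with
probability

    P = 1 - exp(-k (V_c - V_n)),

where k is the bending rigidity. Cells never overlap and never leave the
arena. Migration is the maximum advance of the filament along y. Stiffer
(high k) or longer (high S) cells fold less and migrate farther; the
package's three canonical conditions (default, k x10, S and L0 x2) make that
comparison directly.

## Worked example

Generate a synthetic bundle field and measure its alignment:

```
$ bundlekit synth cells --seed 7 --out demo/cells
$ bundlekit align --cells demo/cells/centerlines.csv --seed 7 --out demo/align
INFO bundlekit: mean neighbor angle 5.19 deg over 1103 pairs
```

`demo/align/summary.json` then holds:

```json
{
  "mean_angle_deg": 5.188905026484802,
  "n_pairs": 1103,
  "n_focal": 68,
  "n_segments": 683
}
```

The generator laid 200 chained cells in near-parallel rows with 5 degrees of
axial orientation noise; the measured mean angular difference between
neighboring cell segments (within 20 px, same-cell segments excluded, 10% of
segments as foci) is 5.19 degrees — the tight-alignment regime of a bundle.
For two independent wrapped-normal orientations with sd 5 the expected folded
difference is 2*5/sqrt(pi) ~ 5.64 degrees; a dispersed field with uniform
random orientations measures ~45 degrees instead.

Run a short simulation (2 x 10^4 steps; the default experiment uses 2 x 10^5):

```
$ printf 'N = 20\nT = 20000\n' > demo/sim.cfg
$ bundlekit simulate --config demo/sim.cfg --seed 1 --out demo/sim
INFO bundlekit: final migration extent 0.2113 with 210 cells
```

`demo/sim/trajectory.csv` records (step, migration_extent, n_cells,
arc_length); here the filament grew from 20 to 210 cells and its folds formed
loops whose apices advanced 0.21 arena units from the starting line. The
Python API mirrors the CLI: `bundlekit.filament.SimParams`, `run()`,
`compare_conditions()`, and the analysis modules `alignment`, `fluorescence`,
`folding`, `synthetic`, `io`.

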