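# kelpmorph

Morphometry, cell-lineage tracking and growth statistics for early kelp
(*Saccharina latissima*) embryos — plus a synthetic-embryo simulator so the
whole pipeline can be validated without microscopy data.

## The problem

The sugar-kelp embryo starts as an elongated zygote that grows as a
one-dimensional stack of cells through transverse divisions; around the
8-cell stage the apical-most cells begin dividing longitudinally (new wall
parallel to the growth axis) and the embryo widens into its lamina. Laser
ablation experiments show this behaviour is controlled by two distinct
mechanisms: growth is *cell-autonomous* (an ablated region is never
compensated by faster growth elsewhere), while the orientation of division
is *non-cell-autonomous* — the basal cell inhibits longitudinal divisions
within a finite range, so removing it triggers longitudinal division
immediately.

`kelpmorph` is for researchers quantifying such experiments from manually
segmented time-lapse images (Inkscape-style SVG outlines, one layer per
day). It computes, per cell and per blade (the union of living cells):

- surface area `S` (shoelace; blade area = Σ cell areas),
- length `L`, width `W` and the anisotropy ratio `LWR = L/W` from the
  minimal bounding rectangle of the convex hull (cells) or the principal
  area-moment axes (blades),
- division events with orientation (transverse vs longitudinal, by the
  acute angle of the new wall to the blade main axis; < 45° ⇒
  longitudinal) and the living-cell count at the first longitudinal
  division,
- per-embryo increase rates as OLS slopes on log-transformed measures, and
  group comparisons by Mann–Whitney U (exact for small tie-free samples)
  or Student t (cell LWR), at α = 0.05.

The built-in simulator implements the basal-inhibition model — positional
growth gradient `g(x) = g_b + (g_a − g_b)·x` along the axis, area-threshold
divisions, longitudinal orientation iff the basal lineage is dead or the
cell lies more than `R` living cells above the base — and renders daily
snapshots to the same SVG dialect, with ground-truth lineage for testing.

## Worked example

```python
from kelpmorph.simulator import intact_config, simulate_embryo, render_snapshots
from kelpmorph.segio import read_segmentation
from kelpmorph.morphometry import blade_metrics
from kelpmorph.lineage import track_series, first_longitudinal_stage

series = simulate_embryo(intact_config())                 # default intact embryo
svg = render_snapshots(series, calibration=0.5,
                       embryo_id="demo", condition="CT8") # draw daily snapshots
ts = read_segmentation(svg, calibration=0.5,
                       condition="CT8", embryo_id="demo") # read them back

for snap in ts.snapshots[:7]:
    bm = blade_metrics(snap)
    print(f"day {bm.day}: {bm.n_cells_alive} cells, "
          f"area {bm.blade_area:8.1f} um2, LWR {bm.lwr:5.2f}")

maps = track_series(ts)
print("first longitudinal division at", first_longitudinal_stage(maps), "cells")
```

prints

```
day 0: 1 cells, area    350.0 um2, LWR  3.50
day 1: 1 cells, area    586.2 um2, LWR  5.86
day 2: 2 cells, area    982.0 um2, LWR  9.82
day 3: 2 cells, area   1644.8 um2, LWR 16.45
day 4: 4 cells, area   2755.0 um2, LWR 27.55
day 5: 4 cells, area   4614.7 um2, LWR 46.15
day 6: 8 cells, area   7729.6 um2, LWR 77.30
first longitudinal division at 8 cells
```

The blade grows exponentially at the partition-independent mean rate
`(g_b + g_a)/2` while cell counts double every two days, and the first
longitudinal division arrives exactly at the 8-cell stage — the onset
observed in intact embryos. Repeating this with a basal ablation at the
2-cell stage (`ablated_config("basal", 2)`) yields a first longitudinal
division at 1 living cell: with the basal inhibitor gone, the very next
division is longitudinal.

## Command line

```sh
kelpmorph simulate  -o fixtures --seed 1 --replicates 5      # 9-condition SVG bundle
kelpmorph analyze   -o results  -i fixtures --calibration 1  # full analysis tables
kelpmorph end-to-end -o study   --seed 1 --noise-cv 0.1 --jitter-sd 0.2
```

`analyze` emits CSV tables (per-cell metrics, per-day blade metrics,
division events, first-longitudinal-stage per embryo, condition
comparisons) and a JSON run log; outputs are byte-identical under a fixed
seed.

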