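# dentoproxy

A toolkit for multi-proxy dietary-ecology analysis of herbivore dentitions.
Tooth crowns record how an animal fed at several independent timescales —
daily dentine growth increments, microscopic wear textures accumulated over
days to weeks, and macroscopic volume loss over the functional life of the
tooth.  `dentoproxy` computes the standard quantitative proxies from each of
these records and combines them into a single comparative table, so that
co-occurring taxa can be compared across all proxies at once (for example to
test niche partitioning between sympatric herbivores).

It is aimed at vertebrate palaeontologists and zoologists working with 3-D
crown scans, confocal surface metrology of wear facets, operator-digitized
2-D microwear, and histological thin sections.

## What it computes

**Crown complexity — OPCR.**  The crown surface is resampled to a square
raster standardised to a fixed number of rows per tooth (RPT, default 50)
along the mesiodistal axis.  Each cell takes the compass aspect of steepest
descent, discretised into eight 45° bins; contiguous same-bin cells form
patches, and patches of ≥ 3 cells are counted.  The count is repeated at
eight rotations of the bin boundaries (45°/8 = 5.625° apart) and averaged:

    OPCR = (1/8) Σₖ patch_count(rotation k · 5.625°)

A monotone single-aspect surface scores exactly 1.

**Microwear texture — SSFA.**  From a leveled, hole-filled height map the
relative area A_rel(s) is measured by virtual triangular tiling at a dyadic
series of scales s.  The attributes are

- `Asfc = −1000 · min slope of log A_rel vs log s` (steepest window),
- `Smc` — the finest scale of that steepest window,
- `epLsar` — the resultant length of the exact-proportion rose of transect
  relative lengths on doubled (axial) angles, `|Σ_θ p_θ (cos 2θ, sin 2θ)|`,
- `HAsfc(9×9)` — median(|Asfc_i − median|)/median over a 9×9 partition.

High Asfc with low epLsar is the pit-dominated texture of browsers; high
epLsar signals parallel-scratch-dominated (grazer-like) wear.

**Traditional 2-D microwear.**  Digitized features with length:width < 4:1
are pits, > 4:1 scratches; features over 0.5 mm are macrowear and excluded.
Four variables are reported: % pitting, mean scratch width, mean pit width,
mean pit length (with sample SDs).

**Macrowear volumetrics.**  Crown volumes by the divergence theorem on
(cap-closed) triangle meshes; percent crown volume lost between
size-matched intact and worn crowns; per-quadrant abraded volume
(tooth count × per-tooth loss); wear-facet area coverage and facet angle to
the apicobasal axis.

**Incremental dentine chronology.**  One von Ebner incremental band (a
dark + light dentine couplet) records one day of tooth formation, so the
band count of a complete transect is the formation time in days; widths on
the working vs balancing side of the crown quantify asymmetric daily
dentine deposition; a fully erupted, germ-free functional tooth bounds the
tooth replacement interval from below by its formation time.

**Multi-proxy comparison.**  A per-taxon proxy table and centered/scaled
PCA (SVD, `prcomp` conventions) over per-micrograph microwear or DMTA
variables.

Every input kind has a synthetic generator with machine-readable ground
truth (closed-form crown volumes, stamped feature lists, known band
counts), so the entire pipeline is testable without scan data.

## Worked example

```python
from dentoproxy.synthetic import SyntheticCrownSpec, SyntheticSurfaceSpec, \
    make_crown, make_surface
from dentoproxy.wear import crown_volume, percent_volume_lost
from dentoproxy.opcr import opcr, GridSpec
from dentoproxy.ssfa import analyze

complete, worn, truth = make_crown(
    SyntheticCrownSpec(shape="cone", radius=3, height=8,
                       removal_fraction=0.28, sections=256))
vc, vw = crown_volume(complete), crown_volume(worn)
print(f"complete crown volume: {vc:.2f} mm^3 (closed form {truth.v_complete:.2f})")
print(f"worn crown volume:     {vw:.2f} mm^3")
print(f"percent volume lost:   {percent_volume_lost(vc, vw):.1f} %")

res = opcr(complete, GridSpec(rpt=25))
print(f"OPCR (25 rpt):         {res.opcr:.3f}")

hmap, _ = make_surface(SyntheticSurfaceSpec(n=128, n_features=60,
                                            pit_fraction=0.8), 1)
s = analyze(hmap)
print(f"Asfc {s.asfc:.3f}  Smc {s.smc:.2f} um^2  epLsar {s.eplsar:.4f}")
```

prints

```
complete crown volume: 75.39 mm^3 (closed form 75.40)
worn crown volume:     54.28 mm^3
percent volume lost:   28.0 %
OPCR (25 rpt):         8.000
Asfc 4.222  Smc 1.38 um^2  epLsar 0.0013
```

The worn cone was engineered to lose 28% of its volume and the measured
loss recovers it to 0.1%; the cone with its circular flank covers all eight
aspect bins, giving 8 patches at every rotation; the pit-dominated
synthetic facet shows high complexity with near-zero anisotropy, the
texture signature of a browser.

The same stages are scriptable from the shell:

```sh
dentoproxy simulate crown --seed 1 --out synthetic/
dentoproxy opcr synthetic/complete.ply --rpt 50 --out opcr.csv
dentoproxy microwear features.csv --out microwear.csv
dentoproxy veib transects.csv --out bands.csv
dentoproxy pca table.csv --group-col taxon --out pca.csv
```

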