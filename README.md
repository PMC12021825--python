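# axonmorph

Morphometry of myelinated axons in electron-microscopy cross-sections.

Serial scanning EM of white matter (e.g. the mouse corpus callosum at
8 nm working resolution) yields whole-section semantic segmentations in
which every pixel is background, axon lumen, or myelin sheath. This
package turns such label images into quantitative, per-axon biology:

1. **instancing** — connected-component labeling of lumens, splitting of
   touching sheaths by erosion-seeded geodesic assignment, and
   topological pairing of each sheath with the axon it encloses;
2. **morphometry** — per-instance axon and myelin areas, the area-based
   G-ratio, fitted-ellipse long/short diameters, myelin thickness by two
   independent estimators (distance transform over the medial axis, and
   inner/outer ellipse differencing), and patch-wise axon density;
3. **spatial maps** — z-score-normalized patch-mean maps of any metric
   across the section;
4. **stats** — Shapiro–Wilk normality screening and two-sided
   Mann–Whitney U (Wilcoxon rank-sum) comparisons between groups and
   anatomical subregions (genu / body / splenium);
5. **synthetic data** — a phantom generator that renders densely packed
   irregular elliptical axons with annular sheaths and exact ground
   truth, parameterized by published wild-type and Shank3B-mutant group
   statistics, so the whole pipeline is testable without terabyte-scale
   EM data.

## The central quantity

For a fiber with lumen area $A$ and sheath area $M$ the area-based
G-ratio is

$$g = \sqrt{\frac{A}{A + M}}$$

which coincides with the classical inner/outer radius ratio
$r_{\mathrm{inner}}/R_{\mathrm{outer}}$ for circular fibers but stays
well-defined for the irregular cross-sections that dominate real tissue.
Lower values mean relatively thicker myelin. Myelin thickness is
estimated primarily as twice the mean Euclidean distance transform over
the sheath's medial axis — a shape-agnostic wall-width measure — with an
ellipse-difference estimate reported alongside.

## Worked example

Generate one phantom per group from the published area presets
(wild-type axon area 0.401 ± 0.135 μm², myelin area 0.414 ± 0.128 μm²;
mutant 0.380 ± 0.104 and 0.315 ± 0.082), run the pipeline, and compare:

```python
from axonmorph import (preset_spec, generate_phantom, measure_mask,
                       compare_groups, summarize)

tables = {}
for group in ("wild_type", "mutant"):
    spec = preset_spec(group, "area", n_axons=300, seed=42)
    mask, labels, truth = generate_phantom(spec)
    metrics, instances, qc, density = measure_mask(mask)
    tables[group] = metrics
    s = summarize(metrics["g_ratio"])
    print(f"{group}: n={s['n']}  G-ratio {s['mean']:.3f} +/- {s['sd']:.3f} "
          f"(median {s['median']:.3f})")

for r in compare_groups(tables, ["g_ratio", "axon_area"]):
    print(f"{r.metric}: U={r.U:.0f}, z={r.z:.2f}, p={r.p:.3g} ({r.direction})")
```

prints

```
wild_type: n=300  G-ratio 0.691 +/- 0.095 (median 0.696)
mutant: n=300  G-ratio 0.733 +/- 0.071 (median 0.736)
g_ratio: U=32399, z=-5.93, p=2.94e-09 (a<b)
axon_area: U=48887, z=1.83, p=0.0672 (a>b)
```

The mutant phantom's higher G-ratio (0.733 vs 0.691; rank-sum
p ≈ 3·10⁻⁹) reflects its thinner myelin relative to axon caliber, while
the modest axon-area difference does not reach significance at n=300 —
exactly the qualitative pattern the group presets encode.

The same pipeline is available from the shell (`axonmorph generate`,
`instances`, `metrics`, `maps`, `stats`, `report`); every output
directory contains a `run_config.yaml` with the resolved parameters and
seed.

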