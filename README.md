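# vesselbelt

Spatial statistics for tumor vascularization patterns in histology.

Colorectal cancer primary tumors tend to concentrate their microvessels in a
sharply limited, belt-like zone (~1–1.5 mm) at the interface between tumor
tissue and the intestinal lumen; liver metastases show the corresponding band
at the invasion front.  `vesselbelt` detects and quantifies such *vascular
belt zones* from CD34/DAB-immunostained RGB images (or precomputed vessel
centroid tables) plus labeled ROI polygons, and summarizes angiogenic
heterogeneity with kernel-density hotspot metrics.  It is aimed at digital-
pathology and tumor-microenvironment researchers who want a testable,
reproducible implementation of the method, complete with a synthetic-data
generator so that every stage can be validated without any slides.

## The statistic

For the N vessels inside the tumor ROI, the shortest distances to a reference
ROI (intestinal lumen or adjacent tissue) are binned into D_obs(x).  The null
model is complete spatial randomness (CSR) conditioned on the observed count:
the same N points are redistributed uniformly over the tumor region n = 100
times (a 2D Poisson pattern with overall MVD held constant), giving control
histograms D_ctrl_i(x) on the same bins.  The excess profile is

    E(x) = D_obs(x) − (1/n) Σ_i D_ctrl_i(x),        with  ∫₀^∞ E(x) dx = 0

by construction.  Let x₀ be the first x-intersection of E (the first bin
whose sign differs from the initial direction).  Then

    A = ∫₀^x₀ E(x) dx

is the absolute vessel excess near the reference region — the height of one
bar in the waterfall plots.  Per-control excesses A_i over the same window
give a Monte-Carlo 95% interval; the significance call uses the
finite-simulation-corrected Monte-Carlo rank test on the A_i (see
`docs/methods.md` for why).  Because the null conditions on the observed
total, the package also reports a dilution-corrected excess
Â = N·A / (N − C̄ w) that is an unbiased estimate of a *planted* excess in
synthetic benchmarks.

Hotspot metrics follow the same logic: a Gaussian kernel density estimate of
the vessel centroids is thresholded at the (1 − α) quantile of CSR-simulated
density values, and connected super-threshold regions yield the overall MVD,
in-hotspot MVD and hotspot density (hotspots per mm²) of a sample.

## Worked example

```python
import vesselbelt as vb

layout = vb.SyntheticLayout()            # 10 mm wide; lumen 1 mm / tumor 5 mm / adjacent 2 mm
rois = layout.to_roi_set()

# plant a 1.2 mm, 4x-enriched vessel belt at the luminal side of the tumor band
pattern, planted = vb.generate_belt_pattern(
    layout, vb.BeltSpec(baseline_intensity=80, belt_width=1.2,
                        enrichment_factor=4, reference_side="lumen", seed=3))
print(round(planted))                    # 2880  vessels planted in the belt

profile = vb.excess_analysis(pattern, rois, "lumen", seed=4)
print(round(profile.x0, 2), round(profile.mass, 1), round(profile.excess_corrected, 1),
      profile.significant, profile.direction)
# 1.2 2115.9 2784.0 True positive
```

The recovered zone width (1.2 mm) matches the planted belt; the raw excess A
(2115.9) is the primary reported statistic, and the dilution-corrected estimate
(2784.0) recovers the planted 2880 up to Monte-Carlo noise.  The same flow is
available from the shell:

```sh
vesselbelt simulate --out sim/ --seed 3
vesselbelt sample --vessels sim/points.csv --roi sim/rois.geojson --seed 4
```

The `analysis/` scripts run the full study on a synthetic cohort
(30 lumen-belt "primaries", 10 adjacent-belt "metastases"); on the shipped
seed they report 30/30 and 10/10 side-specific belts detected, a
recovered/planted excess ratio of 0.99, and r = 0.72 between overall and
in-hotspot MVD, writing tables under `results/cohort/`.

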