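# sheath3d

3D reconstruction and morphometry of **human splenic capillary sheaths**
from serial brightfield sections double-stained with DAB (brown: smooth
muscle actin + CD34, the arterial tree and endothelium) and Fast Blue
(blue: CD271, the stromal sheath cells). The package is for
histologists and image analysts who want to rebuild a 24-section block of
red pulp into watertight vessel and sheath meshes and ask, for every
CD271+ sheath, whether it sits in a **post-arteriolar** position —
i.e. whether it is contacted by an annotated arteriolar surface.

The pipeline, stage by stage (each a library module):

| stage | what it does |
|---|---|
| `phantom` | synthetic serial-section specimens with voxel/graph ground truth |
| `register` | rigid stack alignment (cross-correlation + small-angle rotation search) |
| `separate` | RGB → CMYK; channel **C** = blue chromogen, **K** = brown |
| `interpolate` | dense-optical-flow inter-slice interpolation, 7 µm → 1 µm z sampling |
| `morph` | per-channel 3D grayscale closing/dilation + Gaussian blur |
| `mesh` | marching cubes, watertight healing, Taubin smoothing, component pruning |
| `annotate` | geodesic red painting of arterioles; green/blue sheath classification |
| `pipeline` / `cli` | end-to-end driver, YAML config, run manifest |
| `study` | multi-phantom parameter-recovery studies |

Key quantities, in the notation used throughout: the anisotropy ratio
t/p = 7 µm / 0.5 µm = 14; component-pruning thresholds f·√(x²+y²+z²) of
the ROI box (f = 0.05 → 71 µm blue, f = 0.02 → 28 µm brown); a sheath is
post-arteriolar iff min‖v − r‖ ≤ ε over its vertices v and red vertices r
(ε = 5 µm); the green fraction is 100·N_green/N_total.

Since no raw specimen scans are publicly available, everything is
exercised on virtual specimens whose sheath count, class and volume are
known exactly — the tests are parameter-recovery experiments.

## Worked example

Generate a virtual specimen, reconstruct it, and classify its sheaths:

```python
from sheath3d.phantom import PhantomSpec
from sheath3d.pipeline import PipelineConfig, run_pipeline

spec = PhantomSpec(width_px=256, height_px=256, n_sections=16,
                   n_sheaths=4, n_arterioles=2, frac_post_arteriolar=0.5,
                   sheath_length_range_um=(25, 45), misalignment_px=0.0,
                   noise_sd=0.0, dropout_rate=0.0,
                   include_fdc_blobs=False, rng_seed=1)
result = run_pipeline(PipelineConfig(
    phantom=spec, skip_registration=True, heal=False,
    iso_calibration="mass",
    cyan_operations=(("closing", (4, 4, 1)), ("blur", 1.0)),
))
print(result.summary)
```

prints (one line, wrapped):

```
{'roi': 'ROI', 'n_sheaths': 4, 'n_post_arteriolar': 2, 'n_undefined': 2,
 'green_fraction_pct': 50.0, 'max_volume_mm3': 1.0085162891358719e-05,
 'median_volume_mm3': 6.524646478170422e-06, 'n_boundary_cut': 2,
 'roi_volume_mm3': 0.0018350080000000002}
```

All four placed sheaths are recovered as separate components; the two
that were attached to arterioles in the truth are classified
post-arteriolar (the mesh is painted green there, blue elsewhere), and
two sheaths are cut by the block surface — in a 128 µm block, as in the
real ~150 µm series, many sheaths outrun the sampled depth. Component
volumes are a few × 10⁻⁶ mm³ for these cuffs; the largest sheaths in a
full 0.17 mm³ ROI reach the 10⁻⁴ mm³ range.

The same run from the shell, plus stage-by-stage commands
(`sheath3d phantom/register/separate/interpolate/morph/mesh/annotate/
summarise`):

```sh
sheath3d run --phantom-seed 1 --out results/demo
```

The `analysis/` scripts tell the study story end to end:
`01_virtual_specimen.py` (build + render the reference block),
`02_reconstruct_quantify.py` (full reconstruction vs truth),
`03_recovery_study.py` (pooled post-arteriolar-fraction recovery over
four noisy specimens). Outputs land in `results/`.

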