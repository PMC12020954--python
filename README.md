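# octbands

Quantification of outer retinal bands in geographic atrophy (GA) from OCT
layer-segmentation surfaces: en-face thickness maps, band-loss areas, ETDRS
topographic summaries, subretinal drusenoid deposit (SDD) volumetry, and
paired-device comparison with linear mixed-effects models.

## Who this is for

GA trials and natural-history studies quantify photoreceptor and RPE
integrity from manually corrected OCT segmentations: the ELM, the EZ band
boundaries and the RPE band boundaries, segmented per A-scan in 49 B-scans
per 20° × 20° volume. `octbands` turns such segmentation tables into the
standard reporting quantities and compares acquisitions of the same eyes
on two devices (e.g. conventional vs high-axial-resolution OCT) while
accounting for both eyes of some patients. Because patient volumes are not
shareable, the package ships a phantom generator that produces paired
two-device cohorts with analytic ground truth for validation.

## The measurements

With surfaces in µm (posterior increasing), per A-scan column:

- thickness: `ELM+MZ = z(EZ inner) − z(ELM)`,
  `EZ = z(RPE inner) − z(EZ inner)` (includes the interdigitation zone),
  `RPE = z(RPE outer) − z(RPE inner)`; missing (not zero) where a band is
  lost, so means describe surviving tissue;
- loss area: `(# columns with a cut boundary) × cell area`, with the cell
  `≈ 5.73 µm × 122 µm` on the default lattice; SDD-disrupted columns count
  as EZ loss;
- SDD volume: `Σ gap(EZ outer → RPE inner) × cell area` over columns where
  the gap exceeds 4 µm strictly, in nL (1 nL = 10⁶ µm³);
- ETDRS summaries: fovea-centered rings of radius 0.5 / 1.5 / 3.0 mm
  (nominal areas 0.79 / 6.28 / 21.21 mm²) with ±45° diagonal quadrants;
  relative loss = absolute loss / nominal ring area × 100;
- device contrasts: REML mixed models `outcome ~ device` with a random
  patient intercept and an eye-within-patient component, Wald-t inference,
  log transform with back-transformed reporting for skewed loss areas,
  Bonferroni correction.

See `docs/methods.md` for conventions, phantom design and limitations.

## Worked example

```python
from octbands import generate_cohort, quantify
from octbands.phantom import PhantomSpec

cohort = generate_cohort(PhantomSpec(seed=7, n_patients=1, prob_both_eyes=0.0))
eye = cohort.eyes[0]
for device, surfaces in eye.acquisitions.items():
    q = quantify(surfaces)
    print(device, round(q.mean_thickness_um("RPE"), 2),
          round(q.loss_area_mm2["RPE"], 3), round(q.sdd_volume_nl, 2))
```

prints

```
standard 20.98 1.185 37.3
high_res 13.71 1.185 63.31
```

one line per device: mean RPE band thickness (µm) over surviving columns —
thinner on the high-resolution device, which demarcates the RPE monolayer
from basal deposits more sharply; RPE loss area (mm², identical because
both devices see the same lesion; the generator's analytic truth is
1.167 mm², recovered to ~1.5%); and SDD volume (nL, larger on the
high-resolution device because shallow deposits register more completely).
The scripts in `examples/` extend this to ETDRS topography and the full
40-eye mixed-model device comparison; `examples/04_device_comparison.py`
recovers the injected device effects (ELM+MZ −1.5 µm, EZ +1.1 µm, RPE
−5.1 µm) with p < 0.001 after Bonferroni correction.

A thin CLI wraps the same functions:

```bash
octbands simulate out/ --seed 3 --n-patients 2
octbands quantify out/E000_standard.tsv
octbands run pipeline_out/ --seed 1
```

Surface tables are TSV (one row per A-scan per B-scan, empty cell =
missing surface) with a JSON geometry sidecar; see
`octbands.io.read_surface_table`.

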