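# slicequant

Quantitative toolkit for **long-term culture of live pancreatic tissue
slices**. Organotypic slices (~120 µm vibratome sections) preserve the
native architecture of islets, acini and ducts, but conventional transwell
culture starves them of oxygen within a day. Culture on a gas-permeable,
liquid-impermeable perfluorocarbon (PFC) membrane — an "oxygen sandwich"
feeding the tissue base directly — keeps slices viable and functional for
10+ days, long enough to watch β-cell regeneration happen in real time.

`slicequant` implements the quantitative machinery such a study needs:

* **`slicequant.oxygen`** — a 2D oxygen reaction–diffusion model of the two
  culture geometries. Transport is written in partial-pressure form,
  `α ∂p/∂t = ∇·(K∇p) − R(p)`, with diffusive permeability `K = D·α`
  (mol m⁻¹ s⁻¹ mmHg⁻¹) so `p` (mmHg) is continuous across phases, and
  Michaelis–Menten consumption `R(p) = r_max·p/(p + km)` in tissue
  (OCR `r_max = 0.03 mol m⁻³ s⁻¹`, `km = 0.44 mmHg`). Outputs: core pO₂
  traces, the anoxic volume fraction (tissue below 0.1 mmHg), anoxia onset
  times, and parametric OCR sweeps.
* **`slicequant.flux`** — evaporation-corrected metabolic rates from daily
  medium assays:
  `GCR = (G_blank − G_culture·Osm_blank/Osm_culture)/ΔT` and
  `LPR = (L_culture·Osm_blank/Osm_culture − L_blank)/ΔT`, per hour per µg
  DNA, plus the ATP-per-glucose efficiency index and daily-rate AUCs.
* **`slicequant.secretion`** — perifusion analysis: stimulation index
  (trace / baseline mean) and trapezoidal AUCs over the canonical windows
  (1–10, 10–32, 32–50, 50–60 min) of the 86-min G3/G16.7/G1/G3+KCl/G3
  protocol.
* **`slicequant.calcium`** — ΔF/F (% over baseline), response AUC above
  baseline, the acceptance rule (≥2 elicitations and peak ≥ 2× baseline
  fluctuation) and β/acinar classification from response profiles.
* **`slicequant.imaging`** — longitudinal red/green/yellow lineage-tracing
  quantification (yellow = pixelwise dsRED∧EGFP co-localization, the
  signature of new insulin expression), slice area, area-based viability,
  nuclei counting and marker-positive fractions.
* **`slicequant.synth`** — seeded generators for every input class with
  ground-truth sidecars, so each stage is tested as the inverse of its
  generator.

## Worked example

```python
from slicequant import oxygen as ox
from slicequant import flux
from slicequant.synth import synth_assays

# oxygen model at the average pancreatic OCR (0.03 mol/m^3/s), 21% O2
layout = ox.build_domain(ox.calibrated_transwell_config(),
                         resolution=ox.CALIBRATED_RESOLUTION)
result = ox.simulate(layout, ox.KineticsSpec(), duration_h=24.0,
                     dt_s=ox.CALIBRATED_DT_S)
print("transwell anoxia onset (h):", ox.anoxia_onset(result))

pfc = ox.build_domain(ox.calibrated_pfc_config(),
                      resolution=ox.GridResolution(nx=6, nz_tissue=13,
                                                   nz_medium_above=21))
pres = ox.simulate(pfc, ox.KineticsSpec(), duration_h=24.0,
                   dt_s=ox.CALIBRATED_DT_S)
print("pfc anoxia onset         :", ox.anoxia_onset(pres))
print("pfc minimum pO2 (mmHg)   :", round(float(pres.min_tissue_po2.min()), 1))

# metabolic fluxes from a synthetic assay table (10% evaporation, no noise)
table, truth = synth_assays(noise_sd=0.0, evaporation_rate=0.10, seed=0)
rates = flux.compute_fluxes(table)
print(rates.groupby("group")[["gcr", "lpr"]].mean().round(3))
print("2-NBDG uptake fold (TW/PFC):", round(flux.fold_change(0.53, 0.075), 2))
```

prints

```
transwell anoxia onset (h): 16.0
pfc anoxia onset         : None
pfc minimum pO2 (mmHg)   : 73.1
           gcr  lpr
group
pfc        1.0  1.0
transwell  2.0  2.5
2-NBDG uptake fold (TW/PFC): 7.07
```

The transwell slice, fed only through the medium's free surface, develops
core anoxia at 16 h and its core pO₂ then collapses; the PFC slice, fed
directly through its base, never drops below 73 mmHg in 24 h. The osmolarity
correction removes the 10% evaporation exactly, recovering the generated
glucose-consumption and lactate-production rates; the higher transwell rates
reflect the glycolytic shift of oxygen-starved tissue, mirrored by its
7-fold higher 2-NBDG (fluorescent glucose analogue) uptake per cell.

## Command line

```bash
slicequant oxygen simulate --config config.yaml --hours 24 --out run/
slicequant oxygen sweep    --config config.yaml --ocr 0.01:0.05:9 --out sweep/
slicequant flux compute    --in assays.csv --out rates.csv
slicequant secretion analyze --in trace.csv --out auc.csv
slicequant calcium analyze --in traces.csv --stimuli stimuli.csv --out cells.csv
slicequant imaging quantify --in imgs/ --channels channels.yaml --out report.csv
slicequant synth assays|traces|timelapse --seed 0 --out data/
```

Every run writes a `manifest.json` (package version, command, parameters,
seed); identical config + seed reproduces outputs byte-for-byte.

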