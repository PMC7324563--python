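# Methods

## Oxygen transport model

The model solves, over a 2D cross-section (lateral × depth) of the culture
vessel,

    α ∂p/∂t = ∇·(K ∇p) − R(p),

with `p` the oxygen partial pressure (mmHg), `α` the solubility of the local
phase (mol m⁻³ mmHg⁻¹) and `K = D_eff·α` the diffusive permeability
(mol m⁻¹ s⁻¹ mmHg⁻¹). The partial-pressure formulation makes `p` continuous
across phase interfaces, so no partition coefficients appear. Consumption in
tissue is Michaelis–Menten, `R(p) = r_max·p/(p + km)`; 2D node areas stand in
for volumes (uniform third dimension).

**Geometries.** *Transwell*: (bottom → top) impermeable dish bottom
(zero flux), lower medium column, zero-thickness flux-conserving membrane,
120 µm tissue slice, upper medium film, Dirichlet boundary at the gas
tension at the free surface. *PFC membrane ("oxygen sandwich")*: Dirichlet
gas boundary at the vessel floor (the gas-permeable membrane) and at the
medium free surface, tissue resting on the floor, medium above. Laterally
the slice is centred, optionally flanked by medium margins; outer lateral
edges are zero flux. The initial field is medium equilibrated at the gas
tension.

**Parameters.**

| parameter | default | units | rationale |
|---|---|---|---|
| `r_max` (OCR) | 0.03 | mol m⁻³ s⁻¹ | average for islet + acinar tissue; swept 0.01–0.05 |
| `km` | 0.44 | mmHg | standard islet-modelling value |
| anoxia threshold | 0.1 | mmHg | literature convention for pancreatic tissue |
| `K` medium / tissue | 3.5 / 2.4 ×10⁻¹² | mol m⁻¹ s⁻¹ mmHg⁻¹ | 37 °C aqueous values |
| `α` medium = tissue | 1.27×10⁻³ | mol m⁻³ mmHg⁻¹ | 37 °C aqueous value |
| gas pO₂ | 0.21·(760−47) ≈ 149.7 | mmHg | 21% O₂, humidified incubator (160 selectable) |
| slice | 120 µm × 10 mm | — | slice thickness and width |

All parameters are configurable per run (YAML/JSON config, see
`slicequant.io.load_oxygen_config`).

**Discretization.** Vertex-centred finite volumes on a structured tensor
grid; nodes sit on layer interfaces, so each grid interval lies in one
phase and interface conductances need no averaging (material changes mid-CV
are volume-weighted, e.g. at the tissue/medium lateral boundary the edge
conductance sums the half-cell contributions of both phases). The scheme is
second order in space; backward-Euler time stepping with the
Michaelis–Menten coefficient resolved by Picard iteration *within* each step
(the per-step system is then an M-matrix, giving unconditional stability,
positivity, and a discrete maximum principle). A per-step discrete oxygen
balance — boundary influx − consumption = storage change — is accumulated
exactly as the scheme defines it and reported with every run; it holds to
machine precision (≪ 10⁻⁴ relative).

The "core" pO₂ is the tissue node nearest the lateral centre at mid-depth.
Snapshots default to 10 min cadence; anoxia onset is the first snapshot at
which any tissue node has been below the threshold, where the minimum tissue
pO₂ is tracked as a running minimum over each snapshot interval (onset is
still reported at snapshot resolution, without sub-step interpolation). The
anoxic fraction is the tissue-volume-weighted fraction of nodes below
threshold at the snapshot instant.

**Anoxic shutoff.** A hard shutoff (zero consumption below the threshold)
is available via `KineticsSpec(shutoff_below_threshold=True)`, but it is
*off* by default, deliberately: treated self-consistently, a hard shutoff
floors the field just above the threshold wherever any supply remains —
cells that stop consuming stop depleting — so the "anoxic volume" statistic
degenerates to the set of completely starved nodes and, numerically, to
on/off chatter. The continuous Michaelis–Menten law lets pO₂ cross the
threshold smoothly and makes onset and anoxic volume well defined; at
0.1 mmHg consumption has anyway fallen to ~19% of `r_max`, so the two laws
differ only inside the (near-)anoxic region they are trying to delineate.

**Calibration of the transwell geometry.** With the stated OCR a 120 µm
slice demands ~3.6×10⁻⁶ mol m⁻² s⁻¹ while air-saturated aqueous medium
holds only ~0.19 mol m⁻³: the slice consumes the oxygen content of its own
medium column in minutes, and an anoxia onset of many hours therefore
constrains the *unprinted* geometry strongly. Two features are required:
(i) an upper unstirred film thin enough that the steady top supply sits just
below the Michaelis–Menten demand (within ~1%), and (ii) a deep lower
medium column under the insert acting as a diffusive oxygen reservoir whose
drain time `d²/D` is of order half a day and which buys the hours between
seeding and core collapse — reproducing the characteristic slow decline of
core pO₂ followed by a precipitous drop. The shipped
`calibrated_transwell_config()` freezes `d_below = 10 mm` and
`d_above = 0.0971484375 mm`, the latter fixed by bisection
(`calibrate_transwell_medium_depth`, log reproducible by rerunning it) so
that onset lands at 16 h at the calibration grid (6×83 nodes, Δt = 30 s,
10 min snapshots) — the onset the near-critical supply-to-demand balance
implies. The default *uncalibrated* transwell (1 mm medium above and below)
reaches anoxia in ~10–20 min; all depths remain user-configurable, and
whether the physical insert geometry or an equivalent effective transport
resistance (e.g. reduced medium permeability) realizes the balance cannot
be distinguished from the onset time alone. The PFC prediction is not
calibrated: with the tissue base held at the gas tension the worst-case
interior drop is `r_max·L²/(2K) ≈ 90 mmHg`, leaving the slice above
~60 mmHg regardless of the medium above, so anoxia-free 24 h culture is a
robust consequence of the geometry.

**Validation.** The steady solver is checked against the closed-form
zeroth-order slab `p(z) = p₀ + (r_max/2K)(z² − Lz)` (both clamped and
half-insulated variants, exact at the nodes for the quadratic profile) and
shows second-order Richardson convergence on a strongly nonlinear
Michaelis–Menten slab. Transient runs are checked for the discrete mass
balance, the maximum principle, monotone core decline from a saturated
start, monotonicity of the terminal anoxic fraction in OCR and in upper
medium depth, and the mode ordering (PFC ≤ transwell at every swept OCR).

## Metabolic fluxes

Evaporation between medium changes concentrates all solutes equally, and
osmolarity measures that concentration factor, so analytes are rescaled by
`Osm_blank/Osm_culture` before differencing against the matched blank:

    GCR = (G_blank − G_culture·Osm_blank/Osm_culture) / ΔT
    LPR = (L_culture·Osm_blank/Osm_culture − L_blank) / ΔT

then normalized per µg DNA. The formulas are unit-agnostic ratios; the
table declares one unit per analyte at ingest. Negative computed rates are
possible under measurement noise and are flagged (`qc_negative_rate`), not
clamped. The ATP-per-glucose efficiency index divides protein-normalized
ATP production by protein-normalized glucose consumption; series are
summarized by trapezoidal AUC over days.

## Perifusion and calcium traces

Stimulation indices divide a trace by its mean over the baseline window;
the default baseline is 1–10 min on the analysis clock (the low-glucose
segment), and AUCs are trapezoids of the raw SI (not baseline-subtracted)
over the canonical windows — the figure-axis quantity. The analysis-window
clock (1–60 min) and the stimulation-sequence clock (0–86 min) are
configurable independently; missing samples are handled by integrating over
available points only, never by imputation.

ΔF/F is `100·(F − F₀)/F₀` with `F₀` the baseline-window mean. "Baseline
fluctuation" is operationalized as the SD of ΔF/F over the baseline window
(half peak-to-peak available as an option); response acceptance requires
≥2 elicitations by the same stimulus *and* a peak ≥2× that fluctuation,
with inclusive (≥) semantics at the boundary. Elicitations are counted per
provided stimulus window, so repeated applications must appear as separate
windows. Classification: β ⇔ accepted for both 16.7 mM glucose and KCl;
acinar ⇔ accepted for carbachol (or CCK8) without KCl depolarization;
anything else (including KCl-only, α-like responders) stays unclassified.
ROI extraction is out of scope; traces enter as tables.

## Lineage imaging

Tissue is segmented from brightfield by Otsu threshold, morphological
closing, hole filling and largest-component selection; area is pixel count
× (pixel size)². Channel masks are thresholded within the tissue mask
(Otsu, or a fixed threshold with inclusive ≥ semantics; optional white
top-hat background subtraction). Yellow is the pixelwise intersection of
the red and green masks — a set operation, not a hue classifier — so
`yellow ≤ min(red, green)` by construction. Viability is area-based
(live/(live+dead)). Nuclei are counted as local maxima of the smoothed
DAPI channel with minimum-distance suppression (closer peaks merge) and
gain-invariant relative thresholds. Z-stacks are max-projected before 2D
analysis. Fractions are normalized to each day's own tissue area, so no
cross-day registration is performed.

## Synthetic data

Generators draw all randomness from one passed seed (bit-identical
regeneration) and attach a `SyntheticTruth` sidecar, making every analysis
stage testable as the inverse of its generator.

*Assays*: osmolarity inflated by `1 + evaporation_rate` (default 10%),
analytes inflated by the same factor and consistent with the chosen true
rates over 12 h intervals; Gaussian measurement noise on culture analytes
only. Default rates (GCR 2.0 vs 1.0, LPR 2.5 vs 1.0 µg h⁻¹ µgDNA⁻¹ for
transwell vs PFC) encode the glycolytic shift of oxygen-starved tissue at
plausible magnitudes. *Traces*: flat baselines with stimulus-locked
square/decaying responses; the calcium protocol applies each stimulus twice
(6 s windows at 1 Hz) so the repeated-elicitation rule is exercised; the
nominal SNR is amplitude / baseline SD of ΔF/F. *Timelapse*: a transduced
tissue disk (red everywhere), islets turning green at day 1, and — in
treated series — Poisson-distributed conversion events during a treatment
window (days 2–4) whose dsRED decays exponentially (default half-life
1.5 days), yielding transient yellow and cumulative green; truth counts a
pixel red while its dsRED is within one half-life of conversion, matching
the 0.5 fixed analysis threshold on unit-intensity channels. Default
frames are 256×256 at 10 µm/px so a 10-day series generates in seconds.

What the generators do *not* emulate: instrument drift and blank-to-blank
variability in analytes, biphasic secretion kinetics, calcium oscillations
and synchrony, photobleaching, uneven illumination, optical PSF, or slice
deformation across days. Passing recovery tests therefore demonstrates the
correctness of the estimators under their stated models, not robustness to
every artifact of real microscopy or perifusion data.

## Problem sizes in the shipped checks

The test suite and acceptance script run the oxygen model on small grids
(hundreds of nodes; the calibrated transwell uses 6×83 nodes at Δt = 30 s),
192–256 px synthetic images, and ~70-cell trace sets — sizes chosen so the
whole suite completes in a few minutes while every property remains
resolvable at them.
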