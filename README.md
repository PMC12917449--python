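# rhizoflux

**Rhizosphere water-depletion analysis for neutron radiograph time series
of drying rhizoboxes.**

When a rooted soil dries, its unsaturated hydraulic conductivity K(ψ)
collapses by orders of magnitude, and at a texture-dependent *critical
water potential* the soil can no longer deliver water to the root surface
at the transpiration rate. Uptake then shifts from the bulk soil into the
narrow rhizosphere around the roots, the root-surface potential drops
rapidly, and whole-plant transpiration declines — the earliest hydraulic
signal of drought stress, arising in the soil rather than in the plant.
`rhizoflux` is for soil–plant hydraulics researchers who want to study
this sequence quantitatively: it provides both a physics-based generator
of synthetic neutron radiograph experiments with known ground truth and
the full inverse chain used to analyze such image series.

## What it computes

**Soil hydraulics** (`rhizoflux.hydraulics`) — van Genuchten retention
θ(ψ) and Mualem conductivity K(ψ); the matric flux potential
Φ(ψ) = ∫ K dψ (Kirchhoff transform), which linearizes steady radial flow
to a root: Φ(r) = Φ(ψ_bulk) − q₀r₀ ln(r_b/r); and the critical bulk
potential solving Φ(ψ_crit) = q₀r₀ ln(r_b/r₀), the wettest state at which
a prescribed root-surface flux q₀ exhausts the supply.

**Drydown model** (`rhizoflux.drydown`) — a two-compartment (bulk /
rhizosphere) mass balance with Gardner radial coupling through Φ and an
uptake law U = min(demand, G_plant·(ψ_rhizo − ψ_leaf_min)) that produces
stomatal-like down-regulation once supply fails. Mass balance is
conserved to rounding by construction and asserted at 1e-6.

**Synthetic radiography** (`rhizoflux.simulate`) — seeded branching root
systems, per-pixel water-content maps (linear depletion annulus around
the root skeleton plus root-tissue chords), and Beer–Lambert detector
images with flat-field gain, dark current, additive scattering and
Poisson noise; written as 16-bit TIFF stacks with metadata and ground
truth.

**Inverse chain** (`rhizoflux.processing`, `rhizoflux.segmentation`,
`rhizoflux.dynamics`) — dark/flat/scatter correction, optical thickness
OT = −ln T, water content θ = (OT − OT_dry)/(μ_w d); denoising, adaptive
thresholding, skeletonization and rhizosphere/bulk mask construction
(with a manual-skeleton import path); and the time-series analytics:
compartment means, the depletion ratio dθ_rhizo/dθ_bulk against its
nighttime baseline, Savitzky–Golay-smoothed RWU rates, θ→ψ conversion,
radial depletion profiles, and transition detection.

**Pipeline & CLI** (`rhizoflux.pipeline`, `rhizoflux.cli`) — a YAML-driven
simulate → process → segment → analyze chain with provenance capture,
exposed as `rhizoflux simulate | process | segment | analyze | run` and
`rhizoflux hydraulics table`.

## Worked example

Critical potentials for the shipped Carsel–Parrish substrates, at root
radius r₀ = 0.015 cm, outer radius r_b = 0.5 cm and per-length demand
Q_L = 2·10⁻³ cm³ cm⁻¹ d⁻¹:

```python
import math
from rhizoflux import hydraulics as H

geom = H.RadialGeometry(r0=0.015, rb=0.5)
q0 = 2e-3 / (2 * math.pi * 0.015)
for soil in (H.SAND, H.LOAM):
    res = H.critical_water_potential(soil, geom, q0)
    print(f"{soil.name:>5}: psi_crit = {res.psi_crit:8.2f} kPa")
```

```
 sand: psi_crit =    -7.80 kPa
 loam: psi_crit =  -208.77 kPa
```

Sand hits its supply limit while still wet (−7.8 kPa); loam sustains the
same demand to potentials ~27× more negative — the headline texture
contrast, with both values inside the ranges where sandy (−5…−20 kPa) and
loamy (−100…−300 kPa) soils are reported to lose uptake.

A full synthetic experiment and its analysis, end to end (~20 s):

```yaml
# config.yaml
out_dir: run_sand
soil: sand
geometry_seed: 0
noise_seed: 0
```

```bash
rhizoflux run --config config.yaml
# pipeline complete: transition at -3.82 kPa; outputs in run_sand
```

`run_sand/transition.json` then holds the detected shift to
rhizosphere-dominated uptake:

```json
{
  "psi_transition_kPa": -3.8169641288486575,
  "tau": 1.5,
  "k_consecutive": 3,
  "baseline": {"slope": 2.542249279616614, "n_points": 201, ...},
  "mean_rwu_cm3_h": 0.2052371769490612,
  "spearman_ratio_rwu": -0.2749872848049566
}
```

Reading: the nighttime baseline slope (2.54) is the passive
retention-difference reference; during the day the depletion ratio first
exceeds 1.5× that baseline persistently at a bulk potential of −3.8 kPa,
i.e. the plant starts mining its rhizosphere while the sand is still
quite wet. The negative Spearman coefficient (−0.27) is the
depletion–uptake coupling: windows with stronger rhizosphere depletion
are windows with lower transpiration. Alongside sit `compartments.csv`,
`ratio.csv`, `rwu.csv`, `profile.csv` (radial depletion profile),
`total_water.csv` and `provenance.json`.

See `docs/methods.md` for the model assumptions, parameter rationale and
known limitations.

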