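# Methods

`rhizoflux` couples a physics-based forward simulator of drying rhizoboxes
imaged by neutron radiography with the inverse chain that turns raw
detector counts into compartment water dynamics, root water uptake (RWU)
and a texture-dependent estimate of the soil water potential at which
uptake shifts from the bulk soil into the rhizosphere. This note records
the models, the parameter choices that matter, and the design decisions
made where the design was genuinely open.

## 1. Soil hydraulics

Water retention follows van Genuchten,

θ(ψ) = θr + (θs − θr) · Se,  Se = (1 + (α|h|)^n)^(−m),  m = 1 − 1/n,

and unsaturated conductivity follows Mualem,

K(ψ) = Ks · Se^l · [1 − (1 − Se^(1/m))^m]².

The public API uses kPa for ψ (negative = drier); internally pressure head
is in cm of water with 1 kPa = 10.197 cm. The shipped substrate fixtures
are the Carsel–Parrish (1988) sets:

| substrate | θr | θs | α (cm⁻¹) | n | l | Ks (cm d⁻¹) |
|---|---|---|---|---|---|---|
| sand | 0.045 | 0.43 | 0.145 | 2.68 | 0.5 | 712.8 |
| loam | 0.078 | 0.43 | 0.036 | 1.56 | 0.5 | 24.96 |

These are standard stand-ins, not fits to any particular packed substrate;
they place the critical potentials in the ranges reported for sandy and
loamy soils (below).

The matric flux potential (Kirchhoff transform) is
Φ(ψ) = ∫_{ψdry}^{ψ} K dψ′ (head units), with ψdry = −10⁶ kPa and
Φ(ψdry) ≡ 0; K is numerically negligible below that limit for both
fixtures. Because K spans more than ten orders of magnitude, Φ is
tabulated once per parameter set by cumulative trapezoid quadrature on a
20 000-node log-spaced head grid and interpolated (with its inverse) by
shape-preserving PCHIP in log–log space. Against a 10⁵-node reference
quadrature the table is accurate to better than 1 part in 10⁴ over
ψ ∈ [−10⁴, −0.1] kPa.

**Steady radial supply and the critical potential.** For steady flow
toward a root of radius r0 at surface flux q0 inside an outer radius rb,

Φ(r) = Φ(ψbulk) − q0 · r0 · ln(rb / r),

which linearizes the nonlinear radial problem exactly. Supply fails when
Φ is exhausted before the root surface; the critical bulk potential solves

Φ(ψcrit) = q0 · r0 · ln(rb / r0)

by bracketing bisection on [ψdry, 0] to 10⁻⁴ relative (bisection rather
than Newton: the function is monotone and the bracket is guaranteed).
With r0 = 0.015 cm, rb = 0.5 cm and a per-length demand
Q_L = 2·10⁻³ cm³ cm⁻¹ d⁻¹ this gives ψcrit ≈ −7.8 kPa for the sand
fixture and ≈ −209 kPa for the loam fixture — sand loses its supply while
still wet, loam two orders of magnitude drier, the central texture
contrast.

**Numerical limits.** The analytic retention inverse is exact, but
float64 caps the achievable round-trip accuracy at the range ends: for
sand at −10⁵ kPa, θ − θr ≈ 8·10⁻¹⁰, so representing θ as a double already
forfeits ~8 digits of Se. Round-trip accuracy is therefore 10⁻¹⁰ relative
over ψ ∈ [−10³, −10⁻²] kPa and ~10⁻⁸ at the extremes; callers needing the
dry tail should carry Se, not θ.

## 2. Two-compartment drydown model

The rhizobox is reduced to a bulk-soil reservoir (volume V_b) and a
rhizosphere reservoir (V_r) exchanging water radially and losing water to
transpiration:

- V_b dθ_b/dt = −J
- V_r dθ_r/dt = J − U
- J = [2π L / ln(rb/r0)] · (Φ_b(ψ_b) − Φ_b(ψ_r))
- U = clamp(min(E_pot(t), G_plant · (ψ_r − ψ_leaf_min)), 0, ∞)

The Kirchhoff coupling term reproduces the steady-state Gardner radial
resistance exactly. The transform of the **bulk** soil is evaluated at
both endpoint potentials: the radial resistance lives in the soil outside
the thin rhizosphere annulus, and this choice puts the zero-flux
equilibrium at equal water potential when the two compartments have
different retention curves (an endpoint-Φ difference with two different
transforms would equilibrate at unequal potentials, which is unphysical).
For identical substrates the two formulations coincide.

The uptake law U = min(demand, plant-conductance-limited supply) is the
minimal closure producing stomatal-like down-regulation: as the
rhizosphere potential falls toward the permitted leaf minimum, realizable
uptake declines linearly. It is a modeling choice of this package, not a
mechanistic stomatal model. E_pot follows the photoperiod square wave;
nocturnal transpiration is 5% of E_max by default (small but not absent),
configurable to zero for the idealized equilibrium baseline.

**Enhanced rhizosphere retention.** By default the rhizosphere substrate
is a retention-enhanced variant of the bulk soil: α scaled by 0.5 and the
shape exponent flattened to n = 1.35, with θ limits, l and Ks unchanged,
and the initial rhizosphere water content set to the equal-potential
equilibrium value. This emulates the mucilage/EPS-modified soil sheath
that retains more water than the bulk at a given potential and keeps
releasing water as it dries. It is load-bearing: with identical retention
curves the rhizosphere's releasable water (~0.5 cm³) vanishes within
minutes of supply limitation, no sustained rhizosphere-depletion phase
exists, and the diagnostic ratio (Section 4) collapses to noise instead
of rising while uptake declines. The enhancement can be disabled by
passing `soil_rhizo=soil_bulk`.

**Default scenario (study conditions).** A 10×12×1 cm class rhizobox
(volumes are re-derived from the rendered geometry, below), initial water
content 18 vol% (sand) / 20 vol% (loam), photoperiod 14 h on / 10 h off,
E_max = 6 cm³ d⁻¹, G_plant = 0.004 cm³ d⁻¹ kPa⁻¹, ψ_leaf_min = −1500 kPa,
duration 120 h, output every 15 min. The transpiration rate is realistic
for a ~2-week-old maize seedling at 300 µmol m⁻² s⁻¹ and drives a
~115 cm³ soil volume across its supply limit within a multi-day imaging
session. With ~100 cm of visible root this puts the model sand transition
near −4 kPa; the loam transition lands near −30 to −50 kPa, wetter than
the −100…−300 kPa range expected for loam under low per-length demand,
because a single shared demand and root length cannot reproduce both
texture ranges at once — the solver-based critical potentials above are
the quantitative anchor, the scenario is the dynamic emulation.

**Integration.** The ODE is stiff after the transition (dψ/dθ grows
without bound at the dry end), so integration uses LSODA (rtol 10⁻⁸,
atol 10⁻¹¹), segmented at the light switches where the forcing is
discontinuous. Mass balance V_b θ_b + V_r θ_r + ∫U dt is a linear
invariant of the augmented state — Runge–Kutta/multistep methods preserve
it to rounding — and is asserted post hoc at 10⁻⁶ relative, together with
physical bounds on both water contents (violations raise, never clamp).

## 3. Forward imaging model and its inverse

Expected detector counts for a water-content map θ are

E = dark + flat_field · I0 · [exp(−(μ_al d_al + μ_soil ρ d + μ_w θ d)) + s],

with path thickness d = 1 cm, Poisson-distributed observed counts, and
s an additive scattered fraction (default 0.05). Attenuation defaults
(μ_w = 3.5 cm⁻¹, μ_soil = 0.02 cm² g⁻¹, μ_al = 0.1 cm⁻¹, I0 = 10⁴ counts)
are order-of-magnitude physical values; beamline calibration is out of
scope. The open-beam reference is rendered **without** the scatter term:
scattering here models neutrons scattered by the sample, absent in the
open beam. That convention makes the correction chain

T = (counts − dark)/(flat − dark) − s,  OT = −ln T,
θ = (OT − OT_dry)/(μ_w d)

an exact inverse: noiseless frames invert to machine precision, and any
strictly positive flat-field gain map is removed identically. The real
correction for sample scattering (black-body grids) is more involved; the
flat additive fraction is the simplification that keeps the inverse
well-posed, and the interface accepts a per-pixel scatter map for future
extension. Sub-floor transmissions are masked invalid rather than
clamped; negative water contents are floored at zero with the count
reported as a noise diagnostic.

At I0 = 10⁴ the per-pixel water-content noise is ≈ 0.005–0.01 cm³ cm⁻³;
over 512×512 frames the per-pixel RMSE stays below 0.02 and compartment
means are good to better than 0.002, which is what makes the 15-min
differencing of compartment means viable.

**Synthetic root systems and painting.** A seeded random walk grows one
vertical primary axis (radius 0.05 cm) and ~20 downward-biased laterals
(radius 0.025 cm, total length ≈ 100 cm) inside the box. The radii sit at
the thick end of the maize range so that roots span 2–5 pixels at the
0.2 mm desk-scale pixel — the same pixels-per-root ratio as a ~70 µm
instrument resolving <0.3 mm laterals; sub-pixel roots cannot survive any
median-filter denoising step and would make segmentation meaningless.
Soil water is painted as a linear blend from θ_rhizo on the rasterized
skeleton to θ_bulk at the annulus edge (rhizo_width = 0.1 cm, matching
the ~1 mm depletion halo); pixels inside a root mix the chord of the root
cylinder, 2√(r0²−d²)/d_path, of tissue water (θ_root = 0.9) into the beam
path. The tissue term is constant in time, so it adds root/soil contrast
for segmentation without perturbing any temporal difference.

**Exact bookkeeping.** The compartment volumes passed to the drydown
model are derived from the same weight maps used to paint:
V_rhizo = d·Σ(1−f)(1−w)·px², V_bulk = d·Σ(1−f)w·px², V_root = d·Σf·px².
Total rendered water then equals V_bθ_b + V_rθ_r + V_rootθ_root
identically, so sealed-box conservation between rendered frames and the
model's cumulative uptake is exact by construction, not approximate.

## 4. Measurement chain

**Segmentation.** Segmentation runs once per sample on the time-averaged
wet-phase map (highest contrast; first 16 light-on frames by default) and
the masks are held fixed across the series, avoiding mask jitter in the
time series. The chain is: 3×3 median + nonlocal means (patch 5, search
11, strength tied to the estimated noise σ); local adaptive threshold
(Gaussian-weighted mean over a 51 px window, offset 3 robust σ of the
residual — invariant to affine intensity rescaling); closing (radius 2);
connected components < 30 px dropped. No morphological opening by
default: roots 1–2 px wide do not survive a disk opening, and the
component-size filter does the speckle rejection. These parameters are
package defaults tuned on the synthetic fixtures and are recorded in the
run provenance. For low-contrast substrates (loam), a manually delineated
skeleton is imported from a polyline CSV instead; in the synthetic
acceptance runs the generator's own polylines stand in for the manual
tracing.

**Compartments.** Because the radiograph projects through ~1 cm of soil,
a skeleton pixel integrates the root plus the soil in front of and behind
it. The *rhizosphere compartment is the skeleton pixel set itself* — not
the geometric annulus of the generator — and the bulk compartment is the
soil region minus a disk dilation of the skeleton (default radius 0.1 cm
in pixels). This mirrors how projection imaging is actually quantified
and is deliberately different from the annulus the forward model paints.

**Ratio, baseline, transition.** The diagnostic is the depletion ratio
dθ_rhizo/dθ_bulk, computed per non-overlapping 30-min window of
consecutive light-on frames as the quotient of least-squares slopes of
compartment mean θ against time. Windows whose bulk decrement is below
ε = 10⁻⁴ are flagged undefined instead of dividing by noise (windowed
slopes rather than raw frame differences, for the same reason). The
nighttime baseline is the OLS slope of θ_rhizo on θ_bulk over light-off
frames: with uptake near zero the compartments equilibrate and the slope
reflects only their relative retention, so it is the no-plant reference;
with nocturnal transpiration enabled the measured baseline is biased
high, making any detected exceedance conservative. A transition is
declared at the bulk potential (from the retention curve) of the first
window of the earliest run of ≥ 3 consecutive defined windows with ratio
> 1.5 × baseline slope. τ = 1.5 and k = 3 are package defaults — the
underlying shift is gradual, and the estimate is indicative rather than a
sharp change point.

**RWU.** Total water is the sum of θ over valid pixels times pixel volume;
it is Savitzky–Golay smoothed (window 9, order 2 — the filter reproduces
polynomial trends up to its order exactly, so a linear drawdown yields
the exact rate) and differenced at 15-min spacing. The transpiration-
period average is the mean over light-on samples.

**Ratio–uptake association.** The rank correlation between the depletion
ratio and concurrent RWU is evaluated over the *active transpiration
period*: ratio windows at least 60 min after lights-on (the first hour is
a transient in which the overnight-refilled rhizosphere re-drains while
gradients re-establish) and RWU at least one third of the run maximum
(below that the plant has effectively shut down and both signals are a
slow equilibration tail carrying no information about the coupling).
Under the default scenarios this association is robustly negative —
rhizosphere-dominated depletion accompanies declining uptake — for both
substrates.

## 5. What the synthetic data does and does not emulate

Emulated: Beer–Lambert attenuation with water/dry-soil/aluminum
components, flat-field gain structure, dark current, additive sample
scattering, Poisson counting noise; a branching root system in a thin
box; bulk-vs-rhizosphere dynamics with a texture-dependent supply limit;
day/night transpiration forcing; nighttime equilibration.

Not emulated: detector point-spread and beam hardening; the spatial
structure of real scattering; root growth during the run (the "water
gain" signature of growing roots); root-tissue water dynamics (tissue
water is constant); 3D root architecture beyond a 2D projection;
plant-to-plant variability in demand and root hydraulics beyond the
geometry seed. Passing tests therefore demonstrate the correctness and
noise robustness of the inverse chain and analytics under the stated
imaging physics — not performance on beamline data with registration
drift, growth artifacts or structured scattering.

## 6. Problem sizes used in the shipped checks

The synthetic grid is 512×512 at 0.02 cm pixels (a desk-scale stand-in
for a 2048×2048 array at ~70 µm: same physics, 16× fewer pixels), runs
are 120 h at 15-min cadence (481 frames), and the seeded acceptance
sweeps use 10 sand and 3 matched loam chains. These sizes keep a full
verification run in minutes on one core while leaving every statistic
(compartment noise, window counts, seed diversity) in the regime the
analysis is designed for.
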