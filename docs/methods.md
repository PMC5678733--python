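# Methods

## The model

`astromap` simulates the development of orientation preference maps (OPMs) in
primary visual cortex with a rate-based, sheet-structured model of the
LISSOM/GCAL family, extended with an astrocyte layer that gates the
plasticity of lateral excitatory connections.

Four square sheets are simulated, all at the same node density:

* **retina** — the stimulus canvas; training inputs are elongated 2-D
  Gaussians with uniformly random centres and orientations, probe inputs are
  full-field sine gratings.
* **ON/OFF LGN** — each channel filters the retina with a zero-sum
  difference-of-Gaussians kernel (centre width `sigma_c`, surround
  `sigma_s`), followed by divisive contrast gain control from a suppressive
  pool of neighbouring LGN units, settled over a short recursion
  (`settle_steps`, default 2) per presentation and half-wave rectified.
* **V1** — each unit receives an afferent kernel over both LGN channels
  (radius `rad_A`), a lateral excitatory kernel E and a lateral inhibitory
  kernel I (both supported on radius `rad_I`).  Per presentation the sheet
  settles from rest:
  `y(t) = f(p·A.L + q·E.y(t-1) - r·I.y(t-1))`, with `f` a rectifier with
  per-unit adaptive threshold `rho` and an upper saturation at 1.  The
  pre-rectification sum is the synaptic drive `gs`.
* **astrocytes** — one node per V1 node; each pools `gs` over a disc of
  radius `R_astro` (the GFAP-marked anatomical radius times 2, because GFAP
  labels only ~15 % of the astrocyte volume) and is normalised into [0, 1].

After settling, three plasticity rules run once per presentation:

* afferent and inhibitory kernels: divisively normalised Hebbian learning
  (each kernel sums to 1 after every step);
* lateral excitatory kernels: a BCM rule whose sliding threshold is set by
  the astrocyte, `dE = eta_E · y (y - theta) y_pre` with `theta = 1 - S`.
  Depression below zero prunes the synapse;
* homeostasis: each unit's smoothed activity trace pulls its rectifier
  threshold toward a target mean activity `mu`.

The mechanism of interest: where astrocytic activation is high (within
`R_astro` of strong synaptic activity), `theta` is low and coactive lateral
synapses potentiate; further away `theta ≈ 1` and coactivity depresses.  The
astrocyte radius thereby controls how far lateral excitation reaches, which
in turn controls the spatial period (hypercolumn width Λ) of the map that
self-organises: large radii give smooth, periodic OPMs with ~π pinwheels
per hypercolumn area Λ², and very small radii push the map toward a
salt-and-pepper organisation that is pseudo-random yet retains local
orientation similarity above chance.

Two model variants change what the astrocyte sees: `full` feeds it the
complete three-term drive; `no_gaba` omits the inhibitory term (no
GABA-mediated gliotransmission).  Optionally, fixed Gaussian-random gap
junction weights couple each astrocyte to its 8 nearest neighbours.

## Parameters

Core constants (strengths `p=1.5, q=2.1, r=1.4`, learning rates
`eta_A=0.1, eta_E=0.3, eta_I=0.3`, radii `rad_A=0.27, rad_I=0.22` sheet
units) follow the standard orientation-map parameterisation of this model
family.  The cortical sheet of extent 1.0 sheet unit represents a 3×3 mm
patch of tissue, so 1 sheet unit = 3 mm; all radii in mm divide by 3.

Constants this family leaves open were fixed once, by explicit calibration,
and are all exposed in `ModelConfig`:

* `gamma_o = 5.0` — LGN afferent gain, set by calibration so the settled
  LGN response to a full-contrast training stimulus peaks near 1 and the
  afferent drive to the best-matching V1 units is of order the rectifier
  saturation, where the BCM threshold (on [0, 1]) can discriminate them.
  `gamma_s = 0.6` for the divisive pool.
* homeostasis `beta = 0.99`, `lam = 0.01`, `mu = 0.024`, initial threshold
  `rho_init = 0.25`, per-step threshold change clipped at
  `max_step = 0.002` (anti-windup): the target mean activity keeps a few
  percent of units active per presentation; the positive initial threshold
  and the clipped step avoid an all-sheet transient at the start of
  training and keep brief saturated episodes from running the threshold
  past the reach of the afferent drive.
* training stimuli `sigma_major = 0.3`, `sigma_minor = 0.1` sheet units
  (3:1 aspect), centres uniform over the LGN-visible extent plus a 0.25
  sheet-unit margin.
* initial kernels: Gaussian of each projection's radius plus uniform noise;
  the afferent noise (0.8) is what seeds orientation-selectivity symmetry
  breaking; the inhibitory kernel starts effectively flat over its disc and
  the excitatory kernel starts at a third of its support radius, giving a
  centre-excitation / surround-inhibition interaction from the first
  iteration.
* `e_normalize = True`: the lateral excitatory kernel is divisively
  renormalised after each BCM step, so the BCM rule (with pruning at zero
  and a per-entry cap `e_max_scale / n_kernel`) shapes the *lag profile* of
  lateral excitation while its total strength stays bounded.  Without this
  the row mass is bounded only by the cap (total up to 4), the recurrent
  loop gain reaches `q·4 ≈ 8.4`, and settling ignites the whole sheet.
* astrocyte normalisation `norm_mode = "presentation"`: each presentation's
  pooled drive is scaled by its own peak, so every stimulus defines one
  maximally activated astrocytic domain whose *width* tracks `R_astro`.  A
  slow running-maximum normaliser (`norm_mode="running"`, time constant
  `norm_tau`) is available; under it, presentations weaker than the recent
  maximum produce no potentiating domain at all.

## Map measurement

Maps are probed with full-field sine gratings at the spatial frequency that
maximises the LGN DoG transfer function (closed form in
`lgn.dog_transfer_peak`), 8 orientations × 4 phases, plasticity frozen;
per-node response is the maximum over phases of the settled activity (`y`
for the neuronal map, `S` for the astrocyte map).  Preference and
selectivity come from the orientation vector sum in the doubled-angle
domain.  Probing never mutates weights, thresholds or normaliser state — a
probed training run finishes with bitwise the same weights as an unprobed
one (tested).

The probe contrast matters and its default (0.2) was calibrated once by
*probe-retest reliability*: the stability index between maps measured from
the same frozen model under different probe parameterisations (4 vs 8
phases, 8 vs 12 orientations).  At full contrast the recurrent sheet
settles into a multistable blob lattice whose geometry depends on grating
phase, and the retest SI is ≈ 0 — the measured "map" is an artefact of the
probe, not a property of the model.  At amplitude ≤ 0.3 the sheet stays in
its graded regime and retest SI exceeds 0.85 (≈ 0.93 at 0.2).  Probing a
fully sub-threshold model (e.g. before training) automatically escalates
the contrast by doubling, up to 1.0, before raising a dead-map error.

## Analysis

* **Difference maps** `I' = r(0°)-r(90°)` and `r(45°)-r(135°)`.
* **Fermi high-pass**: `I = I' - J` with `J` the complementary low-pass
  smoothed component, so the composite attenuation of a pure frequency `k`
  is exactly the Fermi function `S(k) = 1/(1+exp((k_hp-|k|)/beta_hp))`
  (equal to ½ at the cutoff).  On full rectangular maps the ROI
  normalisation field W is identically 1.  Default `k_hp` is half the raw
  spectral argmax, `beta_hp = k_hp/8`; the analysis is re-run with a doubled
  cutoff and flagged when the fitted peak moves by more than two bins.
* **Column spacing**: radially averaged power spectrum of the filtered
  difference maps (zero-padded to a power of two; frequencies reported in
  cycles per map extent), fitted with a Gaussian peak plus quadratic
  background; the peak position ζ gives Λ = extent_mm / ζ.  The fit is
  initialised from the raw argmax and falls back to it (flagged) on
  non-convergence.
* **Pinwheels**: zero contours of the real and imaginary parts of
  `z = selectivity · exp(2i·preference)` are intersected; each occupied
  grid plaquette contributes one centre whose topological charge (±1) is
  the winding of the doubled angle around that plaquette.  Plaquette
  circuits rather than interpolated circles keep close
  pinwheel/anti-pinwheel dipoles distinct, and the detector agrees exactly
  with a brute-force plaquette-winding census on synthetic maps (tested).
  Pinwheel density is reported per hypercolumn area: `count/(extent²/Λ²)`.
* **Stability index**: `SI = 1 - (4/(n·pi)) Σ|(F-O) mod (pi/2)|`; 1 for
  identical maps, ~0 for independent ones.  As written the folding is a
  plain modulus, which makes the index slightly asymmetric in its
  arguments; it is implemented as printed.
* **Local similarity**: per node, the mean folded orientation distance
  `min(d, pi-d)` (reported in degrees, max 90°) to all nodes within a disc;
  0° for a constant map, 45° expected for an independent random map.

## Synthetic fixtures

`astromap.synth` generates maps with known ground truth: a canonical single
pinwheel of either charge; a sine-grid map with an exact, closed-form
pinwheel census (zeros placed off-lattice so no winding is degenerate);
band-pass filtered complex Gaussian noise with a planted dominant
wavelength — a standard statistical stand-in for a real OPM — and idealised
cosine tuning responses.  These validate the analysis chain independently
of the simulator.  What they do not emulate: measurement noise, anisotropic
or spatially varying column spacing, and selectivity structure tied to
pinwheel distance beyond |z|; conclusions about the analysis hold for clean
quasi-periodic maps, not for raw imaging data.

## Problem sizes

The package defaults to a 48×48 cortical sheet and 10 000 training
iterations for study-scale runs (the CLI defaults).  The test suite and the
bundled examples run a reduced protocol — 24×24 cortex, 2 000–2 500
iterations, 3 seeds per astrocyte radius — sized so a full radius sweep
completes in minutes on one core.

What the reduced protocol shows, and what it does not: the model trains
stably and deterministically, homeostasis holds mean activity near its
target, the measured orientation maps are reproducible (probe-retest SI
> 0.9) and converge over development (late-development maps are closer to
the final map than early ones).  However, at this scale the afferent
receptive fields do not break symmetry into strong orientation tuning:
selectivity stays low, the maps are smooth orientation-bias fields with few
or no pinwheels, and the fitted dominant wavelength sits near the map
scale.  Consequently the radius-dependent hypercolumn-width and
pinwheel-density relationships are *not* resolved by the reduced protocol;
the analysis chain that would measure them is instead validated end to end
on synthetic maps with planted wavelengths and exact pinwheel censuses.

## Known limitations

* **Orientation-selectivity development is the binding constraint at desk
  scale.**  The per-stimulus afferent-drive differences between units with
  random receptive fields are only a few percent; turning that weak signal
  into strong tuning requires the recurrent competition to amplify it
  coherently over many presentations.  In the regimes reachable at 24–32
  nodes per axis within a few thousand presentations, either learning is
  fast enough that each receptive field is overwritten by its recent
  stimuli (no coherent averaging) or slow enough that tuning has not yet
  emerged; no tested configuration crossed into the locked, strongly tuned
  regime.  The headline radius–wavelength relationship therefore remains
  unresolved by the bundled reduced protocol.
* The astrocyte gate is per-postsynaptic-unit (as in the learning rule),
  not per-synapse; lag-resolved pruning of lateral excitation is therefore
  indirect, mediated by the width of the astrocytic activation domain.
  The measurable footprint of the radius at desk scale is a modest shift of
  lateral-excitatory mass between short and long lags, not a hard support
  cutoff.
* Settling uses a fixed step count, not a convergence criterion; the
  rectifier carries an upper saturation (`y_max`) that bounds the
  recurrent loop but also caps the contrast enhancement the settling
  process can deliver.
* The homeostatic threshold is controlled by a pure integrator; at small
  sheet sizes, where many units share drive statistics, slow
  activity/threshold relaxation cycles persist and the per-presentation
  activity level fluctuates around its target rather than pinning to it.
* No spiking dynamics, no explicit interneurons, no astrocyte calcium or
  gliotransmitter kinetics (abstracted into the BCM threshold), no
  naturalistic-image training.
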