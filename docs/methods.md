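# Methods

## The model

The simulated cell is a parallelepiped of edge lengths (Lx, Ly, Lz)
(defaults 10 µm each) standing on the coverslip plane z = 0, which is also
the default focal plane. Molecules belong to classes with a compartment
(cytoplasm, membrane or static), a diffusion coefficient D, an abundance
(explicit count, cytoplasmic concentration in nM, or membrane density per
µm² applied to all six faces), one to eight fluorescent tags of a given
colour (or zero tags for dark species), and a list of binding rules. All
internal computation is in µm, seconds and photons; double-precision
positions avoid any lattice artifacts.

Each camera frame is built from `substeps_per_frame` model substeps
(default 10 at 33 fps, so Δt = 3.03 ms). A substep executes, in order:
movement of all molecules, binding trials, dissociation trials, and — if
the illumination gate is open — emission/rendering followed by
photobleaching (a tag emits during the substep in which it bleaches).
One global seed is split into independent streams for placement, motion,
kinetics and imaging, so e.g. camera noise can be switched without
perturbing trajectories; identical configurations are bitwise
reproducible.

### Motion

Cytoplasmic walkers take independent N(0, 2DΔt) steps per axis (MSD 6DΔt
in 3D) and are folded back into the volume by specular reflection, which is
exact for any step length. Membrane walkers take 2D steps in the local
face coordinates; a step crossing a face edge continues on the adjoining
face with the excess path length preserved (corners resolve the larger
overshoot first). Two optional membrane features modulate the walk:

* **Barrier fences** — a square grid of pitch 1 µm (configurable); every
  grid-line crossing of the step segment is an independent Bernoulli trial
  with success probability = permeability, a refused crossing reflects the
  remainder of the step off the line. Multi-line steps are resolved line
  by line.
* **Lipid rafts** — square patches (default 1 × 1 µm² with 1 µm gaps, 25%
  coverage) inside which D is multiplied by R_raft. The factor is decided
  by the position at the start of the substep. With step-size scaling and
  no drift correction the stationary density is ∝ 1/D — molecules crowd
  into the rafts, which is the behaviour being modelled.

Bound pairs receive one shared displacement at the pair mobility
D_pair = D_a/(1 + D_a/D_b) (= D/2 for a homodimer, 0 if either partner is
immobile); a cytoplasm–membrane pair uses the membrane partner's D and
moves on the membrane. On binding, a pair co-locates at the cytoplasmic
partner's membrane target, at the midpoint for symmetric same-compartment
pairs, and at the *less mobile* partner otherwise — the midpoint rule
would make immobile anchors random-walk over repeated bind/release cycles.

### Binding and dissociation

For a candidate pair at separation x with combined mobility
D = D_A + D_B, the average interaction time is

    AIT(x) = ∫0^Δt (4πDt)^(−d/2) · exp(−x²/4Dt) · M_d dt,

with the interaction measure M_d = ID, π(ID/2)², 4/3·π(ID/2)³ for d = 1,
2, 3 and ID the interaction distance (default 5 nm). The probability of
binding in the step is min(AIT·R_bind, 1); dissociation occurs with
min(R_diss·Δt, 1). The integral is evaluated on a 200-node logarithmic
time grid from Δt·10⁻⁶ to Δt (trapezoid), which resolves the near-singular
small-t region; tests verify agreement with closed forms (exponential
integral / erfc) to better than 0.5% and with a micro-stepped brute-force
collision simulator within Monte-Carlo error. AIT(0) is pinned to Δt (a
coincident pair interacts for the whole step). Values are tabulated at
1 nm resolution per (D, ID, Δt, d); rate changes — including scheduled
mid-run changes — reuse tables unchanged. Candidate pairs come from a
k-d-tree search within the distance at which AIT·R_bind falls below 10⁻⁶
(capped at 2 µm); trials are resolved closest-first so a molecule binds
its nearest eligible neighbour, one partner per molecule.

Cytoplasm↔membrane reactions use the 3D propagator with the cytoplasmic
D and 3D separations. Because a membrane target sits on the boundary,
half of its free-space propagator mass lies outside the cell; the
resulting on-flux is R_bind·IV/(2V) per target, which analytically
reproduces the measured PH-domain equilibrium below.

### Illumination and image formation

Epi illumination is a TEM00 Gaussian beam: lateral profile
exp(−4 ln2 · r²/FWHM²) (default FWHM 100 µm), constant in z, optionally
truncated by a circular diaphragm. TIRF multiplies that profile by
exp(−z/d) with d = λ0/(4π·√(n3²sin²θ − n1²)); the defaults 532 nm, 64°,
n1 = 1.33, n3 = 1.52 give d ≈ 135 nm. Sub-critical angles are rejected.
Confocal illumination is laterally uniform with the axial factor
S_zf/(S_zf + π(tanθ·|z − z_f|)²), and detected photons are additionally
divided by 1 + γ_PH(z − z_f)² for the pinhole. Intensities are
normalised to 1 at the field centre on the focal plane; the absolute
scale lives in the camera spec (6000 photons s⁻¹ per fluorophore by
default, i.e. ≈30 000 counts s⁻¹ at EMCCD gain 5).

Per illuminated substep each molecule with k active tags draws an integer
photon packet with mean I(x,y,z)·N_ph·Δt·k and a flat spread of total
width √mean (a Poisson option exists behind
`CameraSpec.photon_noise="poisson"`; the flat law is the default). Every
photon lands at the molecule position plus a 2D Gaussian offset with
FWHM(z) = FWHM_f + γ_obj(z − z_f)² (250 nm in focus, γ_obj = 0.6 µm⁻¹,
appropriate for a 100×/1.45 NA objective); photons outside the frame are
counted as dropped, so photon conservation is testable. Each active tag
bleaches independently with probability R_bleach·Δt·I — bleaching, like
emission, stops entirely during dark gate intervals, which is what makes
the gated-illumination experiment work. Frames are finalised by a
per-pixel multiplicative gain ~ N(g, g/4) (the spread is a model choice;
only the mean is documented for the reference camera), additive Gaussian
background (RMS 2 counts), clipping at zero and 16-bit saturation.

Gated (time-lapse) illumination exposes one frame every
`period_frames` = round(1/duty) frames, giving evenly spaced recordings
with increasing dark intervals as the duty ratio decreases.

### Tracking and analyses

Detection: Gaussian matched filter at the PSF scale; local maxima above
k = 4 × the filtered noise RMS; maxima closer than one FWHM merge into
the brighter one; subpixel positions by intensity-weighted centroid in a
±3 px window. Maxima whose centroid window would be clipped by the frame
border are rejected — a standard margin which also removes molecules on
the lateral cell faces, which project onto the outermost pixel rows as
slow "edge crawlers". Linking: greedy mutual-nearest-neighbour matching
with gate 5·√(4D_expect/fps) and no gap closing; trajectories shorter
than 20 points are discarded. Crossing spots can swap or truncate tracks;
this is deliberate — the reference analyses show the same failure modes.

Mobility: per-track and ensemble time-averaged MSD; D from a weighted
least-squares line MSD = 4DΔt + b over lags 1–4. The free intercept
absorbs localisation noise (+4σ²) and motion blur (−4DΔt/3), so the slope
is unbiased for free diffusion; for confined motion the fitted value
depends on the lag window (see Limitations). Off-rate: weighted
log-linear fit to the number of tracks surviving each lag, starting at
the 20-frame minimum (the survival-curve convention the reference
analyses plot). The gated experiment instead uses a right-censoring-aware
exponential maximum-likelihood rate (disappearances divided by observed
lifetime beyond a 5-recorded-frame minimum — left truncation does not
bias the memoryless MLE and the shorter cut retains several times more
events than the 20-point reporting minimum), because with tens of tracks
per duty ratio the log-count fit carries a multiplicative small-count
bias that would contaminate the regression; it also discards detections
dimmer than
25% of the expected single-fluorophore peak, separating landed molecules
from the ~10× dimmer smears of cytoplasmic molecules passing through the
evanescent field (the two amplitude populations are disjoint on ground
truth). One off-rate is fitted per duty ratio against *real* elapsed
time and regressed on duty ratio: since only exposed time bleaches,
k(r) = R_diss + r·R_bleach, so the slope estimates photobleaching and the
intercept dissociation.
Immobilisation analysis: a rolling mean over 5 consecutive squared
displacements gives an apparent local D; intervals below 0.03 µm²/s are
immobile; complete mobile→immobile→mobile episodes contribute durations
and the rate is the reciprocal mean. Window and threshold were calibrated
on noise-augmented ground-truth trajectories of the anchor scenario
(recall 99% of episodes longer than the window, fitted rate within 3% of
the ground-truth episode rate) and then frozen. Mobility-distribution
shape is assessed by 1- vs 2-component Gaussian mixtures: "bimodal" needs
ΔBIC > 10 (very strong evidence) and component means separated by ≥ 2×.

## Benchmark protocols and run sizes

All protocols live in `virtucell.experiments` and are driven by both the
test suite and `scripts/acceptance.py`. Sizes were chosen to keep each
protocol in the tens of seconds on one CPU while leaving enough tracks
for stable fits:

* Free/hindered mobility: 10 s records (330 frames) at the default
  densities; barriers/rafts imaged under TIRF, free diffusion under a
  flat 200 µm beam; ~70–150 tracks per run, 2–3 seeds. Raft records
  start from uniform seeding and include the crowding transient — that is
  the published protocol; pre-equilibrated rafts crowd to the stationary
  1/D density and read ~0.10 µm²/s instead.
* PH-domain binding: 60 s ground-truth runs (binding equilibrates with
  τ ≈ 11 s), bound fraction time-averaged over the final 30 s.
* Gated titration: duty ratios 0.1/0.2/0.5/1.0 with 70/50/35/25 s runs —
  longer at low duty so tracks span enough real time for the slow
  off-rates.
* Anchor binding: 30 s ground-truth runs, averaged after 10 s;
  bound-time episodes pooled over 6–10 imaged 10 s runs.

## What the generator does and does not emulate

The synthetic movies share real data's photon statistics, defocus blur,
motion blur, bleaching, background noise and density-dependent overlap
artifacts, so pipeline biases measured here (censoring at edges, overlap
truncation, episode erosion) transfer qualitatively to real experiments.
They do not include: curved or fluctuating membranes, polarisation
effects, fixed-pattern or multiplicative camera noise beyond the
stochastic gain, autofluorescent background structure, directed
transport, or higher-order complexes (pairs only). Passing benchmarks
therefore validates the algorithms under idealised geometry, not any
particular biological system.

## Numerical choices and degenerate inputs

AIT quadrature as above; lookup by nearest nm, zero beyond the table.
Candidate search and binding trials consume randomness in a fixed order,
so runs are reproducible; among simultaneous winning trials the closest
pair binds first. Steps larger than a cell edge fold correctly;
impermeable fences are exactly impermeable (no tunnelling); a zero-duty
or zero-duration run yields valid empty outputs. Photon counts clip at
zero; frames saturate at 65535. Config validation rejects negative rates
and sizes, inconsistent fps/substeps, unknown partners and duplicate
class names with a dedicated configuration error.

## Known limitations

* The confined-mobility values depend on the MSD fit window. With the
  declared lags 1–4 the impermeable-fence scenario reads ≈0.19–0.20
  µm²/s (both on ground truth and through the pipeline) versus the
  reference 0.163; reproducing that number would require a longer,
  undocumented fit window (a single-lag estimate near 0.45 s matches it).
  The window is kept fixed rather than tuned; the qualitative behaviour
  (twofold drop, permeability ordering, 40%-of-compartment plateau) is
  reproduced.
* The anchor-scenario equilibrium reads ≈38% bound versus the reference
  45%: detailed balance with this AIT formulation predicts 38–40%, so the
  gap points to a constant-factor ambiguity in the source's 2D
  interaction-measure definition, not to sampling noise. The
  low-rate point (~10%) and the PH-domain equilibrium (~19% vs "about
  15%") are reproduced.
* Fast rebinding of a just-dissociated pair merges episodes at frame
  resolution, so observable bound times exceed 1/R_diss; the rolling-MSD
  classifier then over-fragments noisy episodes — chiefly where passing
  spots transiently merge with a bound one — and the fitted episode rate
  lands well above the truth (≈1.4–1.5 s⁻¹ versus the reference 1.2).
  Morphological smoothing of the mobile/immobile classification would
  lower the pipeline value but visibly degrades the estimator's fidelity
  on noise-augmented ground-truth trajectories, so the classifier is kept
  as calibrated there and the bias is reported rather than patched.
* At D ≲ 0.01 µm²/s the per-frame displacement (~0.35 px) is inside the
  centroid detector's pixel-locking regime: subpixel-phase localisation
  errors are correlated between frames and decorrelate with lag, so the
  fitted D overshoots by ~30% (0.013 for a 0.01 input). Mobilities of
  0.1–0.3 µm²/s recover within 1–2%. A fitted-PSF localiser would reduce
  this but is outside the declared design (centroid localisation suffices
  at the reference SNR for everything else measured here).
* Confocal scanning is modelled as whole-frame acquisition with axial
  weighting; per-pixel scan timing is not simulated.
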