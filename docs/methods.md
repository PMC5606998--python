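# Methods

## Ray-optics trap model

The otolith is modelled as a homogeneous isotropic sphere (default radius
27.5 µm, index 1.63 — the mean of the aragonite triple n_α = 1.53,
n_β = 1.68, n_γ = 1.69) in water (n_m = 1.33). At 55 µm diameter the sphere
is ~50 wavelengths across, far inside the ray-optics regime, so the focused
beam is treated as a bundle of straight rays through the focal point filling
the cone of half-angle `asin(NA / n_m)`.

Per ray, the momentum transfer uses the classical closed form: with
incidence angle θ and refraction angle r,

    Qs + i·Qg = 1 + R e^{2iθ} − T² e^{2i(θ−r)} / (1 + R e^{2ir}),

where R and T are Fresnel reflectance/transmittance (mean of s and p by
default; the polarisation convention is configurable) and the denominator
sums the infinite internal-reflection series exactly. The force on the
sphere is `Qs·d − Qg·a2` per unit ray momentum flux, with `d` the ray
direction and `a2` the transverse part of the outward surface normal; rays
that miss contribute zero. Total internal reflection is handled (R = 1) but
cannot occur for a sphere denser than its medium.

**Sign convention.** Results are reported as the reaction exerted by the
particle on the beam — the quantity a position-sensitive detector measures —
which is equal and opposite to the optical force on the particle. A trap
below the sphere centre on the y axis therefore yields a positive y force.

**Discretisation.** The ray fan is a deterministic midpoint grid, uniform in
`(sin²α, φ)` (uniform in aperture area under the Abbe sine condition), with
`n_phi ≈ 8·n_alpha` and 2×10⁴ rays by default; no RNG is used anywhere in
the optics module, so maps are node-wise reproducible and any sub-grid of a
map equals the full map at shared nodes. At 2×10⁴ rays the Q value at a
mid-profile offset differs from a 2×10⁵-ray computation by < 0.5 %.

**Aperture fill** defaults to uniform (overfilled objective); a Gaussian
fill with configurable 1/e² fraction is available. The trap plane is the
sphere's equatorial plane (z = 0). With these defaults a 500 mW beam peaks
at ≈ 790 pN with the focus ~2 µm inside the edge; the force falls to 80 % of
its maximum within ~1.6 µm moving outward, while the inward flank is gentle
(~4 µm), reflecting the quasi-linear rise of Q from centre to edge.

Known limitations: no electromagnetic (T-matrix / generalised Lorenz–Mie)
corrections, no birefringent wave propagation (birefringence is treated
empirically as angular sectors in measured/synthetic maps), no aberrations,
spherical particles only.

## Tissue Monte Carlo

Standard weighted photon-packet transport through a single homogeneous slab:
free paths `s = −ln ξ / µ_t`, fractional absorption `µ_a/µ_t` per
interaction, Henyey–Greenstein deflection cosines, azimuth uniform. Packets
below weight 1e-4 undergo Russian roulette with survival probability 0.1
(survivors boosted ×10). Boundaries are index-matched and packets are
launched normally incident — a deliberate simplification; focused-beam and
layered-anatomy effects are out of scope.

Defaults (µ_s = 10 mm⁻¹, µ_a = 0.1 mm⁻¹, g = 0.9, 150 µm depth) are a
generic near-infrared soft-tissue ballpark for larval fish, fully
configurable. With them, ~22 % of light arrives unscattered at otolith
depth and ~94 % of total weight is transmitted.

Bookkeeping is exact: transmitted + reflected + absorbed + roulette-killed −
roulette-gained equals the launched weight to 1e-9 (the roulette gain term
is tallied explicitly because weight boosting creates weight at kill-time
parity). The unscattered (ballistic) fraction reproduces Beer–Lambert
`exp(−µ_t d)` within Monte Carlo error, and runs are bit-reproducible for a
fixed seed, which is recorded in every result.

## Force-map analysis

A deflection scan is a grid of trap positions with per-node (Fx, Fy). The
total force is the per-node vector magnitude. The otolith boundary is
estimated from the ridge of force maxima: an initial centre (centroid of the
top-decile |F| nodes) seeds per-angular-bin ridge detection, where each
bin's ridge point is the |F|-weighted centroid of its top-60 % nodes — on a
flat-topped noisy ridge this is far more stable than the per-bin argmax —
followed by a least-squares (Kåsa) circle fit, refined once. On synthetic
scans the centre is recovered to ~0.1 µm and the radius within a grid step.

Radial decomposition rotates (Fx, Fy) into the local radial frame; the
per-node norm is preserved exactly and a node at the centre is flagged
invalid rather than silently dropped.

Sector statistics operate on the edge band (fitted radius ± one grid step by
default). Two summaries are reported per angular sector: the mean ± SD of
|F| (the statistic conventionally quoted for measured maps) and an
*amplitude* estimate — the magnitude of the mean signed radial component.
The latter is preferred for quantitative recovery because |F| of a noisy
vector is biased upward by ~σ²/2A (Rician), whereas the radial mean is
unbiased for a radial field with isotropic noise. Sectors are classified
strong/weak about the midpoint of the extreme sector means; empty sectors
are flagged, never dropped silently. Free sector edges can be fitted by
circular change-point segmentation of the binned angular profile (dynamic
programming over bin boundaries, all rotations scanned).

## Behaviour tracking

**Tail.** The midline is traced from the swim-bladder anchor tailward in 19
equal steps (20 points): at each step, candidate headings within ±40° of the
previous heading are probed at the step radius and the next heading is the
intensity-weighted circular mean of above-threshold probes. The deflection
angle is the signed angle between the body axis and the chord from the
midline's 70 % arclength point to the tip — a definition chosen for
robustness to proximal tracking noise (the proximal tail hardly moves). A
lost tail sets a per-frame failure flag instead of raising.

**Bouts.** The angle trace is detrended by a 0.25 s running mean (removing
postural ramps) and lightly smoothed; sign crossings are counted with ±4°
hysteresis, so noise up to ~2° SD produces none. A run of crossings at rate
above 10 Hz spanning at least 3 cycles (2k − 1 interior alternations for k
cycles) forms a bout; bouts separated by < 100 ms are merged. A bout whose
peak angular velocity exceeds 3000 °/s is classified an escape — ordinary
bouts in the generator peak below ~1900 °/s and escape-like events above
~7000 °/s, so the threshold separates the two regimes cleanly.

**Eyes.** Eye roll is the angle of the chord between two pigment landmarks
versus the body midline, reported as change from a pre-stimulus baseline
mean. The chord is undirected, so angles are wrapped to (−90°, 90°];
landmark detection segments the darkest blobs in a small ROI about each eye
and takes intensity-weighted centroids, ordered by x for frame-to-frame
correspondence (stable for rolls below ~45°). Frames with missing landmarks
are flagged and carry NaN.

## Trial statistics

The protocol presents 1 s traps with 9 s rest, three trials per condition,
over powers (50, 100, 200, 400, 600 mW) and trap loci (lateral, medial,
centre; single or dual). A trial is excluded iff a spontaneous bout ends
within 1 s before trap onset, begins within 1 s after trap offset, or an
escape occurs during or within 1 s of the trap. When several criteria match,
precedence is escape > pre-bout > post-bout (the escape is the stronger
event). Exclusion is idempotent and order-independent; more than one
exclusion per condition is logged, not fatal.

Onset responses are the signed extremum of the baseline-subtracted angle
during the trap window; offset responses the signed extremum within 1 s
after trap end relative to the immediately pre-offset level. Bout intervals
are masked by linear interpolation before extremum-taking, recovering the
underlying posture beneath swim oscillations. The dual-trap summation test
reports the residual `dual − (lateral + medial)`; residual fractions are
normalised by the amplitude of the *linear prediction*, so a dual response
constructed as `c·(lat + med)` yields a residual fraction of exactly
|1 − c|. Swim probability is the per-power fraction of usable trials with a
swim bout during the trap (monotonicity is reported, never enforced).
Power-response curves use an ordinary degree-2 least-squares fit of the
across-larva means with per-power SEM; inference uses the two-sided paired t
test (sidedness is a convention choice, recorded here), with the degenerate
all-zero-difference case defined as t = 0, p = 1.

## Synthetic data

The generators define the conditions under which the pipeline is validated;
every generator records its seed and returns its ground truth, and a fixed
seed reproduces output bit for bit.

*Scans.* A radial inward field `A(φ)·bump(r)` plus isotropic Gaussian noise
(0.5 pN SD). `bump` is 1 within 2 µm of the radius with a 3 µm Gaussian
shoulder; `A(φ)` steps through four sectors (5.0 / 3.0 / 5.0 / 3.0 pN over
110° / 70° / 110° / 70°), emulating the measured birefringence pattern of
two wide strong and two narrow weak arcs. The default grid step is 0.5 µm —
a realistic piezo-scan resolution for a 55 µm particle — giving each sector
enough edge-band nodes (~130 in the narrow sectors) that amplitude recovery
is estimator-limited rather than noise-limited.

*Trials.* Tail plateaus follow a saturating power map `p²/(p² + p_half²)`
(quadratic at low power, capped near the top power, hence well described by
a second-order polynomial over the tested range) with defaults of 25° tail /
10° eye maximum and p_half = 300 mW; per-larva gains vary by 10 %. Lateral
traps ramp to plateau (τ = 150 ms) and decay after offset (τ = 300 ms);
medial traps are flat during the trap with a peak-normalised −8° rebound at
offset; dual traps are the additivity-weighted sum; centre traps are pure
baseline. Swim bouts (10° at 20 Hz, 0.35 s) occur with logistic probability
(p50 = 300 mW, slope 80 mW) in lateral/dual trials; eyes roll in unison only
for conditions containing a lateral trap. Contamination (spontaneous
pre/post bouts, escapes at 35° / 35 Hz) is injected at configurable rates
with labelled ground truth. Magnitudes are in the spirit of the in-vivo
phenomenology, not reproductions of unpublished recordings — passing
recovery tests demonstrates the pipeline's correctness on data with this
structure, not the biological values themselves.

*Frames.* 600×300 px at 2 µm/px and 200 Hz: soft-edged dark body and
tapering tail on a light noisy background, plus two near-black pigment dots
per eye placed diametrally so the dot chord angle equals the eye roll. The
tail is a constant-curvature arc with curvature `k = θ/(0.85 L)`, chosen so
the rendered 70 %→tip chord angle equals the requested deflection exactly;
the renderer refuses angles beyond ±45° (undrawable within the frame).
Render-and-recover errors are ~0.1° RMS for the tail and ~0.15° for the
eyes under default noise. Real recordings differ in ways the renderer does
not attempt: uneven illumination, pigmentation variability, occlusions,
torsional movements and free-swimming displacement are all absent, so
tracking performance on real data must be validated separately.

## Problem sizes

Default simulation sizes — 2×10⁴ rays per trap position, 10⁵ photon
packets, 0.1 µm profile resolution over a ±5 µm window, nine-angle render
sweeps — were chosen so every headline quantity is reproduced in seconds on
a single core while keeping discretisation and Monte Carlo errors well
below the tolerances they are tested against.
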