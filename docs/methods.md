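# Methods

Internal units are ms, mm, mT/m and mT/(m·ms) (numerically T/m/s), Hz, and
s/mm²; conversions happen only at I/O boundaries. γ̄ = 42.576 MHz/T,
γ = 2.6752×10⁸ rad/s/T.

## EPI readout timing

One EPI echo traverses a read-axis k-space width of N/FOV, i.e. a gradient
area N/(FOV·γ̄). The readout lobe is the shortest symmetric trapezoid
achieving that area under the coil's duty-cycle (nominal) amplitude limit
and slew limit; below the triangle capacity G²/SR the lobe is a
slew-limited triangle with peak √(area·SR). The readout is ramp-sampled
(ADC on over the ramps), so

    ES = trapezoid duration + t_dead,        t_dead = 30 µs,
    TE_min = t_pre + n_before_centre · ES,   t_pre = 1.3 ms,

with n_before_centre = ⌈N·(PF − ½)/(R·S)⌉ echoes before the k-space centre
(R in-plane GRAPPA, S in-plane segments, PF partial Fourier; ceil at every
division, the centre echo counted in n_before_centre). The per-echo dead
time stands for phase blips and ADC gaps; the pre-readout time for the
excitation half-duration and pre-winders. Both are configurable; the
defaults reproduce the standard operating points of the three bundled coil
presets to within a couple of percent. Timing is continuous — no gradient
raster — with an optional raster mode (`raster_us`) for sensitivity
analysis only.

Echo spacings falling inside a coil's forbidden mechanical-resonance bands
are bumped to the band's upper edge and flagged, mirroring scanner
practice. The bands are closed intervals; a degenerate interval marks a
single excluded echo spacing.

`achievable_resolution` inverts the model by exhaustive scan over matrix
sizes (monotone apart from ceil steps and band bumps), returning the
finest FOV/N whose minimum TE fits the target. Exact printed resolutions
from performance-comparison figures are not claimed — the acceleration and
constraint set behind them is under-specified — only the coil ordering.

## Point spread function

T2* decay across the echo train imposes a k-space weighting (MTF): the
reconstructed phase-encode line i belongs to the echo j = ⌊(i − i₀)/(R·S)⌋
(i₀ = N·(1 − PF) lines skipped by partial Fourier and zero-filled — no
conjugate synthesis), acquired at t_j = TE + (j − j_c)·ES where j_c is the
echo covering the centre line; its weight is exp(−t_j/T2*). The PSF is the
magnitude of the Fourier transform of the MTF, evaluated by zero-padding
64× (the |DTFT| is invariant to where the window sits, so no centring
shift is applied — shifting a zero-padded array would split the window and
corrupt the spectrum) and reading the FWHM by linear interpolation at the
half-maximum crossings; padding keeps the interpolation error below 0.1%.
A full-Fourier undecayed MTF reproduces the sinc main lobe, 1.2067 voxels.
The default T2* is 25 ms (white matter at 7 T); T2 = 46 ms feeds the
closed-form TE SNR factor exp(TE1/T2)/exp(TE2/T2).

A note on volumetric gains: ratios of rounded voxel volumes quoted in
figure captions (0.23/0.09 ≈ 2.56) differ from exact cube ratios
((0.61/0.45)³ ≈ 2.49); `volumetric_gain` returns the exact cube.

## Diffusion encoding

Monopolar trapezoidal PGSE only. With δ the flat-top-plus-one-ramp
duration, Δ the leading-edge separation and ε the ramp time,

    b = γ²G²[δ²(Δ − δ/3) + ε³/30 − δε²/6].

Encoding lobes run at the *absolute* amplitude limit (diffusion is low
duty cycle), packed symmetrically against the refocusing pulse
(Δ = δ + ε + t_refocus), and spin-echo symmetry gives
TE = t_refocus + 2·(δ + ε + t_readout-to-centre). The unprinted overheads
default to t_refocus = 7 ms and t_readout-to-centre = 8 ms. Minimum TE at
a target b is solved by bisection on the lobe duration; below the
full-amplitude threshold the lobes become slew-limited triangles, so
TE → overheads as b → 0. Because the overheads are fixed, the TE ratio
between two coils is diluted relative to the asymptotic constant-b law
t ∝ G^(−2/3) (= 0.54 at a 2.5× amplitude ratio): at b = 10,000 s/mm² the
head-to-body TE ratio of this model is ≈ 0.64, while the encoding-time
ratio alone approaches 0.50. Scanner-reported TE pairs additionally
contain fat saturation and other unprinted overheads and are treated as an
ordering claim only.

## PNS supervision

The supervision model differentiates each axis to slew rate, passes it
through a weighted chain of first-order low-pass filters, rectifies,
combines axes by root-sum-square and compares the time-maximum to a
rheobase-like scale; the result is a fraction of the first-level ceiling
(Stimlim), with the normal operating mode capped at 0.8 × Stimlim. The
pipeline is positively homogeneous and time-shift invariant by
construction, and the discrete filter is exact for piecewise-constant
slew.

The filter constants of a real scanner derive from volunteer threshold
studies and are not public. The shipped defaults — a single stage with
τ = 1 ms, weight 1, rheobase 120 T/m/s — are a **placeholder
calibration**, chosen only to satisfy the qualitative operating geometry:
a bipolar readout at 98 mT/m, 213 T/m/s, ES 0.92 ms evaluates as allowed,
while a 200 mT/m train at the full 900 T/m/s does not (full amplitude and
full slew cannot be combined). They are user-replaceable and carry no
claim of reproducing measured thresholds. Operating curves are obtained by
bisection on trapezoid amplitude to the normal-mode cap, optionally capped
by the coil's amplitude and slew limits.

## Receive arrays, SNR, g-factor

Helmet arrays tile an ellipsoidal surface (175 × 215 mm footprint) with
rows of overlapped circular loops; the 96-channel layout keeps 12/18/24
loops in the top three rows and 42 on the remainder, and loop radius
shrinks as channel count grows (≈2 cm at 96 channels; larger loops capped
at 27 mm). Loop placement is deterministic given the seed (azimuthal
stagger only). Sensitivities are quasi-static unit-current loop fields
(elliptic-integral solution) combined as Bx − iBy with B0 along z. Grid
points nearer the conductor ring than the wire radius receive the finite
wire-surface field; with an explicit voxel mask such points raise instead.

Channel noise is Ψ = σ²(I + c·K), K a Gaussian overlap kernel of
centre-to-centre distance (length scale the summed radii), symmetrised and
eigenvalue-floored. The helmet comparisons additionally scale each
channel's σ by loop radius (body-noise dominance), the regime in which
shrinking loops pays off at the periphery — without it a small-loop
surrogate array loses peripheral SNR, contrary to what high-density arrays
measure.

SNR maps use the noise-covariance-weighted optimal combination,
SNR ∝ √(SᴴΨ⁻¹S), in relative units only (uniform synthetic excitation; no
absolute calibration, so scanner-measured absolute SNR/tSNR values are out
of scope). Parallel-imaging noise amplification uses SENSE algebra over
the aliasing set A of in-plane folding × SMS slices with integer CAIPI
shifts (slice m shifted by m·shift/SMS of the PE FOV):

    g_j = √([(S_AᴴΨ⁻¹S_A)⁻¹]_jj · [S_AᴴΨ⁻¹S_A]_jj) ≥ 1,

reported as retained SNR 1/g ∈ (0,1]; rank-deficient systems yield 1/g = 0.
SENSE stands in for autocalibrated reconstructions deliberately:
sensitivities are known exactly in simulation, making SENSE the natural
noise-propagation model. Central/peripheral ROI statistics use the inner
40% / outer 60% of the normalised brain-mask radius (configurable).

## Distortion

Off-resonance Δf displaces voxels along phase encode by
Δf · ES_eff · N_pe pixels (ES_eff = ES/(R·S); partial Fourier does not
change the dwell), opposite signs for opposed PE polarities; 1D only (no
read-axis or through-plane terms, no eddy-current distortion). The forward
model deposits intensity by mass-preserving linear splatting, which
applies the Jacobian (pile-up/stretch) modulation implicitly and matches a
discrete per-line phase-accrual k-space simulation to well under 0.1 pixel.

Warp estimation from an opposed-PE pair minimises, per PE line,
‖ap(y+u)(1+u′) − pa(y−u)(1−u′)‖² + λ‖D₂u‖² (λ = 0.1; the (1±u′) factors
are the Jacobian intensity corrections, without which the data term is
biased). The solver initialises u by equal-cumulative-mass matching — the
distortion conserves line integrals, so points of equal cumulative mass in
the two images are displaced copies of one source point — then refines by
Levenberg-damped Gauss–Newton at decreasing image-smoothing widths, with
per-column step acceptance and light cross-column smoothing of u. The
estimate is exactly antisymmetric under swapping the inputs. On synthetic
pairs at 0.6 mm with multi-pixel displacements the recovery RMSE is
≈ 0.06 mm.

## Synthetic phantoms

The phantom is a nested-ellipsoid head (white core, grey ribbon, CSF
shell; outer semi-axes 70/85/65 mm) whose implicit function is perturbed
by a seeded low-frequency cosine series evaluated at *physical*
coordinates — grid refinement samples the same continuous shape, so tissue
volume fractions are stable across resolutions (observed < 0.1% change on
doubling). Defaults: proton density 1.0/0.85/0.7 (CSF/grey/white), T2*
100/33/25 ms, field map a low-order polynomial plus a focal Gaussian near
the sinus region, capped at ±50 Hz and zero outside the brain. Identical
seed and configuration give bit-identical output.

Multi-channel acquisitions are sensitivity × proton density plus circular
complex Gaussian noise with channel covariance scale²·Ψ (Cholesky
factorisation), independent across voxels. What the phantom does **not**
emulate: real anatomy and tissue heterogeneity, physiological noise,
motion, B1 transmit inhomogeneity, eddy currents, k-space trajectory
imperfections. Passing tests therefore validate the algebra and the
statistical machinery (noise propagation, unfolding conditioning,
warp recovery) under the model's own assumptions, not performance on
scanned participants — which is why in vivo quantities (absolute SNR/tSNR,
fiber counts, sound levels) are explicitly out of scope.

## Problem sizes and numerical choices

Simulation sizes were chosen at desk scale: 24³ grids at 7–8 mm spacing
for helmet comparisons, 16×16 toys with 10⁵ noise draws for the
g-factor Monte-Carlo cross-check (agreement within 2%), 32×32 phantoms for
the distortion oracle, 48×64 images for warp recovery, 64³ default
phantoms. FWHM interpolation uses 64× zero-padding; SENSE systems are
solved as batched Hermitian inversions with a per-voxel fallback for
singular aliasing sets; the bisections (diffusion lobe duration, PNS
amplitude) run to 10⁻⁶ ms / 0.1% tolerances and are verified against
dense grid scans in the tests.
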