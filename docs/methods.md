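# Methods

This note documents the models implemented in `musicbrain`, the choices
made where the design was genuinely open, and what the synthetic-data
generators do and do not emulate.

## Cochlea model

The basilar membrane is treated as a one-dimensional damped wave equation

    K(x)/mu(x) * u_xx - d * u_t = u_tt + f(t)

on x in [0, l], l = 3.5 cm, with homogeneous Dirichlet boundaries,
stiffness K(x) = 2e9 * exp(-3.4 x) dyn/cm^3, cross section
A(x) = 0.1*(0.1 + 0.02 x/l) cm^2 and linear density mu(x) = m/A(x). The
sound pressure f(t) acts uniformly on all interior points (long-wave
approximation, valid below ~4 kHz). The scheme is explicit central
differences in space and time (second order), with the damping term
discretized symmetrically about the current step so it enters the update
as a (1 +- d*dt/2) pair; stability (CFL) is checked at construction.

Parameters the governing equations do not fix, and how they were chosen:

- **Mass constant m = 4.0.** The explicit scheme at dt = 1/192000 s and
  240 grid points bounds the admissible wave speed; m = 4 puts the basal
  wave speed at ~22 m/s (CFL ~0.8) and the steady-state best-frequency map
  spans the audible range basal to apical (reported by
  `best_frequency_map`, not hard-coded).
- **Damping d = 1000 /s.** The smallest value, on a coarse grid of
  candidates, that gives temporally stable, spatially localized single-tone
  responses and lets onset transients decay within the 5 ms spike-discard
  window (amplitude decay time constant 2/d = 2 ms).
- **Grid: 240 points, 10 per critical band.** The 24 critical bands are
  contiguous equal segments of the grid; the exponential stiffness already
  makes this roughly logarithmic in frequency. Band 1 is basal (highest
  best frequency).
- **Spikes.** A spike fires at a strict spatial and temporal displacement
  maximum with u > 0 (positive peaks only by default; the sign constraint
  is a flag). The spike weight is the displacement value. I(t) is the
  per-sample sum of all spike weights, max-normalized to 1.

Known discretization artifact: beyond the position where a tone's local
wavelength falls below two grid spacings, the field carries grid-scale
ripples of small amplitude. Because the admissible wave speed is itself
CFL-limited, this region starts near the apex (last few bands) at any
resolution; apical-band spikes from mid/high-frequency tones are therefore
partly numerical. Tests and analyses use weighted band statistics, which
the ripple band does not dominate.

## Brain network model

Each of 90 AAL regions (relabelled: nodes 1-45 left, 46-90 right
hemisphere) is a FitzHugh-Nagumo oscillator

    eps u_k' = u_k - u_k^3/3 - v_k + [coupling]_u + C_k I(t)
        v_k' = u_k + a + [coupling]_v

with eps = 0.05, a = 0.5 (oscillatory regime), coupling strength
sigma = 0.7 within and varsigma = 0.15 between hemispheres, through the
rotation matrix B(phi), phi = pi/2 - 0.1 (mostly activator-inhibitor
cross-coupling), and the input mask C_k = 1 exactly at the superior
temporal nodes 41 and 86.

The measured single-oscillator limit cycle at these parameters has period
T = 2.6659 and angular frequency omega = 2.3569 (dimensionless frequency
f = 0.3751), stable to <0.5% across integrator tolerances 1e-6..1e-9 and
confirmed by three independent integrators (RK45, Radau, LSODA) at rtol
1e-10. All physical-to-dimensionless time conversions use this measured T
(one physical second = T * n_b time units for frequency-band parameter
n_b in Hz), never a rounded constant.

**Integration.** Adaptive Dormand-Prince RK45 (the same embedded 5(4)
pair and per-component error control as scipy's `RK45`), JIT-compiled and
ensemble-batched: an ensemble of initial conditions shares the network
and the input and is advanced with one step-size sequence controlled by
the worst member, so every member is integrated at least as accurately as
a solo run. The core is validated against `scipy.integrate.solve_ivp`
trajectories in the test suite. Default tolerances rtol 1e-7 / atol 1e-9
(scan drivers default to 1e-6 / 1e-8). Output states are sampled on a
uniform grid of 20 points per oscillator period.

**Input handling.** I(t) arrives at 192 kHz, orders of magnitude below
the integrator step scale. The drive is resampled by summing spike mass
into bins of ~1/10 oscillator period and re-normalizing the binned signal
to max 1 -- the same sum-and-normalize construction that defines I(t),
applied at the drive resolution -- then evaluated as a zero-order hold.
Plain mean-pooling was rejected: with spikes occupying ~0.1% of samples it
scales the drive by that occupancy and the input becomes dynamically
invisible, which contradicts the role the input signal plays in this
model (the driven auditory nodes' mean phase velocities visibly shift).

**Initial conditions and transients.** (u, v) uniform on the circle of
radius 2 per node, one independent draw per seed; a transient with I = 0
precedes the driven epoch. Desk-scale drivers default to 200 time units
of transient; the publication-scale value (10000) is a parameter.

## Synchrony measures

The geometric phase is atan2(v, u) (quadrant-aware; the limit cycle
encloses the origin). The dynamical phase map tabulates arrival times
t(phi) on one uncoupled cycle at 4096 phase grid points and sets
theta = 2*pi*t(phi)/T, making theta advance uniformly on the unperturbed
cycle; the tabulated map is made monotone across its single wrap point so
interpolation never bridges a 2*pi jump. The Kuramoto order parameter
R(t) uses these dynamical phases. Mean phase velocities count complete
2*pi windings of the unwrapped geometric phase (fraction discarded).

The stimulus coherence gamma = (1/DeltaT) * integral R(t) I(t) dt is
evaluated by trapezoidal quadrature on the *finer* of the two time grids
after linear interpolation. With a spike-train-like I most mass sits in
isolated samples; interpolating onto the coarser (R) grid would discard
it. On the finer grid the quadrature is exact up to R's smoothness, and
gamma inherits I's fixed 192-kHz normalization, so values are comparable
across n_b. Typical desk-scale magnitudes are small (gamma <= mean I);
only relative variation across n_b carries meaning.

## Synthetic connectome

The empirical DTI matrix is not distributed, so `connectome` ships a
surrogate generator calibrated to the statistics reported for such
matrices: two 45x45 intra-hemispheric blocks with edge density 0.3 versus
0.06 between hemispheres, heavy-tailed log-normal weights (sigma = 2.0;
streamline-count distributions are strongly right-skewed, so after
max-normalization most weights are small), an elevated homologous
anti-diagonal (pairs (k, k+45)), and a connectivity boost (factor 2.5) on
the rows of the two superior temporal nodes, reflecting their high degree
in measured networks. The weight scale is chosen so that at the reference
coupling (sigma = 0.7, varsigma = 0.15) the network exhibits *partial*
synchronization -- temporal-mean R well below 1 with large fluctuations
and hemispheric asymmetry -- rather than the complete synchrony a denser
surrogate produces.

What the surrogate does not emulate: the modular community structure,
distance-dependent connection probability, and specific hub topology of a
measured connectome. A consequence observed in the scan experiments (and
stated as a limitation): the stimulus injected at the two auditory nodes
shifts their own dynamics clearly, but its imprint on the *global* order
parameter is weak, so n_b-dependent trends of R and gamma that rely on
network-wide recruitment of the input are at or below ensemble noise at
desk scale.

## Synthetic song

`generate_song_envelope` builds a deterministic music-like signal on
three timescales: a harmonic carrier (f0 = 220 Hz, 8 partials with 1/m
amplitudes) plus an equally strong sub-bass sine (35 Hz, the dominant
low-frequency periodicity a hip-hop mix would contribute to the cochlear
spike train); a percussive beat layer (2 Hz, 20-ms raised-cosine bursts,
depth 0.75); and an alternating loud/quiet section envelope (contrast
0.1, 0.25-s raised-cosine ramps, +-10% seeded level jitter). It does not
emulate broadband percussion noise, melodic variation, or production
dynamics of a real recording.

## EEG pipeline

Nine octave bands FB1 (125-250 Hz) to FB9 (0.49-0.98 Hz) are obtained by
a Mexican-hat (Ricker) continuous wavelet transform,
w(u, s) = s^(-1/2) * sum_k x_k psi((k-u)dt/s), scales
s_oct = alpha * 2^(oct-1). The wavelet width is 1 in wavelet-native
units; alpha = sqrt(2)/(2*pi*sqrt(125*250)) s places the analytic Ricker
peak response of the smallest scale at FB1's geometric-mean frequency
(verified against test sinusoids). Edges are zero-padded with a validity
mask. Electrode pairs are correlated in successive non-overlapping 1-s
windows (Pearson, n = 500; zero-variance windows give r = 0 with a flag),
block-averaged over 4 s, ranked per band against the rectified,
1-s-then-4-s-averaged stimulus amplitude, and the top 25 pair series per
band are averaged and correlated with the stimulus (ties broken by pair
index).

Two properties of this chain matter for interpretation. Octave-spaced
Ricker filters overlap strongly (amplitude response one octave off peak
is ~0.5), so band-specific effects leak into neighbours. And selecting
the best 25 of 496 series *by* their stimulus correlation inflates all
profile values (selection bias), the more so the fewer 4-s blocks enter;
at the 270-s stimulus length the bias is moderate but profile values
remain optimistic. Both effects are visible in the synthetic recovery
experiments: injected bands win, but by modest margins over saturated
neighbours.

The synthetic EEG generator gives every band an independent per-channel
band-limited noise floor plus a weak pink broadband background; bands
with positive gain additionally receive a channel-common band-limited
component whose amplitude follows the stimulus envelope. Inter-channel
windowed correlation in a driven band therefore swings with the envelope.
The generator draws a fresh common component per trial, so grand
averaging improves nothing (unlike real evoked responses); it is a test
harness for the analysis chain, not a forward model of EEG physics.

## Desk-scale defaults

Simulation sizes used by the tests and experiment drivers: 30-s songs,
10-seed ensembles, transient 200 time units, scan tolerances 1e-6/1e-8,
EEG recovery with 270-s envelopes and 2 trials. The corresponding
publication-scale settings (270-s song, 200-250 runs, transient 10000)
are plain parameters of the same functions.
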