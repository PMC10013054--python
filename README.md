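# musicbrain

From sound to brain network dynamics: a modelling chain for studying how
music induces synchronization in the brain.

Listening to music modulates large-scale neural synchrony: EEG studies
find that the synchronization between brain regions — especially in the
gamma band — rises and falls with the large-scale form (verse/chorus
structure, loudness) of a piece. `musicbrain` implements a complete
simulation and analysis chain for this phenomenon:

1. **Cochlea** (`musicbrain.cochlea`): a finite-difference model of the
   basilar membrane, a damped 1-D wave equation
   `K(x)/mu(x) u_xx − d u_t = u_tt + f(t)` with exponentially decaying
   stiffness `K(x) = 2e9 exp(−3.4x) dyn/cm³`, driven uniformly by the
   sound pressure (long-wave approximation). Neural spikes fire at strict
   spatio-temporal displacement maxima, are grouped into 24 critical
   bands (tonotopy), and are summed into the neural input signal `I(t)`.
2. **Brain network** (`musicbrain.connectome`, `musicbrain.fhn`): 90
   AAL regions, one FitzHugh–Nagumo oscillator each
   (`ε u̇ = u − u³/3 − v + …`, `v̇ = u + a + …`, ε = 0.05, a = 0.5),
   coupled through a weighted connectome with hemisphere-dependent
   strengths (σ = 0.7 intra, ς = 0.15 inter) and a rotational coupling
   matrix `B(φ)`, φ = π/2 − 0.1. `I(t)` drives the two auditory-cortex
   nodes (superior temporal gyri, nodes 41/86). A synthetic connectome
   generator stands in for the (undistributed) DTI matrix.
3. **Synchrony measures** (`musicbrain.synchrony`): dynamical phases
   (uniform-velocity reparameterization of the geometric phase), the
   Kuramoto order parameter `R(t) = |⟨e^{iθ_k}⟩|`, mean phase velocities
   `ω_k = 2πM_k/ΔT`, and the stimulus coherence
   `γ = (1/ΔT)∫R(t)I(t)dt`, which is large when synchrony peaks coincide
   with loud episodes. The frequency-band parameter `n_b` (Hz) maps
   physical stimulus time onto dimensionless model time (1 s = T·n_b
   time units with T the measured oscillator period).
4. **EEG pipeline** (`musicbrain.eeg`): Mexican-hat wavelet
   decomposition of 32-channel recordings into nine octave bands
   (125–250 Hz down to 0.49–0.98 Hz), Pearson correlations of all 496
   electrode pairs in 1-s windows (4464 series), 4-s block averaging,
   top-25 selection per band against the stimulus amplitude, and the
   band-wise stimulus-correlation profile — plus a synthetic EEG
   generator so the chain runs without recorded data.

The package is aimed at computational-neuroscience researchers who want
to reproduce, probe, or extend this sound-to-brain pipeline on synthetic
or their own data (WAV audio, CSV connectomes, CSV/EEG recordings).

## Worked example

```python
import musicbrain as mb

# 1. a 475 Hz tone complex with ten 1/m partials, through the cochlea
wave = mb.generate_tone_complex(475.0, 10, duration=0.05)
spikes = mb.sound_to_spikes(wave)
signal = mb.spikes_to_input(spikes, wave.duration, 192_000.0)
print(f"{spikes.n_spikes} spikes in {wave.duration*1e3:.0f} ms, "
      f"bands {spikes.bands.min()}..{spikes.bands.max()}")

# 2. the uncoupled oscillator calibration
omega, T = mb.natural_frequency()
print(f"omega_FHN = {omega:.4f}, period T = {T:.4f}")

# 3. drive the network with a synthetic song at n_b = 30 Hz
song = mb.generate_song_envelope(n_sections=4, section_length=2.0, seed=1)
I = mb.sound_to_input(song)
net = mb.generate_synthetic_connectome(seed=1)
model = mb.FHNNetwork(net)
traj = model.simulate(I, n_b=30.0, seeds=0, t_transient=200.0, period=T)

pmap = mb.DynamicalPhaseMap()
R = mb.kuramoto_order(pmap(mb.geometric_phase(traj.u, traj.v)))
gamma = mb.coherence_gamma(R, traj.times_physical, I.values, I.times)
print(f"mean R = {R.mean():.3f}, gamma = {gamma:.2e}")
```

Output:

```
48 spikes in 50 ms, bands 2..24
omega_FHN = 2.3569, period T = 2.6659
mean R = 0.292, gamma = 1.82e-05
```

The tone complex excites spikes clustered at the tonotopic positions of
its partials, recurring at the waveform maxima. The single-oscillator
period T = 2.666 (ω = 2.357, f = 0.375) is the measured calibration that
converts seconds to model time. On the synthetic connectome the network
sits in a partial-synchronization regime (mean R ≈ 0.29, strongly
fluctuating); γ is bounded above by the time-mean of the sparse,
max-normalized `I(t)`, so its absolute magnitude is small and only its
variation across `n_b` is meaningful.

A command-line interface wraps the same functionality:

```bash
musicbrain audio tone --f0 475 --partials 10 --out tone.wav
musicbrain cochlea --in tone.wav --out spikes.csv --input-signal I.csv
musicbrain connectome --seed 1 --out A.csv
musicbrain scan --connectome A.csv --input I.csv --out scan_out/
```

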