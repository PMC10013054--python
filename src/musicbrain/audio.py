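"""Acoustic stimuli: tone complexes, synthetic song-like signals, WAV I/O.

All signals are dimensionless pressure amplitudes in [-1, 1]; the cochlea
model's force scale absorbs physical units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "SoundWave",
    "generate_tone_complex",
    "generate_song_envelope",
    "read_wav",
    "write_wav",
    "upsample",
]


@dataclass(frozen=True)
class SoundWave:
    """A uniformly sampled pressure signal.

    Attributes
    ----------
    samples : ndarray
        Dimensionless pressure amplitudes.
    sample_rate : float
        Sampling rate in Hz.
    """

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a 1-D array with at least one sample")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal length in seconds (= n_samples / sample_rate)."""
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


def generate_tone_complex(
    f0: float,
    n_partials: int = 10,
    duration: float = 0.05,
    sample_rate: float = 192_000.0,
    normalize: bool = False,
) -> SoundWave:
    """Harmonic tone complex y(t) = sum_m (1/m) sin(2 pi m f0 t), m = 1..n_partials.

    Parameters
    ----------
    f0 : float
        Fundamental frequency in Hz.
    n_partials : int
        Number of harmonics; partial m has amplitude 1/m.
    normalize : bool
        If True, rescale so the peak amplitude is 1 (off by default).
    """
    if not f0 > 0:
        raise ValueError("f0 must be positive")
    if n_partials < 1:
        raise ValueError("n_partials must be >= 1")
    f_top = f0 * n_partials
    if f_top >= sample_rate / 2:
        raise ValueError(
            f"partial {n_partials} at {f_top} Hz violates the Nyquist limit "
            f"{sample_rate / 2} Hz"
        )
    t = np.arange(int(round(duration * sample_rate))) / sample_rate
    y = np.zeros_like(t)
    for m in range(1, n_partials + 1):
        y += np.sin(2 * np.pi * m * f0 * t) / m
    if normalize:
        peak = np.abs(y).max()
        if peak > 0:
            y = y / peak
    return SoundWave(y, sample_rate)


def generate_song_envelope(
    n_sections: int = 8,
    section_length: float = 4.0,
    seed: int = 0,
    sample_rate: float = 192_000.0,
    f0: float = 220.0,
    n_partials: int = 8,
    contrast: float = 0.1,
    ramp_time: float = 0.25,
    beat_rate: float = 2.0,
    beat_depth: float = 0.75,
    beat_width: float = 0.02,
    f_bass: float = 35.0,
    bass_gain: float = 1.0,
) -> SoundWave:
    """Music-like test signal: harmonic carrier plus sub-bass under a
    sectional + beat envelope.

    Emulates the structure of a (hip-hop-like) song on three timescales:
    alternating loud and quiet sections (chorus/verse contrast with
    raised-cosine ramps), a percussive beat layer of short raised-cosine
    bursts at ``beat_rate`` Hz, and a sub-bass sine at ``f_bass`` Hz whose
    per-cycle peaks give the cochlear spike train a low-frequency
    periodicity, as the bass line of a real mix does. Loud sections have
    level 1, quiet sections level ``contrast``, with a small seeded jitter
    per section. The result is deterministic for a fixed seed.
    """
    if n_sections < 2:
        raise ValueError("n_sections must be >= 2")
    if not 0 <= contrast <= 1:
        raise ValueError("contrast must be in [0, 1]")
    rng = np.random.default_rng(seed)
    carrier = generate_tone_complex(
        f0,
        n_partials=n_partials,
        duration=n_sections * section_length,
        sample_rate=sample_rate,
        normalize=True,
    )
    n = carrier.n_samples
    t = carrier.times
    base = carrier.samples
    if bass_gain > 0 and f_bass > 0:
        base = base + bass_gain * np.sin(2 * np.pi * f_bass * t)
    # piecewise-constant section levels: alternate loud / quiet with jitter
    levels = np.empty(n_sections)
    for i in range(n_sections):
        lvl = 1.0 if i % 2 == 0 else contrast
        levels[i] = lvl * (1.0 + 0.1 * rng.uniform(-1, 1))
    env = levels[np.minimum((t / section_length).astype(int), n_sections - 1)]
    # smooth ramps: raised-cosine filtering of the section pattern
    if ramp_time > 0:
        m = int(ramp_time * sample_rate)
        if m >= 2:
            win = 0.5 * (1 - np.cos(2 * np.pi * np.arange(m) / (m - 1)))
            win /= win.sum()
            env = np.convolve(env, win, mode="same")
    if beat_rate > 0 and beat_depth > 0:
        phase = (t * beat_rate) % 1.0  # position within the beat, 0..1
        frac = min(1.0, beat_width * beat_rate)
        burst = np.where(
            phase < frac, 0.5 * (1 - np.cos(2 * np.pi * phase / frac)), 0.0
        )
        env = env * (1.0 - beat_depth + beat_depth * burst)
    y = base * env
    peak = np.abs(y).max()
    if peak > 0:
        y = y / peak
    return SoundWave(y, sample_rate)


def read_wav(path) -> SoundWave:
    """Read a PCM WAV file; stereo is averaged to mono, samples scaled to [-1, 1]."""
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # pragma: no cover - error text depends on scipy
        raise ValueError(f"could not read WAV file {path!r}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    data = data.astype(float)
    peak = np.abs(data).max()
    if peak > 0:
        data = data / peak
    return SoundWave(data, float(rate))


def write_wav(path, wave: SoundWave) -> None:
    """Write a SoundWave to a 16-bit PCM WAV file for inspection."""
    peak = np.abs(wave.samples).max()
    scaled = wave.samples / peak if peak > 0 else wave.samples
    wavfile.write(path, int(round(wave.sample_rate)), (scaled * 32767).astype(np.int16))


def upsample(wave: SoundWave, target_rate: float = 192_000.0) -> SoundWave:
    """Band-limited (polyphase) upsampling to ``target_rate``.

    Raises on a downsampling request; duration is preserved to within one
    sample period, and spectral content below the original Nyquist frequency
    is unchanged up to filter ripple.
    """
    if target_rate < wave.sample_rate:
        raise ValueError(
            f"target_rate {target_rate} Hz is below the current rate "
            f"{wave.sample_rate} Hz; downsampling is not supported"
        )
    if target_rate == wave.sample_rate:
        return SoundWave(wave.samples.copy(), wave.sample_rate)
    # rational resampling factors
    from fractions import Fraction

    frac = Fraction(target_rate / wave.sample_rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = resample_poly(wave.samples, up, down)
    return SoundWave(out, wave.sample_rate * up / down)
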