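"""EEG wavelet-synchronization pipeline.

Reusable implementation of the experimental analysis chain: grand averaging
over subjects and trials, Mexican-hat continuous wavelet decomposition into
nine octave-spaced frequency bands (FB1 = 125-250 Hz down to FB9 =
0.49-0.98 Hz at 500 Hz sampling), Pearson correlation of every electrode
pair within successive 1-s windows, 4-s block averaging, selection of the
25 pair series per band that track the stimulus amplitude most strongly,
and the band-wise correlation profile of those averages against the
stimulus. A synthetic EEG generator with stimulus-locked, band-specific
inter-channel correlation makes the whole chain testable without recorded
data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.signal import fftconvolve

from .synchrony import pearson

__all__ = [
    "EEGRecording",
    "BandDecomposition",
    "CorrelationDynamics",
    "BandCorrelationProfile",
    "CHANNELS_32",
    "BAND_EDGES_HZ",
    "grand_average",
    "mexican_hat",
    "octave_scales",
    "default_alpha",
    "cwt_band",
    "band_decompose",
    "windowed_correlation",
    "correlation_dynamics",
    "block_average",
    "stimulus_blocks",
    "select_top_k",
    "band_correlation_profile",
    "generate_synthetic_eeg",
]

#: standard 32-electrode 10-20 montage (Brain Products actiCAP layout)
CHANNELS_32 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8", "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
]

N_BANDS = 9

#: frequency-band edges in Hz, FB1 (highest) .. FB9 (lowest)
BAND_EDGES_HZ = [
    (125.0, 250.0), (62.5, 125.0), (31.25, 62.5), (15.63, 31.25),
    (7.81, 15.63), (3.91, 7.81), (1.95, 3.91), (0.98, 1.95), (0.49, 0.98),
]

#: Ricker peak response: f_peak = sqrt(2) / (2 pi width s) for scale s
_RICKER_PEAK = np.sqrt(2.0) / (2.0 * np.pi)


@dataclass
class EEGRecording:
    """Multichannel EEG samples: data[(n_samples, n_channels)] at 500 Hz."""

    data: np.ndarray
    sample_rate: float = 500.0
    channels: list = field(default_factory=lambda: list(CHANNELS_32))
    subject: int = 0
    trial: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_samples, n_channels)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError(
                f"data has {self.data.shape[1]} columns but "
                f"{len(self.channels)} channel names"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.data, columns=self.channels)


@dataclass
class BandDecomposition:
    """Per-channel band-filtered series: coeffs[(n_bands, n_samples, n_channels)]."""

    coeffs: np.ndarray
    valid: np.ndarray
    scales: np.ndarray
    sample_rate: float
    channels: list

    @property
    def n_bands(self) -> int:
        return self.coeffs.shape[0]


@dataclass
class CorrelationDynamics:
    """Windowed pair correlations: r[(n_bands, n_windows, n_pairs)] at 1/s."""

    r: np.ndarray
    pairs: list
    channels: list
    flagged: np.ndarray | None = None

    @property
    def n_series(self) -> int:
        return self.r.shape[0] * self.r.shape[2]


@dataclass
class BandCorrelationProfile:
    """Per-band correlation of averaged top-k synchronization dynamics with
    the stimulus, plus the all-band average's correlation."""

    per_band: np.ndarray
    overall: float
    band_means: np.ndarray
    selected_pairs: list


def grand_average(recordings) -> EEGRecording:
    """Arithmetic mean over recordings (same channels and length required)."""
    recordings = list(recordings)
    if not recordings:
        raise ValueError("need at least one recording")
    first = recordings[0]
    for rec in recordings[1:]:
        if rec.data.shape != first.data.shape:
            raise ValueError("all recordings must have the same shape")
        if rec.channels != first.channels:
            raise ValueError("all recordings must have the same channels")
    mean = np.mean([rec.data for rec in recordings], axis=0)
    return EEGRecording(mean, first.sample_rate, list(first.channels))


def mexican_hat(x, width: float = 1.0):
    """Mexican-hat (Ricker) wavelet
    psi(x) = -(2 / (pi^(1/4) sqrt(3 width))) (x^2/width^2 - 1) exp(-x^2 / (2 width^2)).

    Zero-mean with zero crossings at +-width; the central peak is positive.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    x = np.asarray(x, dtype=float)
    norm = 2.0 / (np.pi**0.25 * np.sqrt(3.0 * width))
    return -norm * (x**2 / width**2 - 1.0) * np.exp(-(x**2) / (2.0 * width**2))


def default_alpha(sample_rate: float = 500.0, width: float = 1.0) -> float:
    """Smallest wavelet scale, calibrated so the scale-alpha peak frequency
    response lands at the geometric mean of FB1 (sqrt(125*250) Hz)."""
    f1 = np.sqrt(BAND_EDGES_HZ[0][0] * BAND_EDGES_HZ[0][1])
    return _RICKER_PEAK / (width * f1)


def octave_scales(alpha: float | None = None, n_octaves: int = N_BANDS):
    """Octave-spaced wavelet scales s_oct = alpha * 2^(oct-1), oct = 1..9.

    Consecutive scales differ by exactly a factor 2, mirroring an
    equal-tempered musical octave ladder. ``alpha`` defaults to the FB1
    calibration of :func:`default_alpha` (scales in seconds).
    """
    if alpha is None:
        alpha = default_alpha()
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return alpha * 2.0 ** np.arange(n_octaves)


def cwt_band(x, scale: float, dt: float, width: float = 1.0, support: float = 5.0):
    """Continuous wavelet transform at one scale.

    w(u) = (1/sqrt(s)) * sum_k x_k psi((k - u) dt / s), computed by FFT
    convolution with zero-padded edges. Returns (coefficients, valid_mask)
    where the mask flags samples whose wavelet support lies fully inside the
    series.
    """
    x = np.asarray(x, dtype=float)
    if scale <= 0:
        raise ValueError("scale must be positive")
    half = int(np.ceil(support * width * scale / dt))
    n = x.shape[-1]
    if 2 * half + 1 > 3 * n:
        raise ValueError(
            f"scale {scale:.4g} s is too large for a series of {n} samples "
            f"at dt = {dt:.4g} s"
        )
    k = np.arange(-half, half + 1)
    kernel = mexican_hat(k * dt / scale, width)
    # enforce discrete admissibility: the sampled, truncated wavelet is not
    # exactly zero-mean, which would leak any DC offset into every band
    kernel = kernel - kernel.mean()
    w = fftconvolve(x, np.broadcast_to(kernel, x.shape[:-1] + kernel.shape), axes=-1, mode="same") / np.sqrt(scale)
    valid = np.zeros(n, dtype=bool)
    if n > 2 * half:
        valid[half : n - half] = True
    return w, valid


def band_decompose(
    rec: EEGRecording,
    alpha: float | None = None,
    width: float = 1.0,
) -> BandDecomposition:
    """Decompose every channel into the nine octave bands FB1..FB9."""
    scales = octave_scales(alpha)
    coeffs = np.empty((len(scales), rec.n_samples, rec.n_channels))
    valid = np.empty((len(scales), rec.n_samples), dtype=bool)
    dt = 1.0 / rec.sample_rate
    for b, s in enumerate(scales):
        w, v = cwt_band(rec.data.T, s, dt, width)
        coeffs[b] = w.T
        valid[b] = v
    return BandDecomposition(coeffs, valid, scales, rec.sample_rate, list(rec.channels))


def windowed_correlation(
    band_a,
    band_b,
    window_samples: int = 500,
):
    """Pearson r of two series within successive non-overlapping windows.

    Returns one value per complete window (1 value per second at 500 Hz).
    Zero-variance windows yield r = 0 and are flagged rather than NaN so
    that downstream averages stay finite.
    """
    a = np.asarray(band_a, float)
    b = np.asarray(band_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and equally long")
    n_win = a.size // window_samples
    if n_win < 1:
        raise ValueError("series shorter than one window")
    aw = a[: n_win * window_samples].reshape(n_win, window_samples)
    bw = b[: n_win * window_samples].reshape(n_win, window_samples)
    ac = aw - aw.mean(axis=1, keepdims=True)
    bc = bw - bw.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    flagged = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(flagged, 0.0, (ac * bc).sum(axis=1) / np.where(flagged, 1.0, denom))
    if flagged.any():
        warnings.warn(f"{flagged.sum()} zero-variance window(s); r set to 0")
    return r


def _all_pair_windowed_correlation(coeffs: np.ndarray, window_samples: int):
    """Windowed Pearson r for all channel pairs of one band, vectorized.

    coeffs: (n_samples, n_channels). Returns (n_windows, n_pairs) with pairs
    in ``itertools.combinations`` order.
    """
    n, c = coeffs.shape
    n_win = n // window_samples
    w = coeffs[: n_win * window_samples].reshape(n_win, window_samples, c)
    wc = w - w.mean(axis=1, keepdims=True)
    cov = np.einsum("twi,twj->tij", wc, wc)
    sd = np.sqrt(np.einsum("tii->ti", cov))
    denom = sd[:, :, None] * sd[:, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom == 0, 0.0, cov / np.where(denom == 0, 1.0, denom))
    iu, ju = np.triu_indices(c, k=1)
    return corr[:, iu, ju]


def correlation_dynamics(
    decomp: BandDecomposition, window_samples: int = 500
) -> CorrelationDynamics:
    """Windowed Pearson correlation for every electrode pair and band.

    For 32 electrodes and 9 bands this yields 32*31/2*9 = 4464 series with a
    resolution of one value per window (1 s at 500 Hz).
    """
    bands = []
    for b in range(decomp.n_bands):
        bands.append(_all_pair_windowed_correlation(decomp.coeffs[b], window_samples))
    r = np.stack(bands, axis=0)
    pairs = list(combinations(range(len(decomp.channels)), 2))
    return CorrelationDynamics(r, pairs, list(decomp.channels))


def block_average(series, block: int = 4):
    """Non-overlapping means over ``block`` consecutive values along the
    leading axis; a trailing partial block is dropped."""
    x = np.asarray(series, dtype=float)
    n_blocks = x.shape[0] // block
    if n_blocks < 1:
        raise ValueError("series shorter than one block")
    shape = (n_blocks, block) + x.shape[1:]
    return x[: n_blocks * block].reshape(shape).mean(axis=1)


def stimulus_blocks(stimulus, sample_rate: float, window_s: float = 1.0, block: int = 4):
    """Stimulus amplitude at the 4-s block resolution of the pipeline.

    The signal is rectified, averaged within successive 1-s windows, then
    block-averaged over 4 consecutive windows.
    """
    x = np.abs(np.asarray(stimulus, dtype=float))
    win = int(round(window_s * sample_rate))
    n_win = x.size // win
    if n_win < block:
        raise ValueError("stimulus shorter than one block")
    per_s = x[: n_win * win].reshape(n_win, win).mean(axis=1)
    return block_average(per_s, block)


def select_top_k(
    corr: CorrelationDynamics,
    stimulus_block_series,
    k: int = 25,
    block: int = 4,
):
    """Top-k electrode-pair series per band by correlation with the stimulus.

    Every pair series is block-averaged and ranked by its Pearson r against
    the block-averaged stimulus amplitude; the k best per band are kept
    (ties broken by pair index for determinism). Returns
    (selected pair-index lists per band, per-band mean block series,
    per-band r matrix of all pairs).
    """
    stim = np.asarray(stimulus_block_series, dtype=float)
    n_bands, n_win, n_pairs = corr.r.shape
    if k > n_pairs:
        raise ValueError(f"k = {k} exceeds the number of pairs {n_pairs}")
    # block_average works on the leading axis; put windows first
    blocked = block_average(np.moveaxis(corr.r, 1, 0), block)  # (n_blocks, n_bands, n_pairs)
    n_blocks = min(blocked.shape[0], stim.size)
    blocked = blocked[:n_blocks]
    stim = stim[:n_blocks]
    sc = stim - stim.mean()
    s_sd = np.sqrt((sc**2).sum())
    bc = blocked - blocked.mean(axis=0, keepdims=True)
    p_sd = np.sqrt((bc**2).sum(axis=0))
    num = np.einsum("tbp,t->bp", bc, sc)
    r_all = np.where(
        (p_sd == 0) | (s_sd == 0),
        0.0,
        num / np.where(p_sd == 0, 1.0, p_sd) / (s_sd if s_sd > 0 else 1.0),
    )
    selected = []
    band_means = np.empty((n_bands, n_blocks))
    for b in range(n_bands):
        order = np.lexsort((np.arange(n_pairs), -r_all[b]))
        top = np.sort(order[:k])
        selected.append(top.tolist())
        band_means[b] = blocked[:, b, top].mean(axis=1)
    return selected, band_means, r_all


def band_correlation_profile(
    rec: EEGRecording,
    stimulus,
    stimulus_rate: float,
    k: int = 25,
    alpha: float | None = None,
    width: float = 1.0,
    window_samples: int = 500,
    block: int = 4,
) -> BandCorrelationProfile:
    """Full analysis chain from an (averaged) EEG recording to the band-wise
    stimulus-correlation profile.

    Decomposes into nine octave bands, computes windowed correlations for
    every electrode pair, block-averages, selects the top-k series per band,
    and correlates each band's mean series -- and the grand mean across
    bands -- with the block-averaged stimulus amplitude.
    """
    stim = stimulus_blocks(stimulus, stimulus_rate, window_samples / rec.sample_rate, block)
    decomp = band_decompose(rec, alpha, width)
    corr = correlation_dynamics(decomp, window_samples)
    selected, band_means, _ = select_top_k(corr, stim, k, block)
    n_blocks = band_means.shape[1]
    stim = stim[:n_blocks]
    per_band = np.array([pearson(band_means[b], stim) for b in range(band_means.shape[0])])
    overall = pearson(band_means.mean(axis=0), stim)
    return BandCorrelationProfile(per_band, overall, band_means, selected)


def _pink_noise(rng, shape):
    """1/f-amplitude noise along the leading axis, unit variance."""
    n = shape[0]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=0)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if f.size > 1 else 1.0
    spec /= np.sqrt(f)[(...,) + (None,) * (len(shape) - 1)]
    pink = np.fft.irfft(spec, n=n, axis=0)
    return pink / pink.std(axis=0, keepdims=True)


def generate_synthetic_eeg(
    stimulus_envelope,
    envelope_rate: float,
    band_gain,
    n_subjects: int = 1,
    n_trials: int = 1,
    seed: int = 0,
    duration: float | None = None,
    sample_rate: float = 500.0,
    alpha: float | None = None,
    width: float = 1.0,
    noise_level: float = 0.5,
    band_noise_level: float = 1.0,
    coupling_strength: float = 1.5,
):
    """Synthetic 32-channel recordings with stimulus-locked band coupling.

    Per band b, all channels share a band-limited component whose mixing
    amplitude is modulated by the (max-normalized) stimulus envelope with
    depth ``band_gain[b]``. Every band additionally carries independent
    per-channel band-limited noise (``band_noise_level``) -- so each band
    has its own floor against which coupling must compete -- plus a weak
    broadband pink background (``noise_level``). Windowed inter-channel
    correlation in band b therefore tracks the envelope with a strength
    increasing in ``band_gain[b]``. Deterministic for a fixed seed.
    """
    env = np.asarray(stimulus_envelope, dtype=float)
    band_gain = np.asarray(band_gain, dtype=float)
    if band_gain.shape != (N_BANDS,):
        raise ValueError(f"band_gain must have {N_BANDS} entries")
    if duration is None:
        duration = env.size / envelope_rate
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    env_t = np.interp(t, np.arange(env.size) / envelope_rate, np.abs(env))
    peak = env_t.max()
    if peak > 0:
        env_t = env_t / peak
    scales = octave_scales(alpha)
    dt = 1.0 / sample_rate
    n_chan = len(CHANNELS_32)
    rng = np.random.default_rng(seed)
    recordings = []
    for subject in range(n_subjects):
        for trial in range(n_trials):
            data = noise_level * _pink_noise(rng, (n, n_chan))
            for b, s in enumerate(scales):
                # independent band-limited noise floor per channel
                floor, _ = cwt_band(rng.standard_normal((n_chan, n)), s, dt, width)
                floor_sd = floor.std(axis=-1, keepdims=True)
                floor_sd[floor_sd == 0] = 1.0
                data += band_noise_level * (floor / floor_sd).T
                if band_gain[b] == 0:
                    continue
                shared, _ = cwt_band(rng.standard_normal(n), s, dt, width)
                sd = shared.std()
                if sd > 0:
                    shared = shared / sd
                gains = 1.0 + 0.2 * rng.standard_normal(n_chan)
                mix = coupling_strength * band_gain[b] * env_t * shared
                data += mix[:, None] * gains[None, :]
            recordings.append(
                EEGRecording(data, sample_rate, list(CHANNELS_32), subject, trial)
            )
    return recordings
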