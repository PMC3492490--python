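"""Epoching, Hann-windowed zero-padded power spectra, band-ratio coordinates.

Each 5-s epoch (500 samples at 100 Hz) is multiplied by a Hann window,
zero-padded to the next power of two (512) and Fourier transformed; the
one-sided power spectrum then yields two log10 band-power ratios that place
the epoch as one point in the 2-D sleep state space. Short-term fluctuation
is removed with a running Hann-window average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window
from scipy.signal.windows import hann

from .io import Recording


@dataclass(frozen=True)
class Band:
    """A frequency band [lo, hi] in Hz, inclusive at both edges."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise ValueError(f"invalid band ({self.lo}, {self.hi}): need 0 <= lo < hi")

    def __str__(self) -> str:
        return f"{self.lo:g}-{self.hi:g} Hz"


@dataclass(frozen=True)
class BandRatioPair:
    """The four bands defining the two state-space ratios.

    Ratio1 = power(ratio1_num) / power(ratio1_den),
    Ratio2 = power(ratio2_num) / power(ratio2_den); coordinates are the
    log10 of these ratios.
    """

    ratio1_num: Band
    ratio1_den: Band
    ratio2_num: Band
    ratio2_den: Band

    def bands(self) -> tuple[Band, Band, Band, Band]:
        return (self.ratio1_num, self.ratio1_den, self.ratio2_num, self.ratio2_den)

    def edges(self) -> np.ndarray:
        """The eight band edges as a flat array (optimizer genome layout)."""
        return np.array([e for b in self.bands() for e in (b.lo, b.hi)])

    @classmethod
    def from_edges(cls, edges) -> "BandRatioPair":
        e = np.asarray(edges, dtype=float)
        if e.shape != (8,):
            raise ValueError("expected 8 band edges")
        return cls(Band(e[0], e[1]), Band(e[2], e[3]), Band(e[4], e[5]), Band(e[6], e[7]))

    def to_dict(self) -> dict:
        return {
            "ratio1_num": [self.ratio1_num.lo, self.ratio1_num.hi],
            "ratio1_den": [self.ratio1_den.lo, self.ratio1_den.hi],
            "ratio2_num": [self.ratio2_num.lo, self.ratio2_num.hi],
            "ratio2_den": [self.ratio2_den.lo, self.ratio2_den.hi],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BandRatioPair":
        return cls(**{k: Band(*v) for k, v in d.items()})


#: Optimized bands for human sleep staging (held fixed across subjects).
DEFAULT_BANDS = BandRatioPair(
    ratio1_num=Band(8.6, 19.3),
    ratio1_den=Band(1.0, 10.9),
    ratio2_num=Band(11.5, 20.3),
    ratio2_den=Band(17.9, 31.5),
)


@dataclass
class EpochSpectra:
    """One-sided power spectra, one row per epoch."""

    freqs: np.ndarray
    power: np.ndarray  # (n_epochs, n_bins), nonnegative
    epoch_length: float
    sampling_rate: float
    channel: str = ""

    @property
    def n_epochs(self) -> int:
        return self.power.shape[0]


@dataclass
class StateTrajectory:
    """Time-ordered 2-D log-ratio points for one channel."""

    channel: str
    points: np.ndarray  # (n_epochs, 2)
    epoch_length: float
    smoothing_window: int = 0


def next_pow2(n: int) -> int:
    """Smallest power of two >= n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return 1 << (n - 1).bit_length()


def epoch_signal(x: np.ndarray, sampling_rate: float, epoch_length: float) -> np.ndarray:
    """Cut a 1-D signal into non-overlapping epochs (rows); trailing
    partial epoch dropped."""
    n_per = epoch_length * sampling_rate
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError(
            f"epoch_length {epoch_length} s at {sampling_rate} Hz is not a whole "
            f"number of samples"
        )
    n_per = int(round(n_per))
    x = np.asarray(x, dtype=float)
    n_epochs = len(x) // n_per
    return x[: n_epochs * n_per].reshape(n_epochs, n_per)


def epoch_spectrum(epochs: np.ndarray, sampling_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum of Hann-windowed, zero-padded epochs.

    Parameters
    ----------
    epochs : ndarray, (n_epochs, n_samples) or (n_samples,)
    sampling_rate : float

    Returns
    -------
    freqs : ndarray, (nfft//2 + 1,)
        Bin centers, 0 .. Nyquist, resolution sampling_rate/nfft.
    power : ndarray, same leading shape as epochs
        Periodogram scaled by 1/(fs * sum(w^2)) with one-sided doubling of
        interior bins; only ratios of band sums are used downstream, so the
        convention is fixed purely for reproducibility.
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    n = epochs.shape[1]
    if n == 0:
        raise ValueError("empty epoch")
    nfft = next_pow2(n)
    w = get_window("hann", n)
    spec = np.fft.rfft(epochs * w, n=nfft, axis=1)
    power = (np.abs(spec) ** 2) / (sampling_rate * np.sum(w**2))
    power[:, 1:-1] *= 2.0  # one-sided: double all but DC and Nyquist
    freqs = np.fft.rfftfreq(nfft, d=1.0 / sampling_rate)
    return freqs, power


def compute_spectra(
    rec: Recording, channel: str, epoch_length: float = 5.0
) -> EpochSpectra:
    """Epoch one channel of a recording and compute its spectra."""
    epochs = epoch_signal(rec.channel(channel), rec.sampling_rate, epoch_length)
    freqs, power = epoch_spectrum(epochs, rec.sampling_rate) if len(epochs) else (
        np.fft.rfftfreq(next_pow2(int(epoch_length * rec.sampling_rate)),
                        1.0 / rec.sampling_rate),
        np.zeros((0, next_pow2(int(epoch_length * rec.sampling_rate)) // 2 + 1)),
    )
    return EpochSpectra(
        freqs=freqs,
        power=power,
        epoch_length=epoch_length,
        sampling_rate=rec.sampling_rate,
        channel=channel,
    )


def band_bin_mask(freqs: np.ndarray, band: Band) -> np.ndarray:
    """Boolean mask of bins whose center f satisfies lo <= f <= hi
    (inclusive at both edges)."""
    return (freqs >= band.lo) & (freqs <= band.hi)


def band_power(power: np.ndarray, freqs: np.ndarray, band: Band) -> np.ndarray:
    """Sum of spectral power over the band's bins, per epoch.

    Raises if the band contains no bin centers.
    """
    mask = band_bin_mask(freqs, band)
    if not mask.any():
        raise ValueError(f"band {band} contains no spectral bins")
    power = np.atleast_2d(power)
    return power[:, mask].sum(axis=1)


def ratio_coordinates(
    spectra: EpochSpectra, bands: BandRatioPair, normalize: bool = True
) -> np.ndarray:
    """Per-epoch state-space coordinates (log10 Ratio1, log10 Ratio2).

    With ``normalize``, each epoch's spectrum is first divided by its total
    power — analytically a no-op for the ratios, but it keeps intermediate
    magnitudes in a safe numeric range. Zero band powers are floored at
    1e-12 x (epoch total power + machine epsilon) so silent or clipped
    epochs produce large-but-finite coordinates instead of infinities.
    """
    power = np.atleast_2d(spectra.power)
    total = power.sum(axis=1)
    if normalize:
        power = power / np.where(total > 0, total, 1.0)[:, None]
        total = power.sum(axis=1)
    floor = 1e-12 * (total + np.finfo(float).eps)
    coords = np.empty((power.shape[0], 2))
    for j, (num, den) in enumerate(
        [(bands.ratio1_num, bands.ratio1_den), (bands.ratio2_num, bands.ratio2_den)]
    ):
        p_num = np.maximum(band_power(power, spectra.freqs, num), floor)
        p_den = np.maximum(band_power(power, spectra.freqs, den), floor)
        coords[:, j] = np.log10(p_num / p_den)
    return coords


def _hann_kernel(window_points: int) -> np.ndarray:
    # interior samples of a Hann window so every weight is positive
    # (the raw symmetric window has zero endpoints and degenerates at M<=2)
    k = hann(window_points + 2, sym=True)[1:-1]
    return k / k.sum()


def hann_smooth(series: np.ndarray, window_points: int) -> np.ndarray:
    """Running Hann-window average along axis 0, length-preserving.

    The kernel is normalized to unit sum; at the series edges it is
    truncated to the available support and renormalized (no padding, so no
    fabricated data at recording boundaries). A window at least as long as
    the series degenerates to the series mean everywhere.
    """
    if window_points < 1:
        raise ValueError("window_points must be >= 1")
    series = np.asarray(series, dtype=float)
    one_d = series.ndim == 1
    x = series[:, None] if one_d else series
    n = x.shape[0]
    if window_points >= n:
        out = np.tile(x.mean(axis=0), (n, 1))
        return out[:, 0] if one_d else out
    k = _hann_kernel(window_points)
    out = np.empty_like(x)
    norm = np.convolve(np.ones(n), k, mode="same")
    for c in range(x.shape[1]):
        out[:, c] = np.convolve(x[:, c], k, mode="same") / norm
    return out[:, 0] if one_d else out


def state_trajectory(
    rec: Recording,
    channel: str,
    bands: BandRatioPair = DEFAULT_BANDS,
    epoch_length: float = 5.0,
    smooth_window: int = 10,
    normalize: bool = True,
) -> StateTrajectory:
    """Full projection of one channel into the 2-D state space.

    ``smooth_window`` points of running Hann average are applied to the
    coordinate series (10 for staging, 50 for slow/fast cluster work, 0 to
    disable — laterality velocities require the unsmoothed trajectory).
    """
    spectra = compute_spectra(rec, channel, epoch_length)
    coords = ratio_coordinates(spectra, bands, normalize=normalize)
    if smooth_window and smooth_window > 1 and len(coords) > 1:
        coords = hann_smooth(coords, smooth_window)
    return StateTrajectory(
        channel=channel,
        points=coords,
        epoch_length=epoch_length,
        smoothing_window=smooth_window if smooth_window else 0,
    )
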