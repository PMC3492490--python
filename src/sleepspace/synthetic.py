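"""Seeded synthetic polysomnography with stage-dependent spectra.

Each sleep stage has a spectral template — narrowband components (white
noise through second-order resonators: alpha in WAKE, theta in NREM1,
spindle-band activity in NREM2, dominant slow-wave activity in NREM3,
low-amplitude mixed frequencies in REM) over a 1/f background. A sticky
Markov chain produces the stage sequence. Epoch-to-epoch lognormal jitter
of the component powers creates the spectral variability that state-space
velocity measures; an optional antiphase sinusoidal modulation of that
jitter between one homologous left/right channel pair injects a slow
interhemispheric velocity oscillation (of the kind the laterality module
detects) without touching raw signal amplitude.

Everything is bit-reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .io import Hypnogram, Recording, STAGES


@dataclass(frozen=True)
class StageTemplate:
    """Spectral recipe for one stage.

    components : tuple of (center Hz, bandwidth Hz, relative power)
    background : relative power of the 1/f background
    bg_exponent : spectral slope of the background (power ~ f^-exponent)
    amplitude_uv : overall RMS amplitude in microvolts (cancels in ratios;
        kept for realism of the raw traces)
    """

    components: tuple[tuple[float, float, float], ...]
    background: float
    bg_exponent: float = 1.2
    amplitude_uv: float = 30.0


#: Stage templates chosen so the default optimized band ratios separate the stages
#: (alpha-dominant WAKE, theta NREM1, spindle+weak delta NREM2,
#: delta-dominant NREM3, low-amplitude mixed-frequency REM with theta and
#: weak beta content — REM needs spectral mass in both ratio planes so that
#: jitter modulation moves both state-space coordinates).
DEFAULT_TEMPLATES: dict[str, StageTemplate] = {
    "WAKE": StageTemplate(((10.0, 1.5, 0.50), (20.0, 6.0, 0.20)), 0.30, 1.2, 30.0),
    "NREM1": StageTemplate(((5.5, 2.0, 0.50),), 0.50, 1.2, 25.0),
    "NREM2": StageTemplate(((13.0, 1.5, 0.45), (2.0, 1.5, 0.20)), 0.35, 1.2, 35.0),
    "NREM3": StageTemplate(((1.8, 1.2, 0.75),), 0.25, 1.5, 70.0),
    "REM": StageTemplate(((6.0, 3.0, 0.30), (15.0, 4.0, 0.15)), 0.55, 1.0, 20.0),
}

#: Sticky stage-transition matrix. Self-transition probability is
#: 1 - 1/L with mean bout length L in 5-s epochs (WAKE 60, NREM1 24,
#: NREM2 120, NREM3 120, REM 120); the remainder goes to physiologically
#: plausible successor stages.
DEFAULT_MEAN_BOUT_EPOCHS: dict[str, float] = {
    "WAKE": 60.0, "NREM1": 24.0, "NREM2": 120.0, "NREM3": 120.0, "REM": 120.0,
}
_SUCCESSORS: dict[str, dict[str, float]] = {
    "WAKE": {"NREM1": 1.0},
    "NREM1": {"NREM2": 0.60, "WAKE": 0.25, "REM": 0.15},
    "NREM2": {"NREM3": 0.50, "REM": 0.25, "NREM1": 0.15, "WAKE": 0.10},
    "NREM3": {"NREM2": 0.80, "WAKE": 0.20},
    "REM": {"NREM1": 0.40, "NREM2": 0.40, "WAKE": 0.20},
}


def default_transition_matrix(
    mean_bout_epochs: dict[str, float] | None = None,
) -> np.ndarray:
    """5x5 row-stochastic matrix in canonical stage order."""
    bouts = mean_bout_epochs or DEFAULT_MEAN_BOUT_EPOCHS
    mat = np.zeros((5, 5))
    for i, s in enumerate(STAGES):
        p_stay = 1.0 - 1.0 / bouts[s]
        mat[i, i] = p_stay
        for succ, w in _SUCCESSORS[s].items():
            mat[i, STAGES.index(succ)] = (1.0 - p_stay) * w
    return mat


@dataclass(frozen=True)
class Oscillation:
    """Antiphase modulation of spectral jitter between one channel pair."""

    pair: tuple[str, str] = ("C3", "C4")
    period_s: float = 48.0
    depth: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError("depth must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one synthetic subject."""

    templates: dict[str, StageTemplate] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATES)
    )
    transition: np.ndarray = field(default_factory=default_transition_matrix)
    sampling_rate: float = 100.0
    duration: float = 3600.0
    epoch_length: float = 5.0
    channels: tuple[str, ...] = ("F3", "F4", "C3", "C4", "O1", "O2")
    jitter_sigma: float = 0.5
    oscillation: Oscillation | None = None
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.transition, dtype=float)
        if t.shape != (5, 5) or np.any(t < 0):
            raise ValueError("transition must be a nonnegative 5x5 matrix")
        if np.max(np.abs(t.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("transition rows must sum to 1")
        if self.oscillation is not None:
            missing = set(self.oscillation.pair) - set(self.channels)
            if missing:
                raise ValueError(f"oscillation pair channel(s) {sorted(missing)} "
                                 f"not in channel set")

    def with_seed(self, seed: int) -> "SyntheticSpec":
        return replace(self, seed=seed)


def generate_hypnogram(spec: SyntheticSpec, n_epochs: int | None = None) -> Hypnogram:
    """Markov-chain stage sequence on the 5-s grid, starting in WAKE."""
    if n_epochs is None:
        n_epochs = int(spec.duration // spec.epoch_length)
    rng = np.random.default_rng([spec.seed, 1])
    t = np.asarray(spec.transition, dtype=float)
    cum = np.cumsum(t, axis=1)
    labels = np.empty(n_epochs, dtype=object)
    state = 0  # WAKE
    for i in range(n_epochs):
        labels[i] = STAGES[state]
        state = int(np.searchsorted(cum[state], rng.random()))
    return Hypnogram(epoch_length=spec.epoch_length, labels=labels)


def _background_epochs(rng, m: int, n: int, exponent: float) -> np.ndarray:
    """m epochs of unit-RMS 1/f^exponent noise, length n each."""
    n_bins = n // 2 + 1
    freqs = np.fft.rfftfreq(n, d=1.0)  # shape only; absolute scale irrelevant
    shape = (freqs + freqs[1]) ** (-exponent / 2.0)
    spec = (rng.standard_normal((m, n_bins)) + 1j * rng.standard_normal((m, n_bins)))
    spec *= shape
    x = np.fft.irfft(spec, n=n, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x / np.where(rms > 0, rms, 1.0)


def _resonator_epochs(rng, m: int, n: int, f0: float, bw: float, fs: float) -> np.ndarray:
    """m epochs of unit-RMS narrowband noise centered at f0."""
    b, a = sps.iirpeak(f0, Q=max(f0 / bw, 0.5), fs=fs)
    x = sps.lfilter(b, a, rng.standard_normal((m, n)), axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x / np.where(rms > 0, rms, 1.0)


def generate_recording(spec: SyntheticSpec, hypnogram: Hypnogram) -> Recording:
    """Render a multichannel recording for a stage sequence.

    Per epoch and channel the signal is a sum of the stage template's
    resonator components and 1/f background, each component's power
    multiplied by an independent lognormal jitter exp(sigma * g). Left and
    right homologous channels share templates. If an oscillation is
    configured, the jitter scale sigma of the two target channels is
    modulated in antiphase, sigma * (1 +/- depth * sin(2 pi t / period)) —
    modulating spectral *variability*, hence state-space velocity, not raw
    power.
    """
    fs = spec.sampling_rate
    n_per = int(round(spec.epoch_length * fs))
    if abs(spec.epoch_length * fs - n_per) > 1e-9:
        raise ValueError("epoch_length x sampling_rate must be integer")
    n_epochs = len(hypnogram)
    labels = hypnogram.labels
    rng = np.random.default_rng([spec.seed, 2])

    t_epoch = np.arange(n_epochs) * spec.epoch_length
    sigma = np.full((len(spec.channels), n_epochs), spec.jitter_sigma)
    if spec.oscillation is not None:
        osc = spec.oscillation
        mod = osc.depth * np.sin(2 * np.pi * t_epoch / osc.period_s)
        left, right = osc.pair
        sigma[spec.channels.index(left)] *= 1.0 - mod
        sigma[spec.channels.index(right)] *= 1.0 + mod

    signal = np.zeros((len(spec.channels), n_epochs * n_per))
    for stage in STAGES:
        idx = np.flatnonzero(labels == stage)
        if len(idx) == 0:
            continue
        tmpl = spec.templates[stage]
        m = len(idx)
        for ci in range(len(spec.channels)):
            parts = np.zeros((m, n_per))
            for f0, bw, p in tmpl.components:
                comp = _resonator_epochs(rng, m, n_per, f0, bw, fs)
                gain = np.sqrt(p) * np.exp(sigma[ci, idx] * rng.standard_normal(m))
                parts += comp * gain[:, None]
            bg = _background_epochs(rng, m, n_per, tmpl.bg_exponent)
            gain = np.sqrt(tmpl.background) * np.exp(
                sigma[ci, idx] * rng.standard_normal(m)
            )
            parts += bg * gain[:, None]
            rms = np.sqrt(np.mean(parts**2))
            parts *= tmpl.amplitude_uv / max(rms, 1e-12)
            flat = signal[ci].reshape(n_epochs, n_per)
            flat[idx] = parts
    return Recording(
        channel_labels=list(spec.channels), sampling_rate=fs, signal=signal
    )


def make_cohort(
    n_subjects: int,
    duration: float = 3600.0,
    seed: int = 0,
    spec: SyntheticSpec | None = None,
) -> list[tuple[Recording, Hypnogram]]:
    """Generate a cohort of independent synthetic subjects.

    Subject k uses seed ``seed + k`` on a shared spec.
    """
    base = spec if spec is not None else SyntheticSpec(duration=duration)
    base = replace(base, duration=duration)
    out = []
    for k in range(n_subjects):
        s = base.with_seed(seed + k)
        h = generate_hypnogram(s)
        out.append((generate_recording(s, h), h))
    return out


# ---------------------------------------------------------------------------
# laterality null and sinusoid models


def rayleigh_null(n: int, seed: int = 0) -> np.ndarray:
    """Uncorrelated laterality series: two independent Rayleigh velocity
    draws per epoch, combined by the laterality score. Mirrors the random
    model used to show that white velocities yield no oscillating ACF."""
    from .laterality import laterality_score

    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    v_left = rng.rayleigh(1.0, n)
    v_right = rng.rayleigh(1.0, n)
    return laterality_score(v_left, v_right)


def modulated_rayleigh_laterality(
    n: int,
    period_s: float,
    depth: float,
    seed: int = 0,
    epoch_length: float = 5.0,
) -> np.ndarray:
    """Laterality with an injected interhemispheric velocity oscillation.

    Left/right velocities are Rayleigh draws whose scales are modulated in
    antiphase, (1 -/+ depth * sin(2 pi t / period)); the laterality score of
    the pair then oscillates with amplitude ~ depth on top of the Rayleigh
    null fluctuation.
    """
    from .laterality import laterality_score

    if not 0.0 <= depth <= 1.0:
        raise ValueError("depth must be in [0, 1]")
    rng = np.random.default_rng(seed)
    t = np.arange(n) * epoch_length
    mod = depth * np.sin(2 * np.pi * t / period_s)
    v_left = (1.0 - mod) * rng.rayleigh(1.0, n)
    v_right = (1.0 + mod) * rng.rayleigh(1.0, n)
    return laterality_score(v_left, v_right)


def sinusoid_model(
    n: int,
    period_s: float,
    noise_amplitude: float = 0.3,
    seed: int = 0,
    epoch_length: float = 5.0,
) -> np.ndarray:
    """Sinusoidal laterality with uniform noise, clipped to [-1, 1]."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    t = np.arange(n) * epoch_length
    x = np.sin(2 * np.pi * t / period_s)
    x = x + rng.uniform(-noise_amplitude, noise_amplitude, n)
    return np.clip(x, -1.0, 1.0)
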