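"""Seed-reproducible synthetic single-lead ECG with two labelled classes.

Each beat is a sum of five Gaussian deflections (P, Q, R, S, T) placed at
R-peak times drawn from a lognormal RR-interval distribution. The
``pre_af_like`` class differs from ``non_af_like`` in two qualitative ways
that mirror AF physiology: a much larger RR coefficient of variation
(irregular ventricular response) and an attenuated P wave (impaired atrial
depolarisation). Signals are optionally contaminated with the three
classic ECG noise sources: sinusoidal baseline drift, sinusoidal powerline
interference, and high-passed white noise emulating muscle artifact.

The generator is test scaffolding for the downstream pipeline; it makes no
claim of clinical fidelity (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import log, sqrt

import numpy as np
from scipy.signal import butter, sosfiltfilt

from rpaf.ecg import ECGSignal, ParameterError

__all__ = [
    "BeatTemplate",
    "RhythmSpec",
    "NoiseSpec",
    "generate_ecg",
    "generate_dataset",
    "PRE_AF_RHYTHM",
    "NON_AF_RHYTHM",
]

# (amplitude mV, center offset s relative to R peak, width s)
_DEFAULT_WAVES = {
    "P": (0.15, -0.20, 0.025),
    "Q": (-0.10, -0.035, 0.010),
    "R": (1.00, 0.00, 0.012),
    "S": (-0.15, 0.035, 0.010),
    "T": (0.30, 0.25, 0.055),
}


@dataclass
class BeatTemplate:
    """Sum-of-Gaussians beat morphology.

    ``waves`` maps deflection name to (amplitude mV, center offset s
    relative to the R peak, Gaussian width s).
    """

    waves: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_WAVES)
    )
    p_scale: float = 1.0  # extra multiplier on the P-wave amplitude

    def __post_init__(self) -> None:
        if "R" not in self.waves or self.waves["R"][0] <= 0:
            raise ParameterError("template needs an R deflection with amplitude > 0")
        for name, (_, _, width) in self.waves.items():
            if width <= 0:
                raise ParameterError(f"wave {name!r} width must be > 0")
        if self.p_scale < 0:
            raise ParameterError("p_scale must be >= 0")

    @property
    def extent(self) -> float:
        """Half-width of the template in seconds (3 sigma past extreme centers)."""
        return max(abs(c) + 3 * w for _, c, w in self.waves.values())


@dataclass
class RhythmSpec:
    """Heart rate, RR variability and class identity of a generated signal."""

    heart_rate: float = 75.0  # beats/min
    rr_cv: float = 0.05  # coefficient of variation of RR intervals
    label: str = "non_af_like"

    def __post_init__(self) -> None:
        if not 30.0 <= self.heart_rate <= 220.0:
            raise ParameterError("heart rate must be within [30, 220] bpm")
        if self.rr_cv < 0:
            raise ParameterError("rr_cv must be >= 0")
        if self.label not in ("pre_af_like", "non_af_like"):
            raise ParameterError(f"unknown class label {self.label!r}")


# default stated world: same mean rate, irregularity + P attenuation set the
# classes apart; pre_af_like CV is strictly larger by construction
NON_AF_RHYTHM = RhythmSpec(heart_rate=75.0, rr_cv=0.05, label="non_af_like")
PRE_AF_RHYTHM = RhythmSpec(heart_rate=75.0, rr_cv=0.30, label="pre_af_like")
_PRE_AF_P_SCALE = 0.3


@dataclass
class NoiseSpec:
    """Amplitudes/frequencies of the three contaminating noise sources."""

    drift_amplitude: float = 0.2  # mV
    drift_frequency: float = 0.25  # Hz, must stay below 0.5
    powerline_amplitude: float = 0.05  # mV
    powerline_frequency: float = 50.0  # Hz
    muscle_sigma: float = 0.05  # mV
    muscle_corner: float = 45.0  # high-pass corner, Hz

    def __post_init__(self) -> None:
        for name in ("drift_amplitude", "powerline_amplitude", "muscle_sigma"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not self.drift_frequency < 0.5:
            raise ParameterError("drift frequency must be < 0.5 Hz")
        if not self.muscle_corner > 40.0:
            raise ParameterError("muscle band must start above 40 Hz")

    @classmethod
    def silent(cls) -> "NoiseSpec":
        return cls(drift_amplitude=0.0, powerline_amplitude=0.0, muscle_sigma=0.0)


def _rr_intervals(rhythm: RhythmSpec, total: float, rng: np.random.Generator) -> np.ndarray:
    """Lognormal RR draws with the requested mean and CV, covering ``total`` s."""
    mean_rr = 60.0 / rhythm.heart_rate
    n_draw = int(np.ceil(total / mean_rr)) + 8
    if rhythm.rr_cv == 0:
        return np.full(n_draw, mean_rr)
    s2 = log(1.0 + rhythm.rr_cv**2)
    mu = log(mean_rr) - s2 / 2.0
    return rng.lognormal(mean=mu, sigma=sqrt(s2), size=n_draw)


def generate_ecg(
    rhythm: RhythmSpec,
    template: BeatTemplate | None = None,
    noise: NoiseSpec | None = None,
    duration: float = 10.0,
    fs: float = 500.0,
    seed: int = 0,
) -> ECGSignal:
    """Generate one synthetic single-lead ECG segment.

    Identical arguments (including ``seed``) reproduce the output
    bit-for-bit. With an all-zero :class:`NoiseSpec` the result is the
    clean beat train.
    """
    if not duration > 0:
        raise ParameterError("duration must be > 0")
    if not fs >= 100:
        raise ParameterError("fs must be >= 100 Hz")
    template = template or BeatTemplate()
    noise = noise if noise is not None else NoiseSpec()
    if template.extent >= 60.0 / rhythm.heart_rate:
        raise ParameterError("beat template wider than the minimum RR interval")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    rr = _rr_intervals(rhythm, duration + 2.0, rng)
    r_times = rr[0] / 2.0 + np.concatenate([[0.0], np.cumsum(rr[:-1])])
    r_times = r_times[r_times < duration + template.extent]

    p_scale = template.p_scale * (_PRE_AF_P_SCALE if rhythm.label == "pre_af_like" else 1.0)
    x = np.zeros(n)
    for name, (amp, center, width) in template.waves.items():
        if name == "P":
            amp = amp * p_scale
        for rt in r_times:
            c = rt + center
            lo = max(0, int((c - 4 * width) * fs))
            hi = min(n, int((c + 4 * width) * fs) + 1)
            if hi > lo:
                x[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - c) / width) ** 2)

    if noise.drift_amplitude > 0:
        x += noise.drift_amplitude * np.sin(
            2 * np.pi * noise.drift_frequency * t + rng.uniform(0, 2 * np.pi)
        )
    if noise.powerline_amplitude > 0:
        x += noise.powerline_amplitude * np.sin(
            2 * np.pi * noise.powerline_frequency * t + rng.uniform(0, 2 * np.pi)
        )
    if noise.muscle_sigma > 0:
        white = rng.normal(0.0, noise.muscle_sigma, n)
        corner = min(noise.muscle_corner, 0.95 * fs / 2.0)
        sos = butter(4, corner, btype="highpass", fs=fs, output="sos")
        x += sosfiltfilt(sos, white)

    label = 1 if rhythm.label == "pre_af_like" else 0
    return ECGSignal(
        samples=x, fs=fs, record_id=f"sim-{rhythm.label}-{seed}", lead="I",
        label=label, meta={"seed": seed, "rhythm": rhythm},
    )


def generate_dataset(
    n_per_class: int,
    duration: float = 10.0,
    fs: float = 500.0,
    seed: int = 0,
    noise: NoiseSpec | None = None,
) -> list[ECGSignal]:
    """Balanced labelled collection; per-signal seeds derive from ``seed``.

    Returns ``2 * n_per_class`` signals, non-AF-like first.
    """
    if n_per_class < 1:
        raise ParameterError("n_per_class must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_per_class) % (2**31)
    signals: list[ECGSignal] = []
    for cls_idx, rhythm in enumerate((NON_AF_RHYTHM, PRE_AF_RHYTHM)):
        for i in range(n_per_class):
            s = int(child_seeds[cls_idx * n_per_class + i])
            sig = generate_ecg(rhythm, noise=noise, duration=duration, fs=fs, seed=s)
            sig = replace(sig, record_id=f"sim-{rhythm.label}-{i:04d}")
            signals.append(sig)
    return signals
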