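"""Synthetic multichannel EEG generator emulating a 5-mental-task protocol.

Real cue-based mental-task recordings (word association, subtraction,
navigation, hand and feet motor imagery) are not redistributable, so the
package ships a generator that emulates their *structure*: 30 channels at
256 Hz, 10-s trials with the imagery period starting at the 3-s cue, one
class-specific oscillatory signature per task, 1/f^beta background noise,
and optional spike/blink artifacts.  The class signatures are stand-ins —
disjoint narrow bands with distinct spatial mixing patterns — chosen so
that class separability is controllable, not to imitate true task
physiology.

Every draw is routed through one seeded :class:`numpy.random.Generator`,
so a configuration plus a seed fully determines the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import Recording, TrialSet

__all__ = [
    "ClassSpec",
    "GeneratorConfig",
    "ArtifactSpec",
    "default_class_specs",
    "generate_dataset",
    "generate_recording",
    "inject_artifacts",
    "pink_noise",
]

#: Default band centers (Hz) for the five stand-in task signatures.
DEFAULT_BAND_CENTERS = (6.0, 10.0, 14.0, 20.0, 26.0)


@dataclass
class ClassSpec:
    """Oscillatory signature of one synthetic task class.

    The class signal is band-limited noise centred on ``band_center``
    with an ``am_rate`` sinusoidal amplitude modulation, mixed into the
    montage by ``spatial_pattern`` (nonnegative per-channel weights).
    """

    class_id: int
    band_center: float  # Hz
    band_width: float  # Hz
    spatial_pattern: np.ndarray
    amplitude: float = 5.0  # µV RMS on the strongest channel
    am_rate: float = 1.0  # Hz

    def __post_init__(self) -> None:
        self.spatial_pattern = np.asarray(self.spatial_pattern, dtype=float)
        if self.band_center - self.band_width / 2 <= 0:
            raise ValueError("band must stay above 0 Hz")
        if not (self.spatial_pattern > 0).any():
            raise ValueError("spatial_pattern needs at least one positive weight")
        if (self.spatial_pattern < 0).any():
            raise ValueError("spatial_pattern weights must be nonnegative")


@dataclass
class GeneratorConfig:
    """Stated world of the synthetic protocol.

    Defaults mirror the acquisition the package emulates: 30 channels,
    256 Hz, 10-s trials, imagery from the 3-s cue, five classes, and
    pink (1/f) background noise at 10 µV RMS — a typical resting EEG
    amplitude scale.
    """

    class_specs: list[ClassSpec] = field(default_factory=list)
    n_trials_per_class: int = 40
    fs: float = 256.0
    trial_len: float = 10.0
    cue_time: float = 3.0
    n_channels: int = 30
    noise_exponent: float = 1.0
    noise_amplitude: float = 10.0  # µV RMS per channel
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.class_specs:
            self.class_specs = default_class_specs(self.n_channels, self.fs)
        if len(self.class_specs) < 2:
            raise ValueError("need at least two classes")
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be nonnegative")
        nyq = self.fs / 2
        for cs in self.class_specs:
            if cs.band_center + cs.band_width / 2 >= nyq:
                raise ValueError(
                    f"class {cs.class_id} band reaches the Nyquist frequency"
                )
            if len(cs.spatial_pattern) != self.n_channels:
                raise ValueError("spatial_pattern length must equal n_channels")


@dataclass
class ArtifactSpec:
    """Parametric template for injected artifacts.

    ``spike``: a one-channel exponentially decaying transient (electrode
    glitch).  ``blink``: a half-sine deflection across the affected
    (frontal) channels.  Event times follow a homogeneous Poisson process
    at ``rate`` events per minute.
    """

    kind: str = "spike"  # {"spike", "blink"}
    rate: float = 6.0  # events / min
    amplitude: float = 200.0  # µV
    duration: float = 0.3  # s
    affected_channels: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("spike", "blink"):
            raise ValueError("kind must be 'spike' or 'blink'")
        if self.rate < 0:
            raise ValueError("rate must be nonnegative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def default_class_specs(n_channels: int, fs: float,
                        amplitude: float = 5.0) -> list[ClassSpec]:
    """Five disjoint-band signatures with smooth, distinct spatial bumps."""
    specs = []
    idx = np.arange(n_channels)
    for k, center in enumerate(DEFAULT_BAND_CENTERS, start=1):
        # Gaussian bump of mixing weights centred on a class-specific site
        loc = (k - 0.5) * n_channels / len(DEFAULT_BAND_CENTERS)
        pattern = np.exp(-0.5 * ((idx - loc) / (n_channels / 8)) ** 2)
        specs.append(
            ClassSpec(
                class_id=k,
                band_center=center,
                band_width=2.0,
                spatial_pattern=pattern,
                amplitude=amplitude,
                am_rate=1.0,
            )
        )
    return specs


def pink_noise(n_samples: int, fs: float, exponent: float,
               rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent noise by spectral shaping of white Gaussian noise, unit RMS."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC drift
    x = np.fft.irfft(spec * shaping, n=n_samples)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def _band_limited_oscillation(n_samples: int, fs: float, center: float,
                              width: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS narrowband rhythm: a sinusoid whose frequency is drawn
    uniformly within the class band per trial, with random phase.

    A tonal carrier (rather than band-filtered noise) keeps the per-trial
    band energy stable, so within-class feature variability is governed by
    the background-noise amplitude — the generator's separability dial.
    """
    t = np.arange(n_samples) / fs
    f = rng.uniform(center - width / 2, center + width / 2)
    phase = rng.uniform(0, 2 * np.pi)
    x = np.sin(2 * np.pi * f * t + phase)
    return x / np.sqrt(np.mean(x ** 2))


def _class_trial(cs: ClassSpec, cfg: GeneratorConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """One (window_samples, n_channels) trial: signal from cue onward + noise."""
    n_samples = int(round(cfg.trial_len * cfg.fs))
    cue_sample = int(round(cfg.cue_time * cfg.fs))
    t = np.arange(n_samples) / cfg.fs

    source = _band_limited_oscillation(n_samples, cfg.fs, cs.band_center,
                                       cs.band_width, rng)
    phase = rng.uniform(0, 2 * np.pi)
    envelope = 1.0 + 0.5 * np.sin(2 * np.pi * cs.am_rate * t + phase)
    gate = np.zeros(n_samples)
    gate[cue_sample:] = 1.0
    source = source * envelope * gate

    pattern = cs.spatial_pattern / cs.spatial_pattern.max()
    trial = cs.amplitude * np.outer(source, pattern)
    if cfg.noise_amplitude > 0:
        for ch in range(cfg.n_channels):
            trial[:, ch] += cfg.noise_amplitude * pink_noise(
                n_samples, cfg.fs, cfg.noise_exponent, rng
            )
    return trial


def generate_dataset(cfg: GeneratorConfig) -> TrialSet:
    """Draw ``K * n_trials_per_class`` labeled trials, grouped by class.

    Deterministic given ``cfg.seed``; trial order is class 1 block first,
    then class 2, etc. (shuffling, when needed, is the caller's concern —
    the one-vs-rest splitter draws by label anyway).
    """
    rng = np.random.default_rng(cfg.seed)
    trials = []
    for cs in cfg.class_specs:
        for _ in range(cfg.n_trials_per_class):
            trials.append((_class_trial(cs, cfg, rng), cs.class_id))
    return TrialSet(trials, cfg.fs, (0.0, cfg.trial_len))


def generate_recording(cfg: GeneratorConfig, rng=None) -> Recording:
    """Concatenate one round of per-class trials into a continuous marked recording.

    Useful for exercising recording-level stages (artifact marking, MWF);
    markers land at each trial onset.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_trial = int(round(cfg.trial_len * cfg.fs))
    blocks, markers = [], []
    pos = 0
    for cs in cfg.class_specs:
        blocks.append(_class_trial(cs, cfg, rng))
        markers.append((pos, cs.class_id))
        pos += n_trial
    labels = [f"ch{i:02d}" for i in range(cfg.n_channels)]
    return Recording(np.vstack(blocks), cfg.fs, labels, markers)


def inject_artifacts(rec: Recording, spec: ArtifactSpec,
                     seed: int = 0) -> tuple[Recording, np.ndarray]:
    """Add Poisson-arriving artifact events; return the dirty recording and a mask.

    The boolean mask marks exactly the support of injected events; clean
    samples are bitwise unchanged.
    """
    n_dur = int(round(spec.duration * rec.fs))
    if n_dur < 1:
        raise ValueError("artifact duration is shorter than one sample")
    rng = np.random.default_rng(seed)
    data = rec.data.copy()
    mask = np.zeros(rec.n_samples, dtype=bool)

    n_events = rng.poisson(spec.rate * rec.duration / 60.0)
    if spec.affected_channels is None:
        frontal = tuple(range(min(3, rec.n_channels)))
    else:
        frontal = tuple(spec.affected_channels)

    for _ in range(n_events):
        onset = int(rng.integers(0, max(1, rec.n_samples - n_dur)))
        sl = slice(onset, onset + n_dur)
        t = np.arange(n_dur)
        if spec.kind == "spike":
            channel = int(rng.choice(frontal))
            template = spec.amplitude * np.exp(-t / max(1.0, n_dur / 5.0))
            data[sl, channel] += template * (1 if rng.random() < 0.5 else -1)
        else:  # blink: half-sine across frontal channels
            template = spec.amplitude * np.sin(np.pi * t / n_dur)
            for channel in frontal:
                data[sl, channel] += template
        mask[sl] = True

    dirty = Recording(data, rec.fs, list(rec.channel_labels),
                      list(rec.markers) if rec.markers else None)
    return dirty, mask
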