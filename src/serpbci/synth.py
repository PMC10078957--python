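"""Synthetic continuous EEG with schedule-locked somatosensory responses.

Human recordings for this paradigm are not publicly deposited, so the test
bed is a generative model of what the amplifier would record: each
electrotactile pulse evokes a transient somatosensory potential (P1/N1/P3
lobes) on the five scalp channels with contralateral dominance, attention
multiplies the attended site's response amplitude, 1/f background noise
runs on every channel, and eye blinks contaminate Fp1 (with small scaled
copies on the scalp).  Every stochastic element is driven by one seed.

Default response morphology: P1 +2 uV at 50 ms, N1 -4 uV at 120 ms,
P3 +3 uV at 280 ms (Gaussian lobes of width 15/25/60 ms) — a conventional
transient SEP shape; the published waveforms are shown but not
parameterized, so these are package conventions, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .protocol import RATE_HZ, Location, StimulusSchedule

SCALP_CHANNELS = ("C3", "Cz", "C4", "CP3", "Pz")
EOG_CHANNEL = "Fp1"
CHANNELS = SCALP_CHANNELS + (EOG_CHANNEL,)

#: stimulus-locked epoch geometry: 100 ms baseline + 400 ms post-stimulus
PRE_SAMPLES = 120
POST_SAMPLES = 480
EPOCH_SAMPLES = PRE_SAMPLES + POST_SAMPLES

# contralateral dominance for right-forearm stimulation; Fp1 carries no SEP
DEFAULT_GAIN_MAP = {"C3": 1.0, "CP3": 1.0, "Cz": 0.8, "Pz": 0.6, "C4": 0.4}

# blink propagation from the frontopolar site to the scalp montage
BLINK_WEIGHTS = {"Fp1": 1.0, "C3": 0.15, "Cz": 0.2, "C4": 0.15, "CP3": 0.1, "Pz": 0.05}

__all__ = [
    "SCALP_CHANNELS",
    "EOG_CHANNEL",
    "CHANNELS",
    "PRE_SAMPLES",
    "POST_SAMPLES",
    "EPOCH_SAMPLES",
    "SepTemplate",
    "SubjectModel",
    "Recording",
    "render_template",
    "pink_noise",
    "simulate_recording",
    "inject_blinks",
]


@dataclass(frozen=True)
class SepTemplate:
    """Sum of Gaussian-windowed component lobes, zero before the stimulus.

    ``components`` is a list of (label, latency_ms, width_ms, amplitude_uV);
    amplitudes are signed (negative for N1).  ``gain_map`` scales the
    template per scalp channel.
    """

    components: tuple[tuple[str, float, float, float], ...] = (
        ("P1", 50.0, 15.0, 2.0),
        ("N1", 120.0, 25.0, -4.0),
        ("P3", 280.0, 60.0, 3.0),
    )
    gain_map: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GAIN_MAP))

    def validate(self) -> None:
        for label, lat, width, _amp in self.components:
            if width <= 0:
                raise ValueError(f"component {label}: width must be > 0")
            if not (0.0 <= lat <= 400.0):
                raise ValueError(
                    f"component {label}: latency {lat} ms outside the 0-400 ms window"
                )


def render_template(
    template: SepTemplate, rate_hz: float = RATE_HZ, n_post: int = POST_SAMPLES
) -> np.ndarray:
    """Evaluate a template on the post-stimulus grid (t >= 0).

    Returns ``n_post`` samples; the implied pre-stimulus part is zero by
    construction (components live in 0-400 ms and are windowed to t >= 0).
    """
    template.validate()
    t_ms = np.arange(n_post) / rate_hz * 1000.0
    wave = np.zeros(n_post)
    for _label, lat, width, amp in template.components:
        wave += amp * np.exp(-0.5 * ((t_ms - lat) / width) ** 2)
    return wave


def pink_noise(
    rng: np.random.Generator, n_samples: int, sd_uV: float, exponent: float = 1.0
) -> np.ndarray:
    """1/f^exponent noise via spectral shaping, scaled to the target sd."""
    if sd_uV == 0 or n_samples == 0:
        return np.zeros(n_samples)
    white = rng.standard_normal(n_samples)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spectrum * shaping, n=n_samples)
    return shaped * (sd_uV / shaped.std())


def _blink_kernel(rate_hz: float, duration_ms: float = 300.0) -> np.ndarray:
    n = int(round(duration_ms / 1000.0 * rate_hz))
    # smooth positive deflection (Hann lobe), peak 1
    return np.hanning(n)


@dataclass(frozen=True)
class SubjectModel:
    """Generative model of one subject's evoked responses and noise."""

    template_D: SepTemplate = field(default_factory=SepTemplate)
    template_V: SepTemplate = field(default_factory=SepTemplate)
    attention_gain: float = 1.5
    noise_sd_uV: float = 10.0
    pink_exponent: float = 1.0
    blink_rate_hz: float = 0.2
    blink_amp_uV: float = 120.0
    seed: int = 0

    def validate(self) -> None:
        if self.attention_gain < 0:
            raise ValueError("attention_gain must be >= 0")
        if self.noise_sd_uV < 0:
            raise ValueError("noise_sd_uV must be >= 0")
        self.template_D.validate()
        self.template_V.validate()


@dataclass
class Recording:
    """Continuous multi-channel EEG in microvolts with its event table."""

    data: np.ndarray  # channels x samples, uV
    rate_hz: float
    channel_labels: tuple[str, ...]
    events: StimulusSchedule

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data rows must match channel_labels")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]


def simulate_recording(
    schedule: StimulusSchedule,
    subject: SubjectModel | None = None,
    tail_s: float = 2.0,
) -> Recording:
    """Render a schedule into a continuous 6-channel recording.

    For every event the stimulated site's template — multiplied by
    ``attention_gain`` when the site is the attended one — is added at the
    event onset on the scalp channels according to the template's gain map;
    pink noise is then added to all channels and blinks injected at Poisson
    times.  Deterministic given ``subject.seed``.
    """
    subject = subject or SubjectModel()
    subject.validate()
    rate = schedule.config.rate_hz
    onsets = schedule.onsets()
    n_samples = int(onsets[-1] + POST_SAMPLES + round(tail_s * rate))
    data = np.zeros((len(CHANNELS), n_samples))

    waves = {
        Location.D: render_template(subject.template_D, rate),
        Location.V: render_template(subject.template_V, rate),
    }
    templates = {Location.D: subject.template_D, Location.V: subject.template_V}

    for event in schedule.events:
        wave = waves[event.location]
        gain_map = templates[event.location].gain_map
        scale = subject.attention_gain if event.location is event.attended_location else 1.0
        sl = slice(event.onset_sample, event.onset_sample + POST_SAMPLES)
        for ci, ch in enumerate(CHANNELS):
            g = gain_map.get(ch, 0.0)
            if g:
                data[ci, sl] += scale * g * wave

    rng = np.random.default_rng(subject.seed)
    if subject.noise_sd_uV > 0:
        for ci in range(len(CHANNELS)):
            data[ci] += pink_noise(rng, n_samples, subject.noise_sd_uV, subject.pink_exponent)

    rec = Recording(data, rate, CHANNELS, schedule)
    if subject.blink_rate_hz > 0:
        rec, _ = inject_blinks(
            rec, subject.blink_rate_hz, subject.blink_amp_uV, rng=rng
        )
    return rec


def inject_blinks(
    recording: Recording,
    rate_hz: float,
    amp_uV: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Recording, np.ndarray]:
    """Add Poisson-timed blink artifacts in place; returns (recording, onset samples).

    Each blink is a smooth ~300 ms positive deflection of peak ``amp_uV``
    on Fp1 with fixed scaled copies on the scalp channels.
    """
    if amp_uV <= 0:
        raise ValueError("amp_uV must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    if rate_hz == 0:
        return recording, np.array([], dtype=np.int64)
    duration_s = recording.n_samples / recording.rate_hz
    n_blinks = rng.poisson(rate_hz * duration_s)
    kernel = _blink_kernel(recording.rate_hz)
    max_start = recording.n_samples - len(kernel)
    starts = np.sort(rng.integers(0, max(1, max_start), size=n_blinks))
    for start in starts:
        sl = slice(int(start), int(start) + len(kernel))
        for ci, ch in enumerate(recording.channel_labels):
            w = BLINK_WEIGHTS.get(ch, 0.0)
            if w:
                recording.data[ci, sl] += amp_uV * w * kernel
    return recording, starts.astype(np.int64)
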