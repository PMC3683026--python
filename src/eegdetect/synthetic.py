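"""Seeded synthetic multichannel EEG with labeled spikes and seizures.

The generator emulates the statistical and spatial structure the detector
assumes, so the whole pipeline is testable without clinical recordings:

* background: 1/f-weighted noise band-limited to 0.1-70 Hz plus a per-channel
  alpha-range oscillation, with a shared common-mode component giving
  realistic inter-channel correlation; amplitudes are clipped just below the
  100 uV artifact-rejection threshold;
* interictal spikes and sharp waves: a biphasic derivative-of-Gaussian
  transient (width = full duration at 10% amplitude, 20-200 ms) at a focus
  electrode, with a potential field decaying by 0.5 per hop over the scalp
  adjacency graph -- in a bipolar montage this peaked field produces
  opposite-signed deflections on the chain channels flanking the focus
  (a phase reversal);
* electrographic seizures: an amplitude-modulated rhythm plus harmonic whose
  envelope increases linearly over the interval, spreading to neighbouring
  electrodes with a per-hop delay.

All randomness flows from the config seed; identical configs produce
bit-identical recordings and ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .montage import DEFAULT_UNIPOLAR, INTERIOR_ELECTRODES, electrode_hops
from .preprocess import EPOCH_SECONDS, EegRecording

CLASSES = ("normal", "spike", "seizure")

#: Spatial decay of the potential field per hop on the scalp adjacency graph.
FIELD_DECAY_PER_HOP = 0.5

# Half-support of the unit derivative-of-Gaussian kernel, in units of sigma:
# the solution u of u*exp(-u^2/2) = 0.1*exp(-1/2), so that the full duration
# at 10% of peak amplitude equals 2*u*sigma.
_DOG_HALF_SUPPORT = brentq(
    lambda u: u * np.exp(-(u ** 2) / 2.0) - 0.1 * np.exp(-0.5), 1.0, 10.0
)


class DomainError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Simulation conditions for the reference 16-channel, 200 Hz setup.

    Amplitudes are standard deviations / peak values in uV.  The defaults
    describe a low-voltage adult background (8 uV RMS per channel, half of
    the variance common across channels) with 60 uV spikes of 50 ms and
    30 uV rhythmic seizures at 5 Hz, all well below the 100 uV
    artifact-rejection ceiling.
    """

    n_channels: int = 16
    fs: float = 200.0
    duration_s: float = 20.0
    seed: int = 0
    background_amp_uv: float = 8.0
    spike_rate_per_min: float = 6.0
    spike_focus_channel: str = "T3"
    spike_width_ms: float = 50.0
    spike_amp_uv: float = 60.0
    seizure_intervals: tuple[tuple[float, float], ...] = ()
    seizure_rhythm_hz: float = 5.0
    seizure_amp_uv: float = 30.0
    spatial_correlation: float = 0.5
    alpha_hz: float = 10.0
    channels: tuple[str, ...] = DEFAULT_UNIPOLAR

    def __post_init__(self) -> None:
        if self.fs <= 2 * 70.0:
            raise DomainError(f"fs={self.fs} must exceed twice the 70 Hz band edge")
        if self.duration_s <= 0:
            raise DomainError("duration_s must be positive")
        if not 20.0 <= self.spike_width_ms <= 200.0:
            raise DomainError(
                f"spike_width_ms={self.spike_width_ms} outside [20, 200] ms"
            )
        if self.n_channels != len(self.channels):
            raise DomainError("n_channels must match the channel label list")
        iv = sorted(self.seizure_intervals)
        for (a0, a1), (b0, b1) in zip(iv, iv[1:]):
            if b0 < a1:
                raise DomainError(f"overlapping seizure intervals {(a0, a1)} / {(b0, b1)}")
        for a0, a1 in iv:
            if not (0 <= a0 < a1 <= self.duration_s):
                raise DomainError(f"seizure interval {(a0, a1)} outside the recording")


@dataclass(frozen=True)
class Event:
    time_s: float          # spike centre, or seizure start
    end_s: float           # == time_s + support for spikes
    channel: str           # focus electrode
    width_ms: float        # spike/sharp-wave duration (0 for seizures)
    klass: str             # "spike" | "seizure"


@dataclass
class GroundTruth:
    """Per-epoch class labels plus the injected event list."""

    labels: np.ndarray                 # dtype=str, one entry per 2-s epoch
    events: list[Event] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in CLASSES}

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"epoch_index": np.arange(self.labels.size), "label": self.labels}
        ).to_csv(path, index=False)

    def events_to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "time_s": e.time_s,
                    "channel": e.channel,
                    "width_ms": e.width_ms,
                    "class": e.klass,
                }
                for e in self.events
            ],
            columns=["time_s", "channel", "width_ms", "class"],
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroundTruth":
        df = pd.read_csv(path)
        return cls(labels=df["label"].to_numpy(dtype=object).astype(str))


# ---------------------------------------------------------------------------
# Background
# ---------------------------------------------------------------------------

def _shaped_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance noise with a 1/f-weighted spectrum inside 0.1-70 Hz."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    weight = np.where((freqs >= 0.1) & (freqs <= 70.0), 1.0 / (1.0 + freqs) ** 0.6, 0.0)
    spec = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)) * weight
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_background(config: SimConfig) -> EegRecording:
    """Band-limited 1/f background with alpha rhythm and shared common mode.

    All spectral energy lies within 0.1-70 Hz by construction; samples are
    clipped at +/-95 uV so the output never trips the 100 uV artifact gate.
    A zero ``background_amp_uv`` yields an all-zero recording.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    rho = config.spatial_correlation
    common = _shaped_noise(rng, n, config.fs)
    data = np.empty((config.n_channels, n))
    for i in range(config.n_channels):
        private = _shaped_noise(rng, n, config.fs)
        osc_amp = 0.6 + 0.4 * rng.random()
        osc_f = config.alpha_hz + rng.uniform(-1.0, 1.0)
        osc = osc_amp * np.sin(2 * np.pi * osc_f * t + rng.uniform(0, 2 * np.pi))
        x = np.sqrt(rho) * common + np.sqrt(1 - rho) * private + 0.5 * osc
        sd = x.std()
        data[i] = x / sd if sd > 0 else x
    data *= config.background_amp_uv
    np.clip(data, -95.0, 95.0, out=data)
    return EegRecording(data, config.channels, config.fs)


# ---------------------------------------------------------------------------
# Event injection
# ---------------------------------------------------------------------------

def spike_kernel(width_ms: float, fs: float) -> tuple[np.ndarray, int]:
    """Unit-peak biphasic derivative-of-Gaussian kernel.

    ``width_ms`` is the full duration at 10% of peak amplitude.  Returns the
    kernel samples and the offset of the kernel centre.
    """
    sigma_s = (width_ms / 1000.0) / (2.0 * _DOG_HALF_SUPPORT)
    half = int(np.ceil(_DOG_HALF_SUPPORT * sigma_s * fs))
    t = np.arange(-half, half + 1) / fs
    u = t / sigma_s
    k = u * np.exp(-(u ** 2) / 2.0) / np.exp(-0.5)
    return k, half


def inject_spike(
    recording: EegRecording,
    time_s: float,
    focus_channel: str,
    width_ms: float,
    amp_uv: float,
) -> EegRecording:
    """Add a biphasic transient with a spatially decaying potential field.

    The field peaks at the focus electrode and decays by ``FIELD_DECAY_PER_HOP``
    per hop on the scalp adjacency graph; in a bipolar montage the chain
    channels entering and leaving the focus therefore deflect with opposite
    signs (phase reversal).  Returns a new recording.
    """
    if not 20.0 <= width_ms <= 200.0:
        raise DomainError(f"width_ms={width_ms} outside [20, 200] ms")
    if not 0.0 <= time_s <= recording.duration_s:
        raise DomainError(f"time_s={time_s} outside the recording")
    hops = electrode_hops(focus_channel, recording.labels)
    kernel, half = spike_kernel(width_ms, recording.fs)
    centre = int(round(time_s * recording.fs))
    lo = max(0, centre - half)
    hi = min(recording.n_samples, centre + half + 1)
    k = kernel[lo - (centre - half): kernel.size - ((centre + half + 1) - hi)]
    out = recording.copy()
    for i, lab in enumerate(recording.labels):
        gain = FIELD_DECAY_PER_HOP ** hops.get(lab, 10)
        out.data[i, lo:hi] += amp_uv * gain * k
    return out


def inject_seizure(
    recording: EegRecording,
    start_s: float,
    end_s: float,
    rhythm_hz: float,
    amp_uv: float = 30.0,
    focus_channel: str | None = None,
    spread_delay_s: float = 0.1,
) -> EegRecording:
    """Add a rhythmic discharge with progressively increasing amplitude.

    The envelope rises linearly from 20% to 100% of ``amp_uv`` over the
    interval; the rhythm reaches neighbouring electrodes with a per-hop
    onset delay and the same 0.5-per-hop field decay.
    """
    if not (0 <= start_s < end_s <= recording.duration_s):
        raise DomainError(f"seizure interval {(start_s, end_s)} outside the recording")
    focus = focus_channel or recording.labels[0]
    hops = electrode_hops(focus, recording.labels)
    fs = recording.fs
    t = np.arange(recording.n_samples) / fs
    out = recording.copy()
    for i, lab in enumerate(recording.labels):
        h = hops.get(lab, 10)
        onset = min(start_s + h * spread_delay_s, end_s)
        active = (t >= onset) & (t < end_s)
        if not np.any(active):
            continue
        frac = (t[active] - start_s) / (end_s - start_s)  # global ramp
        env = (0.2 + 0.8 * frac) * amp_uv * FIELD_DECAY_PER_HOP ** h
        phase = 2 * np.pi * rhythm_hz * (t[active] - start_s)
        wave = np.sin(phase) + 0.3 * np.sin(2 * phase)
        out.data[i, active] += env * wave
    return out


def inject_seizures(
    recording: EegRecording,
    intervals: list[tuple[float, float]],
    rhythm_hz: float,
    **kwargs,
) -> EegRecording:
    iv = sorted(intervals)
    for (a0, a1), (b0, b1) in zip(iv, iv[1:]):
        if b0 < a1:
            raise DomainError(f"overlapping seizure intervals {(a0, a1)} / {(b0, b1)}")
    out = recording
    for a0, a1 in iv:
        out = inject_seizure(out, a0, a1, rhythm_hz, **kwargs)
    return out


# ---------------------------------------------------------------------------
# Labeling and labeled datasets
# ---------------------------------------------------------------------------

def assign_labels(n_epochs: int, events: list[Event], epoch_s: float = EPOCH_SECONDS) -> np.ndarray:
    """Epoch labels by overlap: an epoch overlapping an event by at least one
    sample carries that event's class; seizure takes precedence over spike."""
    labels = np.array(["normal"] * n_epochs, dtype=object)
    for e in sorted(events, key=lambda e: e.klass):  # seizure sorts after spike
        first = int(np.floor(e.time_s / epoch_s))
        last = int(np.ceil(e.end_s / epoch_s)) - 1
        for i in range(max(0, first), min(n_epochs, last + 1)):
            if e.klass == "seizure" or labels[i] != "seizure":
                labels[i] = e.klass
    return labels


def simulate_dataset(
    n_normal: int,
    n_spike: int,
    n_seizure: int,
    config: SimConfig | None = None,
    seed: int | None = None,
) -> tuple[EegRecording, GroundTruth]:
    """A labeled recording with the requested per-class 2-s epoch counts.

    Epoch classes are randomly interleaved.  Each spike epoch receives one
    spike at an interior chain electrode, with mild jitter of position,
    width (x0.8-1.2) and amplitude (x0.7-1.1) around the config values;
    each seizure epoch holds a rhythmic discharge spanning the epoch with a
    safety margin, so every event maps to exactly one labeled epoch.
    """
    base = config or SimConfig()
    if seed is not None:
        base = replace(base, seed=seed)
    n_total = n_normal + n_spike + n_seizure
    duration = n_total * EPOCH_SECONDS
    base = replace(base, duration_s=duration, seizure_intervals=())
    rng = np.random.default_rng(base.seed + 1)
    slots = np.array(
        ["normal"] * n_normal + ["spike"] * n_spike + ["seizure"] * n_seizure,
        dtype=object,
    )
    rng.shuffle(slots)
    rec = generate_background(base)
    events: list[Event] = []
    for i, klass in enumerate(slots):
        t0 = i * EPOCH_SECONDS
        if klass == "spike":
            width = base.spike_width_ms * rng.uniform(0.8, 1.2)
            amp = base.spike_amp_uv * rng.uniform(0.7, 1.1)
            margin = width / 1000.0 / 2.0 + 0.05
            centre = t0 + rng.uniform(margin, EPOCH_SECONDS - margin)
            focus = str(rng.choice(INTERIOR_ELECTRODES))
            rec = inject_spike(rec, centre, focus, width, amp)
            events.append(
                Event(centre - width / 2000.0, centre + width / 2000.0, focus, width, "spike")
            )
        elif klass == "seizure":
            a0, a1 = t0 + 0.15, t0 + EPOCH_SECONDS - 0.15
            f = base.seizure_rhythm_hz * rng.uniform(0.9, 1.1)
            focus = str(rng.choice(INTERIOR_ELECTRODES))
            rec = inject_seizure(rec, a0, a1, f, base.seizure_amp_uv, focus)
            events.append(Event(a0, a1, focus, 0.0, "seizure"))
    labels = assign_labels(n_total, events)
    return rec, GroundTruth(labels=labels, events=events)


def simulate_spike_clusters(
    n_epochs: int,
    cluster_starts: list[int],
    cluster_len: int = 3,
    config: SimConfig | None = None,
    seed: int | None = None,
) -> tuple[EegRecording, GroundTruth]:
    """A time-ordered stream with clustered (periodic) spikes.

    Each cluster places one spike in ``cluster_len`` consecutive epochs
    starting at the given epoch indices, emulating periodic epileptiform
    discharges; amplitudes within a cluster vary (x0.6-1.1) so that some
    members are harder to detect than others.
    """
    base = config or SimConfig()
    if seed is not None:
        base = replace(base, seed=seed)
    base = replace(base, duration_s=n_epochs * EPOCH_SECONDS, seizure_intervals=())
    rng = np.random.default_rng(base.seed + 2)
    rec = generate_background(base)
    events: list[Event] = []
    for start in cluster_starts:
        focus = str(rng.choice(INTERIOR_ELECTRODES))
        for j in range(cluster_len):
            i = start + j
            if i >= n_epochs:
                break
            width = base.spike_width_ms * rng.uniform(0.8, 1.2)
            amp = base.spike_amp_uv * rng.uniform(0.6, 1.1)
            margin = width / 1000.0 / 2.0 + 0.05
            centre = i * EPOCH_SECONDS + rng.uniform(margin, EPOCH_SECONDS - margin)
            rec = inject_spike(rec, centre, focus, width, amp)
            events.append(
                Event(centre - width / 2000.0, centre + width / 2000.0, focus, width, "spike")
            )
    labels = assign_labels(n_epochs, events)
    return rec, GroundTruth(labels=labels, events=events)
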