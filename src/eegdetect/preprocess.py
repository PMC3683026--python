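"""Preprocessing: filtering, montage derivation, epoching, sub-band split.

The preprocessing contract for the reference configuration (16 channels of
the 10-20 system at 200 Hz, microvolt units):

1. artifact rejection marks any 2-s window in which any channel exceeds
   100 uV in absolute value, evaluated on the raw recording;
2. a zero-phase 0.1-70 Hz band pass, a 60 Hz notch and Daubechies-4 wavelet
   denoising are applied to the continuous signal;
3. unipolar and bipolar (longitudinal chain) views are derived and cut into
   consecutive, non-overlapping 2-s epochs sharing one surviving index set;
4. each epoch channel is decomposed into the five physiological frequency
   bands (delta 0-4, theta 4-8, alpha 8-15, beta 15-30, gamma 30-70 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps

from .montage import MontageSpec, bipolar_label, default_montage

EPOCH_SECONDS = 2.0
AMPLITUDE_REJECT_UV = 100.0

#: Physiological band edges in Hz, in the order used throughout the package.
BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 0.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 15.0),
    ("beta", 15.0, 30.0),
    ("gamma", 30.0, 70.0),
)
BAND_NAMES: tuple[str, ...] = tuple(b[0] for b in BANDS)


class ConfigurationError(ValueError):
    pass


class MontageError(KeyError):
    pass


@dataclass
class EegRecording:
    """Continuous multichannel EEG: ``data`` is channels x samples in uV."""

    data: np.ndarray
    labels: tuple[str, ...]
    fs: float

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.labels = tuple(self.labels)
        if self.data.shape[0] != len(self.labels):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.labels)} channel labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.labels.index(label)]
        except ValueError as exc:
            raise MontageError(f"electrode {label!r} not present") from exc

    def pick(self, labels: tuple[str, ...]) -> "EegRecording":
        """Sub-recording with the given channels, in the given order."""
        rows = np.array([self.labels.index(l) for l in labels])
        return EegRecording(self.data[rows].copy(), tuple(labels), self.fs)

    def copy(self) -> "EegRecording":
        return EegRecording(self.data.copy(), self.labels, self.fs)


@dataclass
class Epoch:
    """One 2-s, 16-channel window in a stated montage."""

    data: np.ndarray          # channels x samples, uV
    labels: tuple[str, ...]
    fs: float
    montage: str              # "unipolar" | "bipolar"
    index: int                # 0-based position in the source recording
    label: str | None = None  # optional class: normal | spike | seizure

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class SubbandSet:
    """Per-channel band signals; ``bands[name]`` is channels x samples."""

    bands: dict[str, np.ndarray]
    labels: tuple[str, ...]
    fs: float

    def channel_bands(self, label: str) -> dict[str, np.ndarray]:
        i = self.labels.index(label)
        return {name: arr[i] for name, arr in self.bands.items()}


# ---------------------------------------------------------------------------
# Filter chain
# ---------------------------------------------------------------------------

def _zero_phase_sos(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Forward-backward second-order-section filtering along the last axis.

    Initial conditions are scaled to the first sample of each pass, so a
    signal sitting at a constant level produces no start-up transient; with
    a slow high-pass pole this is far better conditioned than reflection
    padding, which can excite the pole over the whole record.
    """
    zi = sps.sosfilt_zi(sos)  # (n_sections, 2)
    x = np.atleast_2d(x)
    out = np.empty_like(x)
    for i, ch in enumerate(x):
        fwd, _ = sps.sosfilt(sos, ch, zi=zi * ch[0])
        bwd, _ = sps.sosfilt(sos, fwd[::-1], zi=zi * fwd[-1])
        out[i] = bwd[::-1]
    return out


def _zero_phase_ba(b: np.ndarray, a: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Forward-backward transfer-function filtering along the last axis."""
    zi = sps.lfilter_zi(b, a)
    x = np.atleast_2d(x)
    out = np.empty_like(x)
    for i, ch in enumerate(x):
        fwd, _ = sps.lfilter(b, a, ch, zi=zi * ch[0])
        bwd, _ = sps.lfilter(b, a, fwd[::-1], zi=zi * fwd[-1])
        out[i] = bwd[::-1]
    return out


def _wavelet_denoise(x: np.ndarray, wavelet: str = "db4", level: int = 4) -> np.ndarray:
    """Soft-threshold wavelet denoising with the universal threshold."""
    coeffs = pywt.wavedec(x, wavelet, level=level)
    detail = coeffs[-1]
    sigma = np.median(np.abs(detail)) / 0.6745
    if sigma == 0.0:
        return x.copy()
    thresh = sigma * np.sqrt(2.0 * np.log(x.size))
    coeffs = [coeffs[0]] + [pywt.threshold(c, thresh, mode="soft") for c in coeffs[1:]]
    out = pywt.waverec(coeffs, wavelet)
    return out[: x.size]


def filter_chain(
    recording: EegRecording,
    band: tuple[float, float] = (0.1, 70.0),
    notch_hz: float = 60.0,
    wavelet_denoise: bool = True,
) -> EegRecording:
    """Zero-phase 0.1-70 Hz band pass, 60 Hz notch, db4 wavelet denoising.

    Raises ``ConfigurationError`` when the sampling rate cannot represent the
    gamma band (fs <= 140 Hz).
    """
    fs = recording.fs
    if fs <= 2 * band[1]:
        raise ConfigurationError(
            f"fs={fs} Hz cannot represent the {band[1]} Hz band edge"
        )
    # The band pass is split into a gentle high pass and a steeper low pass:
    # the 0.1 Hz corner has a multi-second time constant, so the signal is
    # demeaned first and filtered with matched initial conditions instead of
    # reflection padding (which rings the slow pole across the record).
    out = recording.data - recording.data.mean(axis=1, keepdims=True)
    hp = sps.butter(2, band[0], btype="highpass", fs=fs, output="sos")
    lp = sps.butter(4, band[1], btype="lowpass", fs=fs, output="sos")
    out = _zero_phase_sos(hp, out)
    out = _zero_phase_sos(lp, out)
    if notch_hz < fs / 2:
        b, a = sps.iirnotch(notch_hz, Q=30.0, fs=fs)
        out = _zero_phase_ba(b, a, out)
    if wavelet_denoise:
        out = np.stack([_wavelet_denoise(ch) for ch in out])
    return EegRecording(out, recording.labels, fs)


# ---------------------------------------------------------------------------
# Montage derivation
# ---------------------------------------------------------------------------

def derive_bipolar(recording: EegRecording, montage: MontageSpec | None = None) -> EegRecording:
    """Derive the 16 bipolar chain channels, channel i = anode_i - cathode_i."""
    montage = montage or default_montage()
    rows = []
    labels = []
    for anode, cathode in montage.bipolar_pairs:
        rows.append(recording.channel(anode) - recording.channel(cathode))
        labels.append(bipolar_label(anode, cathode))
    return EegRecording(np.stack(rows), tuple(labels), recording.fs)


# ---------------------------------------------------------------------------
# Epoching and artifact rejection
# ---------------------------------------------------------------------------

def rejection_mask(
    recording: EegRecording,
    threshold_uv: float = AMPLITUDE_REJECT_UV,
    epoch_s: float = EPOCH_SECONDS,
) -> np.ndarray:
    """Boolean keep-mask per consecutive epoch (True = keep).

    An epoch is rejected when any channel holds any sample with an absolute
    amplitude strictly greater than the threshold.  A trailing partial window
    is not represented in the mask.
    """
    n_per = int(round(epoch_s * recording.fs))
    n_epochs = recording.n_samples // n_per
    keep = np.ones(n_epochs, dtype=bool)
    for i in range(n_epochs):
        seg = recording.data[:, i * n_per:(i + 1) * n_per]
        if np.any(np.abs(seg) > threshold_uv):
            keep[i] = False
    return keep


def epoch_and_reject(
    recording: EegRecording,
    threshold_uv: float = AMPLITUDE_REJECT_UV,
    epoch_s: float = EPOCH_SECONDS,
    montage_kind: str = "unipolar",
    keep_mask: np.ndarray | None = None,
    labels_by_epoch: np.ndarray | None = None,
) -> list[Epoch]:
    """Cut a recording into surviving consecutive, non-overlapping epochs.

    Windows are half-open sample ranges ``[i*n, (i+1)*n)``; the trailing
    partial window is discarded; rejected epochs are dropped but surviving
    epochs keep their original index.  A precomputed ``keep_mask`` (for
    example computed on the raw recording before filtering) overrides the
    amplitude test on this recording.
    """
    n_per = int(round(epoch_s * recording.fs))
    n_epochs = recording.n_samples // n_per
    if keep_mask is None:
        keep_mask = rejection_mask(recording, threshold_uv, epoch_s)
    epochs = []
    for i in range(n_epochs):
        if not keep_mask[i]:
            continue
        lab = None
        if labels_by_epoch is not None:
            lab = str(labels_by_epoch[i])
        epochs.append(
            Epoch(
                data=recording.data[:, i * n_per:(i + 1) * n_per].copy(),
                labels=recording.labels,
                fs=recording.fs,
                montage=montage_kind,
                index=i,
                label=lab,
            )
        )
    return epochs


def epoch_index_table(
    recording: EegRecording,
    threshold_uv: float = AMPLITUDE_REJECT_UV,
    epoch_s: float = EPOCH_SECONDS,
) -> pd.DataFrame:
    """Index table (epoch_index, start_sample, kept_flag, reject_reason)."""
    n_per = int(round(epoch_s * recording.fs))
    keep = rejection_mask(recording, threshold_uv, epoch_s)
    return pd.DataFrame(
        {
            "epoch_index": np.arange(keep.size),
            "start_sample": np.arange(keep.size) * n_per,
            "kept_flag": keep,
            "reject_reason": ["" if k else f"amplitude>{threshold_uv:g}uV" for k in keep],
        }
    )


def make_epoch_pairs(
    raw: EegRecording,
    montage: MontageSpec | None = None,
    truth_labels: np.ndarray | None = None,
    wavelet_denoise: bool = True,
    threshold_uv: float = AMPLITUDE_REJECT_UV,
) -> tuple[list[Epoch], list[Epoch]]:
    """Full preprocessing: raw recording -> matched unipolar/bipolar epochs.

    Rejection is decided once on the raw unipolar recording; the surviving
    epoch index set is shared by both montage views.
    """
    montage = montage or default_montage()
    uni_raw = raw.pick(montage.unipolar_channels)
    keep = rejection_mask(uni_raw, threshold_uv)
    filtered = filter_chain(raw, wavelet_denoise=wavelet_denoise)
    uni = filtered.pick(montage.unipolar_channels)
    bip = derive_bipolar(filtered, montage)
    uni_epochs = epoch_and_reject(
        uni, montage_kind="unipolar", keep_mask=keep, labels_by_epoch=truth_labels
    )
    bip_epochs = epoch_and_reject(
        bip, montage_kind="bipolar", keep_mask=keep, labels_by_epoch=truth_labels
    )
    return uni_epochs, bip_epochs


# ---------------------------------------------------------------------------
# Sub-band decomposition
# ---------------------------------------------------------------------------

def _leaf_band_map(fs: float, level: int) -> dict[str, list[int]]:
    """Assign each wavelet-packet leaf to the band of dominant overlap."""
    width = fs / 2.0 / (2 ** level)
    mapping: dict[str, list[int]] = {name: [] for name in BAND_NAMES}
    for leaf in range(2 ** level):
        lo, hi = leaf * width, (leaf + 1) * width
        overlaps = {
            name: max(0.0, min(hi, b_hi) - max(lo, b_lo))
            for name, b_lo, b_hi in BANDS
        }
        best = max(BAND_NAMES, key=lambda n: overlaps[n])
        if overlaps[best] > 0:
            mapping[best].append(leaf)
    return mapping


def _wavelet_band_split(x: np.ndarray, fs: float, level: int = 5,
                        wavelet: str = "db4") -> dict[str, np.ndarray]:
    """Band signals from a frequency-ordered wavelet-packet decomposition.

    The ``2**level`` leaf reconstructions are regrouped to the five
    physiological bands by dominant frequency overlap with the band edges.
    """
    wp = pywt.WaveletPacket(x, wavelet, mode="symmetric", maxlevel=level)
    nodes = wp.get_level(level, order="freq")
    leaf_map = _leaf_band_map(fs, level)
    out = {}
    for name in BAND_NAMES:
        sel = pywt.WaveletPacket(
            np.zeros_like(x), wavelet, mode="symmetric", maxlevel=level
        )
        for leaf in leaf_map[name]:
            sel[nodes[leaf].path] = nodes[leaf].data
        rec = sel.reconstruct(update=False)
        out[name] = np.asarray(rec[: x.size], dtype=float)
    return out


def _fir_band_split(x: np.ndarray, fs: float, numtaps: int = 201) -> dict[str, np.ndarray]:
    """Zero-phase FIR filter-bank with the same band edges (reference path)."""
    out = {}
    padlen = min(3 * numtaps, x.size - 1)
    for name, lo, hi in BANDS:
        if lo <= 0:
            taps = sps.firwin(numtaps, hi, fs=fs)
        else:
            taps = sps.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)
        # constant-edge padding: reflection padding injects spurious
        # low-frequency energy into the narrow delta band on 2-s epochs
        out[name] = sps.filtfilt(taps, [1.0], x, padlen=padlen, padtype="constant")
    return out


def decompose_bands(epoch: Epoch, method: str = "wavelet") -> SubbandSet:
    """Split every epoch channel into the five physiological bands.

    ``method`` is ``"wavelet"`` (wavelet-packet leaves regrouped to bands)
    or ``"fir"`` (zero-phase FIR filter bank with the same edges).
    """
    if method not in ("wavelet", "fir"):
        raise ConfigurationError(f"unknown band method {method!r}")
    split = _wavelet_band_split if method == "wavelet" else _fir_band_split
    per_channel = [split(ch, epoch.fs) for ch in epoch.data]
    bands = {
        name: np.stack([pc[name] for pc in per_channel]) for name in BAND_NAMES
    }
    return SubbandSet(bands=bands, labels=epoch.labels, fs=epoch.fs)


# ---------------------------------------------------------------------------
# I/O: simulator CSV dialect and EDF
# ---------------------------------------------------------------------------

def write_recording_csv(recording: EegRecording, path: str | Path) -> None:
    """CSV dialect: first column time in s, remaining columns channels in uV."""
    t = np.arange(recording.n_samples) / recording.fs
    df = pd.DataFrame(recording.data.T, columns=list(recording.labels))
    df.insert(0, "time_s", t)
    df.to_csv(path, index=False, float_format="%.6f")


def read_recording_csv(path: str | Path) -> EegRecording:
    df = pd.read_csv(path)
    if df.columns[0] != "time_s":
        raise ConfigurationError("recording CSV must start with a time_s column")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ConfigurationError("recording CSV too short")
    fs = 1.0 / float(np.median(np.diff(t)))
    data = df.drop(columns="time_s").to_numpy().T
    return EegRecording(data, tuple(df.columns[1:]), fs)


def read_recording_edf(path: str | Path) -> EegRecording:
    """Read an EDF/EDF+ file (requires the optional mne dependency)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EegRecording(data, tuple(raw.ch_names), float(raw.info["sfreq"]))


def read_recording(path: str | Path) -> EegRecording:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_recording_edf(path)
    return read_recording_csv(path)
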