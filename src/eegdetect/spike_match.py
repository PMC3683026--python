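"""Post-classification spike matching on the bipolar montage.

A two-stage detector applied to 2-s bipolar epochs:

1. pulse stage -- transient deflections whose peak exceeds a multiple of the
   per-channel background SD and whose full duration at 10% of the peak lies
   within the epileptiform gates (20-70 ms spikes, 70-200 ms sharp waves);
2. phase-reversal stage -- the first differences (derivatives) of the two
   chain channels flanking the candidate must reach opposite-signed extremes
   of comparable magnitude inside the candidate window.

Each candidate receives a summed magnitude/duration score

    S_pm = w_mag * (peak / background SD) + w_dur * triangular duration fit,

where the duration fit is 1 at the 45 ms spike-band centre and decays
linearly to 0 at the 20 and 200 ms gates.  An epoch is a spike when at
least one candidate has S_pm at or above the threshold and passes the
phase-reversal check.

The follow-up screening rule re-examines the five 2-s epochs (10 s) after
every classifier-labeled spike with this matcher; an epoch becomes a spike
if either the classifier or the matcher says so.  Newly found spikes open
their own follow-up windows (periodic discharges chain), and seizure labels
are never overwritten.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .features import difference_sum_series
from .montage import MontageSpec, default_montage
from .preprocess import Epoch


@dataclass(frozen=True)
class SpikeMatchConfig:
    """Detector parameters.

    ``mag_floor_sd`` and ``s_pm_threshold`` were calibrated once on a seeded
    labeled simulation with ``fit_spm_threshold`` (sensitivity subject to a
    specificity floor) and then frozen; both remain user-settable.
    """

    w_mag: float = 0.2
    w_dur: float = 1.0
    s_pm_threshold: float = 1.5
    pulse_min_ms: float = 20.0
    pulse_max_ms: float = 200.0
    spike_sharp_split_ms: float = 70.0
    duration_center_ms: float = 45.0
    mag_floor_sd: float = 4.0
    reversal_mag_ratio: float = 3.5
    equidistant_ratio: float = 1.25
    followup_epochs: int = 5
    gap_merge_ms: float = 15.0

    def __post_init__(self) -> None:
        if not self.pulse_min_ms < self.pulse_max_ms:
            raise ValueError("pulse_min_ms must be below pulse_max_ms")
        if self.followup_epochs < 0:
            raise ValueError("followup_epochs must be >= 0")
        if self.w_mag < 0 or self.w_dur < 0:
            raise ValueError("score weights must be non-negative")


DEFAULT_SPM = SpikeMatchConfig()


@dataclass
class PulseCandidate:
    channel: str
    onset_ms: float
    duration_ms: float
    peak_uv: float          # absolute peak amplitude
    peak_sign: int
    peak_sample: int
    band: str               # "spike" (20-70 ms) | "sharp" (70-200 ms)


@dataclass
class ReversalCheck:
    passed: bool
    localization: str | None = None   # "equidistant" | "at-electrode"
    electrode: str | None = None
    reason: str = ""


@dataclass
class SpikeMatchResult:
    epoch_index: int
    candidates: list[PulseCandidate] = field(default_factory=list)
    s_pm: list[float] = field(default_factory=list)
    reversal: list[ReversalCheck] = field(default_factory=list)
    verdict: bool = False

    def best_localization(self) -> ReversalCheck | None:
        best, best_score = None, -np.inf
        for cand_score, rev in zip(self.s_pm, self.reversal):
            if rev.passed and cand_score > best_score:
                best, best_score = rev, cand_score
        return best


def robust_channel_sd(data: np.ndarray) -> np.ndarray:
    """Per-channel background SD estimate, robust to embedded transients."""
    mad = np.median(np.abs(data - np.median(data, axis=1, keepdims=True)), axis=1)
    sd = 1.4826 * mad
    fallback = data.std(axis=1)
    return np.where(sd > 0, sd, np.maximum(fallback, 1e-12))


# ---------------------------------------------------------------------------
# Stage 1: pulses
# ---------------------------------------------------------------------------

def detect_pulses(
    bipolar_epoch: Epoch,
    config: SpikeMatchConfig | None = None,
    background_sd: np.ndarray | None = None,
) -> list[PulseCandidate]:
    """Transient deflection candidates of one bipolar epoch.

    The duration of a candidate is the full width at 10% of its peak,
    measured on the rectified signal after bridging sub-10% gaps shorter
    than ``gap_merge_ms`` so that a biphasic transient counts as one pulse.
    """
    cfg = config or DEFAULT_SPM
    fs = bipolar_epoch.fs
    data = bipolar_epoch.data
    sds = background_sd if background_sd is not None else robust_channel_sd(data)
    gap = max(1, int(round(cfg.gap_merge_ms / 1000.0 * fs)))
    out: list[PulseCandidate] = []
    for ci, lab in enumerate(bipolar_epoch.labels):
        x = data[ci]
        thr = cfg.mag_floor_sd * sds[ci]
        supra = np.abs(x) > thr
        if not np.any(supra):
            continue
        regions, n_regions = ndimage.label(supra)
        seen_components: set[tuple[int, int]] = set()
        for ri in range(1, n_regions + 1):
            seg = np.flatnonzero(regions == ri)
            peak_idx = seg[np.argmax(np.abs(x[seg]))]
            peak = float(np.abs(x[peak_idx]))
            # duration at 10% of peak, floored at 1.5 background SD so the
            # measurement does not bridge into ongoing background activity
            level = max(0.1 * peak, 1.5 * sds[ci])
            above = np.abs(x) >= level
            closed = ndimage.binary_closing(above, structure=np.ones(gap, dtype=bool))
            comp, _ = ndimage.label(closed)
            cid = comp[peak_idx]
            members = np.flatnonzero(comp == cid)
            span = (int(members[0]), int(members[-1]))
            if (ci, span[0]) in seen_components:
                continue
            seen_components.add((ci, span[0]))
            duration_ms = (span[1] - span[0] + 1) / fs * 1000.0
            if not cfg.pulse_min_ms <= duration_ms <= cfg.pulse_max_ms:
                continue
            band = "spike" if duration_ms < cfg.spike_sharp_split_ms else "sharp"
            out.append(
                PulseCandidate(
                    channel=lab,
                    onset_ms=span[0] / fs * 1000.0,
                    duration_ms=duration_ms,
                    peak_uv=peak,
                    peak_sign=int(np.sign(x[peak_idx])),
                    peak_sample=int(peak_idx),
                    band=band,
                )
            )
    return out


# ---------------------------------------------------------------------------
# S_pm score
# ---------------------------------------------------------------------------

def duration_fit(duration_ms: float, config: SpikeMatchConfig | None = None) -> float:
    """Triangular duration term: 1 at the spike-band centre, 0 at the gates."""
    cfg = config or DEFAULT_SPM
    d, c = duration_ms, cfg.duration_center_ms
    if d <= cfg.pulse_min_ms or d >= cfg.pulse_max_ms:
        return 0.0
    if d <= c:
        return (d - cfg.pulse_min_ms) / (c - cfg.pulse_min_ms)
    return (cfg.pulse_max_ms - d) / (cfg.pulse_max_ms - c)


def s_pm(
    candidate: PulseCandidate,
    background_sd: float,
    config: SpikeMatchConfig | None = None,
) -> float:
    """Summed magnitude/duration score of a candidate."""
    cfg = config or DEFAULT_SPM
    if background_sd <= 0:
        raise ValueError("background SD must be positive")
    mag = candidate.peak_uv / background_sd
    return cfg.w_mag * mag + cfg.w_dur * duration_fit(candidate.duration_ms, cfg)


# ---------------------------------------------------------------------------
# Stage 2: phase reversal
# ---------------------------------------------------------------------------

def check_phase_reversal(
    candidate: PulseCandidate,
    bipolar_epoch: Epoch,
    montage: MontageSpec | None = None,
    config: SpikeMatchConfig | None = None,
) -> ReversalCheck:
    """Opposite-signed derivative extremes on the two flanking chain channels.

    Similar magnitudes (ratio within ``equidistant_ratio``) localize the
    discharge equidistant between the electrodes; a larger asymmetry places
    it at the electrode shared with the stronger-derivative channel.
    A candidate at a chain end fails with a reason (not an error).
    """
    montage = montage or default_montage()
    cfg = config or DEFAULT_SPM
    prev_lab, next_lab = montage.chain_neighbors(candidate.channel)
    if prev_lab is None or next_lab is None:
        return ReversalCheck(False, reason="no chain neighbor")
    fs = bipolar_epoch.fs
    half = int(round(max(candidate.duration_ms, 30.0) / 2000.0 * fs)) + int(round(0.005 * fs))
    lo = max(0, candidate.peak_sample - half)
    hi = min(bipolar_epoch.n_samples, candidate.peak_sample + half + 1)
    idx = {lab: i for i, lab in enumerate(bipolar_epoch.labels)}
    d_prev = np.diff(bipolar_epoch.data[idx[prev_lab], lo:hi])
    d_next = np.diff(bipolar_epoch.data[idx[next_lab], lo:hi])
    if d_prev.size == 0 or d_next.size == 0:
        return ReversalCheck(False, reason="window too short")
    e_prev = d_prev[np.argmax(np.abs(d_prev))]
    e_next = d_next[np.argmax(np.abs(d_next))]
    if e_prev == 0 or e_next == 0 or np.sign(e_prev) == np.sign(e_next):
        return ReversalCheck(False, reason="same-signed derivatives")
    hi_mag, lo_mag = max(abs(e_prev), abs(e_next)), min(abs(e_prev), abs(e_next))
    ratio = hi_mag / lo_mag
    if ratio > cfg.reversal_mag_ratio:
        return ReversalCheck(False, reason=f"magnitude ratio {ratio:.2f}")
    if ratio <= cfg.equidistant_ratio:
        return ReversalCheck(True, localization="equidistant", electrode=None)
    stronger = prev_lab if abs(e_prev) >= abs(e_next) else next_lab
    shared = set(candidate.channel.split("-")) & set(stronger.split("-"))
    return ReversalCheck(True, localization="at-electrode", electrode=shared.pop())


def match_epoch(
    bipolar_epoch: Epoch,
    montage: MontageSpec | None = None,
    config: SpikeMatchConfig | None = None,
    background_sd: np.ndarray | None = None,
    epoch_index: int | None = None,
) -> SpikeMatchResult:
    """Run both stages on one bipolar epoch and return the verdict."""
    montage = montage or default_montage()
    cfg = config or DEFAULT_SPM
    sds = (
        background_sd
        if background_sd is not None
        else robust_channel_sd(bipolar_epoch.data)
    )
    idx = {lab: i for i, lab in enumerate(bipolar_epoch.labels)}
    result = SpikeMatchResult(
        epoch_index=epoch_index if epoch_index is not None else bipolar_epoch.index
    )
    for cand in detect_pulses(bipolar_epoch, cfg, sds):
        score = s_pm(cand, float(sds[idx[cand.channel]]), cfg)
        rev = check_phase_reversal(cand, bipolar_epoch, montage, cfg)
        result.candidates.append(cand)
        result.s_pm.append(score)
        result.reversal.append(rev)
        if score >= cfg.s_pm_threshold and rev.passed:
            result.verdict = True
    return result


# ---------------------------------------------------------------------------
# Focus localization from the six-neighbour difference sums
# ---------------------------------------------------------------------------

def localize_focus(
    bipolar_epoch: Epoch,
    montage: MontageSpec | None = None,
) -> str:
    """Electrode focus from the six-neighbour difference-sum series.

    The channel whose difference-sum series reaches the extreme (minimal,
    i.e. largest-magnitude) value marks the phase reversal; the electrode it
    shares with the channel deflecting opposite at that instant is returned
    as the focus.  With the biphasic transients of epileptiform discharges
    the extreme excursion identifies the reversal channel regardless of
    which lobe the background noise favours.
    """
    montage = montage or default_montage()
    s = difference_sum_series(
        bipolar_epoch.data, bipolar_epoch.labels, montage.neighbor_graph
    )
    c_star = int(np.argmax(np.abs(s).max(axis=1)))
    t_star = int(np.argmax(np.abs(s[c_star])))
    sign = np.sign(s[c_star, t_star])
    lab_star = bipolar_epoch.labels[c_star]
    sharing = montage.channels_sharing_electrode(lab_star)
    idx = {lab: i for i, lab in enumerate(bipolar_epoch.labels)}
    best_lab = max(sharing, key=lambda lab: -sign * s[idx[lab], t_star])
    return sharing[best_lab]


# ---------------------------------------------------------------------------
# Follow-up screening
# ---------------------------------------------------------------------------

def stream_background_sd(
    bip_epochs: list[Epoch],
    classifier_labels: np.ndarray,
    window: int = 5,
) -> np.ndarray:
    """Per-epoch, per-channel background SD from surrounding normal epochs.

    For every epoch the median per-channel SD over the classifier-normal
    epochs within +/-``window`` positions (about +/-10 s) is used; an epoch
    with no normal neighbours falls back to its own robust SD.
    """
    n = len(bip_epochs)
    own = np.stack([robust_channel_sd(e.data) for e in bip_epochs])
    out = np.empty_like(own)
    for i in range(n):
        lo, hi = max(0, i - window), min(n, i + window + 1)
        sel = [j for j in range(lo, hi) if classifier_labels[j] == "normal"]
        out[i] = np.median(own[sel], axis=0) if sel else own[i]
    return out


def followup_screen(
    bip_epochs: list[Epoch],
    classifier_labels: np.ndarray,
    montage: MontageSpec | None = None,
    config: SpikeMatchConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, dict[int, SpikeMatchResult]]:
    """Apply the 10-s follow-up rule to a time-ordered epoch stream.

    Returns (final_labels, matcher_fired, matcher_results).  The matcher is
    consulted only inside follow-up windows; the final spike set always
    contains the classifier spike set, and seizure labels are preserved.
    """
    montage = montage or default_montage()
    cfg = config or DEFAULT_SPM
    labels = np.asarray(classifier_labels, dtype=object).copy()
    n = len(bip_epochs)
    if labels.size != n:
        raise ValueError("one classifier label per epoch is required")
    sds = stream_background_sd(bip_epochs, labels) if n else np.empty((0, 0))
    fired = np.zeros(n, dtype=bool)
    results: dict[int, SpikeMatchResult] = {}
    queue = deque(i for i in range(n) if labels[i] == "spike")
    queued = set(queue)
    while queue:
        t = queue.popleft()
        for u in range(t + 1, min(n, t + 1 + cfg.followup_epochs)):
            if labels[u] in ("spike", "seizure"):
                continue
            if u not in results:
                results[u] = match_epoch(
                    bip_epochs[u], montage, cfg, background_sd=sds[u], epoch_index=u
                )
            if results[u].verdict:
                labels[u] = "spike"
                fired[u] = True
                if u not in queued:
                    queue.append(u)
                    queued.add(u)
    return labels, fired, results


# ---------------------------------------------------------------------------
# Threshold fitting (trial-and-error grid, as a calibration utility)
# ---------------------------------------------------------------------------

def fit_spm_threshold(
    bip_epochs: list[Epoch],
    true_labels: np.ndarray,
    montage: MontageSpec | None = None,
    config: SpikeMatchConfig | None = None,
    grid: np.ndarray | None = None,
    specificity_floor: float = 0.95,
) -> float:
    """Pick the S_pm threshold maximizing spike sensitivity subject to a
    specificity floor on labeled epochs."""
    from dataclasses import replace

    montage = montage or default_montage()
    cfg = config or DEFAULT_SPM
    grid = np.asarray(grid if grid is not None else np.arange(0.5, 4.01, 0.1))
    y = np.asarray(true_labels, dtype=object)
    scores = []
    for e in bip_epochs:
        res = match_epoch(e, montage, replace(cfg, s_pm_threshold=-np.inf))
        best = -np.inf
        for sc, rev in zip(res.s_pm, res.reversal):
            if rev.passed:
                best = max(best, sc)
        scores.append(best)
    scores = np.asarray(scores)
    is_spike = y == "spike"
    is_normal = y == "normal"
    best_thr, best_sen = float(grid[-1]), -1.0
    for thr in grid:
        pred = scores >= thr
        sen = pred[is_spike].mean() if is_spike.any() else 0.0
        spe = (~pred[is_normal]).mean() if is_normal.any() else 1.0
        if spe >= specificity_floor and sen > best_sen:
            best_thr, best_sen = float(thr), float(sen)
    return best_thr
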