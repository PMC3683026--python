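"""The ordered 1700-feature representation of one unipolar/bipolar epoch pair.

Layout of the reference configuration:

* 800 unipolar features: 16 channels x 5 major feature kinds x 10
  sub-features.  The 10 sub-features of a (channel, kind) cell are the kind
  applied to each of the five frequency bands (delta, theta, alpha, beta,
  gamma) followed by the maximum, minimum, sum, average and standard
  deviation of those five band values.
* 800 bipolar features: the same construction on the bipolar chain channels.
* 100 phase-reversal features: for each bipolar channel c the six-neighbour
  difference-sum series s_c(t) = sum_n (x_c(t) - x_n(t)) is formed; each of
  the 5 kinds is applied to the 16 series, and the minimum, sum, average and
  standard deviation over the 16 per-channel values are appended
  (5 x (16 + 4) = 100).  These operate on the filtered bipolar time series,
  not on sub-bands.

Feature names are deterministic and encode (montage, channel, kind, sub).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import hashlib

import numpy as np
from scipy import stats as sstats

from .entropy import SampEnParams, sample_entropy
from .montage import MontageSpec, default_montage
from .preprocess import BAND_NAMES, Epoch, SubbandSet, decompose_bands

#: The five major feature kinds, in vector order.
KINDS: tuple[str, ...] = (
    "total_variation",
    "standard_deviation",
    "sample_entropy",
    "skewness",
    "energy",
)

AGGREGATES: tuple[str, ...] = ("max", "min", "sum", "avg", "sd")
PR_AGGREGATES: tuple[str, ...] = ("min", "sum", "avg", "sd")


class FeatureDomainError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction configuration.

    ``kinds`` defaults to the five reference kinds; a sixth optional kind
    ``"shannon_entropy"`` (spectral Shannon entropy of the band signal) can
    be enabled, at the cost of leaving the reference 1700 count.
    """

    kinds: tuple[str, ...] = KINDS
    sampen: SampEnParams = field(default_factory=SampEnParams)
    band_method: str = "wavelet"


DEFAULT_FEATURE_CONFIG = FeatureConfig()


@dataclass
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.names):
            raise ValueError("values and names differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return self.values.size


def feature_name_hash(names: tuple[str, ...]) -> str:
    return hashlib.sha256("\n".join(names).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Major features
# ---------------------------------------------------------------------------

def _shannon_entropy(x: np.ndarray) -> float:
    p = np.abs(np.fft.rfft(x)) ** 2
    total = p.sum()
    if total == 0:
        return 0.0
    p = p / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def major_feature(band_signal: np.ndarray, kind: str,
                  sampen: SampEnParams | None = None) -> float:
    """One major feature of a 1-D band signal.

    total_variation = sum_t |x_{t+1} - x_t|; standard_deviation = sample SD;
    sample_entropy per the entropy module; skewness = m3 / m2^{3/2} (0 when
    m2 = 0); energy = sum_t x_t^2.
    """
    x = np.asarray(band_signal, dtype=float).ravel()
    if x.size == 0:
        raise FeatureDomainError("empty band signal")
    if kind == "total_variation":
        return float(np.abs(np.diff(x)).sum())
    if kind == "standard_deviation":
        return float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    if kind == "sample_entropy":
        return sample_entropy(x, sampen)
    if kind == "skewness":
        if np.var(x) == 0:
            return 0.0
        return float(sstats.skew(x))
    if kind == "energy":
        return float(np.dot(x, x))
    if kind == "shannon_entropy":
        return _shannon_entropy(x)
    raise FeatureDomainError(f"unknown feature kind {kind!r}")


def channel_subfeatures(
    channel_bands: dict[str, np.ndarray],
    kind: str,
    sampen: SampEnParams | None = None,
) -> np.ndarray:
    """The 10 sub-features of one channel for one major-feature kind.

    Values 1-5 are the kind on the delta..gamma band signals; values 6-10
    are the maximum, minimum, sum, average and (sample) standard deviation
    of values 1-5.
    """
    missing = [b for b in BAND_NAMES if b not in channel_bands]
    if missing:
        raise FeatureDomainError(f"missing band signals: {missing}")
    band_vals = np.array(
        [major_feature(channel_bands[b], kind, sampen) for b in BAND_NAMES]
    )
    aggs = np.array(
        [band_vals.max(), band_vals.min(), band_vals.sum(),
         band_vals.mean(), np.std(band_vals, ddof=1)]
    )
    return np.concatenate([band_vals, aggs])


# ---------------------------------------------------------------------------
# Phase reversal
# ---------------------------------------------------------------------------

def difference_sum_series(
    bipolar_data: np.ndarray,
    labels: tuple[str, ...],
    neighbor_graph: dict[str, tuple[str, ...]],
) -> np.ndarray:
    """Six-neighbour difference-sum series s_c(t) for every bipolar channel.

    s_c(t) = sum over the six neighbours n of (x_c(t) - x_n(t))
           = 6 x_c(t) - sum_n x_n(t).
    """
    idx = {lab: i for i, lab in enumerate(labels)}
    out = np.empty_like(bipolar_data)
    for i, lab in enumerate(labels):
        nbrs = neighbor_graph[lab]
        if len(nbrs) != 6:
            raise FeatureDomainError(
                f"neighbor list of {lab!r} has length {len(nbrs)}, expected 6"
            )
        rows = [idx[n] for n in nbrs]
        out[i] = 6.0 * bipolar_data[i] - bipolar_data[rows].sum(axis=0)
    return out


def phase_reversal_profile(
    bipolar_data: np.ndarray,
    labels: tuple[str, ...],
    neighbor_graph: dict[str, tuple[str, ...]],
) -> dict[str, float]:
    """The 20-quantity time-summed profile: per-channel sums s(c) plus the
    minimum, sum, average and SD over the 16 channel sums."""
    s = difference_sum_series(bipolar_data, labels, neighbor_graph).sum(axis=1)
    prof = {lab: float(v) for lab, v in zip(labels, s)}
    prof["min"] = float(s.min())
    prof["sum"] = float(s.sum())
    prof["avg"] = float(s.mean())
    prof["sd"] = float(np.std(s, ddof=1))
    return prof


def phase_reversal_features(
    bipolar_epoch: Epoch,
    montage: MontageSpec | None = None,
    config: FeatureConfig | None = None,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """The 100 phase-reversal features of a bipolar epoch.

    For each major-feature kind: the kind applied to the 16 difference-sum
    series, then the minimum, sum, average and SD over those 16 values.
    """
    montage = montage or default_montage()
    cfg = config or DEFAULT_FEATURE_CONFIG
    series = difference_sum_series(
        bipolar_epoch.data, bipolar_epoch.labels, montage.neighbor_graph
    )
    values: list[float] = []
    names: list[str] = []
    for kind in cfg.kinds:
        ch_vals = np.array(
            [major_feature(series[i], kind, cfg.sampen) for i in range(series.shape[0])]
        )
        values.extend(ch_vals)
        names.extend(f"pr|{lab}|{kind}" for lab in bipolar_epoch.labels)
        aggs = [ch_vals.min(), ch_vals.sum(), ch_vals.mean(), np.std(ch_vals, ddof=1)]
        values.extend(float(a) for a in aggs)
        names.extend(f"pr|{agg}|{kind}" for agg in PR_AGGREGATES)
    return np.asarray(values), tuple(names)


# ---------------------------------------------------------------------------
# Full vector
# ---------------------------------------------------------------------------

def _montage_block(
    epoch: Epoch, montage_name: str, cfg: FeatureConfig
) -> tuple[list[float], list[str]]:
    subbands: SubbandSet = decompose_bands(epoch, method=cfg.band_method)
    values: list[float] = []
    names: list[str] = []
    for lab in epoch.labels:
        bands = subbands.channel_bands(lab)
        for kind in cfg.kinds:
            vals = channel_subfeatures(bands, kind, cfg.sampen)
            values.extend(vals)
            names.extend(
                f"{montage_name}|{lab}|{kind}|{sub}"
                for sub in BAND_NAMES + AGGREGATES
            )
    return values, names


def extract_features(
    unipolar_epoch: Epoch | None,
    bipolar_epoch: Epoch | None,
    config: FeatureConfig | None = None,
    montage: MontageSpec | None = None,
) -> FeatureVector:
    """Assemble the full ordered feature vector of an epoch pair.

    With both views and the reference configuration the vector has
    800 + 800 + 100 = 1700 entries; a unipolar-only extraction yields 800.
    """
    cfg = config or DEFAULT_FEATURE_CONFIG
    montage = montage or default_montage()
    if unipolar_epoch is None and bipolar_epoch is None:
        raise FeatureDomainError("at least one montage view is required")
    if unipolar_epoch is not None and unipolar_epoch.montage != "unipolar":
        raise FeatureDomainError("first epoch must be the unipolar view")
    if bipolar_epoch is not None and bipolar_epoch.montage != "bipolar":
        raise FeatureDomainError("second epoch must be the bipolar view")
    if (
        unipolar_epoch is not None
        and bipolar_epoch is not None
        and unipolar_epoch.index != bipolar_epoch.index
    ):
        raise FeatureDomainError("epoch views must share their index")
    values: list[float] = []
    names: list[str] = []
    if unipolar_epoch is not None:
        v, n = _montage_block(unipolar_epoch, "uni", cfg)
        values.extend(v)
        names.extend(n)
    if bipolar_epoch is not None:
        v, n = _montage_block(bipolar_epoch, "bip", cfg)
        values.extend(v)
        names.extend(n)
        pv, pn = phase_reversal_features(bipolar_epoch, montage, cfg)
        values.extend(pv)
        names.extend(pn)
    return FeatureVector(np.asarray(values), tuple(names))


def extract_feature_matrix(
    uni_epochs: list[Epoch],
    bip_epochs: list[Epoch],
    config: FeatureConfig | None = None,
    montage: MontageSpec | None = None,
) -> tuple[np.ndarray, tuple[str, ...], np.ndarray, np.ndarray]:
    """Feature matrix for matched epoch lists.

    Returns (X, feature_names, epoch_indices, labels); labels are ``""``
    where the epochs carry none.
    """
    rows = []
    names: tuple[str, ...] | None = None
    idxs = []
    labels = []
    for ue, be in zip(uni_epochs, bip_epochs):
        fv = extract_features(ue, be, config, montage)
        if names is None:
            names = fv.names
        rows.append(fv.values)
        idxs.append(ue.index)
        labels.append(ue.label or "")
    X = np.vstack(rows) if rows else np.empty((0, 0))
    return X, names or (), np.asarray(idxs), np.asarray(labels, dtype=object)
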