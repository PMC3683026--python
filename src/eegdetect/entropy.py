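"""Sample entropy (SampEn) with a Euclidean template distance.

SampEn quantifies the regularity of a time series: for a signal S of length
N, count the pairs of distinct m-sample templates lying within a tolerance
r = k * SD(S) of each other (B), count the pairs of (m+1)-sample templates
within r (A), and return -ln(A/B).  More regular signals produce lower
values.  This implementation follows the template distance d[.] as the
Euclidean norm; the conventional Chebyshev (max-norm) distance is available
as an option.

Template indices are restricted so that both the m- and the (m+1)-sample
template exist for every index, keeping A and B on a common pair set, and
self-matches (i = j) are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

_METRICS = {"euclidean": "euclidean", "chebyshev": "chebyshev"}


@dataclass(frozen=True)
class SampEnParams:
    """SampEn parameters: template length m, tolerance multiplier k.

    The tolerance is r = k * SD(signal); k is restricted to [0.1, 0.9].
    """

    m: int = 2
    k: float = 0.2
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0.1 <= self.k <= 0.9:
            raise ValueError(f"k must lie in [0.1, 0.9], got {self.k}")
        if self.metric not in _METRICS:
            raise ValueError(f"metric must be one of {sorted(_METRICS)}")


DEFAULT_SAMPEN = SampEnParams()


def _templates(x: np.ndarray, m: int, n_templates: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(x, m)[:n_templates]


def sample_entropy(signal: np.ndarray, params: SampEnParams | None = None) -> float:
    """SampEn of a 1-D signal.

    Degenerate rules keeping the value finite: a constant signal (SD = 0)
    returns 0; an empty match set (A = 0 or B = 0) returns the cap
    ln(N-m) + ln(N-m-1) - ln(2), the largest value resolvable from the
    available number of template pairs.

    Raises ``ValueError`` when N <= m + 1.
    """
    p = params or DEFAULT_SAMPEN
    x = np.asarray(signal, dtype=float).ravel()
    n = x.size
    if n <= p.m + 1:
        raise ValueError(f"signal length {n} must exceed m+1={p.m + 1}")
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    r = p.k * sd
    n_templates = n - p.m  # indices where both m- and (m+1)-templates exist
    tm = _templates(x, p.m, n_templates)
    tm1 = _templates(x, p.m + 1, n_templates)
    metric = _METRICS[p.metric]
    dm = cdist(tm, tm, metric=metric)
    dm1 = cdist(tm1, tm1, metric=metric)
    # distinct ordered pairs i != j; the matrices are symmetric so the ratio
    # A/B equals the unordered-pair ratio
    b = int(np.count_nonzero(dm <= r)) - n_templates
    a = int(np.count_nonzero(dm1 <= r)) - n_templates
    if a == 0 or b == 0:
        return float(np.log(n - p.m) + np.log(n - p.m - 1) - np.log(2.0))
    return float(-np.log(a / b))
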