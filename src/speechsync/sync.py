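"""Phase-locking value (PLV) and high/low synchronizer classification.

The PLV between two phase series theta1, theta2 of common length T is

    PLV = (1/T) * | sum_t exp(i * (theta1(t) - theta2(t))) |

It is 1 for a constant phase relation and concentrates around
sqrt(pi / (4 T)) for independent uniform phases.  Trial-level PLVs are the
mean over sliding windows (5 s windows, 2 s overlap by default), participant
PLVs the mean over trials, and the cohort of participant PLVs is split into
HIGH and LOW synchronizers by 1-D k-means with k = 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .envelope import PhaseSeries

__all__ = [
    "PLVResult",
    "SyncClassification",
    "plv",
    "windowed_plv",
    "participant_plv",
    "classify_synchronizers",
]


@dataclass
class PLVResult:
    """Windowed PLVs for one trial plus their mean."""

    window_plvs: np.ndarray
    window_spans: list[tuple[float, float]]
    trial_plv: float

    def __post_init__(self) -> None:
        self.window_plvs = np.asarray(self.window_plvs, dtype=float)
        if np.any((self.window_plvs < 0) | (self.window_plvs > 1 + 1e-12)):
            raise ValueError("window PLVs must lie in [0, 1]")


@dataclass
class SyncClassification:
    """k-means (k=2) split of participant PLVs into HIGH and LOW groups."""

    participant_ids: list
    participant_plvs: np.ndarray
    labels: list[str]
    cluster_centers: tuple[float, float]  # (low_center, high_center)
    within_cluster_ss: float
    silhouette: float


def _phase_array(theta) -> np.ndarray:
    if isinstance(theta, PhaseSeries):
        return theta.phase
    return np.asarray(theta, dtype=float)


def plv(theta1, theta2) -> float:
    """Phase-locking value of two equally long phase series.

    Accepts :class:`~speechsync.envelope.PhaseSeries` or plain arrays of
    radians.  Invariant to adding a constant to either series and symmetric
    in its arguments.
    """
    t1, t2 = _phase_array(theta1), _phase_array(theta2)
    if t1.shape != t2.shape:
        raise ValueError(
            f"phase series lengths differ: {t1.shape} vs {t2.shape}"
        )
    if t1.size < 2:
        raise ValueError("need at least T = 2 time points")
    if isinstance(theta1, PhaseSeries) and isinstance(theta2, PhaseSeries):
        if theta1.sample_rate != theta2.sample_rate:
            raise ValueError("phase series sample rates differ")
    return float(np.abs(np.exp(1j * (t1 - t2)).mean()))


def windowed_plv(
    theta1,
    theta2,
    sample_rate: float | None = None,
    window_s: float = 5.0,
    overlap_s: float = 2.0,
    trim_edges: bool = False,
) -> PLVResult:
    """PLV in sliding windows; the trial PLV is their arithmetic mean.

    Windows of ``window_s`` seconds advance by ``window_s - overlap_s``; a
    trailing partial window is dropped.  With ``trim_edges`` the series'
    declared edge-artifact margin is removed first.
    """
    t1, t2 = _phase_array(theta1), _phase_array(theta2)
    if t1.shape != t2.shape:
        raise ValueError("phase series lengths differ")
    if sample_rate is None:
        if not isinstance(theta1, PhaseSeries):
            raise ValueError("sample_rate required for plain arrays")
        sample_rate = theta1.sample_rate
    if trim_edges and isinstance(theta1, PhaseSeries):
        k = int(round(theta1.edge_trim_s * sample_rate))
        if len(t1) > 2 * k + 2 and k > 0:
            t1, t2 = t1[k:-k], t2[k:-k]
    if overlap_s >= window_s:
        raise ValueError("overlap must be shorter than the window")
    win = int(round(window_s * sample_rate))
    hop = int(round((window_s - overlap_s) * sample_rate))
    if len(t1) < win:
        raise ValueError(
            f"series of {len(t1)} samples shorter than one "
            f"{window_s} s window ({win} samples)"
        )
    starts = range(0, len(t1) - win + 1, hop)
    plvs, spans = [], []
    for s in starts:
        plvs.append(plv(t1[s : s + win], t2[s : s + win]))
        spans.append((s / sample_rate, (s + win) / sample_rate))
    return PLVResult(window_plvs=np.array(plvs), window_spans=spans,
                     trial_plv=float(np.mean(plvs)))


def participant_plv(trial_results: list[PLVResult]) -> float:
    """Unweighted mean of trial PLVs across runs."""
    if not trial_results:
        raise ValueError("need at least one trial")
    return float(np.mean([r.trial_plv for r in trial_results]))


def classify_synchronizers(
    participant_plvs,
    seed: int = 0,
    n_restarts: int = 50,
    participant_ids: list | None = None,
) -> SyncClassification:
    """Split a cohort of participant PLVs into HIGH and LOW synchronizers.

    1-D k-means with k = 2, ``n_restarts`` random initialisations, keeping
    the solution with the lowest within-cluster sum of squares.  The cluster
    with the larger centre is labelled HIGH.  Bimodality of the PLV
    distribution is assumed, not tested; the silhouette score is reported so
    degenerate cohorts are visible.
    """
    x = np.asarray(participant_plvs, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need at least two participant PLVs")
    if np.ptp(x) == 0:
        raise ValueError("degenerate clustering: all PLVs identical")
    if participant_ids is None:
        participant_ids = list(range(len(x)))
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(x[:, None])
    centers = km.cluster_centers_.ravel()
    high_cluster = int(np.argmax(centers))
    labels = ["HIGH" if r == high_cluster else "LOW" for r in raw]
    sil = float(silhouette_score(x[:, None], raw)) if len(x) > 2 else np.nan
    return SyncClassification(
        participant_ids=list(participant_ids),
        participant_plvs=x,
        labels=labels,
        cluster_centers=(float(np.min(centers)), float(np.max(centers))),
        within_cluster_ss=float(km.inertia_),
        silhouette=sil,
    )
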