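"""Articulation rate from audio and preferred auditory rate from 2IFC trials.

The articulation (spontaneous speech motor production) rate is the number of
syllable nuclei divided by the utterance duration excluding silent pauses.
Nuclei are detected on a frame-wise intensity contour (25 ms frames, 10 ms
hop, dB scale) as peaks above the median intensity that are separated by a
sufficient intensity dip — the approach popularised by Praat syllable-nuclei
scripts, reimplemented here with every threshold exposed.

The preferred auditory rate comes from two-interval forced-choice trials:
per-rate preference counts are aggregated over all non-catch trials and a
Gaussian is fitted; its peak is the preferred rate and its full width at
half maximum (FWHM = 2 sqrt(2 ln 2) sigma) indexes preference specificity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .envelope import AudioRecording

__all__ = [
    "NucleiParams",
    "NucleiResult",
    "PreferenceDistribution",
    "GaussianFitResult",
    "FWHM_FACTOR",
    "detect_syllable_nuclei",
    "articulation_rate_cohort",
    "exclude_catch_failures",
    "build_preference_distribution",
    "fit_gaussian_preference",
]

#: FWHM of a Gaussian with unit sigma
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


# ---------------------------------------------------------------------------
# syllable-nuclei detection


@dataclass
class NucleiParams:
    """Tunables of the nuclei detector (all in conventional units).

    frame_s / hop_s: intensity analysis window and hop.
    threshold_db: a peak must exceed the median intensity by this much.
    dip_db: required intensity dip between consecutive nuclei.
    silence_db: frames more than this far below the intensity maximum
        count as silent.
    min_pause_s: minimal run of silent frames that counts as a pause
        (excluded from the voiced duration).
    pause_margin_s: allowance trimmed from each speech-adjacent edge of a
        detected pause.  The intensity contour falls silent roughly half an
        inter-syllable gap after the last syllable ends (and rises the same
        way before the next), so the acoustically silent run overshoots the
        perceptual pause; 0.1 s compensates at typical articulation rates.
    """

    frame_s: float = 0.025
    hop_s: float = 0.010
    threshold_db: float = 2.0
    dip_db: float = 2.0
    silence_db: float = 25.0
    min_pause_s: float = 0.3
    pause_margin_s: float = 0.1


@dataclass
class NucleiResult:
    nucleus_times: np.ndarray
    voiced_duration: float
    pause_segments: list[tuple[float, float]]
    total_duration: float

    @property
    def n_nuclei(self) -> int:
        return len(self.nucleus_times)

    @property
    def articulation_rate(self) -> float | None:
        """Nuclei per second of voiced speech; None when undefined."""
        if self.n_nuclei == 0 or self.voiced_duration <= 0:
            return None
        return self.n_nuclei / self.voiced_duration


def _intensity_db(x: np.ndarray, fs: float, frame_s: float,
                  hop_s: float) -> tuple[np.ndarray, np.ndarray]:
    frame = max(2, int(round(frame_s * fs)))
    hop = max(1, int(round(hop_s * fs)))
    n_frames = 1 + max(0, (len(x) - frame) // hop)
    idx = np.arange(frame)[None, :] + hop * np.arange(n_frames)[:, None]
    rms = np.sqrt(np.mean(x[idx] ** 2, axis=1))
    db = 20.0 * np.log10(np.maximum(rms, 1e-12))
    t = (np.arange(n_frames) * hop + frame / 2) / fs
    return t, db


def detect_syllable_nuclei(
    audio: AudioRecording,
    params: NucleiParams | None = None,
) -> NucleiResult:
    """Detect syllable nuclei and silent pauses in a mono recording.

    Returns nucleus times, the voiced duration (total minus pauses) and the
    articulation rate (``None`` for silent input).
    """
    if params is None:
        params = NucleiParams()
    if audio.duration < 0.5:
        raise ValueError("audio must be at least 0.5 s long")
    t, db = _intensity_db(audio.samples, audio.sample_rate,
                          params.frame_s, params.hop_s)
    total = audio.duration

    peak_db = float(db.max())
    silent = db < (peak_db - params.silence_db)
    # contiguous silent runs of at least min_pause_s are pauses
    pauses: list[tuple[float, float]] = []
    hop = params.hop_s
    i = 0
    while i < len(silent):
        if silent[i]:
            j = i
            while j < len(silent) and silent[j]:
                j += 1
            span = (j - i) * hop
            if span >= params.min_pause_s:
                start = t[i] - params.frame_s / 2
                end = t[j - 1] + params.frame_s / 2
                pauses.append((max(0.0, start), min(total, end)))
            i = j
        else:
            i += 1
    # voiced duration: trim the onset/decay allowance from pause edges that
    # border speech (edges at the recording boundary are kept as-is)
    pause_time = 0.0
    for s, e in pauses:
        margin = params.pause_margin_s * (int(s > 1e-9)
                                          + int(e < total - 1e-9))
        pause_time += max(0.0, (e - s) - margin)
    voiced = total - pause_time

    median_db = float(np.median(db))
    if peak_db - median_db < params.threshold_db:
        # flat contour (e.g. digital silence or pure noise): no nuclei
        return NucleiResult(np.array([]), voiced, pauses, total)
    peaks, _ = find_peaks(
        db,
        height=median_db + params.threshold_db,
        prominence=params.dip_db,
    )
    # peaks inside detected pauses cannot be nuclei
    times = t[peaks]
    keep = np.ones(len(times), dtype=bool)
    for s, e in pauses:
        keep &= ~((times >= s) & (times <= e))
    return NucleiResult(times[keep], voiced, pauses, total)


def articulation_rate_cohort(
    trial_results: dict[object, list[NucleiResult]],
) -> pd.DataFrame:
    """Per-participant mean articulation rate over their trials.

    Trials with undefined rates (no nuclei) are dropped; participants with
    no valid trial are flagged with a NaN rate.
    """
    rows = []
    for pid, results in trial_results.items():
        vals = [r.articulation_rate for r in results
                if r.articulation_rate is not None]
        rows.append((pid, np.mean(vals) if vals else np.nan, len(vals)))
    return pd.DataFrame(rows, columns=["participant", "motor_rate",
                                       "n_valid_trials"])


def exclude_catch_failures(
    accuracies: dict[object, float] | pd.Series,
    threshold: float = 75.0,
) -> list:
    """Participants retained by the catch-trial criterion.

    Accuracies are percentages in [0, 100]; a participant is excluded only
    when strictly below the threshold.
    """
    items = accuracies.items() if hasattr(accuracies, "items") else accuracies
    kept = []
    for pid, acc in items:
        if not 0 <= acc <= 100:
            raise ValueError(f"accuracy {acc} for {pid!r} outside [0, 100]")
        if acc >= threshold:
            kept.append(pid)
    return kept


# ---------------------------------------------------------------------------
# 2IFC preference distribution and Gaussian fit


@dataclass
class PreferenceDistribution:
    rate_grid: np.ndarray
    counts: np.ndarray
    n_trials_used: int

    def __post_init__(self) -> None:
        self.rate_grid = np.asarray(self.rate_grid, dtype=float)
        self.counts = np.asarray(self.counts)
        if int(self.counts.sum()) != self.n_trials_used:
            raise ValueError("counts must sum to the number of trials used")


@dataclass
class GaussianFitResult:
    peak: float
    sigma: float
    amplitude: float
    fit_rmse: float
    fwhm: float = field(init=False)

    def __post_init__(self) -> None:
        self.fwhm = FWHM_FACTOR * self.sigma


def build_preference_distribution(
    trials: pd.DataFrame,
) -> PreferenceDistribution:
    """Aggregate each trial's preferred item into per-rate counts.

    Catch trials (``is_catch``) are excluded.  Every ``choice`` must equal
    the trial's ``rate_a`` or ``rate_b``; self-pairs simply increment their
    rate once.
    """
    t = trials
    if "is_catch" in t.columns:
        t = t[~t["is_catch"].astype(bool)]
    grid = np.unique(np.concatenate([t["rate_a"].to_numpy(float),
                                     t["rate_b"].to_numpy(float)]))
    ok = (t["choice"].to_numpy(float) == t["rate_a"].to_numpy(float)) | (
        t["choice"].to_numpy(float) == t["rate_b"].to_numpy(float))
    if not ok.all():
        bad = t.index[~ok].tolist()
        raise ValueError(f"choice not among the trial's pair at rows {bad}")
    counts = np.array([(t["choice"] == r).sum() for r in grid])
    return PreferenceDistribution(rate_grid=grid, counts=counts,
                                  n_trials_used=int(len(t)))


def _gauss(r, a, mu, sigma):
    return a * np.exp(-((r - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian_preference(
    dist: PreferenceDistribution,
) -> GaussianFitResult:
    """Least-squares Gaussian fit ``a * exp(-(r - mu)^2 / 2 sigma^2)``.

    Initialised at the empirical mode; the peak is bounded to one syl/s
    beyond the grid.  Peak and FWHM are invariant to rescaling the counts.
    """
    r = dist.rate_grid
    c = dist.counts.astype(float)
    if np.count_nonzero(c) < 3:
        raise ValueError("need at least 3 nonzero grid points to fit")
    lo, hi = float(r.min()), float(r.max())
    mode = float(r[np.argmax(c)])
    span = hi - lo
    p0 = (float(c.max()), mode, span / 4.0)
    bounds = ([1e-9, lo - 1.0, 1e-3], [np.inf, hi + 1.0, 10.0 * span])
    try:
        popt, _ = curve_fit(_gauss, r, c, p0=p0, bounds=bounds,
                            maxfev=20000)
    except RuntimeError as err:  # pragma: no cover - diagnostics path
        raise RuntimeError(
            f"Gaussian preference fit failed to converge: {err}; "
            f"counts={c.tolist()}"
        ) from err
    a, mu, sigma = (float(v) for v in popt)
    rmse = float(np.sqrt(np.mean((_gauss(r, *popt) - c) ** 2)))
    return GaussianFitResult(peak=mu, sigma=sigma, amplitude=a,
                             fit_rmse=rmse)
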