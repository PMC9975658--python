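"""Synthetic generators for every input the analysis pipeline consumes.

Speech-production recordings from synchronization studies typically cannot be
shared, so each pipeline stage is exercised on simulated data with known
ground truth:

* syllable-train stimuli whose rate ramps in blocks (4.3 -> 4.7 syl/s in
  0.1 steps every 60 syllables by default);
* stimulus/production phase pairs coupled through von Mises phase noise with
  concentration kappa, for which the expected PLV is the Bessel ratio
  I1(kappa) / I0(kappa);
* bimodal synchronizer cohorts (group mean PLVs ~0.73 and ~0.36);
* burst-structured "speech" with known syllable nuclei and silent pauses;
* two-interval forced-choice (2IFC) preference trials driven by a latent
  Gaussian rate preference;
* binary comprehension trials from a logit-linear model with crossed random
  intercepts and a by-participant rate slope.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from .envelope import AudioRecording, PhaseSeries

__all__ = [
    "StimulusTrain",
    "CouplingSpec",
    "PopulationSpec",
    "SpeechBurstSpec",
    "PreferenceSpec",
    "ComprehensionSpec",
    "SimulatedParticipant",
    "SpeechBursts",
    "expected_plv",
    "kappa_for_plv",
    "make_stimulus_train",
    "make_coupled_phases",
    "make_population",
    "make_speech_bursts",
    "make_2ifc_trials",
    "make_comprehension_trials",
    "simulate_comprehension_outcomes",
    "DEFAULT_2IFC_GRID",
    "DEFAULT_RATE_LEVELS",
]

#: 2IFC syllabic-rate grid (syl/s)
DEFAULT_2IFC_GRID = (3.00, 3.92, 4.83, 5.75, 6.67, 7.58, 8.50)

#: syllabic rates of the comprehension stimuli (syl/s)
DEFAULT_RATE_LEVELS = (5.00, 10.69, 12.48, 13.58, 14.38, 15.00)


# ---------------------------------------------------------------------------
# circular-statistics helpers


def expected_plv(kappa: float) -> float:
    """Expected PLV of von Mises phase noise: I1(kappa)/I0(kappa)."""
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    if math.isinf(kappa):
        return 1.0
    return float(i1e(kappa) / i0e(kappa))


def kappa_for_plv(r: float) -> float:
    """Invert the Bessel ratio: concentration giving expected PLV ``r``."""
    if not 0 <= r < 1:
        raise ValueError("target PLV must lie in [0, 1)")
    if r == 0:
        return 0.0
    return float(brentq(lambda k: expected_plv(k) - r, 1e-12, 1e4))


# ---------------------------------------------------------------------------
# stimulus trains


@dataclass
class StimulusTrain:
    """Syllable train with block-wise constant rate."""

    syllable_onsets: np.ndarray  # seconds, strictly increasing
    rates_per_block: tuple[float, ...]
    syllables_per_block: int
    sample_rate: float | None = None
    audio: np.ndarray | None = None

    @property
    def n_syllables(self) -> int:
        return len(self.syllable_onsets)

    @property
    def duration(self) -> float:
        """Total duration: last onset plus the final inter-onset interval."""
        return float(self.syllable_onsets[-1] + 1.0 / self.rates_per_block[-1])

    def phase_at(self, t: np.ndarray) -> np.ndarray:
        """Wrapped instantaneous syllable phase at times ``t``.

        Phase advances linearly by 2*pi per inter-onset interval, i.e. at
        angular rate 2*pi*block_rate, and is wrapped to (-pi, pi].
        """
        t = np.asarray(t, dtype=float)
        # cumulative syllable index as piecewise-linear function of time
        block_starts = [0.0]
        for r in self.rates_per_block[:-1]:
            block_starts.append(block_starts[-1]
                                + self.syllables_per_block / r)
        block_starts = np.asarray(block_starts)
        idx = np.clip(np.searchsorted(block_starts, t, side="right") - 1,
                      0, len(self.rates_per_block) - 1)
        rates = np.asarray(self.rates_per_block)[idx]
        syllable_pos = (idx * self.syllables_per_block
                        + (t - block_starts[idx]) * rates)
        phase = 2 * np.pi * syllable_pos
        return np.angle(np.exp(1j * phase))


def make_stimulus_train(
    rates_per_block=(4.3, 4.4, 4.5, 4.6, 4.7),
    syllables_per_block: int = 60,
    total_duration: float | None = None,
    with_audio: bool = False,
    sample_rate: float = 16000.0,
    seed: int = 0,
) -> StimulusTrain:
    """Build a syllable train ramping through ``rates_per_block``.

    Two sizing modes exist because a trial's nominal duration (e.g. 80 s) and
    its syllable budget (blocks x syllables_per_block) can disagree: by
    default the train contains exactly ``syllables_per_block`` syllables per
    block (~66.7 s for the defaults); with ``total_duration`` set, the block
    schedule repeats/truncates to fill that many seconds instead.
    """
    rates = tuple(float(r) for r in rates_per_block)
    if any(r <= 0 for r in rates):
        raise ValueError("all block rates must be positive")
    if syllables_per_block < 1:
        raise ValueError("syllables_per_block must be >= 1")

    onsets, block_rates, t = [], [], 0.0
    if total_duration is None:
        for r in rates:
            for _ in range(syllables_per_block):
                onsets.append(t)
                t += 1.0 / r
            block_rates.append(r)
    else:
        i = 0
        while t < total_duration:
            r = rates[min(i, len(rates) - 1)]
            for _ in range(syllables_per_block):
                if t >= total_duration:
                    break
                onsets.append(t)
                t += 1.0 / r
            block_rates.append(r)
            i += 1

    train = StimulusTrain(
        syllable_onsets=np.asarray(onsets),
        rates_per_block=tuple(block_rates),
        syllables_per_block=syllables_per_block,
        sample_rate=sample_rate if with_audio else None,
    )
    if with_audio:
        rng = np.random.default_rng(seed)
        dur = train.duration
        n = int(round(dur * sample_rate))
        wave = np.zeros(n)
        burst = _hann_burst(sample_rate, 0.05, 500.0, rng)
        for onset in train.syllable_onsets:
            s = int(round(onset * sample_rate))
            e = min(s + len(burst), n)
            wave[s:e] += burst[: e - s]
        train.audio = wave
    return train


def _hann_burst(fs: float, dur_s: float, carrier_hz: float,
                rng: np.random.Generator) -> np.ndarray:
    n = int(round(dur_s * fs))
    tt = np.arange(n) / fs
    return np.hanning(n) * np.sin(2 * np.pi * carrier_hz * tt)


# ---------------------------------------------------------------------------
# von Mises phase coupling


@dataclass
class CouplingSpec:
    """Ground-truth coupling between stimulus and produced phases.

    ``kappa`` is the von Mises concentration of the phase noise; the
    expected PLV is I1(kappa)/I0(kappa).  ``noise_update_hz`` controls how
    often an independent noise value is drawn: ``None`` means one draw per
    sample (the marginal is exactly von Mises and the Bessel-ratio identity
    holds sample-wise); a finite value holds each draw constant for
    1/noise_update_hz seconds, giving a slowly varying, more
    physiological-looking phase while preserving the marginal distribution.
    """

    kappa: float = 2.0
    mean_lag: float = 0.0
    duration: float | None = None
    noise_update_hz: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be nonnegative")


def make_coupled_phases(
    train: StimulusTrain,
    coupling: CouplingSpec,
    fs: float = 100.0,
) -> tuple[PhaseSeries, PhaseSeries]:
    """Stimulus phase theta1 and a coupled production phase theta2.

    theta2(t) = theta1(t) + mean_lag + eps(t) with eps ~ von Mises(0, kappa);
    kappa = inf is the noise-free convention (eps = 0).
    """
    max_rate = max(train.rates_per_block)
    if fs <= 2 * max_rate:
        raise ValueError("fs must exceed twice the maximum syllable rate")
    dur = coupling.duration if coupling.duration is not None else train.duration
    t = np.arange(int(round(dur * fs))) / fs
    theta1 = train.phase_at(t)
    rng = np.random.default_rng(coupling.seed)
    if math.isinf(coupling.kappa):
        eps = np.zeros_like(t)
    elif coupling.noise_update_hz is None:
        eps = rng.vonmises(0.0, coupling.kappa, size=len(t))
    else:
        hold = max(1, int(round(fs / coupling.noise_update_hz)))
        n_draw = int(np.ceil(len(t) / hold))
        eps = np.repeat(rng.vonmises(0.0, coupling.kappa, size=n_draw),
                        hold)[: len(t)]
    theta2 = np.angle(np.exp(1j * (theta1 + coupling.mean_lag + eps)))
    mk = lambda ph, sid: PhaseSeries(phase=ph, sample_rate=fs,
                                     band=(3.5, 5.5), edge_trim_s=0.0,
                                     source_id=sid)
    return mk(theta1, "stimulus"), mk(theta2, "production")


# ---------------------------------------------------------------------------
# synchronizer cohorts


@dataclass
class PopulationSpec:
    """A bimodal cohort of high and low synchronizers.

    Default concentrations place the group mean PLVs near the empirically
    observed 0.73 (highs) and 0.36 (lows); ``plv_sd`` disperses individual
    target PLVs around the group mean (default 0.09).
    """

    n_high: int = 41
    n_low: int = 41
    kappa_high: float = field(default_factory=lambda: kappa_for_plv(0.73))
    kappa_low: float = field(default_factory=lambda: kappa_for_plv(0.36))
    plv_sd: float = 0.09
    trial_count: int = 2
    trial_duration: float | None = None
    fs: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_high < 0 or self.n_low < 0:
            raise ValueError("group sizes must be nonnegative")
        if self.kappa_high <= self.kappa_low:
            raise ValueError("kappa_high must exceed kappa_low")


@dataclass
class SimulatedParticipant:
    participant_id: int
    true_label: str  # "HIGH" or "LOW"
    kappa: float
    target_plv: float
    trials: list[tuple[PhaseSeries, PhaseSeries]]


def make_population(
    spec: PopulationSpec,
    train: StimulusTrain | None = None,
) -> list[SimulatedParticipant]:
    """Simulate a labelled cohort of stimulus/production phase pairs.

    Each participant gets an individual target PLV drawn around their
    group's expected PLV (sd ``plv_sd``), converted back to a von Mises
    concentration, a characteristic mean lag, and ``trial_count`` trials of
    coupled phases.
    """
    if spec.n_high + spec.n_low < 1:
        raise ValueError("cohort must contain at least one participant")
    rng = np.random.default_rng(spec.seed)
    if train is None:
        train = make_stimulus_train()
    out = []
    groups = [("HIGH", spec.n_high, expected_plv(spec.kappa_high)),
              ("LOW", spec.n_low, expected_plv(spec.kappa_low))]
    pid = 0
    for label, n, mean_plv in groups:
        for _ in range(n):
            target = float(np.clip(rng.normal(mean_plv, spec.plv_sd),
                                   0.03, 0.97))
            kappa = kappa_for_plv(target)
            lag = float(rng.uniform(-np.pi, np.pi))
            trials = []
            for _ in range(spec.trial_count):
                c = CouplingSpec(
                    kappa=kappa, mean_lag=lag,
                    duration=spec.trial_duration,
                    seed=int(rng.integers(2**31 - 1)),
                )
                trials.append(make_coupled_phases(train, c, fs=spec.fs))
            out.append(SimulatedParticipant(
                participant_id=pid, true_label=label, kappa=kappa,
                target_plv=target, trials=trials,
            ))
            pid += 1
    return out


# ---------------------------------------------------------------------------
# burst-structured speech


@dataclass
class SpeechBurstSpec:
    """Burst train emulating whispered/spoken syllables with pauses.

    Bursts (50 ms Hann-windowed carriers) mark syllable nuclei inside
    ``voiced_segments``; ``pause_segments`` hold only the noise floor.
    ``noise_floor`` is the background amplitude relative to burst peak
    (0.001 ~ -60 dB).
    """

    n_syllables: int | None = None
    voiced_segments: tuple = ((0.0, 8.0),)
    pause_segments: tuple = ()
    burst_rate_within_voiced: float = 4.0
    noise_floor: float = 1e-3
    jitter_s: float = 0.0
    sample_rate: float = 16000.0
    carrier_hz: float = 500.0
    burst_dur_s: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        segs = sorted([*self.voiced_segments, *self.pause_segments])
        for (a0, a1), (b0, b1) in zip(segs, segs[1:]):
            if b0 < a1 - 1e-12:
                raise ValueError("voiced/pause segments overlap")
        for s, e in segs:
            if e <= s:
                raise ValueError("segments must have positive duration")


@dataclass
class SpeechBursts:
    audio: AudioRecording
    nucleus_times: np.ndarray
    voiced_segments: tuple
    pause_segments: tuple

    @property
    def n_syllables(self) -> int:
        return len(self.nucleus_times)

    @property
    def true_articulation_rate(self) -> float | None:
        """Bursts per second of voiced time; None for an empty burst set."""
        if self.n_syllables == 0:
            return None
        voiced = sum(e - s for s, e in self.voiced_segments)
        return self.n_syllables / voiced


def make_speech_bursts(spec: SpeechBurstSpec) -> SpeechBursts:
    """Generate a burst waveform with known syllable-nucleus times."""
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate
    total = max(e for _, e in [*spec.voiced_segments, *spec.pause_segments])
    n = int(round(total * fs))
    wave = spec.noise_floor * rng.standard_normal(n)

    # nominal nucleus times: centred grid at the burst rate in each segment
    times = []
    for s, e in sorted(spec.voiced_segments):
        k = 0
        while True:
            t = s + (k + 0.5) / spec.burst_rate_within_voiced
            if t + spec.burst_dur_s / 2 > e:
                break
            times.append(t)
            k += 1
    if spec.n_syllables is not None:
        if spec.n_syllables > len(times):
            raise ValueError(
                f"cannot place {spec.n_syllables} bursts at "
                f"{spec.burst_rate_within_voiced} syl/s in the voiced "
                f"segments (capacity {len(times)})"
            )
        times = times[: spec.n_syllables]
    times = np.asarray(times)
    if spec.jitter_s > 0:
        times = times + rng.uniform(-spec.jitter_s, spec.jitter_s,
                                    size=len(times))

    burst = _hann_burst(fs, spec.burst_dur_s, spec.carrier_hz, rng)
    half = len(burst) // 2
    for t in times:
        c = int(round(t * fs))
        s0, e0 = max(0, c - half), min(n, c - half + len(burst))
        wave[s0:e0] += burst[: e0 - s0]

    return SpeechBursts(
        audio=AudioRecording(samples=wave, sample_rate=fs),
        nucleus_times=times,
        voiced_segments=tuple(sorted(spec.voiced_segments)),
        pause_segments=tuple(sorted(spec.pause_segments)),
    )


# ---------------------------------------------------------------------------
# 2IFC preference trials


@dataclass
class PreferenceSpec:
    """Latent Gaussian rate preference driving 2IFC choices.

    The preference strength at rate r is
    g(r) = exp(-(r - true_peak)^2 / (2 sigma^2)) with
    sigma = true_fwhm / (2 sqrt(2 ln 2)).  On each trial the item with the
    larger noisy utility g(r) + N(0, decision_noise) is chosen; exact ties
    (noise-free self-pairs) fall to a fair coin.
    """

    true_peak: float = 5.57
    true_fwhm: float = 4.89
    rate_grid: tuple[float, ...] = DEFAULT_2IFC_GRID
    trials_per_pair: int = 20
    decision_noise: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_fwhm <= 0:
            raise ValueError("true_fwhm must be positive")
        if len(self.rate_grid) < 2:
            raise ValueError("rate grid needs at least 2 rates")
        if not (min(self.rate_grid) <= self.true_peak <= max(self.rate_grid)):
            raise ValueError("true_peak must lie within the rate grid span")

    @property
    def sigma(self) -> float:
        return self.true_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    def preference(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return np.exp(-((r - self.true_peak) ** 2) / (2 * self.sigma**2))


def make_2ifc_trials(spec: PreferenceSpec,
                     participant: int = 0) -> pd.DataFrame:
    """All unordered rate pairs (self-pairs included), ``trials_per_pair``
    trials each; returns a long trial table with the chosen rate."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    trial = 0
    for a, b in combinations_with_replacement(spec.rate_grid, 2):
        ga, gb = spec.preference(a), spec.preference(b)
        for _ in range(spec.trials_per_pair):
            ua = ga + spec.decision_noise * rng.standard_normal()
            ub = gb + spec.decision_noise * rng.standard_normal()
            if ua > ub:
                choice = a
            elif ub > ua:
                choice = b
            else:  # exact tie (noise-free self-pair): fair coin
                choice = a if rng.random() < 0.5 else b
            rows.append((participant, trial, a, b, choice, False))
            trial += 1
    return pd.DataFrame(
        rows,
        columns=["participant", "trial", "rate_a", "rate_b", "choice",
                 "is_catch"],
    )


# ---------------------------------------------------------------------------
# comprehension trials


#: default generating log-odds per SD of each (z-scored) predictor,
#: matching the odds ratios reported for the word-order comprehension task
DEFAULT_COEFFICIENTS = {
    "intercept": 1.75,
    "syllabic_rate": math.log(0.65),
    "motor_rate": math.log(1.19),
    "sync_group": math.log(1.34),
    "preferred_rate": math.log(1.14),
    "working_memory": math.log(1.20),
    "perplexity": math.log(0.84),
}

_PARTICIPANT_LEVEL = {"motor_rate", "preferred_rate", "working_memory",
                      "sync_group"}
_ITEM_LEVEL = {"syllabic_rate", "perplexity", "target1_prob", "target2_prob",
               "sentence_length", "target_distance", "compression"}


@dataclass
class ComprehensionSpec:
    """Generative logit model for binary word-order comprehension trials.

    ``coefficients`` are log-odds per SD of each z-scored predictor (the
    scale on which such models are conventionally reported); ``sync_group``
    is a 0/1 contrast (LOW/HIGH).  Crossed random intercepts for participant
    and item plus a by-participant random slope for syllabic rate.
    Interaction terms are written "a:b".
    """

    n_participants: int = 82
    n_items: int = 240
    coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    participant_intercept_sd: float = 0.5
    item_intercept_sd: float = 0.3
    rate_slope_sd: float = 0.2
    rate_levels: tuple[float, ...] = DEFAULT_RATE_LEVELS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2 or self.n_items < 2:
            raise ValueError("need at least 2 participants and 2 items")
        for k, v in self.coefficients.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite coefficient for {k!r}")
        if min(self.participant_intercept_sd, self.item_intercept_sd,
               self.rate_slope_sd) < 0:
            raise ValueError("random-effect sds must be nonnegative")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def make_comprehension_trials(
    spec: ComprehensionSpec,
) -> tuple[pd.DataFrame, dict]:
    """Simulate trials and return (trial table, ground-truth parameters).

    Participant covariates are drawn in realistic raw units (motor rate
    ~N(4.30, 0.45) syl/s, preferred rate ~N(5.57, 0.86) syl/s, digit span
    ~N(8.46, 2.12)); the linear predictor applies the coefficients to the
    z-scored covariates so the generating values are directly comparable to
    the fitted per-SD odds ratios.
    """
    rng = np.random.default_rng(spec.seed)
    nP, nI = spec.n_participants, spec.n_items

    part = pd.DataFrame({
        "participant": np.arange(nP),
        "motor_rate": rng.normal(4.30, 0.45, nP),
        "preferred_rate": rng.normal(5.57, 0.86, nP),
        "working_memory": rng.normal(8.46, 2.12, nP),
        "sync_group": (np.arange(nP) % 2).astype(float),
    })
    items = pd.DataFrame({
        "item": np.arange(nI),
        "syllabic_rate": np.asarray(spec.rate_levels)[
            np.arange(nI) % len(spec.rate_levels)],
        "perplexity": rng.lognormal(mean=4.0, sigma=0.5, size=nI),
    })
    # extra nuisance covariates only materialize if a coefficient names them
    for name in spec.coefficients:
        if name in ("intercept",) or ":" in name:
            continue
        if name in part.columns or name in items.columns:
            continue
        if name in _PARTICIPANT_LEVEL:
            part[name] = rng.standard_normal(nP)
        else:
            items[name] = rng.standard_normal(nI)

    df = part.merge(items, how="cross")
    df["item"] = df["item"].astype(int)
    return simulate_comprehension_outcomes(
        df,
        coefficients=spec.coefficients,
        participant_intercept_sd=spec.participant_intercept_sd,
        item_intercept_sd=spec.item_intercept_sd,
        rate_slope_sd=spec.rate_slope_sd,
        seed=int(rng.integers(2**31 - 1)),
    )


def simulate_comprehension_outcomes(
    covariates: pd.DataFrame,
    coefficients: dict,
    participant_intercept_sd: float = 0.5,
    item_intercept_sd: float = 0.3,
    rate_slope_sd: float = 0.2,
    rate_column: str = "syllabic_rate",
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Draw binary outcomes for an assembled trial covariate table.

    ``covariates`` needs ``participant`` and ``item`` columns plus one column
    per named coefficient (``sync_group`` enters as its raw 0/1 contrast, all
    other predictors are z-scored internally before the coefficients apply).
    Used by the cohort generator and by the end-to-end pipeline, where the
    covariates are the *measured* upstream quantities.
    """
    df = covariates.copy()
    z = {}
    for col in set(df.columns) - {"participant", "item", "sync_group",
                                  "correct", "true_prob"}:
        if np.issubdtype(df[col].dtype, np.number):
            z[col] = _zscore(df[col].to_numpy(float))
    if "sync_group" in df.columns:
        z["sync_group"] = df["sync_group"].to_numpy(float)

    rng = np.random.default_rng(seed)
    eta = np.full(len(df), float(coefficients.get("intercept", 0.0)))
    for name, beta in coefficients.items():
        if name == "intercept":
            continue
        if ":" in name:
            a, b = name.split(":")
            eta += beta * z[a] * z[b]
        else:
            eta += beta * z[name]

    p_codes, p_levels = pd.factorize(df["participant"])
    i_codes, i_levels = pd.factorize(df["item"])
    u_p = rng.normal(0.0, participant_intercept_sd, len(p_levels))
    u_i = rng.normal(0.0, item_intercept_sd, len(i_levels))
    s_p = rng.normal(0.0, rate_slope_sd, len(p_levels))
    eta += u_p[p_codes] + u_i[i_codes]
    if rate_column in z:
        eta += s_p[p_codes] * z[rate_column]

    prob = 1.0 / (1.0 + np.exp(-eta))
    df["correct"] = (rng.random(len(df)) < prob).astype(int)
    df["true_prob"] = prob

    truth = {
        "coefficients": dict(coefficients),
        "participant_intercept_sd": participant_intercept_sd,
        "item_intercept_sd": item_intercept_sd,
        "rate_slope_sd": rate_slope_sd,
        "random_intercepts_participant": u_p,
        "random_intercepts_item": u_i,
        "random_slopes_rate": s_p,
    }
    return df, truth
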