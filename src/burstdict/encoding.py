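"""Inference on the burst model: timings, weights and atom identities.

Each selected snippet is explained by the single dictionary atom with which
its normalized cross-correlation (over all admissible lags) is largest; the
event timing tau is the midpoint of the aligned atom support, on the sample
grid (resolution one sample period -- 2 ms at 500 Hz -- with no sub-sample
interpolation), and the weight alpha is the raw inner product between the
aligned window and the unit-norm atom.  The resulting event train is a
temporal marked point process with marks (alpha, omega); the per-trial
features derived from it (event rate, log inter-burst intervals, mean timing,
log squared weight) feed the discriminability analysis, alongside
conventional short-time power baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .embedding import SnippetMatrix
from .mdl import Dictionary, best_alignment

__all__ = [
    "TMPPEvent",
    "TMPPTrain",
    "encode",
    "event_rate",
    "mean_log_ibi",
    "bivariate_features",
    "stft_power_baseline",
    "log_band_power",
    "feature_matrix",
    "impute_class_mean",
]


@dataclass(frozen=True)
class TMPPEvent:
    """One inferred micro-event: timing (s), weight, atom index, provenance."""

    tau_s: float
    alpha: float
    atom_id: int
    trial: int
    channel: int = 0


@dataclass
class TMPPTrain:
    """Time-sorted event list for a (single-channel) multi-trial ensemble."""

    events: list[TMPPEvent]
    fs_hz: float
    n_trials: int
    analysis_window: tuple[float, float] | None = None
    n_omega: dict = field(default_factory=dict)

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: (e.trial, e.tau_s))
        counts: dict[int, int] = {}
        for e in self.events:
            counts[e.atom_id] = counts.get(e.atom_id, 0) + 1
        self.n_omega = counts

    def __len__(self) -> int:
        return len(self.events)

    def trial_events(self, trial: int, window: tuple[float, float] | None = None):
        evs = [e for e in self.events if e.trial == trial]
        if window is not None:
            evs = [e for e in evs if window[0] <= e.tau_s < window[1]]
        return evs


def encode(
    snippets: SnippetMatrix,
    dictionary: Dictionary,
    fs_hz: float,
    t_zero_s: float = 0.0,
    polarity: bool = True,
    analysis_window: tuple[float, float] | None = None,
    channel: int = 0,
) -> TMPPTrain:
    """Assign each selected snippet its best atom, timing and weight.

    For every snippet (column of X with (trial, center) provenance) the atom
    with the largest normalized cross-correlation magnitude over admissible
    lags wins; tau is the aligned atom's energy-centroid sample in trial time
    (the support midpoint for symmetric waveforms; seconds, relative to
    ``t_zero_s``); alpha is the signed inner product of the aligned raw
    window with the unit-norm atom.  One atom per micro-event.
    """
    if dictionary.K == 0:
        raise ValueError("cannot encode with an empty dictionary")
    events: list[TMPPEvent] = []
    half = snippets.M // 2
    # tau anchor: energy centroid of each atom (== support midpoint for
    # symmetric waveforms; unbiased when a learned support extends past the
    # burst on one side)
    anchors = {}
    for atom in dictionary.atoms:
        w2 = atom.waveform**2
        centroid = float(np.sum(np.arange(w2.size) * w2) / np.sum(w2))
        anchors[atom.atom_id] = int(np.floor(centroid + 0.5))
    for j in range(snippets.psi):
        col = snippets.snippet(j)
        trial, center = snippets.provenance[j]
        best = None
        for atom in dictionary.atoms:
            al = best_alignment(col, atom.waveform, polarity=polarity)
            score = abs(al.ncc) if polarity else al.ncc
            if best is None or score > best[0]:
                best = (score, al, atom)
        _, al, atom = best
        d = atom.duration_samples
        w = col[al.lag : al.lag + d]
        alpha = float(w @ atom.waveform)
        tau_samples = (center - half) + al.lag + anchors[atom.atom_id]
        events.append(
            TMPPEvent(
                tau_s=tau_samples / fs_hz - t_zero_s,
                alpha=alpha,
                atom_id=atom.atom_id,
                trial=trial,
                channel=channel,
            )
        )
    n_trials = 1 + max((e.trial for e in events), default=-1)
    return TMPPTrain(
        events=events, fs_hz=fs_hz, n_trials=n_trials, analysis_window=analysis_window
    )


def _resolve_window(train: TMPPTrain, window):
    if window is None:
        window = train.analysis_window
    if window is None:
        window = (-np.inf, np.inf)
    return window


def event_rate(train: TMPPTrain, window=None) -> np.ndarray:
    """Events per trial whose tau falls inside the analysis window."""
    window = _resolve_window(train, window)
    counts = np.zeros(train.n_trials)
    for e in train.events:
        if window[0] <= e.tau_s < window[1]:
            counts[e.trial] += 1
    return counts


def mean_log_ibi(train: TMPPTrain, window=None) -> np.ndarray:
    """Per-trial mean natural log of inter-burst intervals (s); NaN if < 2 events."""
    window = _resolve_window(train, window)
    out = np.full(train.n_trials, np.nan)
    for t in range(train.n_trials):
        taus = [e.tau_s for e in train.trial_events(t, window)]
        if len(taus) >= 2:
            ibis = np.diff(taus)
            out[t] = float(np.mean(np.log(ibis)))
    return out


def bivariate_features(train: TMPPTrain, window=None):
    """Per-trial (mean tau, mean log alpha^2); NaN for event-free trials."""
    window = _resolve_window(train, window)
    mean_tau = np.full(train.n_trials, np.nan)
    mean_log_a2 = np.full(train.n_trials, np.nan)
    for t in range(train.n_trials):
        evs = train.trial_events(t, window)
        if evs:
            mean_tau[t] = float(np.mean([e.tau_s for e in evs]))
            mean_log_a2[t] = float(np.mean([np.log(e.alpha**2) for e in evs]))
    return mean_tau, mean_log_a2


def stft_power_baseline(
    trace: np.ndarray,
    fs_hz: float,
    band=None,
    window_s: float = 0.25,
    overlap: float = 0.5,
):
    """Short-time band power on sliding windows (default 250 ms, 50% overlap).

    Returns ``(power, seg_times)``: the summed spectral power in ``band``
    (a BandSpec or (low, high) tuple; all frequencies if None) per segment,
    and each segment's center time in seconds.
    """
    trace = np.asarray(trace, dtype=float)
    nperseg = int(round(window_s * fs_hz))
    noverlap = int(round(nperseg * overlap))
    freqs, times, sxx = signal.spectrogram(
        trace, fs=fs_hz, nperseg=nperseg, noverlap=noverlap, detrend=False
    )
    if band is not None:
        lo = getattr(band, "low_hz", None)
        hi = getattr(band, "high_hz", None)
        if lo is None:
            lo, hi = band
        mask = (freqs >= lo) & (freqs <= hi)
        sxx = sxx[mask]
    return sxx.sum(axis=0), times


def log_band_power(trace: np.ndarray) -> float:
    """Natural log of the mean squared amplitude; NaN for an all-zero trace."""
    trace = np.asarray(trace, dtype=float)
    ms = float(np.mean(trace**2))
    if ms == 0:
        return np.nan
    return float(np.log(ms))


def feature_matrix(
    train: TMPPTrain,
    traces: np.ndarray | None = None,
    window=None,
):
    """Per-trial feature table as a dict of arrays (one row per trial).

    Columns: rate, mean_log_ibi, mean_tau, mean_log_alpha_sq and, when the
    band-limited traces are supplied, log_power over the full trial.
    """
    feats = {
        "rate": event_rate(train, window),
        "mean_log_ibi": mean_log_ibi(train, window),
    }
    mt, ma = bivariate_features(train, window)
    feats["mean_tau"] = mt
    feats["mean_log_alpha_sq"] = ma
    if traces is not None:
        traces = np.atleast_2d(np.asarray(traces, dtype=float))
        feats["log_power"] = np.array([log_band_power(traces[t]) for t in range(traces.shape[0])])
    return feats


def impute_class_mean(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Replace NaNs with the mean of the trial's class (grand mean fallback)."""
    values = np.asarray(values, dtype=float).copy()
    labels = np.asarray(labels)
    grand = np.nanmean(values) if np.any(np.isfinite(values)) else 0.0
    for cls in np.unique(labels):
        mask = labels == cls
        fill = np.nanmean(values[mask]) if np.any(np.isfinite(values[mask])) else grand
        values[mask & ~np.isfinite(values)] = fill
    return values
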