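"""The discriminative embedding transform (DET).

Maps a band-limited trace to the norms of its constituent M-sample snippets
(the "beta_M" space), fits the Gaussian that describes the rest-state mode of
that distribution, and selects the snippets whose norm exceeds

    gamma = mu_ZM + gamma_prime * sigma_ZM

as candidate micro-events.  Under a purely Gaussian background the snippet
norms follow a chi distribution with M degrees of freedom (scaled by the
background sigma), which for the M used here (tens of samples) is close to
Gaussian; snippets containing bursts populate the right tail.

Snippet centers are chosen in two passes: peaks of a smoothed instantaneous-
amplitude envelope mark modulated stretches, and the remaining unmodulated
stretches are tiled at the snippet length so the whole trace is represented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "SnippetIndex",
    "BetaSample",
    "NullFit",
    "SnippetMatrix",
    "extract_snippet_centers",
    "build_snippet_index",
    "embed",
    "fit_background",
    "select_snippets",
    "half_sample_mode",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SnippetIndex:
    """Snippet centers (Pi), with provenance and peak/tile origin."""

    centers: np.ndarray  # int, per snippet
    trial_index: np.ndarray  # int, per snippet
    M: int
    is_peak: np.ndarray = field(default=None)  # bool, per snippet

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=int)
        self.trial_index = np.asarray(self.trial_index, dtype=int)
        if self.M < 2 or self.M % 2:
            raise ValueError("M must be an even integer >= 2")
        if self.is_peak is None:
            self.is_peak = np.zeros(self.centers.shape, dtype=bool)
        self.is_peak = np.asarray(self.is_peak, dtype=bool)

    def __len__(self) -> int:
        return int(self.centers.size)

    def window(self, i: int) -> tuple[int, int]:
        """Half-open sample span of snippet ``i`` within its trial."""
        start = int(self.centers[i]) - self.M // 2
        return start, start + self.M


@dataclass
class BetaSample:
    """Snippet l2-norms (the beta_M surrogate variable)."""

    values: np.ndarray
    M: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("beta values are norms and must be >= 0")


@dataclass(frozen=True)
class NullFit:
    """Gaussian fit of the background mode of beta_M, plus the DET threshold."""

    mu_zm: float
    sigma_zm: float
    gamma_prime: float

    def __post_init__(self):
        if self.sigma_zm <= 0:
            raise ValueError("sigma_zm must be > 0")

    @property
    def gamma(self) -> float:
        return self.mu_zm + self.gamma_prime * self.sigma_zm


@dataclass
class SnippetMatrix:
    """Selected snippets as columns of an (M x Psi) matrix, with provenance."""

    columns: np.ndarray  # (M, Psi)
    provenance: list[tuple[int, int]]  # (trial, center) per column
    M: int

    def __post_init__(self):
        self.columns = np.atleast_2d(np.asarray(self.columns, dtype=float))
        if self.columns.size and self.columns.shape[0] != self.M:
            raise ValueError("column length must equal M")

    @property
    def psi(self) -> int:
        return int(self.columns.shape[1]) if self.columns.size else 0

    def snippet(self, j: int) -> np.ndarray:
        return self.columns[:, j]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _smoothed_envelope(trace: np.ndarray, smooth: int) -> np.ndarray:
    env = np.abs(signal.hilbert(trace))
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        env = np.convolve(env, kernel, mode="same")
    return env


def extract_snippet_centers(
    trace: np.ndarray,
    M: int,
    fs_hz: float | None = None,
    peak_threshold_sd: float = 3.0,
    trial: int = 0,
) -> SnippetIndex:
    """Snippet centers for one trace: envelope peaks plus tiling.

    Modulated stretches are found as peaks of the analytic-signal magnitude
    smoothed by an M/2 moving average, with peak height above the envelope's
    median + ``peak_threshold_sd`` robust standard deviations (1.4826 x MAD,
    so that the bursts themselves cannot inflate the threshold) and spacing
    >= M/2.  The
    rest of the trace is tiled with centers every M samples, skipping tiles
    whose window overlaps a peak window.  All centers respect the M/2 edge
    bounds, so every snippet window lies inside the trace.
    """
    trace = np.asarray(trace, dtype=float)
    eta = trace.size
    if eta <= M:
        raise ValueError(f"trace length {eta} must exceed M={M}")
    half = M // 2
    env = _smoothed_envelope(trace, half)
    med = np.median(env)
    robust_sd = 1.4826 * np.median(np.abs(env - med))
    thresh = med + peak_threshold_sd * robust_sd
    peaks, _ = signal.find_peaks(env, height=thresh, distance=max(half, 1))
    peaks = peaks[(peaks >= half) & (peaks <= eta - half)]
    peak_set = list(int(p) for p in peaks)

    centers = list(peak_set)
    flags = [True] * len(peak_set)
    occupied = [(p - half, p + half) for p in peak_set]

    def overlaps(a, b):
        return any(a < hi and b > lo for lo, hi in occupied)

    c = half
    while c <= eta - half:
        if not overlaps(c - half, c + half):
            centers.append(c)
            flags.append(False)
        c += M

    order = np.argsort(centers)
    return SnippetIndex(
        centers=np.asarray(centers)[order],
        trial_index=np.full(len(centers), trial, dtype=int),
        M=M,
        is_peak=np.asarray(flags)[order],
    )


def build_snippet_index(traces: np.ndarray, M: int, **kwargs) -> SnippetIndex:
    """Concatenate per-trial snippet indices for a (trials, samples) matrix."""
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    parts = [
        extract_snippet_centers(traces[t], M, trial=t, **kwargs)
        for t in range(traces.shape[0])
    ]
    return SnippetIndex(
        centers=np.concatenate([p.centers for p in parts]),
        trial_index=np.concatenate([p.trial_index for p in parts]),
        M=M,
        is_peak=np.concatenate([p.is_peak for p in parts]),
    )


def embed(traces: np.ndarray, index: SnippetIndex) -> BetaSample:
    """l2-norms of the M-sample windows at the indexed centers."""
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    half = index.M // 2
    eta = traces.shape[1]
    values = np.empty(len(index))
    for i in range(len(index)):
        c = index.centers[i]
        if not (half <= c <= eta - half):
            raise ValueError(f"center {c} violates edge bounds for M={index.M}")
        w = traces[index.trial_index[i], c - half : c - half + index.M]
        values[i] = np.linalg.norm(w)
    return BetaSample(values=values, M=index.M)


def half_sample_mode(x: np.ndarray) -> float:
    """Robust mode estimate by recursive half-range narrowing."""
    x = np.sort(np.asarray(x, dtype=float))
    while x.size > 3:
        h = (x.size + 1) // 2
        widths = x[h - 1 :] - x[: x.size - h + 1]
        i = int(np.argmin(widths))
        x = x[i : i + h]
    return float(np.mean(x))


def fit_background(
    beta: BetaSample, gamma_prime: float = 1.0, robust: bool = True
) -> NullFit:
    """Fit the Gaussian describing the rest-state mode of beta_M.

    The robust fit (default) anchors the mean at the half-sample mode and
    estimates sigma from the squared deviations of the values at or below the
    mode; burst-bearing snippets contaminate only the right tail, so the left
    half of the background mode is clean.  ``robust=False`` uses the plain
    sample mean and SD.
    """
    v = beta.values
    if v.size < 50:
        raise ValueError("need at least 50 beta values to fit the background")
    if np.ptp(v) == 0:
        raise ValueError("degenerate (constant) beta sample")
    if robust:
        mu = half_sample_mode(v)
        left = v[v <= mu]
        if left.size < 10:
            raise ValueError("too few values below the mode for a robust fit")
        sigma = float(np.sqrt(np.mean((left - mu) ** 2)))
    else:
        mu = float(np.mean(v))
        sigma = float(np.std(v, ddof=1))
    if sigma <= 0:
        raise ValueError("degenerate beta sample: zero spread")
    return NullFit(mu_zm=mu, sigma_zm=sigma, gamma_prime=gamma_prime)


def select_snippets(
    traces: np.ndarray, index: SnippetIndex, fit: NullFit
) -> SnippetMatrix:
    """Collect into X every snippet whose norm is >= gamma (ties included)."""
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    beta = embed(traces, index)
    keep = beta.values >= fit.gamma
    half = index.M // 2
    cols = []
    prov = []
    for i in np.flatnonzero(keep):
        c = int(index.centers[i])
        t = int(index.trial_index[i])
        cols.append(traces[t, c - half : c - half + index.M])
        prov.append((t, c))
    if not cols:
        warnings.warn("no snippets exceeded gamma; returning an empty matrix", stacklevel=2)
        return SnippetMatrix(
            columns=np.empty((index.M, 0)), provenance=[], M=index.M
        )
    return SnippetMatrix(columns=np.stack(cols, axis=1), provenance=prov, M=index.M)
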