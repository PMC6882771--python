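"""Discriminability statistics for the learned representations.

One-way MANOVA with sequential dimensionality tests and canonical variates,
silhouette separability, timing--power correlation, a label-shuffle
randomization test, and sample-wise detection scoring against ground-truth
event spans.

The MANOVA follows the classic canonical-variate construction: eigenvalues of
the between-group SSCP matrix relative to the within-group SSCP matrix, with
a Wilks-lambda/Bartlett chi-square test for each nested null "the group means
lie in a d-dimensional affine subspace" (d = 0 .. min(p, g-1) - 1); for four
classes the largest testable null is the 3-dimensional hyperplane.  The
canonical projection maximizes Mahalanobis separation between groups and is
scaled so that canonical variates have unit within-group variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats as sps
from scipy.spatial.distance import cdist

from .encoding import TMPPTrain

__all__ = [
    "ManovaResult",
    "SilhouetteResult",
    "DetectionScore",
    "RandomizationResult",
    "one_way_manova",
    "silhouette",
    "timing_power_correlation",
    "randomization_test",
    "sample_wise_detection",
]


# ---------------------------------------------------------------------------
# MANOVA
# ---------------------------------------------------------------------------

@dataclass
class ManovaResult:
    p_values: np.ndarray      # p for mean-subspace dimension d = 0 .. s-1
    wilks: np.ndarray         # Wilks lambda per dimension test
    chi2: np.ndarray          # Bartlett chi-square statistics
    dof: np.ndarray           # degrees of freedom per test
    eigenvalues: np.ndarray   # canonical eigenvalues, descending
    projection: np.ndarray    # (p x s) canonical coefficients
    scores: np.ndarray        # (n x s) canonical coordinates
    groups: np.ndarray


def one_way_manova(Y: np.ndarray, labels, ridge: float = 1e-8) -> ManovaResult:
    """One-way MANOVA with sequential dimensionality tests.

    ``Y`` is (trials x features); ``labels`` the class per trial.  Returns
    Wilks lambda, Bartlett's chi-square approximation and p-value for each
    null "multivariate means lie in a d-dimensional subspace", plus the
    canonical projection (unit within-group variance scaling) and projected
    coordinates.  A singular within-class covariance is ridge-regularized
    (``ridge`` x trace/dim on the diagonal) with a warning.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    labels = np.asarray(labels)
    if np.any(~np.isfinite(Y)):
        raise ValueError("design matrix contains missing values; impute first")
    groups = np.unique(labels)
    g = groups.size
    n, p = Y.shape
    if g < 2:
        raise ValueError("need at least two classes")
    grand = Y.mean(axis=0)
    B = np.zeros((p, p))
    W = np.zeros((p, p))
    for cls in groups:
        sub = Y[labels == cls]
        mk = sub.mean(axis=0)
        B += sub.shape[0] * np.outer(mk - grand, mk - grand)
        dev = sub - mk
        W += dev.T @ dev
    # guard singular within-class scatter
    try:
        cho = linalg.cholesky(W, lower=True)
        cond_bad = 1.0 / np.linalg.cond(W) < np.finfo(float).eps
    except linalg.LinAlgError:
        cho, cond_bad = None, True
    if cho is None or cond_bad:
        warnings.warn(
            "singular within-class covariance; applying ridge regularization",
            stacklevel=2,
        )
        W = W + ridge * (np.trace(W) / p) * np.eye(p)
    s = min(p, g - 1)
    evals, evecs = linalg.eigh(B, W)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order][:s], 0.0, None)
    A = evecs[:, order][:, :s]
    # scale canonical coefficients: unit within-group variance of the variates
    Sw = W / (n - g)
    norms = np.sqrt(np.einsum("ij,jk,ki->i", A.T, Sw, A))
    norms[norms == 0] = 1.0
    A = A / norms
    scores = (Y - grand) @ A

    dims = np.arange(s)
    wilks = np.array([np.prod(1.0 / (1.0 + evals[d:])) for d in dims])
    factor = n - 1 - (p + g) / 2.0
    with np.errstate(divide="ignore"):
        chi2 = -factor * np.log(wilks)
    dof = np.array([(p - d) * (g - 1 - d) for d in dims], dtype=float)
    p_values = sps.chi2.sf(chi2, dof)
    return ManovaResult(
        p_values=p_values,
        wilks=wilks,
        chi2=chi2,
        dof=dof,
        eigenvalues=evals,
        projection=A,
        scores=scores,
        groups=groups,
    )


# ---------------------------------------------------------------------------
# Silhouette
# ---------------------------------------------------------------------------

@dataclass
class SilhouetteResult:
    s: np.ndarray
    a: np.ndarray
    b: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.s))


def silhouette(points: np.ndarray, labels) -> SilhouetteResult:
    """Per-point silhouette S_i = (b_i - a_i) / max(a_i, b_i).

    a_i is the mean Euclidean distance from point i to the other members of
    its own cluster; b_i the smallest mean distance to any other cluster.
    Members of singleton clusters get S_i = 0 by convention.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points.reshape(-1, 1)
    labels = np.asarray(labels)
    if points.shape[0] != labels.shape[0]:
        raise ValueError("points and labels must have matching first dimension")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("silhouette requires at least two clusters")
    D = cdist(points, points)
    n = points.shape[0]
    a = np.full(n, np.nan)
    b = np.full(n, np.nan)
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own > 1:
            a[i] = D[i, own].sum() / (n_own - 1)
        b[i] = min(D[i, labels == c].mean() for c in classes if c != labels[i])
        if n_own > 1:
            s[i] = (b[i] - a[i]) / max(a[i], b[i])
    return SilhouetteResult(s=s, a=a, b=b)


# ---------------------------------------------------------------------------
# Timing--power correlation
# ---------------------------------------------------------------------------

def timing_power_correlation(
    events,
    trace: np.ndarray,
    fs_hz: float,
    window_s: float = 0.25,
    trial: int = 0,
    t_zero_s: float = 0.0,
) -> float:
    """Pearson r between sliding event counts and sliding trace variance.

    ``events`` is either a TMPPTrain (events of ``trial`` are used) or a
    sequence of event times in seconds.  Both series are computed on
    ``window_s`` windows hopping by half a window (mirroring the spectrogram
    convention); returns NaN when either series is constant or empty.
    """
    if isinstance(events, TMPPTrain):
        taus = np.array([e.tau_s for e in events.trial_events(trial)])
    else:
        taus = np.asarray(list(events), dtype=float)
    trace = np.asarray(trace, dtype=float)
    if taus.size == 0:
        return np.nan
    nper = int(round(window_s * fs_hz))
    hop = max(nper // 2, 1)
    starts = np.arange(0, trace.size - nper + 1, hop)
    if starts.size < 3:
        return np.nan
    counts = np.empty(starts.size)
    variances = np.empty(starts.size)
    tau_samples = (taus + t_zero_s) * fs_hz
    for k, st in enumerate(starts):
        counts[k] = np.sum((tau_samples >= st) & (tau_samples < st + nper))
        variances[k] = np.var(trace[st : st + nper])
    if np.ptp(counts) == 0 or np.ptp(variances) == 0:
        return np.nan
    return float(sps.pearsonr(counts, variances)[0])


# ---------------------------------------------------------------------------
# Randomization test
# ---------------------------------------------------------------------------

@dataclass
class RandomizationResult:
    observed: float
    null: np.ndarray
    percentile: float  # percentile of the observed value within the null


def randomization_test(
    Y: np.ndarray,
    labels,
    statistic: str = "mean_silhouette",
    n_perm: int = 1000,
    seed: int = 0,
) -> RandomizationResult:
    """Label-shuffle null for a separability statistic.

    ``statistic`` is ``"mean_silhouette"`` (mean silhouette of the raw
    feature rows) or ``"manova_p"`` (the p-value of the highest-dimension
    MANOVA null).  Labels are permuted ``n_perm`` times with a seeded
    generator; the observed statistic is located on the null distribution.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    labels = np.asarray(labels)

    def stat(lab):
        if statistic == "mean_silhouette":
            return silhouette(Y, lab).mean
        if statistic == "manova_p":
            return float(one_way_manova(Y, lab).p_values[-1])
        raise ValueError(f"unknown statistic {statistic!r}")

    observed = stat(labels)
    rng = np.random.default_rng(seed)
    null = np.array([stat(rng.permutation(labels)) for _ in range(n_perm)])
    percentile = 100.0 * np.mean(null <= observed)
    return RandomizationResult(observed=observed, null=null, percentile=percentile)


# ---------------------------------------------------------------------------
# Sample-wise detection scoring
# ---------------------------------------------------------------------------

@dataclass
class DetectionScore:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def TPR(self) -> float:
        d = self.TP + self.FN
        return self.TP / d if d else 0.0

    @property
    def FPR(self) -> float:
        d = self.FP + self.TN
        return self.FP / d if d else 0.0


def _span_mask(spans, n_samples: int) -> np.ndarray:
    mask = np.zeros(n_samples, dtype=bool)
    for lo, hi in spans:
        mask[max(0, int(lo)) : min(n_samples, int(hi))] = True
    return mask


def sample_wise_detection(pred_spans, truth_spans, n_samples: int) -> DetectionScore:
    """Per-sample confusion counts between predicted and true event spans.

    Spans are half-open sample intervals clipped to [0, n_samples).  A sample
    is a true positive when both the prediction and the ground truth mark it
    as part of a micro-event.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    pred = _span_mask(pred_spans, n_samples)
    truth = _span_mask(truth_spans, n_samples)
    return DetectionScore(
        TP=int(np.sum(pred & truth)),
        FP=int(np.sum(pred & ~truth)),
        TN=int(np.sum(~pred & ~truth)),
        FN=int(np.sum(~pred & truth)),
    )
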