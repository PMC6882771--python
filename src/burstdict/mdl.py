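"""MDL-based hierarchical clustering of selected snippets into a burst dictionary.

The selected M-snippets (columns of X) are partitioned by greedily applying
whichever of three clustering operators -- create a cluster from a motif pair,
add a snippet to a cluster, merge two clusters -- saves the most bits
("bitsave") in a lossless description of X.  The number of atoms K is an
emergent property of the compression, never fixed a priori, and learned atom
durations are free to drift off the initial duration grid (Delta) through
merging, up to the snippet length M.

Bit accounting
--------------
Sequences are quantized to ``L`` amplitude levels (default 64) by per-sequence
min-max scaling, and the description length of a sequence is its length times
the empirical Shannon entropy of its symbol histogram.  Describing a snippet A
through a hypothesis waveform H costs the description length of the residual
of A after the best cross-correlation alignment of H is subtracted at matched
scale; the residual is quantized with A's own step so that conditional and
unconditional description lengths are directly comparable, and it is charged
over the full length of A (samples outside the aligned support at their raw
cost).

A cluster is described by whichever of two realizable two-part codes is
shorter (the MDL principle applied to the coding itself):

* exemplar code -- the member best matching the cluster's average center
  acts as the hypothesis carrier and is stored raw; every other member is
  stored as its residual against the carrier's aligned, unit-normalized
  window.  The carrier's conditional term is thereby the discounted one:

      DLC_ex(C) = DL(A*) + sum_{A in C, A != A*} DL(A | window(A*))

  This code is cheapest for small clusters (nothing but members is
  transmitted) and is what lets a two-member cluster pay for itself.

* center code -- the quantized center itself is transmitted, and every
  member is stored as its residual against it:

      DLC_ctr(C) = DL(H) + sum_{A in C} DL(A | H)

  For populous clusters the averaged center is cleaner than any single
  member, so the residuals are smaller and this code wins; merging two such
  clusters then saves an entire center transmission, which is what lets
  same-waveform clusters consolidate.

DLC(C) = min(DLC_ex, DLC_ctr).  The cluster's *center* (the reported atom)
is the unit-norm, sign-aligned average of the aligned member windows;
min-max quantization is scale-invariant, so for duplicate-member clusters
both codes coincide and the classic identities hold exactly (a cluster of
two identical sequences costs DL(A); a singleton costs DL(H)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .synthetic import Atom

__all__ = [
    "QuantizedSeq",
    "Cluster",
    "Dictionary",
    "LearnConfig",
    "MotifPair",
    "quantize",
    "dequantize",
    "description_length",
    "sequence_dl",
    "conditional_dl",
    "cluster_dl",
    "bitsave_create",
    "bitsave_add",
    "bitsave_merge",
    "find_motifs",
    "motif_score_null",
    "learn_dictionary",
]

DEFAULT_LEVELS = 64


# ---------------------------------------------------------------------------
# Quantization and description length
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuantizedSeq:
    """Integer symbol sequence with the affine map back to amplitudes."""

    symbols: np.ndarray
    L: int
    scale: float
    offset: float

    @property
    def m(self) -> int:
        return int(self.symbols.size)


def quantize(seq: np.ndarray, L: int = DEFAULT_LEVELS) -> QuantizedSeq:
    """Min-max quantize a sequence to ``L`` levels.

    The map is affine (``value ~= symbol * scale + offset``), so symbol
    histograms -- and hence description lengths -- are invariant to scaling
    and shifting of the input, making DLs from different clusters and
    dimensions comparable.  A constant sequence maps to a single symbol.
    """
    seq = np.asarray(seq, dtype=float)
    if seq.ndim != 1 or seq.size < 1:
        raise ValueError("seq must be a non-empty 1-D sequence")
    if L < 2:
        raise ValueError("L must be >= 2")
    lo = float(seq.min())
    rng = float(seq.max() - lo)
    if rng == 0:
        return QuantizedSeq(np.zeros(seq.size, dtype=np.int64), L, 0.0, lo)
    scale = rng / (L - 1)
    symbols = np.clip(np.round((seq - lo) / scale), 0, L - 1).astype(np.int64)
    return QuantizedSeq(symbols, L, scale, lo)


def dequantize(q: QuantizedSeq) -> np.ndarray:
    return q.symbols * q.scale + q.offset


def _entropy_bits(symbols: np.ndarray) -> float:
    """Empirical Shannon entropy (base 2) of an integer symbol sequence."""
    symbols = np.asarray(symbols)
    counts = np.bincount(symbols - symbols.min())
    counts = counts[counts > 0]
    p = counts / symbols.size
    return float(-(p * np.log2(p)).sum())


def description_length(q: QuantizedSeq) -> float:
    """DL of a quantized sequence: length times symbol entropy, in bits."""
    if q.m < 1:
        raise ValueError("empty sequence")
    return q.m * _entropy_bits(q.symbols)


def sequence_dl(seq: np.ndarray, L: int = DEFAULT_LEVELS) -> float:
    """Shorthand for ``description_length(quantize(seq, L))``."""
    return description_length(quantize(seq, L))


# ---------------------------------------------------------------------------
# Alignment and conditional description length
# ---------------------------------------------------------------------------

class Alignment(NamedTuple):
    lag: int
    sign: float
    ncc: float


def best_alignment(A: np.ndarray, H: np.ndarray, polarity: bool = True) -> Alignment:
    """Best placement of H inside A by normalized cross-correlation.

    Scans every admissible lag (H fully inside A).  With ``polarity`` the
    magnitude of the correlation is maximized and the matching sign returned;
    bandpassed bursts are sign-ambiguous.
    """
    A = np.asarray(A, dtype=float)
    H = np.asarray(H, dtype=float)
    if H.size > A.size:
        raise ValueError("hypothesis longer than sequence: no admissible lag")
    Hn = float(np.linalg.norm(H))
    if Hn == 0:
        return Alignment(0, 1.0, 0.0)
    W = sliding_window_view(A, H.size)
    dots = W @ H
    wn = np.linalg.norm(W, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ncc = np.where(wn > 0, dots / (wn * Hn), 0.0)
    score = np.abs(ncc) if polarity else ncc
    lag = int(np.argmax(score))
    sign = 1.0 if (not polarity or ncc[lag] >= 0) else -1.0
    return Alignment(lag, sign, float(ncc[lag]))


class ConditionalDL(NamedTuple):
    bits: float
    lag: int
    sign: float


def conditional_dl(
    A: np.ndarray,
    H: np.ndarray,
    L: int = DEFAULT_LEVELS,
    polarity: bool = True,
) -> ConditionalDL:
    """DL(A|H): bits to describe A given hypothesis H, plus the best lag.

    H (unit-normalized internally) is aligned to A at the lag maximizing the
    normalized cross-correlation, rescaled to the aligned window's norm,
    subtracted over the aligned support, and the full-length residual is
    quantized with A's own quantization step.  An exact (possibly shifted,
    possibly sign-flipped) embedded copy of H therefore costs 0 bits.
    """
    A = np.asarray(A, dtype=float)
    H = np.asarray(H, dtype=float)
    align = best_alignment(A, H, polarity=polarity)
    Hn = np.linalg.norm(H)
    Hu = H / Hn if Hn > 0 else H
    w = A[align.lag : align.lag + H.size]
    wn = np.linalg.norm(w)
    resid = A.copy()
    resid[align.lag : align.lag + H.size] = w - align.sign * wn * Hu
    step = float(np.ptp(A)) / (L - 1)
    if step == 0:
        step = 1.0
    symbols = np.round(resid / step).astype(np.int64)
    bits = A.size * _entropy_bits(symbols)
    return ConditionalDL(bits, align.lag, align.sign)


# ---------------------------------------------------------------------------
# Clusters
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    """A cluster: unit-norm center waveform plus its member snippets."""

    center: np.ndarray
    member_seqs: list
    member_ids: list | None = None
    dl_cached: float = field(default=np.nan)

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        nrm = np.linalg.norm(self.center)
        if abs(nrm - 1.0) > 1e-9:
            raise ValueError("cluster center must be unit-norm")

    @property
    def n_members(self) -> int:
        return len(self.member_seqs)

    @property
    def duration(self) -> int:
        return int(self.center.size)


def _refresh_center(
    center: np.ndarray, member_seqs, polarity: bool = True, max_passes: int = 4
) -> np.ndarray:
    """Re-average the members' aligned, normalized windows; renormalize.

    Alignment and averaging are alternated until the center stabilizes (a
    few passes suffice), so the reported atom is a fixed point of the
    align-average map rather than a single-pass compromise.
    """
    center = np.asarray(center, dtype=float)
    for _ in range(max_passes):
        acc = np.zeros(center.size)
        for A in member_seqs:
            al = best_alignment(A, center, polarity=polarity)
            w = np.asarray(A, dtype=float)[al.lag : al.lag + center.size]
            wn = np.linalg.norm(w)
            if wn > 0:
                acc += al.sign * w / wn
        nrm = np.linalg.norm(acc)
        if nrm == 0:
            return center
        new = acc / nrm
        if np.linalg.norm(new - center) < 1e-9:
            return new
        center = new
    return center


def _carrier_index(C: Cluster, polarity: bool = True) -> int:
    """Member best matching the average center (the hypothesis carrier).

    Scores within 1e-9 are treated as tied (two-member clusters are exactly
    symmetric up to rounding) and the lowest member index wins.
    """
    scores = np.empty(C.n_members)
    for i, A in enumerate(C.member_seqs):
        al = best_alignment(A, C.center, polarity=polarity)
        scores[i] = abs(al.ncc) if polarity else al.ncc
    return int(np.flatnonzero(scores >= scores.max() - 1e-9)[0])


def _carrier_window(C: Cluster, idx: int, polarity: bool = True) -> np.ndarray:
    A = np.asarray(C.member_seqs[idx], dtype=float)
    al = best_alignment(A, C.center, polarity=polarity)
    w = A[al.lag : al.lag + C.center.size]
    wn = np.linalg.norm(w)
    return (al.sign * w / wn) if wn > 0 else C.center


def cluster_dl(C: Cluster, L: int = DEFAULT_LEVELS, polarity: bool = True) -> float:
    """Bits needed to represent all member snippets of cluster C.

    Minimum of the two realizable codes: exemplar (carrier member raw, other
    members conditional on the carrier's aligned unit-norm window) and
    center (the quantized center transmitted, every member conditional on
    it).  See the module docstring for why both are needed.
    """
    if C.n_members == 0:
        raise ValueError("cluster is empty")
    ci = _carrier_index(C, polarity=polarity)
    Hw = _carrier_window(C, ci, polarity=polarity)
    bits_ex = sequence_dl(np.asarray(C.member_seqs[ci], dtype=float), L)
    bits_ctr = sequence_dl(C.center, L)
    for i, A in enumerate(C.member_seqs):
        A = np.asarray(A, dtype=float)
        if i != ci:
            bits_ex += conditional_dl(A, Hw, L, polarity=polarity).bits
        bits_ctr += conditional_dl(A, C.center, L, polarity=polarity).bits
    return min(bits_ex, bits_ctr)


# ---------------------------------------------------------------------------
# Bitsave operators
# ---------------------------------------------------------------------------

def _best_window_pair(A, B, delta, polarity=True):
    """Best (pos_a, pos_b, sign, ncc) over all delta-length window pairs."""
    WA = sliding_window_view(np.asarray(A, dtype=float), delta)
    WB = sliding_window_view(np.asarray(B, dtype=float), delta)
    na = np.linalg.norm(WA, axis=1)
    nb = np.linalg.norm(WB, axis=1)
    G = WA @ WB.T
    denom = np.outer(na, nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        ncc = np.where(denom > 0, G / denom, 0.0)
    score = np.abs(ncc) if polarity else ncc
    ia, jb = np.unravel_index(np.argmax(score), score.shape)
    sign = 1.0 if (not polarity or ncc[ia, jb] >= 0) else -1.0
    return int(ia), int(jb), sign, float(ncc[ia, jb])


def _make_cluster(center, member_seqs, member_ids, L, polarity):
    C = Cluster(center=center, member_seqs=list(member_seqs), member_ids=member_ids)
    C.dl_cached = cluster_dl(C, L, polarity=polarity)
    return C


def bitsave_create(
    A: np.ndarray,
    B: np.ndarray,
    delta: int | None = None,
    L: int = DEFAULT_LEVELS,
    polarity: bool = True,
    ids: tuple | None = None,
):
    """Bits saved by creating a cluster from subsequences A and B.

    BS = DL(A) + DL(B) - DLC(C).  The initial center is the unit-norm average
    of the best-correlated delta-length window pair (delta defaults to the
    shorter input's length).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if delta is None:
        delta = min(A.size, B.size)
    if delta > min(A.size, B.size):
        raise ValueError("delta exceeds an input's length")
    ia, jb, sign, _ = _best_window_pair(A, B, delta, polarity=polarity)
    wa = A[ia : ia + delta]
    wb = B[jb : jb + delta]
    nwa, nwb = np.linalg.norm(wa), np.linalg.norm(wb)
    wa = wa / nwa if nwa > 0 else wa
    wb = wb / nwb if nwb > 0 else wb
    center = wa + sign * wb
    nrm = np.linalg.norm(center)
    center = center / nrm if nrm > 0 else np.ones(delta) / np.sqrt(delta)
    C = _make_cluster(center, [A, B], list(ids) if ids else None, L, polarity)
    bs = sequence_dl(A, L) + sequence_dl(B, L) - C.dl_cached
    return bs, C


def bitsave_add(
    A: np.ndarray,
    C: Cluster,
    L: int = DEFAULT_LEVELS,
    polarity: bool = True,
    member_id=None,
):
    """Bits saved by adding subsequence A to cluster C (append-only).

    BS = DL(A) + DLC(C) - DLC(C'), where C' contains A and has its center
    refreshed as the aligned average of all members.
    """
    A = np.asarray(A, dtype=float)
    old_dl = C.dl_cached if np.isfinite(C.dl_cached) else cluster_dl(C, L, polarity)
    seqs = list(C.member_seqs) + [A]
    ids = (list(C.member_ids) + [member_id]) if C.member_ids is not None else None
    center = _refresh_center(C.center, seqs, polarity=polarity)
    C2 = _make_cluster(center, seqs, ids, L, polarity)
    bs = sequence_dl(A, L) + old_dl - C2.dl_cached
    return bs, C2


def _trim_energy(center: np.ndarray, keep_frac: float = 1.0) -> np.ndarray:
    """Drop leading/trailing samples while retaining >= keep_frac of energy."""
    c = np.asarray(center, dtype=float)
    total = float(np.sum(c**2))
    if total == 0:
        return c
    lo, hi = 0, c.size
    energy = total
    while hi - lo > 2:
        head, tail = c[lo] ** 2, c[hi - 1] ** 2
        drop = min(head, tail)
        if (energy - drop) < keep_frac * total:
            break
        if head <= tail:
            lo += 1
        else:
            hi -= 1
        energy -= drop
    return c[lo:hi]


def bitsave_merge(
    C1: Cluster,
    C2: Cluster,
    L: int = DEFAULT_LEVELS,
    polarity: bool = True,
    max_len: int | None = None,
    keep_frac: float = 1.0,
):
    """Bits saved by merging clusters C1 and C2.

    BS = DLC(C1) + DLC(C2) - DLC(C').  Three candidate merged centers are
    evaluated -- the member-count-weighted average of the two parent centers
    over the union of their aligned supports (trimmed of low-energy edges,
    capped at ``max_len``), and each parent's own center (both refreshed as
    the aligned average of all members and as-is, since refreshing toward a
    small incoming cluster can cost the host cluster more than it gains) --
    and the candidate with the smallest cluster DL wins.  The merged duration may therefore differ from either
    parent's (this is how learned durations drift off the initial grid).
    """
    a, b = C1.center, C2.center
    if b.size > a.size:
        return bitsave_merge(C2, C1, L, polarity, max_len, keep_frac)
    # full-range alignment of the shorter center against the longer one
    min_ov = max(b.size // 2, 2)
    best = (0, 1.0, -np.inf)
    for s in range(-(b.size - min_ov), a.size - min_ov + 1):
        lo_a, hi_a = max(0, s), min(a.size, s + b.size)
        wa = a[lo_a:hi_a]
        wb = b[lo_a - s : hi_a - s]
        na, nb = np.linalg.norm(wa), np.linalg.norm(wb)
        if na == 0 or nb == 0:
            continue
        ncc = float(wa @ wb) / (na * nb)
        sc = abs(ncc) if polarity else ncc
        if sc > best[2]:
            best = (s, 1.0 if (not polarity or ncc >= 0) else -1.0, sc)
    s, sign, _ = best
    lo = min(0, s)
    hi = max(a.size, s + b.size)
    pa = np.zeros(hi - lo)
    pb = np.zeros(hi - lo)
    pa[-lo : -lo + a.size] = a
    pb[s - lo : s - lo + b.size] = sign * b
    w1, w2 = C1.n_members, C2.n_members
    union = (w1 * pa + w2 * pb) / (w1 + w2)
    union = _trim_energy(union, keep_frac)
    if max_len is not None and union.size > max_len:
        excess = union.size - max_len
        union = union[excess // 2 : excess // 2 + max_len]
    seqs = list(C1.member_seqs) + list(C2.member_seqs)
    ids = None
    if C1.member_ids is not None and C2.member_ids is not None:
        ids = list(C1.member_ids) + list(C2.member_ids)
    Cm = None
    seen = []
    for init, refresh in (
        (union, True),
        (C1.center, True),
        (C2.center, True),
        (C1.center, False),
        (C2.center, False),
    ):
        nrm = np.linalg.norm(init)
        if nrm == 0:
            continue
        center = init / nrm
        if refresh:
            center = _refresh_center(center, seqs, polarity=polarity)
        if any(c.size == center.size and np.allclose(c, center) for c in seen):
            continue
        seen.append(center)
        cand = _make_cluster(center, seqs, ids, L, polarity)
        if Cm is None or cand.dl_cached < Cm.dl_cached:
            Cm = cand
    dl1 = C1.dl_cached if np.isfinite(C1.dl_cached) else cluster_dl(C1, L, polarity)
    dl2 = C2.dl_cached if np.isfinite(C2.dl_cached) else cluster_dl(C2, L, polarity)
    bs = dl1 + dl2 - Cm.dl_cached
    return bs, Cm


# ---------------------------------------------------------------------------
# Motif discovery
# ---------------------------------------------------------------------------

class MotifPair(NamedTuple):
    i: int
    j: int
    pos_i: int
    pos_j: int
    sign: float
    score: float

    @property
    def lag(self) -> int:
        return self.pos_j - self.pos_i


def _pair_score_matrix(X: np.ndarray, delta: int, polarity: bool = True) -> np.ndarray:
    """(Psi x Psi) max normalized window cross-correlation per snippet pair."""
    M, psi = X.shape
    nw = M - delta + 1
    W = sliding_window_view(X.T, delta, axis=1)  # (psi, nw, delta)
    norms = np.linalg.norm(W, axis=2, keepdims=True)
    Wn = np.where(norms > 0, W / np.where(norms > 0, norms, 1.0), 0.0)
    V = Wn.reshape(psi * nw, delta)
    scores = np.empty((psi, psi))
    # chunk rows to bound the gram-block memory footprint
    rows_per_snip = nw
    chunk = max(1, int(4e7 // max(1, psi * nw * rows_per_snip)))
    for start in range(0, psi, chunk):
        stop = min(psi, start + chunk)
        block = V[start * nw : stop * nw] @ V.T  # (nc*nw, psi*nw)
        block = block.reshape(stop - start, nw, psi, nw)
        if polarity:
            block = np.abs(block)
        scores[start:stop] = block.max(axis=(1, 3))
    np.fill_diagonal(scores, -np.inf)
    return scores


def find_motifs(
    X: np.ndarray, delta: int, top_k: int = 1, polarity: bool = True
) -> list[MotifPair]:
    """Top disjoint snippet pairs by maximal windowed cross-correlation.

    For every snippet pair the score is the largest normalized
    cross-correlation over all placements of a delta-length window in each
    snippet; the ``top_k`` best pairs with no snippet in common are returned,
    with the winning window positions and relative sign.
    """
    X = np.asarray(X, dtype=float)
    M, psi = X.shape
    if psi < 2:
        raise ValueError("need at least two snippets to find motifs")
    if delta > M:
        raise ValueError("delta exceeds snippet length M")
    scores = _pair_score_matrix(X, delta, polarity=polarity)
    iu = np.triu_indices(psi, k=1)
    order = np.argsort(scores[iu])[::-1]
    used: set[int] = set()
    out: list[MotifPair] = []
    for k in order:
        i, j = int(iu[0][k]), int(iu[1][k])
        if i in used or j in used:
            continue
        ia, jb, sign, ncc = _best_window_pair(X[:, i], X[:, j], delta, polarity)
        out.append(MotifPair(i, j, ia, jb, sign, abs(ncc) if polarity else ncc))
        used.update((i, j))
        if len(out) >= top_k:
            break
    return out


# ---------------------------------------------------------------------------
# Greedy dictionary learning
# ---------------------------------------------------------------------------

@dataclass
class LearnConfig:
    """Hyperparameters of the greedy MDL clustering."""

    delta_grid: tuple
    M: int
    L: int = DEFAULT_LEVELS
    max_iterations: int = 10_000
    seed: int = 0
    polarity: bool = True
    fs_hz: float = 500.0
    motif_top: int = 3  # create candidates evaluated per duration
    null_gate_perms: int = 19  # sample-permutation draws calibrating the create gate (0 = off)

    def __post_init__(self):
        self.delta_grid = tuple(int(d) for d in self.delta_grid)
        if not self.delta_grid:
            raise ValueError("delta_grid must be non-empty")
        if any(d < 2 or d > self.M for d in self.delta_grid):
            raise ValueError("every delta must satisfy 2 <= delta <= M")


@dataclass
class Dictionary:
    """Learned atoms, the operator log of the greedy run, and cluster provenance."""

    atoms: list[Atom]
    learn_log: list[dict]
    clusters: list[Cluster] | None = None

    @property
    def K(self) -> int:
        return len(self.atoms)


def _dominant_freq(w: np.ndarray, fs_hz: float) -> float:
    spec = np.abs(np.fft.rfft(w))
    if spec.size < 2:
        return 0.0
    return float(np.fft.rfftfreq(w.size, d=1.0 / fs_hz)[np.argmax(spec)])


def _center_to_atom(center: np.ndarray, atom_id: int, fs_hz: float) -> Atom:
    c = center / np.linalg.norm(center)
    return Atom(
        waveform=c,
        atom_id=atom_id,
        center_freq_hz=_dominant_freq(c, fs_hz),
        fs_hz=fs_hz,
    )


def motif_score_null(
    X: np.ndarray, delta: int, n_perms: int, polarity: bool = True, seed: int = 0
) -> float:
    """Null level for the best motif-pair score under sample permutation.

    Permuting each snippet's samples destroys any shared waveform while
    preserving the amplitude marginals; the maximum pair score over the
    permuted matrix calibrates how large a best-pair correlation arises from
    featureless data alone.  Returns the maximum over ``n_perms`` draws
    (the conservative tail of the null).
    """
    rng = np.random.default_rng(seed)
    best = -np.inf
    for _ in range(n_perms):
        Xp = np.empty_like(X)
        for j in range(X.shape[1]):
            Xp[:, j] = rng.permutation(X[:, j])
        best = max(best, float(_pair_score_matrix(Xp, delta, polarity).max()))
    return best


def enumerate_operators(
    X, clusters, unassigned, config, score_matrices=None, create_gates=None
):
    """All candidate operators for one greedy step, with their bitsaves.

    Candidates are: for each cluster, adding the unassigned snippet whose
    windows correlate best with the center; every cluster pair merge; and for
    each duration in the grid, creating a cluster from the top unassigned
    motif pairs (pairs whose score does not exceed the permutation-null gate
    for that duration, when one is supplied, are not candidates).  Returns a
    list of dicts in deterministic candidate order (adds, merges, creates).
    """
    L, pol = config.L, config.polarity
    cands = []
    un = sorted(unassigned)
    # -- adds
    for ci, C in enumerate(clusters):
        best_j, best_s = None, -np.inf
        for j in un:
            al = best_alignment(X[:, j], C.center, polarity=pol)
            s = abs(al.ncc) if pol else al.ncc
            if s > best_s:
                best_j, best_s = j, s
        if best_j is not None:
            bs, C2 = bitsave_add(X[:, best_j], C, L, pol, member_id=best_j)
            cands.append(
                {"op": "add", "bs": bs, "cluster": ci, "snippet": best_j, "new": C2}
            )
    # -- merges
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            bs, Cm = bitsave_merge(
                clusters[i], clusters[j], L, pol, max_len=config.M
            )
            cands.append({"op": "merge", "bs": bs, "pair": (i, j), "new": Cm})
    # -- creates
    if len(un) >= 2:
        for delta in config.delta_grid:
            gate = -np.inf if create_gates is None else create_gates.get(delta, -np.inf)
            if score_matrices is not None:
                scores = score_matrices[delta][np.ix_(un, un)]
            else:
                scores = _pair_score_matrix(X[:, un], delta, polarity=pol)
            iu = np.triu_indices(len(un), k=1)
            order = np.argsort(scores[iu])[::-1][: config.motif_top]
            pairs = [
                (un[int(iu[0][k])], un[int(iu[1][k])])
                for k in order
                if scores[iu][k] > gate
            ]
            for i, j in pairs:
                bs, C = bitsave_create(
                    X[:, i], X[:, j], delta, L, pol, ids=(i, j)
                )
                cands.append(
                    {"op": "create", "bs": bs, "pair": (i, j), "delta": delta, "new": C}
                )
    return cands


def _pick_operator(cands):
    """Largest bitsave per snippet consumed; ties add > merge > create, then order.

    A create encodes two snippets at once, an add one (a merge none), so raw
    bitsaves are not commensurable across operators: comparing them directly
    lets a pair-create outbid two individually better adds and strands small
    satellite clusters.  Creates therefore compete at half their bitsave (the
    marginal compression per snippet); the applied operator must still have a
    positive raw bitsave.
    """
    prio = {"add": 0, "merge": 1, "create": 2}
    best, best_key = None, None
    for k, c in enumerate(cands):
        value = c["bs"] / 2.0 if c["op"] == "create" else c["bs"]
        key = (-value, prio[c["op"]], k)
        if best_key is None or key < best_key:
            best, best_key = c, key
    return best


def learn_dictionary(X: np.ndarray, config: LearnConfig):
    """Greedy MDL clustering of the snippet matrix X into a dictionary.

    Iterates create/add/merge, applying the single operator with the largest
    positive bitsave until none remains (or ``max_iterations``).  Returns the
    dictionary (atoms = final cluster centers, unit-norm, K emergent) and a
    per-snippet assignment vector (atom index, -1 for unassigned).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be an (M x Psi) matrix")
    M, psi = X.shape
    log: list[dict] = []
    if psi == 0:
        warnings.warn("empty snippet matrix: returning an empty dictionary", stacklevel=2)
        return Dictionary(atoms=[], learn_log=log), np.empty(0, dtype=int)
    if psi < 2:
        warnings.warn("fewer than two snippets: nothing to cluster", stacklevel=2)
        return Dictionary(atoms=[], learn_log=log), np.full(psi, -1, dtype=int)
    score_matrices = {
        d: _pair_score_matrix(X, d, polarity=config.polarity) for d in config.delta_grid
    }
    create_gates = None
    if config.null_gate_perms > 0:
        create_gates = {
            d: motif_score_null(
                X, d, config.null_gate_perms, config.polarity, seed=config.seed
            )
            for d in config.delta_grid
        }
    clusters: list[Cluster] = []
    unassigned = set(range(psi))
    for it in range(config.max_iterations):
        cands = enumerate_operators(
            X, clusters, unassigned, config, score_matrices, create_gates
        )
        if not cands:
            break
        chosen = _pick_operator(cands)
        if chosen["bs"] <= 0:
            break
        if chosen["op"] == "add":
            clusters[chosen["cluster"]] = chosen["new"]
            unassigned.discard(chosen["snippet"])
            log.append(
                {"iter": it, "op": "add", "bitsave": chosen["bs"],
                 "cluster": chosen["cluster"], "snippet": chosen["snippet"]}
            )
        elif chosen["op"] == "merge":
            i, j = chosen["pair"]
            merged = chosen["new"]
            clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
            clusters.append(merged)
            log.append({"iter": it, "op": "merge", "bitsave": chosen["bs"], "pair": (i, j)})
        else:
            i, j = chosen["pair"]
            clusters.append(chosen["new"])
            unassigned.difference_update((i, j))
            log.append(
                {"iter": it, "op": "create", "bitsave": chosen["bs"],
                 "pair": (i, j), "delta": chosen["delta"]}
            )
    atoms = [
        _center_to_atom(C.center, k, config.fs_hz) for k, C in enumerate(clusters)
    ]
    assignments = np.full(psi, -1, dtype=int)
    for k, C in enumerate(clusters):
        for mid in C.member_ids or []:
            if mid is not None:
                assignments[mid] = k
    return Dictionary(atoms=atoms, learn_log=log, clusters=clusters), assignments
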