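"""Ground-truth simulator for burst-laden single-channel ensembles.

Generates multi-trial recordings following the additive generative picture of
rhythm-specific electrophysiology: a Gaussian background (the network at rest)
with sparse, weighted, shifted unit-norm burst waveforms superimposed (the
network in its active state), plus independent sensor noise.  Every event that
enters a trace is retained as ground truth so that detection, dictionary
recovery and encoding can be scored exactly.

Conventions
-----------
* An event's ``tau_samples`` is the *midpoint* of the atom support within the
  trial: the atom occupies ``[tau - d//2, tau - d//2 + d)`` for duration ``d``.
* Events must fit entirely inside the trial; edge events are rejected rather
  than truncated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "PlannedEvent",
    "EventPlan",
    "NoiseModel",
    "SyntheticEnsemble",
    "make_burst_atom",
    "sample_event_plan",
    "validate_plan",
    "synthesize",
    "simulate_labeled_ensemble",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """A unit-l2-norm prototypical burst waveform.

    ``center_freq_hz`` is a descriptor only (dominant oscillation frequency);
    the waveform itself is the atom.
    """

    waveform: np.ndarray
    atom_id: int
    center_freq_hz: float
    fs_hz: float

    def __post_init__(self):
        w = np.asarray(self.waveform, dtype=float)
        object.__setattr__(self, "waveform", w)
        if w.ndim != 1 or w.size < 1:
            raise ValueError("atom waveform must be a non-empty 1-D sequence")
        nrm = float(np.linalg.norm(w))
        if abs(nrm - 1.0) > 1e-9:
            raise ValueError(f"atom waveform must have unit l2-norm, got {nrm!r}")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    @property
    def duration_samples(self) -> int:
        return int(self.waveform.size)

    @property
    def duration_s(self) -> float:
        return self.duration_samples / self.fs_hz


@dataclass(frozen=True)
class PlannedEvent:
    trial_index: int
    tau_samples: int
    alpha: float
    atom_id: int


@dataclass
class EventPlan:
    """Ground-truth event list for an ensemble."""

    events: list[PlannedEvent]
    min_separation_samples: int

    def __post_init__(self):
        if self.min_separation_samples < 1:
            raise ValueError("min_separation_samples must be >= 1")
        self.events = sorted(
            self.events, key=lambda e: (e.trial_index, e.tau_samples)
        )
        prev: dict[int, int] = {}
        for ev in self.events:
            last = prev.get(ev.trial_index)
            if last is not None and ev.tau_samples - last < self.min_separation_samples:
                raise ValueError(
                    "within-trial event gap below min_separation_samples "
                    f"(trial {ev.trial_index}: {last} -> {ev.tau_samples})"
                )
            prev[ev.trial_index] = ev.tau_samples

    def __len__(self) -> int:
        return len(self.events)

    def for_trial(self, trial: int) -> list[PlannedEvent]:
        return [e for e in self.events if e.trial_index == trial]


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian background (rest-state) plus additive sensor noise."""

    mu_z: float = 0.0
    sigma_z: float = 1.0
    epsilon_sigma: float = 0.0

    def __post_init__(self):
        if self.sigma_z <= 0:
            raise ValueError("sigma_z must be > 0")
        if self.epsilon_sigma < 0:
            raise ValueError("epsilon_sigma must be >= 0")


@dataclass
class SyntheticEnsemble:
    """Multi-trial single-channel ensemble with retained ground truth."""

    traces: np.ndarray  # (n_trials, trial_len)
    fs_hz: float
    labels: np.ndarray
    plan: EventPlan
    dictionary: list[Atom]
    noise: NoiseModel
    seed: int | None = None

    @property
    def n_trials(self) -> int:
        return int(self.traces.shape[0])

    @property
    def trial_len(self) -> int:
        return int(self.traces.shape[1])

    def event_spans(self, trial: int) -> list[tuple[int, int]]:
        """Half-open sample spans occupied by planted events in a trial."""
        atoms = {a.atom_id: a for a in self.dictionary}
        spans = []
        for ev in self.plan.for_trial(trial):
            d = atoms[ev.atom_id].duration_samples
            start = ev.tau_samples - d // 2
            spans.append((start, start + d))
        return spans


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def make_burst_atom(
    center_freq_hz: float,
    duration_s: float,
    fs_hz: float,
    envelope_shape: str = "hann",
    atom_id: int = 0,
    phase: float = 0.0,
) -> Atom:
    """Build a unit-norm amplitude-modulated sinusoid.

    A parametric stand-in for learned burst atoms: a cosine at
    ``center_freq_hz`` under a hann or gaussian envelope, normalized to unit
    l2-norm.  The waveform is symmetric about its midpoint (for ``phase`` 0),
    so the midpoint timing convention is exact for planted events.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if fs_hz <= 0:
        raise ValueError("fs_hz must be > 0")
    if not (0 < center_freq_hz < fs_hz / 2):
        raise ValueError(
            f"center_freq_hz={center_freq_hz} must lie strictly below the "
            f"Nyquist frequency {fs_hz / 2} Hz"
        )
    n = int(round(duration_s * fs_hz))
    if n < 2:
        raise ValueError("duration too short for the requested sampling rate")
    t = (np.arange(n) - (n - 1) / 2) / fs_hz
    if envelope_shape == "hann":
        # interior hann samples: strictly positive support
        env = np.hanning(n + 2)[1:-1]
    elif envelope_shape == "gaussian":
        sigma = duration_s / 6.0
        env = np.exp(-0.5 * (t / sigma) ** 2)
    else:
        raise ValueError(f"unknown envelope_shape {envelope_shape!r}")
    w = env * np.cos(2 * np.pi * center_freq_hz * t + phase)
    w = w / np.linalg.norm(w)
    return Atom(waveform=w, atom_id=atom_id, center_freq_hz=center_freq_hz, fs_hz=fs_hz)


def _draw_amplitudes(rng: np.random.Generator, n: int, amp_law) -> np.ndarray:
    """Draw event amplitudes from a distribution spec.

    ``amp_law`` may be ``None`` (lognormal, median 1, sigma-log 0.5), a dict
    ``{"dist": "lognormal", "median": m, "sigma": s}`` /
    ``{"dist": "fixed", "value": v}`` / ``{"dist": "uniform", "low": a,
    "high": b}``, or a callable ``f(rng, n) -> array``.
    """
    if amp_law is None:
        amp_law = {"dist": "lognormal", "median": 1.0, "sigma": 0.5}
    if callable(amp_law):
        return np.asarray(amp_law(rng, n), dtype=float)
    dist = amp_law.get("dist", "lognormal")
    if dist == "lognormal":
        med = float(amp_law.get("median", 1.0))
        sig = float(amp_law.get("sigma", 0.5))
        return rng.lognormal(mean=np.log(med), sigma=sig, size=n)
    if dist == "fixed":
        return np.full(n, float(amp_law["value"]))
    if dist == "uniform":
        return rng.uniform(float(amp_law["low"]), float(amp_law["high"]), size=n)
    raise ValueError(f"unknown amplitude law {dist!r}")


def sample_event_plan(
    n_trials: int,
    trial_len_samples: int,
    rate_per_s: float,
    fs_hz: float,
    amp_law=None,
    min_sep_samples: int = 1,
    atom_ids=(0,),
    margin_samples: int = 0,
    seed: int = 0,
) -> EventPlan:
    """Sample a homogeneous-rate event plan, thinned to a refractory gap.

    Candidate timings are drawn as a homogeneous Poisson process at
    ``rate_per_s`` on the admissible interval (``margin_samples`` kept clear of
    each trial edge so atoms cannot overhang), then thinned left-to-right so
    consecutive within-trial timings are at least ``min_sep_samples`` apart.
    Atom identities are drawn uniformly from ``atom_ids``.
    """
    if rate_per_s < 0:
        raise ValueError("rate_per_s must be >= 0")
    if min_sep_samples < 1:
        raise ValueError("min_sep_samples must be >= 1")
    rng = np.random.default_rng(seed)
    lo = margin_samples
    hi = trial_len_samples - margin_samples
    if hi <= lo:
        raise ValueError("margin_samples leaves no admissible interval")
    duration_s = (hi - lo) / fs_hz
    events: list[PlannedEvent] = []
    n_drawn = 0
    n_kept = 0
    for trial in range(n_trials):
        n_ev = rng.poisson(rate_per_s * duration_s)
        taus = np.sort(rng.integers(lo, hi, size=n_ev))
        kept = []
        last = None
        for tau in taus:
            if last is None or tau - last >= min_sep_samples:
                kept.append(int(tau))
                last = int(tau)
        n_drawn += n_ev
        n_kept += len(kept)
        amps = _draw_amplitudes(rng, len(kept), amp_law)
        ids = rng.choice(np.asarray(atom_ids), size=len(kept))
        for tau, a, w in zip(kept, amps, ids):
            events.append(PlannedEvent(trial, tau, float(a), int(w)))
    if n_drawn > 0 and n_kept < 0.5 * n_drawn:
        warnings.warn(
            f"requested rate incompatible with min separation: kept {n_kept}"
            f"/{n_drawn} candidate events after thinning",
            stacklevel=2,
        )
    return EventPlan(events=events, min_separation_samples=min_sep_samples)


def validate_plan(
    plan: EventPlan,
    dictionary: list[Atom],
    n_trials: int,
    trial_len_samples: int,
) -> None:
    """Reject plans whose events overhang trial edges or cite unknown atoms."""
    atoms = {a.atom_id: a for a in dictionary}
    for ev in plan.events:
        if not (0 <= ev.trial_index < n_trials):
            raise ValueError(f"event trial {ev.trial_index} outside ensemble")
        atom = atoms.get(ev.atom_id)
        if atom is None:
            raise ValueError(f"event references unknown atom_id {ev.atom_id}")
        d = atom.duration_samples
        start = ev.tau_samples - d // 2
        if start < 0 or start + d > trial_len_samples:
            raise ValueError(
                f"event at tau={ev.tau_samples} (trial {ev.trial_index}, "
                f"atom {ev.atom_id}, duration {d}) overhangs the trial edge"
            )


def _pink_background(rng, shape, sigma):
    """1/f-amplitude Gaussian background, rescaled to target sigma."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1])
    shaping = np.where(freqs > 0, 1.0 / np.sqrt(freqs), 0.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=shape[-1], axis=-1)
    sd = x.std()
    return x * (sigma / sd) if sd > 0 else x


def synthesize(
    plan: EventPlan,
    dictionary: list[Atom],
    noise: NoiseModel,
    n_trials: int,
    trial_len_samples: int,
    fs_hz: float,
    seed: int = 0,
    labels=None,
    background: str = "white",
) -> SyntheticEnsemble:
    """Render traces: background + sum of weighted shifted atoms + sensor noise.

    Deterministic given ``seed``: background noise for every trial is drawn
    first, then the sensor-noise sequence, so replaying a seed reproduces the
    traces bit-identically.  ``background`` is ``"white"`` (the model's
    Gaussian rest state) or ``"pink"`` (1/f, for realism checks only).
    """
    validate_plan(plan, dictionary, n_trials, trial_len_samples)
    rng = np.random.default_rng(seed)
    shape = (n_trials, trial_len_samples)
    if background == "white":
        traces = noise.mu_z + noise.sigma_z * rng.standard_normal(shape)
    elif background == "pink":
        traces = noise.mu_z + _pink_background(rng, shape, noise.sigma_z)
    else:
        raise ValueError(f"unknown background {background!r}")
    atoms = {a.atom_id: a for a in dictionary}
    for ev in plan.events:
        atom = atoms[ev.atom_id]
        d = atom.duration_samples
        start = ev.tau_samples - d // 2
        traces[ev.trial_index, start : start + d] += ev.alpha * atom.waveform
    if noise.epsilon_sigma > 0:
        traces = traces + noise.epsilon_sigma * rng.standard_normal(shape)
    if labels is None:
        labels = np.zeros(n_trials, dtype=int)
    labels = np.asarray(labels)
    if labels.shape[0] != n_trials:
        raise ValueError("labels length must equal n_trials")
    return SyntheticEnsemble(
        traces=traces,
        fs_hz=fs_hz,
        labels=labels,
        plan=plan,
        dictionary=list(dictionary),
        noise=noise,
        seed=seed,
    )


def simulate_labeled_ensemble(
    dictionary: list[Atom],
    class_rates: dict,
    n_trials_per_class: int,
    trial_len_samples: int,
    fs_hz: float,
    noise: NoiseModel | None = None,
    class_amp_laws: dict | None = None,
    min_sep_samples: int = 50,
    seed: int = 0,
) -> SyntheticEnsemble:
    """Multi-class ensemble with class-dependent burst rates (and amplitudes).

    Emulates a task design in which the event rate (and optionally the
    amplitude law) of high-frequency bursts depends on the trial's class
    label.  Trials are generated class by class and concatenated; the labels
    array records class membership.
    """
    if noise is None:
        noise = NoiseModel()
    classes = sorted(class_rates)
    margin = max(a.duration_samples for a in dictionary) // 2 + 1
    atom_ids = [a.atom_id for a in dictionary]
    events: list[PlannedEvent] = []
    rng = np.random.default_rng(seed)
    offset = 0
    for cls in classes:
        amp_law = None if class_amp_laws is None else class_amp_laws.get(cls)
        sub = sample_event_plan(
            n_trials=n_trials_per_class,
            trial_len_samples=trial_len_samples,
            rate_per_s=class_rates[cls],
            fs_hz=fs_hz,
            amp_law=amp_law,
            min_sep_samples=min_sep_samples,
            atom_ids=atom_ids,
            margin_samples=margin,
            seed=int(rng.integers(2**31 - 1)),
        )
        for ev in sub.events:
            events.append(
                PlannedEvent(ev.trial_index + offset, ev.tau_samples, ev.alpha, ev.atom_id)
            )
        offset += n_trials_per_class
    plan = EventPlan(events=events, min_separation_samples=min_sep_samples)
    labels = np.repeat(classes, n_trials_per_class)
    return synthesize(
        plan,
        dictionary,
        noise,
        n_trials=offset,
        trial_len_samples=trial_len_samples,
        fs_hz=fs_hz,
        seed=int(rng.integers(2**31 - 1)),
        labels=labels,
    )
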