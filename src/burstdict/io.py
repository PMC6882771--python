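"""Readers, writers and pipeline configuration.

All artifacts are plain text: delimited trial matrices (UTF-8, comma
separated, '.' decimal, one trial per row, 0-based sample index implying
time) with a JSON sidecar carrying the sampling rate, labels and any
ground-truth event table; dictionaries, configs and reports as JSON; event
and feature tables as CSV.  Seconds are the external time unit; samples are
internal, converted with the fs recorded in metadata (never re-inferred).
Every output sidecar carries the configuration hash and seed that produced
it.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .preprocessing import BandSpec
from .synthetic import Atom

__all__ = [
    "PipelineConfig",
    "Recording",
    "read_recording",
    "write_recording",
    "write_dictionary",
    "read_dictionary",
    "write_events",
    "read_events",
    "write_features",
]


@dataclass
class PipelineConfig:
    """Study-default hyperparameters for the full pipeline.

    Defaults mirror the high-gamma movement study: band 85-145 Hz, analysis
    at 500 Hz, M = 50 samples (100 ms), duration grid 50-100 ms in 10 ms
    steps, gamma' = 1, statistics window -0.5 to 2 s relative to the cue.
    """

    band_low_hz: float = 85.0
    band_high_hz: float = 145.0
    band_order: int = 4
    fs_out: float = 500.0
    M: int = 50
    gamma_prime: float = 1.0
    delta_grid_ms: tuple = (50, 60, 70, 80, 90, 100)
    quant_levels: int = 64
    window_start_s: float = -0.5
    window_end_s: float = 2.0
    t_zero_s: float = 0.0
    min_sep_samples: int = 50
    n_permutations: int = 1000
    seed: int = 0

    @property
    def band(self) -> BandSpec:
        return BandSpec(self.band_low_hz, self.band_high_hz, self.band_order)

    @property
    def delta_grid_samples(self) -> tuple:
        return tuple(
            int(round(ms / 1000.0 * self.fs_out)) for ms in self.delta_grid_ms
        )

    @property
    def analysis_window(self) -> tuple:
        return (self.window_start_s, self.window_end_s)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["delta_grid_ms"] = list(self.delta_grid_ms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "delta_grid_ms" in d:
            d["delta_grid_ms"] = tuple(d["delta_grid_ms"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class Recording:
    """A multi-trial, single-channel recording with optional ground truth."""

    traces: np.ndarray
    fs_hz: float
    labels: np.ndarray | None = None
    events: list | None = None  # dicts: trial, tau_samples, alpha, atom_id
    meta: dict = field(default_factory=dict)


def _read_delimited_matrix(path: Path) -> np.ndarray:
    rows = []
    lengths = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh)):
            row = [c for c in row if c.strip() != ""]
            if not row:
                continue
            rows.append([float(c) for c in row])
            lengths.setdefault(len(row), []).append(lineno)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    if len(lengths) > 1:
        counts = {k: v[:5] for k, v in lengths.items()}
        raise ValueError(
            f"{path}: inconsistent trial lengths {sorted(lengths)} "
            f"(offending rows by length: {counts})"
        )
    return np.asarray(rows, dtype=float)


def read_recording(path, fmt: str = "delimited", channel=0) -> Recording:
    """Read a recording from a delimited matrix (+ JSON sidecar) or EDF.

    Delimited: ``path`` is the traces CSV (rows = trials); the sidecar
    ``<path stem>.json`` (or ``meta.json`` alongside) must provide ``fs_hz``
    and may provide ``labels`` and a ground-truth ``events`` table.  EDF:
    the named channel is returned as a single continuous trial with the fs
    from the header (requires mne).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "delimited":
        traces = _read_delimited_matrix(path)
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            sidecar = path.parent / "meta.json"
        if not sidecar.exists():
            raise ValueError(f"no sidecar with fs_hz found for {path}")
        meta = json.loads(sidecar.read_text())
        if "fs_hz" not in meta:
            raise ValueError(f"{sidecar}: missing required key 'fs_hz'")
        labels = np.asarray(meta["labels"]) if meta.get("labels") is not None else None
        if labels is not None and labels.shape[0] != traces.shape[0]:
            raise ValueError("labels length does not match number of trials")
        return Recording(
            traces=traces,
            fs_hz=float(meta["fs_hz"]),
            labels=labels,
            events=meta.get("events"),
            meta=meta,
        )
    if fmt == "edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover
            raise ImportError("EDF reading requires mne") from exc
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        if isinstance(channel, int):
            if channel >= len(raw.ch_names):
                raise ValueError(
                    f"channel index {channel} out of range "
                    f"({len(raw.ch_names)} channels in {path.name})"
                )
            channel = raw.ch_names[channel]
        data = raw.get_data(picks=[channel])
        return Recording(
            traces=data, fs_hz=float(raw.info["sfreq"]), meta={"source": str(path)}
        )
    raise ValueError(f"unknown format {fmt!r}")


def write_recording(
    outdir,
    traces: np.ndarray,
    fs_hz: float,
    labels=None,
    events=None,
    config: PipelineConfig | None = None,
    seed=None,
) -> Path:
    """Write traces.csv plus a meta.json sidecar; returns the traces path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    tpath = outdir / "traces.csv"
    with open(tpath, "w", newline="") as fh:
        w = csv.writer(fh)
        for row in traces:
            w.writerow([repr(float(v)) for v in row])
    meta = {
        "fs_hz": float(fs_hz),
        "labels": None if labels is None else np.asarray(labels).tolist(),
        "events": events,
        "seed": seed,
        "config_hash": config.config_hash if config is not None else None,
    }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1))
    return tpath


def events_from_plan(plan) -> list:
    return [
        {
            "trial": e.trial_index,
            "tau_samples": e.tau_samples,
            "alpha": e.alpha,
            "atom_id": e.atom_id,
        }
        for e in plan.events
    ]


def write_dictionary(path, dictionary, config=None, seed=None) -> Path:
    """Serialize a learned dictionary (atoms + learn log) as JSON."""
    path = Path(path)
    payload = {
        "K": dictionary.K,
        "atoms": [
            {
                "atom_id": a.atom_id,
                "fs_hz": a.fs_hz,
                "center_freq_hz": a.center_freq_hz,
                "duration_samples": a.duration_samples,
                "waveform": a.waveform.tolist(),
            }
            for a in dictionary.atoms
        ],
        "learn_log": [
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in entry.items()}
            for entry in dictionary.learn_log
        ],
        "seed": seed,
        "config_hash": config.config_hash if config is not None else None,
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_dictionary(path):
    from .mdl import Dictionary

    payload = json.loads(Path(path).read_text())
    atoms = [
        Atom(
            waveform=np.asarray(a["waveform"], dtype=float),
            atom_id=a["atom_id"],
            center_freq_hz=a["center_freq_hz"],
            fs_hz=a["fs_hz"],
        )
        for a in payload["atoms"]
    ]
    return Dictionary(atoms=atoms, learn_log=payload.get("learn_log", []))


def write_events(path, train, config=None, seed=None) -> Path:
    """Event table as CSV: trial, channel, tau_s, alpha, atom_id."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trial", "channel", "tau_s", "alpha", "atom_id"])
        for e in train.events:
            w.writerow([e.trial, e.channel, repr(e.tau_s), repr(e.alpha), e.atom_id])
    return path


def read_events(path, fs_hz: float, n_trials: int | None = None):
    from .encoding import TMPPEvent, TMPPTrain

    events = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            events.append(
                TMPPEvent(
                    tau_s=float(row["tau_s"]),
                    alpha=float(row["alpha"]),
                    atom_id=int(row["atom_id"]),
                    trial=int(row["trial"]),
                    channel=int(row["channel"]),
                )
            )
    if n_trials is None:
        n_trials = 1 + max((e.trial for e in events), default=-1)
    return TMPPTrain(events=events, fs_hz=fs_hz, n_trials=n_trials)


def write_features(path, features: dict, labels=None) -> Path:
    """Per-trial feature table as CSV with an optional label column."""
    path = Path(path)
    names = list(features)
    cols = [np.asarray(features[k], dtype=float) for k in names]
    n = cols[0].shape[0]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        header = names + (["label"] if labels is not None else [])
        w.writerow(header)
        for i in range(n):
            row = [repr(float(c[i])) for c in cols]
            if labels is not None:
                row.append(labels[i])
            w.writerow(row)
    return path
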