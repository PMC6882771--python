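"""Shared fixtures: seeded simulations used across the suite.

The two-atom recovery run (the heaviest fixture) is session-scoped so the
dictionary-recovery and encoding-recovery checks share one learning run.
"""

from __future__ import annotations

import numpy as np
import pytest

import burstdict as bd
from burstdict.mdl import LearnConfig, learn_dictionary


def make_two_atom_ensemble(sim_seed: int = 42):
    """Two planted atoms (80 ms @ 115 Hz, 120 ms @ 100 Hz), 100 events each.

    50 trials of 2.5 s at 500 Hz; four jittered event slots per trial (two per
    atom); amplitudes lognormal around sqrt(10 * duration) so the event energy
    over the atom support is 10 dB above the unit-variance background.
    """
    fs = 500.0
    atoms = [
        bd.make_burst_atom(115.0, 0.08, fs, atom_id=0),
        bd.make_burst_atom(100.0, 0.12, fs, atom_id=1),
    ]
    rng = np.random.default_rng(sim_seed)
    eta = 1250
    slots = [180, 480, 780, 1080]
    events = []
    for trial in range(50):
        order = rng.permutation([0, 1, 0, 1])
        for slot, aid in zip(slots, order):
            tau = int(slot + rng.integers(-50, 51))
            d = atoms[aid].duration_samples
            alpha = float(np.exp(np.log(np.sqrt(10 * d)) + 0.15 * rng.standard_normal()))
            events.append(bd.PlannedEvent(trial, tau, alpha, aid))
    plan = bd.EventPlan(events=events, min_separation_samples=150)
    ens = bd.synthesize(
        plan, atoms, bd.NoiseModel(), 50, eta, fs, seed=sim_seed + 1
    )
    return ens, atoms, plan


@pytest.fixture(scope="session")
def two_atom_run():
    """Full pipeline on the two-atom simulation: DET -> MDL learning -> state."""
    ens, atoms, plan = make_two_atom_ensemble(sim_seed=42)
    M = 70
    index = bd.build_snippet_index(ens.traces, M)
    beta = bd.embed(ens.traces, index)
    fit = bd.fit_background(beta)
    X = bd.select_snippets(ens.traces, index, fit)
    config = LearnConfig(delta_grid=(40, 60), M=M, seed=0, fs_hz=ens.fs_hz, motif_top=2)
    dictionary, assignments = learn_dictionary(X.columns, config)
    return {
        "ensemble": ens,
        "true_atoms": atoms,
        "plan": plan,
        "index": index,
        "beta": beta,
        "fit": fit,
        "X": X,
        "config": config,
        "dictionary": dictionary,
        "assignments": assignments,
    }
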