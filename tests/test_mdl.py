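"""MDL machinery: quantization, description lengths, bitsaves, motifs, learning."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import burstdict as bd
from burstdict import mdl
from burstdict.mdl import (
    Cluster,
    LearnConfig,
    bitsave_add,
    bitsave_create,
    bitsave_merge,
    cluster_dl,
    conditional_dl,
    dequantize,
    description_length,
    find_motifs,
    learn_dictionary,
    quantize,
    sequence_dl,
)


class TestQuantize:
    def test_constant_sequence_single_symbol(self):
        q = quantize(np.full(10, 3.7), 64)
        assert np.all(q.symbols == 0)

    def test_linear_ramp_uses_every_level_once(self):
        q = quantize(np.arange(64.0), 64)
        assert sorted(q.symbols) == list(range(64))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_round_trip_error_bounded(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(40)
        q = quantize(x, 64)
        assert np.max(np.abs(dequantize(q) - x)) <= np.ptp(x) / (2 * 63) + 1e-12

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symbols_in_range(self, seed):
        rng = np.random.default_rng(seed)
        q = quantize(rng.standard_normal(30) * rng.uniform(0.1, 100), 64)
        assert q.symbols.min() >= 0 and q.symbols.max() <= 63

    def test_scale_invariance(self):
        x = np.random.default_rng(0).standard_normal(50)
        assert np.array_equal(quantize(x, 64).symbols, quantize(5 * x + 3, 64).symbols)


class TestDescriptionLength:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            (np.full(7, 2.0), 0.0),  # zero entropy
            (np.array([0.0, 0.0, 1.0, 1.0]), 4.0),  # 1 bit x m=4
            (np.array([0, 0, 1, 1, 2, 2, 3, 3], dtype=float), 16.0),  # 2 bits x m=8
        ],
    )
    def test_hand_cases(self, seq, expected):
        assert sequence_dl(seq, 64) == pytest.approx(expected, abs=1e-12)

    def test_matches_independent_entropy(self):
        from scipy.stats import entropy as scipy_entropy

        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.standard_normal(rng.integers(10, 80))
            q = quantize(x, 64)
            counts = np.bincount(q.symbols)
            expected = q.m * scipy_entropy(counts[counts > 0], base=2)
            assert description_length(q) == pytest.approx(expected, abs=1e-9)


class TestConditionalDL:
    def test_identical_sequences_cost_nothing(self):
        x = np.random.default_rng(2).standard_normal(50)
        res = conditional_dl(x, x)
        assert res.bits == 0.0 and res.lag == 0

    def test_shifted_copy_costs_nothing(self):
        h = bd.make_burst_atom(100.0, 0.06, 500.0).waveform
        a = np.zeros(80)
        a[17 : 17 + h.size] = 3.0 * h
        res = conditional_dl(a, h)
        assert res.bits == 0.0 and res.lag == 17

    def test_sign_flipped_copy_costs_nothing_with_polarity(self):
        h = bd.make_burst_atom(100.0, 0.06, 500.0).waveform
        a = np.zeros(80)
        a[10 : 10 + h.size] = -2.0 * h
        assert conditional_dl(a, h, polarity=True).bits == 0.0
        assert conditional_dl(a, h, polarity=True).sign == -1.0

    def test_independent_noise_is_incompressible(self):
        # brute-force residual-entropy oracle, Monte-Carlo over pairs
        rng = np.random.default_rng(3)
        ratios = []
        for _ in range(300):
            a = rng.standard_normal(50)
            h = rng.standard_normal(50)
            bits = conditional_dl(a, h).bits
            # oracle: recompute the residual DL directly
            hu = h / np.linalg.norm(h)
            ncc = float(a @ hu) / np.linalg.norm(a)
            sign = np.sign(ncc) if ncc != 0 else 1.0
            resid = a - sign * np.linalg.norm(a) * hu
            step = np.ptp(a) / 63
            sym = np.round(resid / step).astype(int)
            counts = np.bincount(sym - sym.min()).astype(float)
            p = counts[counts > 0] / sym.size
            oracle_bits = sym.size * float(-(p * np.log2(p)).sum())
            assert bits == pytest.approx(oracle_bits, abs=1e-9)
            ratios.append(bits / sequence_dl(a))
        assert 0.9 < np.mean(ratios) < 1.3  # no compression on average

    def test_hypothesis_longer_than_sequence_errors(self):
        with pytest.raises(ValueError, match="lag"):
            conditional_dl(np.zeros(10), np.ones(20))


class TestClusterDL:
    def test_two_identical_members_cost_one_member(self):
        a = np.random.default_rng(4).standard_normal(50)
        C = Cluster(center=a / np.linalg.norm(a), member_seqs=[a, a.copy()])
        assert cluster_dl(C) == pytest.approx(sequence_dl(a), abs=1e-9)

    def test_singleton_costs_the_hypothesis(self):
        a = np.random.default_rng(5).standard_normal(50)
        C = Cluster(center=a / np.linalg.norm(a), member_seqs=[a])
        assert cluster_dl(C) == pytest.approx(sequence_dl(a), abs=1e-9)

    def test_small_instance_matches_hand_computation(self):
        # three 8-sample members; enumerate every term of the two codes by hand
        rng = np.random.default_rng(6)
        base = rng.standard_normal(8)
        members = [base, 2.0 * base, base + 0.3 * rng.standard_normal(8)]
        center = base / np.linalg.norm(base)
        C = Cluster(center=center, member_seqs=members)

        def hand_cdl(A, H):
            # H slides over A (equal length here -> single lag)
            hu = H / np.linalg.norm(H)
            ncc = float(A @ hu) / np.linalg.norm(A)
            s = 1.0 if ncc >= 0 else -1.0
            resid = A - s * np.linalg.norm(A) * hu
            step = np.ptp(A) / 63
            sym = np.round(resid / step).astype(int)
            counts = np.bincount(sym - sym.min()).astype(float)
            p = counts[counts > 0] / sym.size
            return sym.size * float(-(p * np.log2(p)).sum())

        # exemplar code: carrier = member best aligned with the center
        nccs = np.array([abs(float((m / np.linalg.norm(m)) @ center)) for m in members])
        ci = int(np.flatnonzero(nccs >= nccs.max() - 1e-9)[0])
        Hw = members[ci] / np.linalg.norm(members[ci])
        ex = sequence_dl(members[ci]) + sum(
            hand_cdl(m, Hw) for i, m in enumerate(members) if i != ci
        )
        ctr = sequence_dl(center) + sum(hand_cdl(m, center) for m in members)
        assert cluster_dl(C) == pytest.approx(min(ex, ctr), abs=1e-9)

    def test_empty_cluster_errors(self):
        C = Cluster(center=np.ones(4) / 2.0, member_seqs=[])
        with pytest.raises(ValueError):
            cluster_dl(C)


class TestBitsaves:
    def test_create_identical_pair_saves_one_member(self):
        a = np.random.default_rng(7).standard_normal(50)
        bs, C = bitsave_create(a, a.copy())
        assert bs == pytest.approx(sequence_dl(a), abs=1e-9)
        assert bs > 0

    def test_create_polarity_symmetry(self):
        a = np.random.default_rng(8).standard_normal(50)
        bs_same, _ = bitsave_create(a, a.copy(), polarity=True)
        bs_flip, _ = bitsave_create(a, -a, polarity=True)
        assert bs_flip == pytest.approx(bs_same, abs=1e-9)

    def test_create_noise_pairs_negative_in_expectation(self):
        rng = np.random.default_rng(9)
        bs = [
            bitsave_create(rng.standard_normal(70), rng.standard_normal(70))[0]
            for _ in range(300)
        ]
        assert np.mean(bs) < 0

    def test_add_identical_member_saves_one_member(self):
        a = np.random.default_rng(10).standard_normal(50)
        _, C = bitsave_create(a, a.copy())
        bs, C2 = bitsave_add(a.copy(), C)
        assert bs == pytest.approx(sequence_dl(a), abs=1e-9)
        assert C2.n_members == 3

    def test_add_noise_to_structured_cluster_negative(self):
        rng = np.random.default_rng(11)
        atom = bd.make_burst_atom(115.0, 0.08, 500.0).waveform

        def burst():
            x = rng.standard_normal(70)
            s = int(rng.integers(0, 31))
            x[s : s + 40] += np.sqrt(400) * atom
            return x

        _, C = bitsave_create(burst(), burst(), delta=40)
        for _ in range(4):
            _, C = bitsave_add(burst(), C)
        bs = np.array([bitsave_add(rng.standard_normal(70), C)[0] for _ in range(120)])
        assert bs.mean() < 0
        assert (bs < 0).mean() > 0.5

    def test_add_genuine_member_positive(self):
        rng = np.random.default_rng(12)
        atom = bd.make_burst_atom(115.0, 0.08, 500.0).waveform

        def burst():
            x = rng.standard_normal(70)
            s = int(rng.integers(0, 31))
            x[s : s + 40] += np.sqrt(400) * atom
            return x

        _, C = bitsave_create(burst(), burst(), delta=40)
        for _ in range(4):
            _, C = bitsave_add(burst(), C)
        bs = np.array([bitsave_add(burst(), C)[0] for _ in range(20)])
        # most same-generator snippets compress; occasional events at this SNR
        # land a marginal alignment
        assert np.mean(bs > 0) >= 0.85
        assert bs.mean() > 0

    def test_merge_duplicate_clusters_positive(self):
        a = np.random.default_rng(13).standard_normal(50)
        _, C1 = bitsave_create(a, a.copy())
        _, C2 = bitsave_create(a.copy(), a.copy())
        bs, Cm = bitsave_merge(C1, C2)
        assert bs > 0
        assert abs(np.linalg.norm(Cm.center) - 1.0) < 1e-9

    def test_merge_different_atoms_negative(self):
        # simulation oracle with two known, distinct generators
        rng = np.random.default_rng(14)
        a1 = bd.make_burst_atom(115.0, 0.08, 500.0).waveform
        a2 = bd.make_burst_atom(60.0, 0.08, 500.0).waveform

        def burst(w):
            x = rng.standard_normal(70)
            s = int(rng.integers(0, 31))
            x[s : s + 40] += 20 * w
            return x

        neg = 0
        n_rep = 30
        for _ in range(n_rep):
            _, C1 = bitsave_create(burst(a1), burst(a1), delta=40)
            _, C2 = bitsave_create(burst(a2), burst(a2), delta=40)
            bs, _ = bitsave_merge(C1, C2, max_len=70)
            neg += bs < 0
        assert neg / n_rep > 0.9


class TestFindMotifs:
    def test_planted_pair_ranks_first(self):
        rng = np.random.default_rng(15)
        atom = bd.make_burst_atom(100.0, 0.08, 500.0).waveform
        X = rng.standard_normal((60, 8)) * 0.01
        X[5:45, 2] += atom
        X[12:52, 6] += atom
        pairs = find_motifs(X, delta=40, top_k=1)
        assert {pairs[0].i, pairs[0].j} == {2, 6}
        assert pairs[0].score > 0.95
        assert pairs[0].lag == 12 - 5

    def test_exhaustive_three_snippet_check(self):
        # brute force over all pairs and all window placements
        rng = np.random.default_rng(16)
        X = rng.standard_normal((12, 3))
        delta = 6
        best = (None, -np.inf)
        for i in range(3):
            for j in range(i + 1, 3):
                for pi in range(12 - delta + 1):
                    for pj in range(12 - delta + 1):
                        wa = X[pi : pi + delta, i]
                        wb = X[pj : pj + delta, j]
                        ncc = abs(wa @ wb) / (np.linalg.norm(wa) * np.linalg.norm(wb))
                        if ncc > best[1]:
                            best = ((i, j), ncc)
        pairs = find_motifs(X, delta, top_k=1)
        assert {pairs[0].i, pairs[0].j} == set(best[0])
        assert pairs[0].score == pytest.approx(best[1], abs=1e-12)

    def test_noise_scores_match_permutation_null(self):
        # the all-noise top score should sit inside its own permutation null
        rng = np.random.default_rng(17)
        X = rng.standard_normal((40, 12))
        observed = find_motifs(X, delta=20, top_k=1)[0].score
        null = []
        for _ in range(60):
            Xp = np.empty_like(X)
            for c in range(X.shape[1]):
                Xp[:, c] = rng.permutation(X[:, c])
            null.append(find_motifs(Xp, delta=20, top_k=1)[0].score)
        lo, hi = np.quantile(null, [0.01, 0.99])
        assert lo <= observed <= hi * 1.05

    def test_single_snippet_errors(self):
        with pytest.raises(ValueError):
            find_motifs(np.zeros((10, 1)), 5)


class TestLearnDictionary:
    def test_single_generator_recovers_one_atom(self):
        # 40 noiseless shifted copies of one 60-sample atom
        rng = np.random.default_rng(18)
        atom = bd.make_burst_atom(100.0, 0.12, 500.0).waveform  # 60 samples
        X = np.zeros((70, 40))
        for j in range(40):
            s = int(rng.integers(0, 11))
            X[s : s + 60, j] = atom
        config = LearnConfig(delta_grid=(50, 60, 70), M=70, seed=0, null_gate_perms=3)
        D, assign = learn_dictionary(X, config)
        assert D.K == 1
        learned = D.atoms[0].waveform
        shorter, longer = sorted([learned, atom], key=len)
        ncc = abs(mdl.best_alignment(np.pad(longer, (5, 5)), shorter).ncc)
        assert ncc > 0.99
        assert np.all(assign >= 0)

    def test_pure_noise_learns_nothing(self):
        rng = np.random.default_rng(19)
        X = rng.standard_normal((70, 50))
        config = LearnConfig(delta_grid=(40, 60), M=70, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            D, assign = learn_dictionary(X, config)
        assert D.K == 0
        assert np.all(assign == -1)

    def test_empty_matrix_warns(self):
        config = LearnConfig(delta_grid=(4,), M=8)
        with pytest.warns(UserWarning):
            D, assign = learn_dictionary(np.empty((8, 0)), config)
        assert D.K == 0

    def test_deterministic_rerun(self):
        rng = np.random.default_rng(20)
        atom = bd.make_burst_atom(100.0, 0.08, 500.0).waveform
        X = rng.standard_normal((50, 16))
        for j in range(0, 16, 2):
            s = int(rng.integers(0, 11))
            X[s : s + 40, j] += 18 * atom
        config = LearnConfig(delta_grid=(40,), M=50, seed=4)
        D1, a1 = learn_dictionary(X, config)
        D2, a2 = learn_dictionary(X, config)
        assert [e for e in D1.learn_log] == [e for e in D2.learn_log]
        assert np.array_equal(a1, a2)
        for x, y in zip(D1.atoms, D2.atoms):
            assert np.array_equal(x.waveform, y.waveform)

    def test_total_description_length_non_increasing(self):
        rng = np.random.default_rng(21)
        atom = bd.make_burst_atom(100.0, 0.08, 500.0).waveform
        X = rng.standard_normal((50, 20))
        for j in range(20):
            s = int(rng.integers(0, 11))
            X[s : s + 40, j] += 18 * atom
        config = LearnConfig(delta_grid=(40,), M=50, seed=0)
        D, _ = learn_dictionary(X, config)
        assert len(D.learn_log) > 0
        assert all(e["bitsave"] > 0 for e in D.learn_log)

    def test_durations_never_exceed_m(self, two_atom_run):
        for atom in two_atom_run["dictionary"].atoms:
            assert atom.duration_samples <= two_atom_run["config"].M
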