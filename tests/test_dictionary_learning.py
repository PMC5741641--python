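"""Shift-invariant k-means with correntropy-robust rank-1 updates."""

import numpy as np
import pytest

from mppeep import (
    AssignmentSet,
    Dictionary,
    SnippetSet,
    assign_snippets,
    correntropy_rank1,
    learn_dictionary,
    make_atoms,
    mutual_coherence,
    seed_dictionary,
    update_dictionary,
)
from conftest import (
    bipartite_match_corr,
    brute_force_assign,
    shiftmax_abs_corr,
    snippets_from_matrix,
)


def unit_rows(X):
    return X / np.linalg.norm(X, axis=1, keepdims=True)


class TestMutualCoherence:
    def test_orthogonal_atoms(self):
        d = Dictionary(atoms=np.eye(8)[:2])
        assert mutual_coherence(d) == 0.0

    def test_duplicated_atom(self):
        a = np.ones(8) / np.sqrt(8)
        assert mutual_coherence(Dictionary(atoms=np.stack([a, a]))) == \
            pytest.approx(1.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(0)
        atoms = unit_rows(rng.standard_normal((4, 16)))
        d = Dictionary(atoms=atoms)
        expected = 0.0
        for i in range(4):
            for j in range(4):
                if i != j:
                    expected = max(expected, abs(float(atoms[i] @ atoms[j])))
        assert mutual_coherence(d) == expected

    def test_single_atom_raises(self):
        with pytest.raises(ValueError):
            mutual_coherence(Dictionary(atoms=np.eye(8)[:1]))


class TestSeedDictionary:
    def test_forced_selection_when_pool_is_exactly_k(self):
        rng = np.random.default_rng(1)
        small = rng.standard_normal((18, 16)) * 0.1
        big = rng.standard_normal((2, 16)) * 10
        events = snippets_from_matrix(np.vstack([small, big]))
        d = seed_dictionary(events, K=2, rng_seed=0)
        assert d.K == 2
        assert np.allclose(np.linalg.norm(d.atoms, axis=1), 1.0)
        # both large-norm snippets must be the chosen seeds (up to sign/norm)
        expected = unit_rows(big)
        for atom in d.atoms:
            assert max(abs(float(atom @ e)) for e in expected) > 0.999

    def test_duplicates_not_both_chosen(self):
        base = np.zeros((3, 16))
        rng = np.random.default_rng(2)
        v = rng.standard_normal(16) * 10
        w = rng.standard_normal(16) * 10
        base[0] = v
        base[1] = v  # exact duplicate
        base[2] = w
        events = snippets_from_matrix(base)
        for seed in range(5):
            d = seed_dictionary(events, K=2, rng_seed=seed, norm_percentile=0)
            assert mutual_coherence(d) < 0.999

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(3)
        events = snippets_from_matrix(rng.standard_normal((50, 16)))
        a = seed_dictionary(events, K=3, rng_seed=42)
        b = seed_dictionary(events, K=3, rng_seed=42)
        assert np.array_equal(a.atoms, b.atoms)

    def test_too_few_qualifying_raises(self):
        events = snippets_from_matrix(np.random.default_rng(4).standard_normal((10, 16)))
        with pytest.raises(ValueError, match="cannot seed"):
            seed_dictionary(events, K=5, rng_seed=0)  # 90th pct pool has 1-2


class TestAssignSnippets:
    def test_exact_member_recovered(self):
        rng = np.random.default_rng(5)
        atoms = unit_rows(rng.standard_normal((5, 32)))
        d = Dictionary(atoms=atoms)
        sn = snippets_from_matrix(2.5 * atoms[3])
        out = assign_snippets(sn, d, max_shift=8)
        assert out.omega[0] == 3
        assert out.shift[0] == 0
        assert out.alpha[0] == pytest.approx(2.5, abs=1e-9)

    def test_shifted_atom_recovers_lag(self, gabor_atoms):
        atom = gabor_atoms.atoms[1]
        M = atom.size
        delayed = np.zeros(M)
        delayed[4:] = atom[:M - 4]  # atom delayed by 4 samples
        out = assign_snippets(snippets_from_matrix(delayed),
                              Dictionary(atoms=gabor_atoms.atoms), max_shift=8)
        assert out.omega[0] == 1
        assert out.shift[0] == 4
        assert abs(out.alpha[0]) >= 0.95 * np.linalg.norm(delayed)

    def test_fft_path_equals_brute_force(self):
        rng = np.random.default_rng(6)
        M, K, S = 32, 5, 8
        atoms = unit_rows(rng.standard_normal((K, M)))
        X = rng.standard_normal((50, M))
        out = assign_snippets(snippets_from_matrix(X),
                              Dictionary(atoms=atoms), max_shift=S)
        omega, alpha, shift = brute_force_assign(X, atoms, S)
        assert np.array_equal(out.omega, omega)
        assert np.array_equal(out.shift, shift)
        assert np.allclose(out.alpha, alpha, atol=1e-9)

    def test_alpha_bounded_by_snippet_norm(self):
        rng = np.random.default_rng(7)
        atoms = unit_rows(rng.standard_normal((3, 24)))
        X = rng.standard_normal((40, 24))
        out = assign_snippets(snippets_from_matrix(X),
                              Dictionary(atoms=atoms), max_shift=5)
        assert np.all(np.abs(out.alpha) <= np.linalg.norm(X, axis=1) + 1e-12)

    def test_shift_bound_enforced(self):
        d = Dictionary(atoms=np.eye(16)[:2])
        sn = snippets_from_matrix(np.ones((1, 16)))
        with pytest.raises(ValueError, match="max_shift"):
            assign_snippets(sn, d, max_shift=8)

    def test_m_mismatch_raises(self):
        d = Dictionary(atoms=np.eye(16)[:2])
        sn = snippets_from_matrix(np.ones((1, 20)))
        with pytest.raises(ValueError, match="M"):
            assign_snippets(sn, d, max_shift=4)


class TestCorrentropyRank1:
    def test_noiseless_rank1_fixed_point(self):
        rng = np.random.default_rng(8)
        d = rng.standard_normal(16)
        d /= np.linalg.norm(d)
        if d[np.argmax(np.abs(d))] < 0:
            d = -d
        X = np.outer(np.full(20, 3.0), d)
        atom, weights = correntropy_rank1(X)
        assert np.allclose(atom, d, atol=1e-9)
        assert np.allclose(weights, weights[0])

    def test_matches_plain_svd_without_outliers(self):
        rng = np.random.default_rng(9)
        d = rng.standard_normal(32)
        d /= np.linalg.norm(d)
        X = np.outer(rng.uniform(1, 3, 100), d) + 0.05 * rng.standard_normal((100, 32))
        atom, _ = correntropy_rank1(X)
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        assert abs(float(atom @ vt[0])) >= 0.99

    def test_outliers_downweighted(self):
        rng = np.random.default_rng(10)
        d = rng.standard_normal(32)
        d /= np.linalg.norm(d)
        X = np.outer(rng.uniform(1, 3, 100), d) + 0.1 * rng.standard_normal((100, 32))
        X[:5] = 20 * rng.standard_normal((5, 32))
        atom, weights = correntropy_rank1(X)
        assert np.mean(weights[:5]) < np.mean(weights[5:])
        angle = np.arccos(min(1.0, abs(float(atom @ d))))
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        angle_svd = np.arccos(min(1.0, abs(float(vt[0] @ d))))
        assert angle < angle_svd

    def test_all_zero_matrix_raises(self):
        with pytest.raises(ValueError):
            correntropy_rank1(np.zeros((5, 8)))

    def test_sign_convention(self):
        rng = np.random.default_rng(11)
        d = rng.standard_normal(16)
        atom, _ = correntropy_rank1(np.outer(np.ones(10), d))
        assert atom[np.argmax(np.abs(atom))] > 0


class TestUpdateDictionary:
    def test_fixed_point_when_cluster_equals_atom(self):
        rng = np.random.default_rng(12)
        atoms = unit_rows(np.abs(rng.standard_normal((3, 16))))
        d = Dictionary(atoms=atoms)
        X = np.tile(atoms[0], (10, 1))
        sn = snippets_from_matrix(X)
        asg = assign_snippets(sn, d, max_shift=4)
        assert np.all(asg.omega == 0)
        out = update_dictionary(asg, sn, d)
        assert np.allclose(out.atoms[0], atoms[0], atol=1e-9)
        assert np.array_equal(out.atoms[1], atoms[1])
        assert np.array_equal(out.atoms[2], atoms[2])

    def test_shifted_cluster_realigned(self, gabor_atoms):
        atom = gabor_atoms.atoms[2]
        M = atom.size
        members = []
        for s in (-2, 0, 2):
            v = np.zeros(M)
            if s >= 0:
                v[s:] = atom[:M - s]
            else:
                v[:M + s] = atom[-s:]
            members.append(v)
        sn = snippets_from_matrix(np.stack(members))
        d = Dictionary(atoms=gabor_atoms.atoms)
        asg = assign_snippets(sn, d, max_shift=6)
        out = update_dictionary(asg, sn, d)
        assert shiftmax_abs_corr(out.atoms[2], atom) >= 0.99

    def test_empty_cluster_bitwise_unchanged(self):
        rng = np.random.default_rng(13)
        atoms = unit_rows(rng.standard_normal((2, 16)))
        d = Dictionary(atoms=atoms)
        sn = snippets_from_matrix(np.tile(atoms[0], (5, 1)))
        asg = AssignmentSet(omega=np.zeros(5, int), alpha=np.ones(5),
                            shift=np.zeros(5, int))
        out = update_dictionary(asg, sn, d)
        assert np.array_equal(out.atoms[1], atoms[1])


class TestLearnDictionary:
    def test_single_atom_near_noiseless_recovery(self, gabor_atoms):
        rng = np.random.default_rng(14)
        atom = gabor_atoms.atoms[0]
        X = np.tile(2.0 * atom, (50, 1)) + 0.01 * rng.standard_normal((50, 50))
        d, log = learn_dictionary(snippets_from_matrix(X), K=1, n_init=2,
                                  rng_seed=0)
        assert shiftmax_abs_corr(d.atoms[0], atom) >= 0.99
        assert log.iterations

    def test_three_atom_recovery_from_clean_clusters(self, gabor_atoms):
        rng = np.random.default_rng(15)
        rows = []
        for k in range(3):
            rows.append(np.outer(rng.uniform(1, 3, 80), gabor_atoms.atoms[k])
                        + 0.05 * rng.standard_normal((80, 50)))
        X = np.vstack(rows)
        d, _ = learn_dictionary(snippets_from_matrix(X), K=3, n_init=3,
                                rng_seed=1)
        assert bipartite_match_corr(d.atoms, gabor_atoms.atoms) >= 0.9

    def test_atoms_stay_unit_norm(self, gabor_atoms):
        rng = np.random.default_rng(16)
        X = np.outer(rng.uniform(1, 2, 60), gabor_atoms.atoms[1]) \
            + 0.1 * rng.standard_normal((60, 50))
        d, _ = learn_dictionary(snippets_from_matrix(X), K=2, n_init=2,
                                rng_seed=2)
        assert np.allclose(np.linalg.norm(d.atoms, axis=1), 1.0, atol=1e-9)

    def test_bitwise_determinism(self, gabor_atoms):
        rng = np.random.default_rng(17)
        X = np.outer(rng.uniform(1, 3, 60), gabor_atoms.atoms[0]) \
            + 0.1 * rng.standard_normal((60, 50))
        sn = snippets_from_matrix(X)
        a, _ = learn_dictionary(sn, K=2, n_init=3, rng_seed=99)
        b, _ = learn_dictionary(sn, K=2, n_init=3, rng_seed=99)
        assert np.array_equal(a.atoms, b.atoms)

    def test_shift_invariance_of_learned_atoms(self, gabor_atoms):
        """Translating every training snippet by s ≤ S leaves the learned
        atom unchanged up to correlation 0.99."""
        rng = np.random.default_rng(18)
        atom = gabor_atoms.atoms[1]
        M = atom.size
        X = np.outer(rng.uniform(1, 3, 60), atom) + 0.02 * rng.standard_normal((60, M))
        shifted = np.zeros_like(X)
        s = 3
        shifted[:, s:] = X[:, :M - s]
        a, _ = learn_dictionary(snippets_from_matrix(X), K=1, n_init=1,
                                rng_seed=5)
        b, _ = learn_dictionary(snippets_from_matrix(shifted), K=1, n_init=1,
                                rng_seed=5)
        assert shiftmax_abs_corr(a.atoms[0], b.atoms[0]) >= 0.99

    def test_empty_events_raise(self):
        empty = SnippetSet(M=16, vectors=np.empty((0, 16)),
                           origins=np.empty(0, int), method=[])
        with pytest.raises(ValueError):
            learn_dictionary(empty, K=2, rng_seed=0)
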