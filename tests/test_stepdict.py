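import numpy as np
import pytest

from floorgait.stepdict import (
    SparseCodes,
    StepDictionary,
    cdl_objective,
    embed,
    learn_dictionary,
    select_num_atoms,
)


def planted_atom(length=70):
    t = np.linspace(0, 1, length)
    atom = np.exp(-0.5 * ((t - 0.4) / 0.15) ** 2) * np.sin(np.pi * t)
    return atom / np.linalg.norm(atom)


def planted_signals(atoms, n_signals, rng, length=1000, density=0.01, sigma=0.01):
    signals = []
    for _ in range(n_signals):
        s = np.zeros(length)
        for atom in np.atleast_2d(atoms):
            spikes = (rng.random(length) < density) * rng.choice([-1.0, 1.0], length)
            s += np.convolve(spikes, atom)[:length]
        signals.append(s + rng.normal(0, sigma, length))
    return signals


def circular_xcorr(a, b):
    """Max over circular shifts and sign of the normalized cross-correlation."""
    best = 0.0
    for sign in (1.0, -1.0):
        xc = np.fft.irfft(np.fft.rfft(a) * np.conj(np.fft.rfft(sign * b)))
        best = max(best, xc.max() / (np.linalg.norm(a) * np.linalg.norm(b)))
    return best


class TestObjective:
    def test_zero_codes_reduce_to_signal_energy(self, rng):
        s = rng.standard_normal(100)
        dic = StepDictionary(planted_atom(20)[None, :])
        codes = [SparseCodes(np.zeros((1, 100)))]
        assert cdl_objective([s], dic, codes, lam=3.0) == pytest.approx(0.5 * np.sum(s**2))

    def test_perfect_reconstruction_zero_lambda(self, rng):
        atom = planted_atom(30)
        x = np.zeros(200)
        x[[20, 90, 150]] = [1.0, -2.0, 0.5]
        s = np.convolve(x, atom)[:200]
        dic = StepDictionary(atom[None, :])
        assert cdl_objective([s], dic, [SparseCodes(x[None, :])], lam=0.0) == pytest.approx(0.0, abs=1e-20)

    def test_three_sample_toy(self):
        s = np.array([1.0, 0.0, 0.0])
        dic = StepDictionary(np.array([[1.0]]))
        codes = [SparseCodes(np.array([[1.0, 0.0, 0.0]]))]
        assert cdl_objective([s], dic, codes, lam=5.0) == pytest.approx(5.0)

    def test_shape_mismatch_raises(self, rng):
        dic = StepDictionary(np.ones((2, 10)) / np.sqrt(10))
        with pytest.raises(ValueError):
            cdl_objective([rng.standard_normal(50)], dic,
                          [SparseCodes(np.zeros((3, 50)))], lam=1.0)


class TestLearnDictionary:
    def test_planted_atom_recovery(self, rng):
        atom = planted_atom()
        signals = planted_signals(atom, 20, rng)
        dic, codes = learn_dictionary(signals, m=1, lam=1.0, iters=300, seed=1)
        assert circular_xcorr(atom, dic.atoms[0]) >= 0.90

    def test_unit_norm_atoms(self, rng):
        signals = planted_signals(planted_atom(), 5, rng)
        dic, _ = learn_dictionary(signals, m=3, lam=1.0, iters=50, seed=0)
        np.testing.assert_allclose(np.linalg.norm(dic.atoms, axis=1), 1.0, atol=1e-6)

    def test_huge_lambda_zeroes_codes(self, rng):
        signals = planted_signals(planted_atom(), 5, rng)
        dic, codes = learn_dictionary(signals, m=1, lam=1e6, iters=30, seed=0)
        assert max(np.abs(c.codes).max() for c in codes) < 1e-6
        obj = cdl_objective(signals, dic, codes, lam=1e6)
        assert obj == pytest.approx(sum(0.5 * np.sum(s**2) for s in signals), rel=1e-6)

    def test_objective_descends_from_init(self, rng):
        signals = planted_signals(planted_atom(), 8, rng)
        dic, codes = learn_dictionary(signals, m=2, lam=0.5, iters=100, seed=3)
        init_obj = sum(0.5 * np.sum(s**2) for s in signals)  # zero-code start
        assert cdl_objective(signals, dic, codes, lam=0.5) <= init_obj

    def test_deterministic_given_seed(self, rng):
        signals = planted_signals(planted_atom(), 4, rng)
        d1, _ = learn_dictionary(signals, m=2, lam=1.0, iters=20, seed=9)
        d2, _ = learn_dictionary(signals, m=2, lam=1.0, iters=20, seed=9)
        np.testing.assert_array_equal(d1.atoms, d2.atoms)

    def test_atom_longer_than_signal_rejected(self, rng):
        with pytest.raises(ValueError):
            learn_dictionary([rng.standard_normal(50)], m=1, atom_sec=0.7, iters=5)


class TestSelectNumAtoms:
    def test_singleton_candidate(self, rng):
        signals = planted_signals(planted_atom(), 3, rng)
        assert select_num_atoms(signals, [3], folds=3, lam=1.0, iters=5) == 3

    def test_two_planted_atoms_selected(self, rng):
        t = np.linspace(0, 1, 70)
        a1 = np.exp(-0.5 * ((t - 0.35) / 0.1) ** 2)
        a1 /= np.linalg.norm(a1)
        a2 = np.sin(2 * np.pi * 2 * t) * np.exp(-3 * t)
        a2 /= np.linalg.norm(a2)
        signals = planted_signals(np.vstack([a1, a2]), 12, rng)
        m = select_num_atoms(signals, [1, 2, 3, 4], folds=3, lam=0.05,
                             iters=200, seed=0)
        assert m == 2

    def test_deterministic(self, rng):
        signals = planted_signals(planted_atom(), 6, rng)
        kw = dict(folds=3, lam=1.0, iters=20, seed=4)
        assert (select_num_atoms(signals, [1, 2], **kw)
                == select_num_atoms(signals, [1, 2], **kw))

    def test_fewer_signals_than_folds_rejected(self, rng):
        with pytest.raises(ValueError):
            select_num_atoms(planted_signals(planted_atom(), 2, rng), [1, 2], folds=5)


class TestEmbed:
    def test_impulse_atom_is_identity(self, rng):
        s = rng.standard_normal(300)
        dic = StepDictionary(np.array([[1.0]]))
        emb = embed(s, dic)
        np.testing.assert_allclose(emb.channels[0], s)

    def test_impulse_signal_reproduces_atom(self):
        atom = planted_atom(21)
        dic = StepDictionary(atom[None, :])
        s = np.zeros(101)
        s[50] = 1.0
        emb = embed(s, dic)
        # "same" convolution centers the atom on the impulse
        np.testing.assert_allclose(emb.channels[0, 40:61], atom, atol=1e-12)

    def test_linearity(self, rng):
        dic = StepDictionary(planted_atom(30)[None, :])
        a, b = rng.standard_normal(200), rng.standard_normal(200)
        np.testing.assert_allclose(
            embed(a + b, dic).channels,
            embed(a, dic).channels + embed(b, dic).channels,
            atol=1e-10,
        )

    def test_shift_equivariance_away_from_borders(self, rng):
        dic = StepDictionary(planted_atom(30)[None, :])
        s = np.zeros(400)
        s[100:130] = rng.standard_normal(30)
        shifted = np.roll(s, 17)
        e1 = embed(s, dic).channels[0]
        e2 = embed(shifted, dic).channels[0]
        np.testing.assert_allclose(np.roll(e1, 17)[60:340], e2[60:340], atol=1e-10)

    def test_short_signal_rejected(self):
        dic = StepDictionary(planted_atom(70)[None, :])
        with pytest.raises(ValueError):
            embed(np.zeros(50), dic)

    def test_m_channels(self, rng):
        dic = StepDictionary(np.vstack([planted_atom(30), planted_atom(30)[::-1]]))
        emb = embed(rng.standard_normal(200), dic)
        assert emb.channels.shape == (2, 200)
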