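"""Surrogate null families: conservation laws and destruction of coupling."""

import numpy as np
import pytest

from conftest import ar2, ar2_pair
from preictalnet.interrelation import mutual_information
from preictalnet.simulate import NonlinearHubSpec, SimulationConfig, default_labels, generate_epoch
from preictalnet.surrogates import (
    Window,
    iaaft_multivariate,
    iaaft_univariate,
    make_ensemble,
    rotate_phases,
    shift_surrogate,
)


def circular_autocorr(x):
    return np.fft.irfft(np.abs(np.fft.rfft(x)) ** 2, n=len(x))


# ---------------------------------------------------------------------------
# univariate IAAFT
# ---------------------------------------------------------------------------

def test_iaaft_amplitude_multiset_is_exact(rng):
    x = ar2(rng, 2048)
    s, _ = iaaft_univariate(x, seed=1)
    assert np.array_equal(np.sort(s), np.sort(x))


def test_iaaft_periodogram_error_decreases_over_first_iterations(rng):
    x = ar2(rng, 2048)
    ps_src = np.abs(np.fft.rfft(x)) ** 2
    errs = []
    for k in range(1, 6):
        # same seed -> same initial permutation -> nested trajectories
        s, _ = iaaft_univariate(x, max_iter=k, seed=3)
        ps = np.abs(np.fft.rfft(s)) ** 2
        errs.append(np.linalg.norm(ps - ps_src) / np.linalg.norm(ps_src))
    assert all(b < a for a, b in zip(errs, errs[1:]))


def test_iaaft_white_noise_autocorrelation_in_sampling_band(rng):
    n = 1024
    x = rng.standard_normal(n)
    s, _ = iaaft_univariate(x, seed=7)
    lag1 = lambda v: np.corrcoef(v[:-1], v[1:])[0, 1]  # noqa: E731
    band = np.quantile(
        [lag1(rng.standard_normal(n)) for _ in range(500)], [0.025, 0.975]
    )
    assert band[0] <= lag1(s) <= band[1]


def test_iaaft_constant_input_rejected():
    with pytest.raises(ValueError, match="constant"):
        iaaft_univariate(np.ones(256), seed=0)


def test_iaaft_surrogates_differ_across_seeds(rng):
    x = ar2(rng, 512)
    a, _ = iaaft_univariate(x, seed=1)
    b, _ = iaaft_univariate(x, seed=2)
    assert not np.array_equal(a, b)


# ---------------------------------------------------------------------------
# multivariate IAAFT
# ---------------------------------------------------------------------------

def test_rigid_phase_rotation_preserves_cross_correlation(rng):
    X = ar2_pair(rng, 1024, rho=0.6)
    alpha = rng.uniform(0, 2 * np.pi, size=513)
    rot = rotate_phases(X, alpha)
    assert np.allclose(np.corrcoef(rot), np.corrcoef(X), atol=1e-10)


def test_multivariate_iaaft_conserves_pearson(rng):
    X = ar2_pair(rng, 2048, rho=0.7)
    w = Window(X, 256.0)
    ens = make_ensemble(w, "multivariate_iaaft", n_surrogates=50, max_iter=30, seed=2)
    cors = [np.corrcoef(s.samples)[0, 1] for s in ens.realizations]
    assert abs(np.mean(cors) - 0.7) < 0.1
    assert max(abs(c - np.corrcoef(X)[0, 1]) for c in cors) < 0.1
    for s in ens.realizations:  # amplitude conservation per channel
        assert np.array_equal(np.sort(s.samples, axis=1), np.sort(X, axis=1))


def test_multivariate_iaaft_destroys_nonlinear_excess(rng):
    # a hub-coupled pair has more MI than a linear pair of equal correlation;
    # its multivariate IAAFT surrogates fall back into the linear MI band
    labels = default_labels(1)
    cfg = SimulationConfig(
        n_channels=4, channel_labels=labels, sampling_rate=256.0,
        epoch_duration=8.0, within_electrode_level=0.0,
        within_hemisphere_level=0.0, between_hemisphere_level=0.0,
        resected_labels=(), hub_spec=NonlinearHubSpec(
            frozenset({1}), frozenset({0}), coupling_strength=1.0
        ),
        seed=3,
    )
    ep = generate_epoch(cfg)
    pair = ep.signals[:2]
    mi_coupled = mutual_information(pair[0], pair[1])

    w = Window(pair, 256.0)
    ens = make_ensemble(w, "multivariate_iaaft", n_surrogates=30, max_iter=30, seed=4)
    mi_surr = [
        mutual_information(s.samples[0], s.samples[1]) for s in ens.realizations
    ]
    # linear reference: independent Gaussian pairs at the surrogate correlation
    rho = float(np.corrcoef(pair)[0, 1])
    mi_lin = []
    for k in range(30):
        Y = ar2_pair(rng, pair.shape[1], rho=rho)
        mi_lin.append(mutual_information(Y[0], Y[1]))
    assert mi_coupled > max(mi_surr)
    assert np.mean(mi_surr) < np.mean(mi_lin) + 3 * np.std(mi_lin)


def test_multivariate_constant_channel_names_offender(rng):
    X = np.vstack([ar2(rng, 256), np.zeros(256)])
    with pytest.raises(ValueError, match="1"):
        iaaft_multivariate(Window(X), seed=0)


# ---------------------------------------------------------------------------
# shift surrogates
# ---------------------------------------------------------------------------

def test_shift_preserves_circular_autocorrelation_exactly(rng):
    X = ar2_pair(rng, 1024, rho=0.5)
    s = shift_surrogate(Window(X), seed=5)
    for c in range(2):
        assert np.allclose(
            circular_autocorr(s.samples[c]), circular_autocorr(X[c]), atol=1e-8
        )
        assert np.array_equal(np.sort(s.samples[c]), np.sort(X[c]))


def test_shift_destroys_zero_lag_correlation(rng):
    X = ar2_pair(rng, 1024, rho=0.9)
    w = Window(X)
    cors = [
        np.corrcoef(shift_surrogate(w, seed=k).samples)[0, 1] for k in range(200)
    ]
    assert abs(np.mean(cors)) < 0.1


def test_shift_offsets_respect_minimum(rng):
    X = ar2_pair(rng, 256, rho=0.0)
    w = Window(X)
    m = int(np.ceil(0.05 * 256))
    for k in range(50):
        s = shift_surrogate(w, min_shift_fraction=0.05, seed=k)
        for c in range(2):
            # recover the applied circular shift from the exact match
            cc = np.fft.irfft(
                np.fft.rfft(s.samples[c]) * np.conj(np.fft.rfft(X[c])), n=256
            )
            lag = int(np.argmax(cc))
            assert m <= lag <= 256 - m


def test_shift_window_too_short():
    from preictalnet.surrogates import _shift_batch

    rng = np.random.default_rng(0)
    with pytest.raises(ValueError, match="too short"):
        _shift_batch(rng.normal(size=(1, 5)), 1, 0.45, rng)


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def test_ensemble_shapes_and_family(rng):
    X = ar2_pair(rng, 256, rho=0.3)
    w = Window(X)
    for family in ("univariate_iaaft", "multivariate_iaaft", "shift"):
        ens = make_ensemble(w, family, n_surrogates=5, max_iter=10, seed=1)
        assert ens.family == family
        assert len(ens) == 5
        assert ens.stacked().shape == (5, 2, 256)
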