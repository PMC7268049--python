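"""Windowing, raw measures and surrogate-corrected matrices."""

import numpy as np
import pytest

from conftest import ar2, ar2_pair
from preictalnet.interrelation import (
    CorrectionConfig,
    InterrelationMatrix,
    WindowingConfig,
    default_mi_bins,
    epoch_average,
    linear_excess_matrix,
    mutual_information,
    nonlinear_excess_matrix,
    pearson_matrix,
    slide_windows,
)
from preictalnet.interrelation import _rescale_excess
from preictalnet.io import EpochRecording
from preictalnet.simulate import desk_scale_config, generate_epoch
from preictalnet.surrogates import SurrogateEnsemble, Window, make_ensemble


def make_epoch(rng, n_channels=2, duration=16.0, fs=64.0):
    import pandas as pd

    n = int(duration * fs)
    sig = rng.standard_normal((n_channels, n))
    labels = [f"AmR{i + 1:02d}" for i in range(n_channels)]
    meta = pd.DataFrame(
        {
            "label": labels,
            "electrode": ["AmR"] * n_channels,
            "hemisphere": ["R"] * n_channels,
            "focal": [True] * n_channels,
            "resected": [False] * n_channels,
        }
    )
    return EpochRecording(sig, fs, meta)


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "epoch_len,window,step,expected",
    [(180.0, 8.0, 1.0, 173), (8.0, 8.0, 1.0, 1), (180.0, 8.0, 4.0, 44)],
)
def test_window_count(rng, epoch_len, window, step, expected):
    ep = make_epoch(rng, duration=epoch_len, fs=64.0)
    cfg = WindowingConfig(window, step, epoch_len)
    wins = slide_windows(ep, cfg)
    assert len(wins) == expected
    assert cfg.n_windows() == expected
    assert all(w.n_samples == int(window * 64) for w in wins)
    # left-aligned, half-open: first window starts at sample 0
    assert np.array_equal(wins[0].samples, ep.signals[:, : int(window * 64)])


def test_epoch_shorter_than_window_fails(rng):
    ep = make_epoch(rng, duration=4.0)
    with pytest.raises(ValueError, match="shorter"):
        slide_windows(ep, WindowingConfig(8.0, 1.0, 8.0))


# ---------------------------------------------------------------------------
# Pearson
# ---------------------------------------------------------------------------

def test_pearson_duplicated_and_negated_channels(rng):
    x = ar2(rng, 256)
    c = pearson_matrix(Window(np.vstack([x, x, -x])))
    assert c[0, 1] == pytest.approx(1.0)
    assert c[0, 2] == pytest.approx(-1.0)
    assert np.allclose(np.diag(c), 1.0)


def test_pearson_independent_noise_small(rng):
    # Fisher-z: |r| < 0.1 for n = 2048 except with probability << 1
    c = pearson_matrix(Window(rng.standard_normal((5, 2048))))
    off = c[np.triu_indices(5, 1)]
    assert np.all(np.abs(off) < 0.1)


def test_pearson_constant_channel_rejected(rng):
    X = np.vstack([ar2(rng, 128), np.full(128, 2.0)])
    with pytest.raises(ValueError, match="1"):
        pearson_matrix(Window(X))


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------

def test_mi_identical_series_is_log2_bins(rng):
    x = rng.standard_normal(2048)
    assert mutual_information(x, x, bins=8) == pytest.approx(3.0)


def test_mi_invariant_under_bin_relabeling(rng):
    # a strictly monotone map and a bin-permuting map both give log2(B)
    x = rng.standard_normal(2048)
    assert mutual_information(x, np.exp(x), bins=8) == pytest.approx(3.0)
    b = (np.argsort(np.argsort(x)) * 8) // 2048
    y = ((b + 3) % 8).astype(float)  # permute bin identities
    assert mutual_information(x, y, bins=8) == pytest.approx(3.0)


def test_mi_plugin_bias_matches_first_order_formula(rng):
    # independent series: E[MI_hat] ~ (B-1)^2 / (2 n ln 2) bits
    B, n, reps = 8, 2048, 100
    est = [
        mutual_information(rng.uniform(size=n), rng.uniform(size=n), bins=B)
        for _ in range(reps)
    ]
    expected = (B - 1) ** 2 / (2 * n * np.log(2))
    se = np.std(est, ddof=1) / np.sqrt(reps)
    assert abs(np.mean(est) - expected) < 3 * se


def test_mi_requires_enough_samples():
    with pytest.raises(ValueError, match="too small"):
        mutual_information(np.arange(100.0), np.arange(100.0), bins=8)


def test_default_bin_rule():
    assert default_mi_bins(2048) == 16  # capped
    assert default_mi_bins(512) == 10
    assert default_mi_bins(45) == 3


# ---------------------------------------------------------------------------
# corrected matrices
# ---------------------------------------------------------------------------

def white_noise_ensemble(rng, family, shape, n_surr=19):
    """A hand-built exchangeable null ensemble of independent noise windows."""
    return SurrogateEnsemble(
        family=family,
        realizations=[Window(rng.standard_normal(shape)) for _ in range(n_surr)],
        iterations_used=[0] * n_surr,
    )


def test_linear_excess_duplicated_channel_saturates(rng):
    x = ar2(rng, 512)
    w = Window(np.vstack([x, x + 1e-12 * rng.standard_normal(512), ar2(rng, 512)]))
    ens = white_noise_ensemble(rng, "univariate_iaaft", (3, 512))
    cfg = CorrectionConfig(n_surrogates=19, pointwise_alpha=0.05)
    M = linear_excess_matrix(w, ens, cfg)
    assert M.values[0, 1] == pytest.approx(1.0)
    assert M.kind == "linear"
    assert np.all(np.diag(M.values) == 0)


def test_rescale_at_quantile_is_strictly_zero():
    obs = np.array([[0.0, 0.5], [0.5, 0.0]])
    q = np.array([[0.0, 0.5], [0.5, 0.0]])
    out = _rescale_excess(obs.copy(), q, np.ones_like(q), signed=True)
    assert np.all(out == 0)


def test_wrong_ensemble_family_rejected(rng):
    w = Window(rng.standard_normal((2, 256)))
    ens = white_noise_ensemble(rng, "shift", (2, 256))
    with pytest.raises(ValueError, match="univariate_iaaft"):
        linear_excess_matrix(w, ens, CorrectionConfig(19, 0.05))
    with pytest.raises(ValueError, match="multivariate_iaaft"):
        nonlinear_excess_matrix(w, ens, CorrectionConfig(19, 0.05))


def test_correction_config_requires_resolvable_rank_test():
    with pytest.raises(ValueError, match="resolvable"):
        CorrectionConfig(n_surrogates=19, pointwise_alpha=0.01)


def test_nonlinear_excess_detects_hub_majority_of_windows(rng):
    # hub-coupled pair at beta = 1: the multivariate-IAAFT null conserves the
    # linear part, the excess MI survives correction in most windows
    cfg = desk_scale_config(epoch_duration=24.0, seed=31)
    ep = generate_epoch(cfg)
    hub, tgt = 4, 5  # HiR01 -> HiR02
    ccfg = CorrectionConfig(n_surrogates=49, pointwise_alpha=0.02, max_iter=20)
    hits = 0
    from preictalnet.interrelation import slide_windows

    wins = slide_windows(ep, WindowingConfig(4.0, 4.0, 24.0))
    for k, w in enumerate(wins):
        sub = Window(w.samples[[hub, tgt]], w.sampling_rate)
        ens = make_ensemble(sub, "multivariate_iaaft", 49, max_iter=20, seed=100 + k)
        M = nonlinear_excess_matrix(sub, ens, ccfg)
        hits += M.values[0, 1] > 0
    assert hits > len(wins) / 2


# ---------------------------------------------------------------------------
# epoch average
# ---------------------------------------------------------------------------

def test_epoch_average_identities(rng):
    v = np.abs(ar2_pair(rng, 3, rho=0.0))  # any 2x3 -> build 3x3 symmetric
    m = np.zeros((3, 3))
    m[0, 1] = m[1, 0] = 0.4
    m[0, 2] = m[2, 0] = -0.2
    A = InterrelationMatrix(m, "linear")
    assert np.array_equal(epoch_average([A, A]).values, m)
    B = InterrelationMatrix(-m, "linear")
    assert np.all(epoch_average([A, B]).values == 0)


def test_epoch_average_matches_bruteforce(rng):
    mats = []
    for k in range(7):
        r = rng.uniform(0, 1, size=(4, 4))
        v = (r + r.T) / 2
        np.fill_diagonal(v, 0)
        mats.append(InterrelationMatrix(v, "nonlinear_excess", k))
    avg = epoch_average(mats)
    brute = sum(m.values for m in mats) / 7
    assert np.allclose(avg.values, brute)
    assert avg.kind == "nonlinear_excess"


def test_epoch_average_rejects_mixed_kinds():
    z = np.zeros((3, 3))
    with pytest.raises(ValueError, match="mixed"):
        epoch_average(
            [InterrelationMatrix(z, "linear"), InterrelationMatrix(z, "mi_shift")]
        )


def test_matrix_invariants_enforced():
    bad = np.array([[0.0, 1.0], [0.5, 0.0]])
    with pytest.raises(ValueError, match="symmetric"):
        InterrelationMatrix(bad, "linear")
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        InterrelationMatrix(np.array([[0.0, -0.5], [-0.5, 0.0]]), "nonlinear_excess")
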