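"""Region grouping, uniform-expectation normalization, nonparametric tests."""

import numpy as np
import pytest

from preictalnet.contrasts import (
    RegionLabels,
    bonferroni,
    contrast_epochs,
    format_significance_level,
    group_pairs,
    kruskal_wallis,
    mann_whitney_u,
    normalize_epochwise,
    sign_test,
)
from preictalnet.interrelation import InterrelationMatrix


def toy_matrix():
    # 4 channels: 0,1 focal; 2,3 nonfocal; |M|: (0,1)=0.8, (2,3)=0.4, cross=0.1
    m = np.full((4, 4), 0.1)
    m[0, 1] = m[1, 0] = 0.8
    m[2, 3] = m[3, 2] = 0.4
    np.fill_diagonal(m, 0.0)
    return m


def toy_labels():
    return RegionLabels(focal=[True, True, False, False],
                        resected=[True, False, False, False])


def test_hemisphere_group_means_on_toy():
    means, counts = group_pairs(toy_matrix(), toy_labels(), "hemisphere")
    assert means == {"within_focal": 0.8, "within_nonfocal": 0.4, "between": 0.1}
    assert counts == {"within_focal": 1, "within_nonfocal": 1, "between": 4}


def test_constant_matrix_gives_equal_groups():
    m = np.full((4, 4), 0.3)
    np.fill_diagonal(m, 0.0)
    means, _ = group_pairs(m, toy_labels(), "hemisphere")
    assert all(v == pytest.approx(0.3) for v in means.values())


def test_group_means_match_bruteforce_enumeration(rng):
    n = 8
    r = rng.uniform(size=(n, n))
    m = (r + r.T) / 2
    np.fill_diagonal(m, 0.0)
    focal = rng.uniform(size=n) < 0.5
    focal[:2] = True  # ensure both hemispheres populated
    focal[-2:] = False
    resected = focal & (rng.uniform(size=n) < 0.5)
    labels = RegionLabels(focal, resected)
    for scheme in ("hemisphere", "resection"):
        means, counts = group_pairs(m, labels, scheme)
        # oracle: explicit loop over all channel pairs
        groups = {g: [] for g in means}
        for i in range(n):
            for j in range(i + 1, n):
                if scheme == "hemisphere":
                    if focal[i] and focal[j]:
                        groups["within_focal"].append(m[i, j])
                    elif not focal[i] and not focal[j]:
                        groups["within_nonfocal"].append(m[i, j])
                    else:
                        groups["between"].append(m[i, j])
                else:
                    ipsi_i = focal[i] and not resected[i]
                    ipsi_j = focal[j] and not resected[j]
                    if resected[i] and resected[j]:
                        groups["within_resected"].append(m[i, j])
                    elif ipsi_i and ipsi_j:
                        groups["within_nonresected"].append(m[i, j])
                    elif (resected[i] and ipsi_j) or (ipsi_i and resected[j]):
                        groups["bridging"].append(m[i, j])
        for g in means:
            assert counts[g] == len(groups[g])
            if groups[g]:
                assert means[g] == pytest.approx(np.mean(groups[g]))
            else:
                assert np.isnan(means[g])


def test_single_resected_channel_flags_absent_group():
    labels = toy_labels()  # exactly one resected channel
    means, counts = group_pairs(toy_matrix(), labels, "resection")
    assert counts["within_resected"] == 0
    assert np.isnan(means["within_resected"])


def test_resected_outside_focal_rejected():
    with pytest.raises(ValueError, match="focal"):
        RegionLabels(focal=[True, False], resected=[False, True])


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_epochwise_normalization_toy_factors():
    means, counts = group_pairs(toy_matrix(), toy_labels(), "hemisphere")
    f = normalize_epochwise(means, counts)
    assert f["within_focal"] == pytest.approx(3.0)
    assert f["within_nonfocal"] == pytest.approx(1.5)
    assert f["between"] == pytest.approx(0.375)


def test_equal_groups_normalize_to_one():
    f = normalize_epochwise({"a": 0.2, "b": 0.2}, {"a": 3, "b": 5})
    assert f == {"a": pytest.approx(1.0), "b": pytest.approx(1.0)}


def test_pair_count_weighted_factor_mean_is_one(rng):
    means = {g: rng.uniform(0.1, 1.0) for g in "abcd"}
    counts = {g: int(rng.integers(1, 9)) for g in "abcd"}
    f = normalize_epochwise(means, counts)
    total = sum(counts.values())
    assert sum(f[g] * counts[g] / total for g in "abcd") == pytest.approx(1.0)


def test_zero_grand_mean_rejected():
    with pytest.raises(ValueError, match="grand mean"):
        normalize_epochwise({"a": 0.0, "b": 0.0}, {"a": 2, "b": 2})


# ---------------------------------------------------------------------------
# nonparametric tests
# ---------------------------------------------------------------------------

def test_kruskal_identical_groups_is_degenerate_null():
    h, p = kruskal_wallis([[1.0, 1.0, 1.0], [1.0, 1.0]])
    assert h == 0.0
    assert p == 1.0


def test_mann_whitney_exact_small_sample():
    # complete separation of 3 vs 3: 2/20 arrangements are as extreme
    u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert p == pytest.approx(0.1)


def test_sign_test_ten_of_ten():
    p = sign_test(np.ones(10) * 2.0, expected=1.0)
    assert p == pytest.approx(2 * 0.5**10)


def test_sign_test_discards_zero_differences():
    p = sign_test([1.0, 1.0, 2.0, 2.0], expected=1.0)
    assert p == pytest.approx(0.5)  # 2/2 positive among nonzero diffs


def test_bonferroni_thresholds_match_printed_values():
    t18 = bonferroni(0.01, 18)
    assert t18 == pytest.approx(0.01 / 18)
    assert format_significance_level(t18) == "5.5e-04"
    t6 = bonferroni(0.01, 6)
    # printed as 0.0017 (standard rounding at the printed precision)
    assert round(t6, 4) == 0.0017
    assert bonferroni(0.037, 1) == 0.037


# ---------------------------------------------------------------------------
# epoch-level battery
# ---------------------------------------------------------------------------

def test_contrast_epochs_recovers_region_effect(rng):
    labels = toy_labels()
    mats = []
    for _ in range(12):
        m = toy_matrix() + rng.normal(0, 0.01, size=(4, 4))
        m = np.abs((m + m.T) / 2)
        np.fill_diagonal(m, 0.0)
        mats.append(InterrelationMatrix(np.clip(m, 0, 1), "nonlinear_excess"))
    res = contrast_epochs(mats, labels, scheme="hemisphere", alpha=0.01)
    assert res.omnibus[1] < 0.01
    assert res.factors.shape == (12, 3)
    assert len(res.pairwise) + len(res.sign_tests) == res.n_comparisons
    assert res.corrected_alpha == pytest.approx(0.01 / res.n_comparisons)
    # focal group factors exceed between-hemisphere factors in every epoch
    assert np.all(res.factors[:, 0] > res.factors[:, 2])
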