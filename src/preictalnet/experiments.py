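"""Reusable study-level experiments on synthetic cohorts.

Each function runs one self-contained experiment at desk scale and returns a
plain dict of computed quantities, so the analysis drivers, the test suite
and the reproduction script share one code path.  Problem sizes default to
the reduced study geometry (16 channels, 40 s epochs at 128 Hz, 4 s
windows); see docs/methods.md for the rationale.
"""

from __future__ import annotations

import numpy as np

from .contrasts import bonferroni
from .interrelation import (
    CorrectionConfig,
    WindowingConfig,
    epoch_average,
    epoch_matrices,
    linear_excess_matrix,
    nonlinear_excess_matrix,
)
from .network import (
    format_percent,
    matrix_metrics,
    node_strength,
    normalized_share,
)
from .reproducibility import mantel_test
from .simulate import (
    desk_scale_config,
    generate_cohort,
    make_target_correlation,
)
from .surrogates import Window, make_ensemble

__all__ = [
    "worked_share_arithmetic",
    "calibration_experiment",
    "recovery_experiment",
    "linearity_experiment",
]


def worked_share_arithmetic() -> dict:
    """Uniform-expectation shares and overrepresentation factors.

    Recomputes, from channel counts and the observed percentage shares of
    three reported patient examples, every step of the share arithmetic:
    expected share under a uniform distribution of node strength, and the
    resulting over/underrepresentation factors.  Observed shares are
    measurement inputs; everything else is derived here.
    """
    out = {}

    def example(prefix, n_channels, subset, observed_pct):
        expected = subset / n_channels
        out[f"{prefix}_expected_pct"] = 100 * expected
        out[f"{prefix}_expected_printed"] = format_percent(expected)
        out[f"{prefix}_factor"] = (observed_pct / 100) / expected

    # patient 1: 48 recorded channels, 7 resected (4 in the hippocampus);
    # resection captured 25.2% of nonlinear-excess NS and 8.9% of linear NS
    example("p1_resected_nonlinear", 48, 7, 25.2)
    example("p1_resected_linear", 48, 7, 8.9)
    example("p1_hippocampus_nonlinear", 48, 4, 16.9)

    # patient 14: 32 channels, 14 resected; 56.3% of nonlinear-excess NS;
    # channel HiR01 alone held 13.8%
    example("p14_resected_nonlinear", 32, 14, 56.3)
    example("p14_hir01_nonlinear", 32, 1, 13.8)

    # patient 13 (phase II montage): 76 contacts, 16 resected (the printed
    # 21.1% expectation times 76); seizures 1 and 2 captured 31.2% / 55.3%
    example("p13_seizure1_nonlinear", 76, 16, 31.2)
    example("p13_seizure2_nonlinear", 76, 16, 55.3)
    out["p13_hir01_expected_pct"] = 100 / 76
    out["p13_hir01_expected_printed"] = format_percent(1 / 76)

    out["bonferroni_m18"] = bonferroni(0.01, 18)
    out["bonferroni_m6"] = bonferroni(0.01, 6)
    return out


def calibration_experiment(
    seed: int,
    n_channels: int = 20,
    n_windows: int = 50,
    n_surrogates: int = 99,
    alpha: float = 0.01,
    n_samples: int = 512,
    max_iter: int = 100,
) -> dict:
    """False-positive rate of both corrected families on independent noise.

    Every channel is independent white noise, so any nonzero element of a
    corrected matrix is a false positive; the pointwise rank test should
    reject at rate alpha.  Returns the empirical rates and the 95% binomial
    sampling band around alpha.
    """
    cfg = CorrectionConfig(
        n_surrogates=n_surrogates, pointwise_alpha=alpha, max_iter=max_iter
    )
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root)
    iu = np.triu_indices(n_channels, 1)
    hits = {"linear": 0, "nonlinear_excess": 0}
    for k, wseed in enumerate(root.spawn(n_windows)):
        X = rng.standard_normal((n_channels, n_samples))
        w = Window(X)
        s1, s2 = [int(s.generate_state(1)[0] % 2**31) for s in wseed.spawn(2)]
        ens_u = make_ensemble(w, "univariate_iaaft", n_surrogates,
                              max_iter=max_iter, seed=s1)
        hits["linear"] += int(
            np.count_nonzero(linear_excess_matrix(w, ens_u, cfg).values[iu])
        )
        ens_m = make_ensemble(w, "multivariate_iaaft", n_surrogates,
                              max_iter=min(max_iter, 20), seed=s2)
        hits["nonlinear_excess"] += int(
            np.count_nonzero(nonlinear_excess_matrix(w, ens_m, cfg).values[iu])
        )
    n_tests = n_windows * len(iu[0])
    half_width = 1.96 * np.sqrt(alpha * (1 - alpha) / n_tests)
    return {
        "alpha": alpha,
        "n_tests": n_tests,
        "linear_rate": hits["linear"] / n_tests,
        "nonlinear_rate": hits["nonlinear_excess"] / n_tests,
        "band_low": alpha - half_width,
        "band_high": alpha + half_width,
    }


def recovery_experiment(
    seed: int,
    n_epochs: int = 10,
    epoch_duration: float = 40.0,
    window_length: float = 4.0,
    step: float = 4.0,
    n_surrogates: int = 99,
    alpha: float = 0.01,
) -> dict:
    """Recovery of planted structure from hub-coupled block epochs.

    For each synthetic epoch (block-linear coupling plus one nonlinear hub on
    later-"resected" focal channels) the experiment records: the mean
    per-window degree assortativity of the linear and the nonlinear-excess
    networks, whether the hub is in the nonlinear core set of the
    epoch-averaged matrix, the uniform-expectation factor of nonlinear node
    strength in the resected channels, and the correlation of the averaged
    linear matrix with the generator's target pattern.
    """
    cfg = desk_scale_config(epoch_duration=epoch_duration)
    wcfg = WindowingConfig(window_length, step, epoch_duration)
    ccfg = CorrectionConfig(
        n_surrogates=n_surrogates, pointwise_alpha=alpha,
        families=("linear", "nonlinear_excess"), max_iter=20,
    )
    target = make_target_correlation(cfg)
    iu = np.triu_indices(cfg.n_channels, 1)
    hub_idx = sorted(cfg.hub_spec.hub_channels)[0]
    meta = cfg.channel_metadata()
    resected_idx = np.where(meta["resected"])[0]

    epochs = generate_cohort(cfg, n_epochs, seed=seed)
    rows = {
        "linear_assortativity": [],
        "nonlinear_assortativity": [],
        "hub_in_core": [],
        "resected_factor": [],
        "linear_pattern_r": [],
    }
    for i, ep in enumerate(epochs):
        mats = epoch_matrices(ep, wcfg, ccfg, seed=seed + 7919 * (i + 1))
        for fam, key in (("linear", "linear_assortativity"),
                         ("nonlinear_excess", "nonlinear_assortativity")):
            vals = []
            for m in mats[fam]:
                try:
                    vals.append(matrix_metrics(m).assortativity)
                except ValueError:
                    vals.append(np.nan)
            rows[key].append(float(np.nanmean(vals)))
        non_avg = epoch_average(mats["nonlinear_excess"])
        lin_avg = epoch_average(mats["linear"])
        met = matrix_metrics(non_avg)
        rows["hub_in_core"].append(bool(hub_idx in met.core_set))
        rows["resected_factor"].append(
            float(normalized_share(node_strength(non_avg), resected_idx))
        )
        rows["linear_pattern_r"].append(
            float(np.corrcoef(lin_avg.values[iu], target[iu])[0, 1])
        )
    rows["n_epochs"] = n_epochs
    rows["linear_positive_fraction"] = float(
        np.mean(np.asarray(rows["linear_assortativity"]) > 0)
    )
    rows["nonlinear_negative_fraction"] = float(
        np.mean(np.asarray(rows["nonlinear_assortativity"]) < 0)
    )
    rows["hub_core_fraction"] = float(np.mean(rows["hub_in_core"]))
    rows["min_resected_factor"] = float(np.min(rows["resected_factor"]))
    rows["median_pattern_r"] = float(np.median(rows["linear_pattern_r"]))
    return rows


def linearity_experiment(
    seed: int,
    n_epochs: int = 6,
    epoch_duration: float = 40.0,
    window_length: float = 4.0,
    step: float = 4.0,
    n_surrogates: int = 99,
    alpha: float = 0.01,
    n_perm: int = 999,
) -> dict:
    """Which nonlinear null is redundant with the linear matrices?

    On purely linearly coupled epochs (no hub) the shift-corrected MI
    matrices should be similar to the linear matrices (the shift null
    destroys cross-correlation, so MI rediscovers the linear coupling),
    while the multivariate-IAAFT-corrected matrices — whose null already
    conserves the linear part — should carry no related structure.
    Mantel p-values per epoch for both comparisons.
    """
    cfg = desk_scale_config(epoch_duration=epoch_duration, with_hub=False)
    wcfg = WindowingConfig(window_length, step, epoch_duration)
    ccfg = CorrectionConfig(
        n_surrogates=n_surrogates, pointwise_alpha=alpha,
        families=("linear", "nonlinear_excess", "mi_shift"), max_iter=20,
    )
    epochs = generate_cohort(cfg, n_epochs, seed=seed)
    out = {"shift_vs_linear_p": [], "nonlinear_vs_linear_p": [],
           "shift_vs_linear_r": [], "nonlinear_vs_linear_r": []}
    for i, ep in enumerate(epochs):
        mats = epoch_matrices(ep, wcfg, ccfg, seed=seed + 104729 * (i + 1))
        lin = epoch_average(mats["linear"])
        shift = epoch_average(mats["mi_shift"])
        non = epoch_average(mats["nonlinear_excess"])
        r, p = mantel_test(np.abs(lin.values), shift.values, n_perm, seed + i)
        out["shift_vs_linear_r"].append(r)
        out["shift_vs_linear_p"].append(p)
        try:
            r2, p2 = mantel_test(np.abs(lin.values), non.values, n_perm, seed + i)
        except ValueError:  # an all-zero excess matrix carries no structure
            r2, p2 = 0.0, 1.0
        out["nonlinear_vs_linear_r"].append(r2)
        out["nonlinear_vs_linear_p"].append(p2)
    out["n_epochs"] = n_epochs
    out["max_shift_vs_linear_p"] = float(np.max(out["shift_vs_linear_p"]))
    out["median_nonlinear_vs_linear_p"] = float(
        np.median(out["nonlinear_vs_linear_p"])
    )
    return out
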