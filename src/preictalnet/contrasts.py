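"""Region grouping, epoch-wise normalization and nonparametric contrasts.

Interrelations are grouped by channel-pair region: with respect to the
hemisphere of seizure onset (within-focal / within-nonfocal / between) or
with respect to the resection (within-resected / within nonresected
ipsilateral tissue / bridging the two).  Group means are normalized per
epoch against the uniform-distribution expectation, so values > 1 mean the
region carries more interrelation strength than its pair count alone would
predict.  Inference is nonparametric throughout: Kruskal-Wallis omnibus,
Mann-Whitney U post hoc, exact sign tests against an expected value, with
Bonferroni correction of the pointwise level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .interrelation import InterrelationMatrix

__all__ = [
    "RegionLabels",
    "ContrastResult",
    "group_pairs",
    "normalize_epochwise",
    "kruskal_wallis",
    "mann_whitney_u",
    "sign_test",
    "bonferroni",
    "format_significance_level",
    "contrast_epochs",
]

HEMISPHERE_GROUPS = ("within_focal", "within_nonfocal", "between")
RESECTION_GROUPS = ("within_resected", "within_nonresected", "bridging")

#: exact rank tests are used up to this group size, approximations above
EXACT_SIZE_LIMIT = 8


@dataclass(frozen=True)
class RegionLabels:
    """Per-channel region assignment.

    ``focal`` marks channels in the hemisphere of seizure onset; ``resected``
    marks channels recording from subsequently resected tissue (resection
    contrasts are restricted to the focal hemisphere).
    """

    focal: np.ndarray
    resected: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "focal", np.asarray(self.focal, bool))
        object.__setattr__(self, "resected", np.asarray(self.resected, bool))
        if self.focal.shape != self.resected.shape:
            raise ValueError("focal and resected flags must have equal length")
        if np.any(self.resected & ~self.focal):
            raise ValueError("resected channels must lie in the focal hemisphere")

    @classmethod
    def from_metadata(cls, metadata) -> "RegionLabels":
        return cls(
            np.asarray(metadata["focal"], bool),
            np.asarray(metadata["resected"], bool),
        )

    @property
    def n_channels(self) -> int:
        return self.focal.size


@dataclass
class ContrastResult:
    """Grouped per-epoch factors with the omnibus and post-hoc test battery."""

    scheme: str
    group_names: tuple
    factors: np.ndarray  # epochs x groups, NaN where a group is absent
    omnibus: tuple  # (H, p)
    pairwise: dict  # (group_a, group_b) -> (U, p)
    sign_tests: dict  # group -> p  (deviation from factor 1)
    alpha: float = 0.01
    n_comparisons: int = 0
    corrected_alpha: float = field(default=0.01)
    decisions: dict = field(default_factory=dict)


def _pair_masks(labels: RegionLabels, scheme: str):
    """Boolean channel-pair masks (upper triangle) for each group of a scheme."""
    n = labels.n_channels
    iu, ju = np.triu_indices(n, k=1)
    if scheme == "hemisphere":
        foc = labels.focal
        masks = {
            "within_focal": foc[iu] & foc[ju],
            "within_nonfocal": ~foc[iu] & ~foc[ju],
            "between": foc[iu] != foc[ju],
        }
    elif scheme == "resection":
        res = labels.resected
        ipsi = labels.focal & ~labels.resected
        masks = {
            "within_resected": res[iu] & res[ju],
            "within_nonresected": ipsi[iu] & ipsi[ju],
            "bridging": (res[iu] & ipsi[ju]) | (ipsi[iu] & res[ju]),
        }
    else:
        raise ValueError(f"unknown grouping scheme {scheme!r}")
    return iu, ju, masks


def group_pairs(M, labels: RegionLabels, scheme: str = "hemisphere"):
    """Mean |M_ij| per region group; empty groups are flagged absent (NaN).

    Returns ``(group_means, group_pair_counts)`` as ordered dicts keyed by
    the scheme's group names.
    """
    v = np.abs(M.values if isinstance(M, InterrelationMatrix) else np.asarray(M))
    iu, ju, masks = _pair_masks(labels, scheme)
    vals = v[iu, ju]
    means, counts = {}, {}
    for name, mask in masks.items():
        counts[name] = int(mask.sum())
        means[name] = float(vals[mask].mean()) if mask.any() else float("nan")
    return means, counts


def normalize_epochwise(group_means: dict, group_counts: dict) -> dict:
    """Normalize group means by the grand mean over all grouped pairs.

    The factor for group g is mean_g / grand_mean, the uniform-expectation
    normalization: the pair-count-weighted mean of the factors is exactly 1.
    """
    names = [g for g in group_means if group_counts.get(g, 0) > 0]
    total_pairs = sum(group_counts[g] for g in names)
    if total_pairs == 0:
        raise ValueError("no channel pairs in any group")
    grand = sum(group_means[g] * group_counts[g] for g in names) / total_pairs
    if grand <= 0:
        raise ValueError("zero grand mean interrelation; cannot normalize")
    return {
        g: (group_means[g] / grand if group_counts.get(g, 0) > 0 else float("nan"))
        for g in group_means
    }


# ---------------------------------------------------------------------------
# nonparametric tests
# ---------------------------------------------------------------------------

def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H and two-sided p (chi-square approximation).

    Degenerate input (all values identical across groups) returns (0, 1).
    """
    groups = [np.asarray(g, float) for g in groups]
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs >= 2 values")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; exact null for small samples.

    Mid-ranks handle ties; exact enumeration is used when both groups have
    at most ``EXACT_SIZE_LIMIT`` values and no ties straddle the groups,
    the normal approximation (tie-corrected) otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if np.all(np.concatenate([a, b]) == a[0]):
        return float(a.size * b.size / 2), 1.0
    small = a.size <= EXACT_SIZE_LIMIT and b.size <= EXACT_SIZE_LIMIT
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if small and not has_ties else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def sign_test(values, expected: float = 0.0) -> float:
    """Exact two-sided binomial sign test of the median against ``expected``.

    Zero differences are discarded; with no nonzero differences p = 1.
    """
    diffs = np.asarray(values, float) - expected
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return 1.0
    k = int(np.sum(nonzero > 0))
    return float(stats.binomtest(k, nonzero.size, 0.5).pvalue)


def bonferroni(alpha: float, m: int) -> float:
    """Corrected pointwise threshold alpha / m."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return alpha / m


def format_significance_level(threshold: float, sig_figs: int = 2) -> str:
    """Render a threshold at two significant figures, truncating.

    E.g. 0.01/18 = 5.55e-4 renders as "5.5e-04".  Reporting convention only;
    comparisons always use the full-precision value.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    exponent = math.floor(math.log10(threshold))
    mantissa = threshold / 10**exponent
    truncated = math.floor(mantissa * 10 ** (sig_figs - 1)) / 10 ** (sig_figs - 1)
    return f"{truncated:.{sig_figs - 1}f}e{exponent:+03d}"


# ---------------------------------------------------------------------------
# epoch-level battery
# ---------------------------------------------------------------------------

def contrast_epochs(
    matrices, labels_per_epoch, scheme: str = "hemisphere", alpha: float = 0.01,
) -> ContrastResult:
    """Grouped, normalized factors across epochs with the full test battery.

    ``matrices``: one epoch-averaged InterrelationMatrix per epoch;
    ``labels_per_epoch``: matching RegionLabels (or one shared instance).
    The epoch is the statistical unit.  The multiple-comparison count covers
    the pairwise group contrasts plus the per-group sign tests against 1.
    """
    matrices = list(matrices)
    if isinstance(labels_per_epoch, RegionLabels):
        labels_per_epoch = [labels_per_epoch] * len(matrices)
    names = HEMISPHERE_GROUPS if scheme == "hemisphere" else RESECTION_GROUPS
    rows = []
    for M, lab in zip(matrices, labels_per_epoch):
        means, counts = group_pairs(M, lab, scheme)
        rows.append([normalize_epochwise(means, counts)[g] for g in names])
    factors = np.asarray(rows, float)

    groups = [factors[:, k][np.isfinite(factors[:, k])] for k in range(len(names))]
    omnibus = kruskal_wallis([g for g in groups if g.size >= 2])
    pairwise = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if groups[i].size >= 2 and groups[j].size >= 2:
                pairwise[(names[i], names[j])] = mann_whitney_u(groups[i], groups[j])
    signs = {
        names[k]: sign_test(groups[k], expected=1.0)
        for k in range(len(names))
        if groups[k].size > 0
    }
    m = len(pairwise) + len(signs)
    corrected = bonferroni(alpha, max(m, 1))
    decisions = {
        **{k: p <= corrected for k, (_, p) in pairwise.items()},
        **{("sign", g): p <= corrected for g, p in signs.items()},
    }
    return ContrastResult(
        scheme=scheme,
        group_names=names,
        factors=factors,
        omnibus=omnibus,
        pairwise=pairwise,
        sign_tests=signs,
        alpha=alpha,
        n_comparisons=m,
        corrected_alpha=corrected,
        decisions=decisions,
    )
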