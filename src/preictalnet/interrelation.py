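"""Sliding-window surrogate-corrected interrelation matrices.

Per 8 s window (stepped by 1 s over a 180 s epoch by default) three matrix
families are available:

* ``linear`` — Pearson zero-lag cross-correlation, thresholded against
  univariate IAAFT surrogates; surviving elements rescaled to [-1, 1].
* ``nonlinear_excess`` — plug-in mutual information, thresholded against
  multivariate IAAFT surrogates (which conserve the Pearson matrix), so only
  interaction *beyond* the linear part survives; rescaled to [0, 1].
* ``mi_shift`` — mutual information thresholded against shift surrogates
  (which destroy all cross-channel alignment); sensitive to linear and
  nonlinear interaction alike.

The correction is a one-sided rank test: an element survives only if it
strictly exceeds the empirical (1 - alpha) quantile of its surrogate null,
then it is mapped onto the residual range above that quantile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import EpochRecording
from .surrogates import SurrogateEnsemble, Window, make_ensemble

__all__ = [
    "WindowingConfig",
    "CorrectionConfig",
    "InterrelationMatrix",
    "slide_windows",
    "pearson_matrix",
    "mutual_information",
    "default_mi_bins",
    "linear_excess_matrix",
    "nonlinear_excess_matrix",
    "mi_shift_matrix",
    "epoch_average",
    "epoch_matrices",
]

KINDS = ("linear", "nonlinear_excess", "mi_shift")

#: surrogate family providing the null for each matrix kind
FAMILY_FOR_KIND = {
    "linear": "univariate_iaaft",
    "nonlinear_excess": "multivariate_iaaft",
    "mi_shift": "shift",
}


@dataclass(frozen=True)
class WindowingConfig:
    """Sliding-window geometry, in seconds."""

    window_length: float = 8.0
    step: float = 1.0
    epoch_length: float = 180.0

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.window_length > self.epoch_length:
            raise ValueError("window_length must not exceed epoch_length")

    def n_windows(self) -> int:
        return int(np.floor((self.epoch_length - self.window_length) / self.step)) + 1


@dataclass(frozen=True)
class CorrectionConfig:
    """Surrogate-correction parameters.

    ``n_surrogates`` and ``pointwise_alpha`` must resolve a rank test:
    (n_surrogates + 1) * alpha >= 1.  ``mi_bins=None`` applies the default
    rule B = round(sqrt(n / 5)) capped at 16.
    """

    n_surrogates: int = 99
    pointwise_alpha: float = 0.01
    mi_bins: int | None = None
    families: tuple = ("linear", "nonlinear_excess")
    max_iter: int = 100
    min_shift_fraction: float = 0.05

    def __post_init__(self):
        if (self.n_surrogates + 1) * self.pointwise_alpha < 1.0 - 1e-12:
            raise ValueError(
                "(n_surrogates + 1) * pointwise_alpha must be >= 1 "
                "for a resolvable rank test"
            )
        bad = [f for f in self.families if f not in KINDS]
        if bad:
            raise ValueError(f"unknown matrix families: {bad}")


@dataclass
class InterrelationMatrix:
    """Symmetric zero-diagonal channel x channel matrix of one kind."""

    values: np.ndarray
    kind: str
    window_index: int = -1
    channel_labels: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.kind not in KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be a square matrix")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("matrix must have zero diagonal")
        if self.kind == "linear":
            if np.any(np.abs(v) > 1 + 1e-12):
                raise ValueError("linear entries must lie in [-1, 1]")
        elif np.any((v < -1e-12) | (v > 1 + 1e-12)):
            raise ValueError("nonlinear entries must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

def slide_windows(epoch: EpochRecording, cfg: WindowingConfig | None = None):
    """Cut an epoch into half-open, left-aligned sliding windows."""
    if cfg is None:
        cfg = WindowingConfig(epoch_length=epoch.duration)
    fs = epoch.sampling_rate
    w = int(round(cfg.window_length * fs))
    s = int(round(cfg.step * fs))
    total = min(epoch.n_samples, int(round(cfg.epoch_length * fs)))
    if total < w:
        raise ValueError("epoch shorter than one analysis window")
    n_win = (total - w) // s + 1
    return [
        Window(epoch.signals[:, k * s : k * s + w], fs) for k in range(n_win)
    ]


# ---------------------------------------------------------------------------
# raw measures
# ---------------------------------------------------------------------------

def pearson_matrix(w: Window) -> np.ndarray:
    """Zero-lag Pearson cross-correlation matrix (unit diagonal)."""
    sd = w.samples.std(axis=1)
    const = np.where(sd == 0)[0]
    if const.size:
        raise ValueError(f"constant channel(s): {list(const)}")
    c = np.corrcoef(w.samples)
    return np.clip(c, -1.0, 1.0)


def default_mi_bins(n: int) -> int:
    """Equiquantal bin count: B = round(sqrt(n / 5)), capped at 16."""
    return int(min(16, max(2, round(np.sqrt(n / 5.0)))))


def _equiquantal_bins(X: np.ndarray, bins: int) -> np.ndarray:
    """Marginal-rank bin indices per channel; ties split by sample order."""
    X = np.atleast_2d(X)
    n = X.shape[-1]
    order = np.argsort(X, axis=-1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(
        ranks, order, np.broadcast_to(np.arange(n), X.shape), axis=-1
    )
    return (ranks * bins) // n


def _mi_from_bins(bx: np.ndarray, by: np.ndarray, bins: int) -> float:
    n = bx.shape[-1]
    joint = np.bincount(bx * bins + by, minlength=bins * bins).astype(float)
    joint = joint.reshape(bins, bins) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    denom = np.outer(px, py)
    return float(np.sum(joint[nz] * np.log2(joint[nz] / denom[nz])))


def mutual_information(x, y, bins: int | None = None) -> float:
    """Plug-in mutual information in bits from a B x B equiquantal histogram.

    Marginal bins are rank-based (near-uniform by construction); ties are
    split in order of appearance, without jitter.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    n = x.size
    if bins is None:
        bins = default_mi_bins(n)
    if n < 4 * bins * bins:
        raise ValueError(f"n = {n} too small for B = {bins} (need n >= 4 B^2)")
    b = _equiquantal_bins(np.stack([x, y]), bins)
    return _mi_from_bins(b[0], b[1], bins)


def _mi_matrix_from_bins(binned: np.ndarray, bins: int) -> np.ndarray:
    """All-pairs MI (bits) from per-channel bin indices (C x n)."""
    C = binned.shape[0]
    out = np.zeros((C, C))
    for i in range(C):
        for j in range(i + 1, C):
            out[i, j] = out[j, i] = _mi_from_bins(binned[i], binned[j], bins)
    return out


# ---------------------------------------------------------------------------
# surrogate correction
# ---------------------------------------------------------------------------

def _null_quantile(stack: np.ndarray, alpha: float) -> np.ndarray:
    """Empirical (1 - alpha) quantile per pair from (N, C, C) surrogate values.

    Uses the order statistic k = ceil((1 - alpha) * (N + 1)): with N = 99 and
    alpha = 0.01 this is the surrogate maximum, giving an exact 1/(N+1)
    exceedance probability under exchangeability.
    """
    N = stack.shape[0]
    k = int(np.ceil((1.0 - alpha) * (N + 1))) - 1
    k = min(max(k, 0), N - 1)
    return np.sort(stack, axis=0)[k]


def _rescale_excess(obs, q, upper, signed):
    """Map observations strictly above the null quantile onto the residual range."""
    denom = upper - q
    degenerate = denom <= 0
    if np.any(degenerate & ((np.abs(obs) if signed else obs) > 0)):
        warnings.warn("degenerate null (quantile at range ceiling); entries zeroed")
    safe = np.where(degenerate, 1.0, denom)
    if signed:
        mag = np.abs(obs)
        out = np.sign(obs) * (mag - q) / safe
        out[(mag <= q) | degenerate] = 0.0
    else:
        out = (obs - q) / safe
        out[(obs <= q) | degenerate] = 0.0
    return out


def linear_excess_matrix(
    w: Window, ens: SurrogateEnsemble, cfg: CorrectionConfig,
    window_index: int = -1, labels=None,
) -> InterrelationMatrix:
    """Univariate-IAAFT-corrected Pearson matrix, rescaled to [-1, 1]."""
    if ens.family != "univariate_iaaft":
        raise ValueError(f"expected univariate_iaaft ensemble, got {ens.family}")
    obs = pearson_matrix(w)
    np.fill_diagonal(obs, 0.0)
    stack = np.abs(np.stack([pearson_matrix(s) for s in ens.realizations]))
    q = _null_quantile(stack, cfg.pointwise_alpha)
    np.fill_diagonal(q, 0.0)
    vals = _rescale_excess(obs, q, np.ones_like(q), signed=True)
    np.fill_diagonal(vals, 0.0)
    vals = np.clip((vals + vals.T) / 2.0, -1.0, 1.0)
    return InterrelationMatrix(vals, "linear", window_index, labels)


def _mi_corrected(
    w, ens, cfg, kind, expected_family, window_index, labels
) -> InterrelationMatrix:
    if ens.family != expected_family:
        raise ValueError(f"expected {expected_family} ensemble, got {ens.family}")
    n = w.n_samples
    bins = cfg.mi_bins or default_mi_bins(n)
    obs = _mi_matrix_from_bins(_equiquantal_bins(w.samples, bins), bins)
    stack = np.stack(
        [
            _mi_matrix_from_bins(_equiquantal_bins(s.samples, bins), bins)
            for s in ens.realizations
        ]
    )
    q = _null_quantile(stack, cfg.pointwise_alpha)
    np.fill_diagonal(q, 0.0)
    upper = np.full_like(q, np.log2(bins))
    vals = _rescale_excess(obs, q, upper, signed=False)
    np.fill_diagonal(vals, 0.0)
    vals = np.clip((vals + vals.T) / 2.0, 0.0, 1.0)
    return InterrelationMatrix(vals, kind, window_index, labels)


def nonlinear_excess_matrix(
    w: Window, ens: SurrogateEnsemble, cfg: CorrectionConfig,
    window_index: int = -1, labels=None,
) -> InterrelationMatrix:
    """MI beyond the Pearson-conserving (multivariate IAAFT) null, in [0, 1]."""
    return _mi_corrected(
        w, ens, cfg, "nonlinear_excess", "multivariate_iaaft", window_index, labels
    )


def mi_shift_matrix(
    w: Window, ens: SurrogateEnsemble, cfg: CorrectionConfig,
    window_index: int = -1, labels=None,
) -> InterrelationMatrix:
    """MI beyond the shift-surrogate null (linear + nonlinear interaction)."""
    return _mi_corrected(w, ens, cfg, "mi_shift", "shift", window_index, labels)


def epoch_average(matrices) -> InterrelationMatrix:
    """Element-wise mean of same-kind window matrices."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no matrices to average")
    kinds = {m.kind for m in matrices}
    if len(kinds) > 1:
        raise ValueError(f"cannot average mixed kinds: {sorted(kinds)}")
    shapes = {m.values.shape for m in matrices}
    if len(shapes) > 1:
        raise ValueError("matrices differ in shape")
    mean = np.mean([m.values for m in matrices], axis=0)
    return InterrelationMatrix(
        mean, matrices[0].kind, window_index=-1,
        channel_labels=matrices[0].channel_labels,
    )


# ---------------------------------------------------------------------------
# per-epoch driver
# ---------------------------------------------------------------------------

_BUILDERS = {
    "linear": linear_excess_matrix,
    "nonlinear_excess": nonlinear_excess_matrix,
    "mi_shift": mi_shift_matrix,
}


def epoch_matrices(
    epoch: EpochRecording,
    windowing: WindowingConfig | None = None,
    correction: CorrectionConfig | None = None,
    seed: int | None = None,
):
    """Windowed corrected matrices for each configured family of one epoch.

    Surrogate ensembles are regenerated independently for every window.
    Returns ``{family: [InterrelationMatrix per window]}``.
    """
    if windowing is None:
        windowing = WindowingConfig(epoch_length=epoch.duration)
    if correction is None:
        correction = CorrectionConfig()
    windows = slide_windows(epoch, windowing)
    labels = epoch.labels
    root = np.random.SeedSequence(seed)
    window_seeds = root.spawn(len(windows))
    out = {fam: [] for fam in correction.families}
    for k, (w, wseed) in enumerate(zip(windows, window_seeds)):
        fam_seeds = wseed.spawn(len(correction.families))
        for fam, fseed in zip(correction.families, fam_seeds):
            ens = make_ensemble(
                w,
                FAMILY_FOR_KIND[fam],
                n_surrogates=correction.n_surrogates,
                max_iter=correction.max_iter,
                min_shift_fraction=correction.min_shift_fraction,
                seed=int(fseed.generate_state(1)[0] % (2**31)),
            )
            out[fam].append(_BUILDERS[fam](w, ens, correction, k, labels))
    return out
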