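"""Surrogate time-series null models.

Three null families:

* **univariate IAAFT** — per-channel iterated amplitude-adjusted Fourier
  transform surrogates (Schreiber & Schmitz style): exact amplitude
  distribution, approximate power spectrum, all cross-channel relations
  destroyed.  Null for the linear (Pearson) matrices.
* **multivariate IAAFT** — joint surrogates that additionally conserve the
  cross-spectrum (hence the zero-lag Pearson matrix) by restoring the source
  channels' relative Fourier phases up to one common random rotation per
  frequency.  Null for the nonlinear-excess (mutual information) matrices.
* **shift** — independent circular time shifts per channel: exact linear and
  nonlinear autocorrelation, destroyed cross-correlation.

Amplitude conservation of both IAAFT families is exact (the final step of
every iteration is a rank remap onto the source values); the spectrum is the
approximate side of the trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Window",
    "SurrogateEnsemble",
    "iaaft_univariate",
    "iaaft_multivariate",
    "shift_surrogate",
    "make_ensemble",
]

FAMILIES = ("univariate_iaaft", "multivariate_iaaft", "shift")


@dataclass
class Window:
    """One analysis window: channels x samples block."""

    samples: np.ndarray
    sampling_rate: float = 1.0

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, float))
        if self.samples.shape[1] < 64:
            raise ValueError("window must contain at least 64 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("window contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class SurrogateEnsemble:
    """A set of surrogate realizations of one window under one null family."""

    family: str
    realizations: list = field(default_factory=list)
    iterations_used: list = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown surrogate family {self.family!r}")

    def __len__(self) -> int:
        return len(self.realizations)

    def stacked(self) -> np.ndarray:
        """All realizations as one (n_surrogates, channels, samples) array."""
        return np.stack([w.samples for w in self.realizations])


def _check_nonconstant(X: np.ndarray, labels=None):
    const = np.where(X.std(axis=1) == 0)[0]
    if const.size:
        names = [labels[i] for i in const] if labels is not None else list(const)
        raise ValueError(f"constant channel(s): {names} (degenerate spectrum)")


# ---------------------------------------------------------------------------
# univariate IAAFT (batched over independent rows)
# ---------------------------------------------------------------------------

def _iaaft_rows(X: np.ndarray, max_iter: int, rng: np.random.Generator):
    """IAAFT on each row of X independently; returns (surrogates, iterations).

    Each iteration (i) imposes the source amplitude spectrum keeping current
    phases, (ii) rank-remaps onto the source amplitudes.  Stops when a row's
    rank order is unchanged between iterations.  Initial state: a random
    permutation of each row.
    """
    X = np.atleast_2d(np.asarray(X, float))
    R, n = X.shape
    _check_nonconstant(X)
    sorted_src = np.sort(X, axis=1)
    amp = np.abs(np.fft.rfft(X, axis=1))

    cur = rng.permuted(X, axis=1)
    prev_order = np.argsort(cur, axis=1)
    out = cur.copy()
    iters = np.full(R, max_iter, dtype=int)
    active = np.arange(R)

    for it in range(1, max_iter + 1):
        F = np.fft.rfft(cur, axis=1)
        mag = np.abs(F)
        mag[mag == 0] = 1.0
        filtered = np.fft.irfft(amp[active] * (F / mag), n=n, axis=1)
        order = np.argsort(filtered, axis=1)
        cur = np.empty_like(filtered)
        np.put_along_axis(cur, order, sorted_src[active], axis=1)

        converged = np.all(order == prev_order, axis=1)
        if np.any(converged):
            idx = active[converged]
            out[idx] = cur[converged]
            iters[idx] = it
            keep = ~converged
            active = active[keep]
            cur = cur[keep]
            order = order[keep]
            if active.size == 0:
                return out, iters
        prev_order = order

    out[active] = cur
    return out, iters


def iaaft_univariate(x: np.ndarray, max_iter: int = 100, seed: int | None = None):
    """Univariate IAAFT surrogate of a single series.

    Returns ``(surrogate, iterations_used)``.  The surrogate's sorted values
    equal the source's sorted values exactly.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    rng = np.random.default_rng(seed)
    out, iters = _iaaft_rows(np.asarray(x, float)[None, :], max_iter, rng)
    return out[0], int(iters[0])


# ---------------------------------------------------------------------------
# multivariate IAAFT (batched over realizations)
# ---------------------------------------------------------------------------

def rotate_phases(X: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Apply one common phase rotation per frequency to all channels.

    A rigid rotation of the cross-spectrum: it preserves every pairwise
    cross-correlation exactly (up to FFT round-off).
    """
    X = np.atleast_2d(np.asarray(X, float))
    n = X.shape[-1]
    F = np.fft.rfft(X, axis=-1)
    rot = np.exp(1j * alpha)
    rot[..., 0] = 1.0
    if n % 2 == 0:
        rot[..., -1] = 1.0
    return np.fft.irfft(F * rot, n=n, axis=-1)


def _iaaft_multivariate_batch(
    X: np.ndarray, n_real: int, max_iter: int, rng: np.random.Generator
):
    """``n_real`` multivariate IAAFT surrogates of X (channels x samples).

    Works on a (n_real, C, n) block.  Phase step: at each frequency the
    source channels' relative phases are restored and one common offset —
    the circular mean of the current deviations from the source phases — is
    applied, so the cross-spectrum is conserved while randomness enters only
    through a global rotation per frequency.  Amplitude step: independent
    rank remap per channel.  Returns (surrogates, iterations) with
    surrogates of shape (n_real, C, n).
    """
    X = np.atleast_2d(np.asarray(X, float))
    C, n = X.shape
    if C < 2:
        raise ValueError("multivariate IAAFT requires >= 2 channels")
    _check_nonconstant(X)
    sorted_src = np.sort(X, axis=1)  # (C, n)
    F_src = np.fft.rfft(X, axis=1)
    amp = np.abs(F_src)  # (C, nf)
    phase_src = np.exp(1j * np.angle(F_src))  # unit phasors (C, nf)
    nf = amp.shape[1]

    # initial state: common random rotation per frequency, then amplitude remap
    alpha0 = rng.uniform(0, 2 * np.pi, size=(n_real, nf))
    cur = rotate_phases(X[None, :, :], alpha0[:, None, :])
    order = np.argsort(cur, axis=2)
    tmp = np.empty_like(cur)
    np.put_along_axis(tmp, order, np.broadcast_to(sorted_src, cur.shape), axis=2)
    cur = tmp
    prev_order = order

    out = cur.copy()
    iters = np.full(n_real, max_iter, dtype=int)
    active = np.arange(n_real)

    for it in range(1, max_iter + 1):
        F = np.fft.rfft(cur, axis=2)  # (r, C, nf)
        # circular mean over channels of the deviation from source phases,
        # weighted by current amplitude (robust at near-zero bins)
        dev = np.sum(F * np.conj(phase_src), axis=1)  # (r, nf)
        mag = np.abs(dev)
        mag[mag == 0] = 1.0
        rot = dev / mag  # e^{i alpha}
        newF = amp[None, :, :] * phase_src[None, :, :] * rot[:, None, :]
        filtered = np.fft.irfft(newF, n=n, axis=2)
        order = np.argsort(filtered, axis=2)
        cur = np.empty_like(filtered)
        np.put_along_axis(cur, order, np.broadcast_to(sorted_src, cur.shape), axis=2)

        converged = np.all(order == prev_order, axis=(1, 2))
        if np.any(converged):
            idx = active[converged]
            out[idx] = cur[converged]
            iters[idx] = it
            keep = ~converged
            active, cur, order = active[keep], cur[keep], order[keep]
            if active.size == 0:
                return out, iters
        prev_order = order

    out[active] = cur
    return out, iters


def iaaft_multivariate(X: Window, max_iter: int = 100, seed: int | None = None):
    """One multivariate IAAFT surrogate window; returns (Window, iterations)."""
    rng = np.random.default_rng(seed)
    out, iters = _iaaft_multivariate_batch(X.samples, 1, max_iter, rng)
    return Window(out[0], X.sampling_rate), int(iters[0])


# ---------------------------------------------------------------------------
# shift surrogates
# ---------------------------------------------------------------------------

def _shift_batch(X, n_real, min_shift_fraction, rng):
    X = np.atleast_2d(np.asarray(X, float))
    C, n = X.shape
    if not 0 < min_shift_fraction < 0.5:
        raise ValueError("min_shift_fraction must lie in (0, 0.5)")
    m = int(np.ceil(min_shift_fraction * n))
    if m >= n - m + 1:
        raise ValueError(f"window of {n} samples too short for minimum shift {m}")
    shifts = rng.integers(m, n - m + 1, size=(n_real, C))
    rows = np.arange(n)
    out = np.empty((n_real, C, n))
    for r in range(n_real):
        idx = (rows[None, :] + shifts[r][:, None]) % n
        out[r] = np.take_along_axis(X, idx, axis=1)
    return out, shifts


def shift_surrogate(X: Window, min_shift_fraction: float = 0.05,
                    seed: int | None = None) -> Window:
    """Circularly shift each channel by an independent random offset.

    Offsets are uniform on ``[ceil(f*n), n - ceil(f*n)]`` so every channel
    moves by at least the configured fraction of the window in either
    direction.  Circular autocorrelation of each channel is untouched.
    """
    rng = np.random.default_rng(seed)
    out, _ = _shift_batch(X.samples, 1, min_shift_fraction, rng)
    return Window(out[0], X.sampling_rate)


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def make_ensemble(
    window: Window,
    family: str,
    n_surrogates: int = 99,
    max_iter: int = 100,
    min_shift_fraction: float = 0.05,
    seed: int | None = None,
) -> SurrogateEnsemble:
    """Generate ``n_surrogates`` realizations of one null family for a window."""
    rng = np.random.default_rng(seed)
    C, n = window.samples.shape
    fs = window.sampling_rate
    if family == "univariate_iaaft":
        # all channels of all realizations are independent rows: one batch
        rows = np.broadcast_to(window.samples, (n_surrogates, C, n)).reshape(-1, n)
        out, iters = _iaaft_rows(rows, max_iter, rng)
        out = out.reshape(n_surrogates, C, n)
        iters = iters.reshape(n_surrogates, C).max(axis=1)
    elif family == "multivariate_iaaft":
        out, iters = _iaaft_multivariate_batch(window.samples, n_surrogates,
                                               max_iter, rng)
    elif family == "shift":
        out, _ = _shift_batch(window.samples, n_surrogates, min_shift_fraction, rng)
        iters = np.zeros(n_surrogates, dtype=int)
    else:
        raise ValueError(f"unknown surrogate family {family!r}")
    return SurrogateEnsemble(
        family=family,
        realizations=[Window(out[r], fs) for r in range(n_surrogates)],
        iterations_used=[int(i) for i in iters],
        seed=seed,
    )
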