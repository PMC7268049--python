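"""Synthetic multichannel epochs with known linear and nonlinear structure.

The generator is a stand-in for bilateral mesiotemporal depth-electrode
recordings (4 electrodes x up to 8 contacts): colored-noise channels with a
block-structured zero-lag correlation (strong within an electrode and
decaying with contact distance, weaker within a hemisphere, weakest between
hemispheres), plus an optional nonlinear "hub" coupling that is invisible to
Pearson correlation but carries mutual information.  It provides ground
truth for the surrogate-correction pipeline; it makes no attempt at
physiological realism (see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import EpochRecording, parse_channel_label

__all__ = [
    "NonlinearHubSpec",
    "SimulationConfig",
    "default_labels",
    "make_target_correlation",
    "nearest_correlation_psd",
    "generate_epoch",
    "generate_cohort",
]

#: zero-linear-correlation transforms g(h) for symmetric drivers h.
#: each is centered/rescaled empirically before use.
HUB_TRANSFORMS = {
    "centered_square": lambda h: h**2,
    "threshold": lambda h: (np.abs(h) > 1.0).astype(float),
    "cubic_minus_linear": lambda h: h**3 - 3.0 * h,
}


@dataclass(frozen=True)
class NonlinearHubSpec:
    """A hub channel driving target channels through a nonlinear transform.

    With ``transform`` an even (or Hermite-orthogonal) function of a
    symmetrically distributed driver, the coupling contributes zero linear
    correlation between hub and target while creating strong mutual
    information — exactly the structure the nonlinear-excess correction is
    designed to recover.  ``coupling_strength`` (beta) scales the injected
    component relative to the unit-variance base signal; beta = 0 reproduces
    the purely linear model.
    """

    hub_channels: frozenset = frozenset()
    target_channels: frozenset = frozenset()
    coupling_strength: float = 1.0
    transform: str = "centered_square"

    def __post_init__(self):
        if self.hub_channels & self.target_channels:
            raise ValueError("hub and target channel sets must be disjoint")
        if self.coupling_strength < 0:
            raise ValueError("coupling_strength must be >= 0")
        if self.transform not in HUB_TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")


def default_labels(n_contacts: int = 8) -> list[str]:
    """Standard bilateral mesiotemporal montage: AmR, HiR, AmL, HiL."""
    return [
        f"{electrode}{contact:02d}"
        for electrode in ("AmR", "HiR", "AmL", "HiL")
        for contact in range(1, n_contacts + 1)
    ]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic epoch generator.

    Defaults emulate the study geometry: 32 channels in 4 electrodes x 8
    contacts, 180 s epochs.  The sampling rate (256 Hz) and the AR(2) base
    process are generator choices, not measured properties; see
    docs/methods.md.
    """

    n_channels: int = 32
    channel_labels: list[str] = field(default_factory=default_labels)
    sampling_rate: float = 256.0
    epoch_duration: float = 180.0
    ar_coefficients: tuple = (1.3, -0.4)
    within_electrode_level: float = 0.8
    within_electrode_decay: float = 0.4
    within_hemisphere_level: float = 0.2
    between_hemisphere_level: float = 0.05
    target_correlation: np.ndarray | None = None
    hub_spec: NonlinearHubSpec | None = None
    focal_side: str = "R"
    resected_labels: tuple = ("HiR01", "HiR02", "HiR03", "HiR04")
    seed: int = 0

    def __post_init__(self):
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("n_channels must equal len(channel_labels)")
        n = self.epoch_duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_duration x sampling_rate must be an integer")
        if not (0 <= self.within_electrode_level < 1
                and 0 <= self.within_hemisphere_level < 1
                and 0 <= self.between_hemisphere_level < 1):
            raise ValueError("coupling levels must lie in [0, 1)")
        if self.within_electrode_decay < 0:
            raise ValueError("within_electrode_decay must be >= 0")
        if self.focal_side not in ("L", "R"):
            raise ValueError("focal_side must be 'L' or 'R'")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_duration * self.sampling_rate))

    def channel_metadata(self) -> pd.DataFrame:
        rows = []
        resected = set(self.resected_labels)
        for lab in self.channel_labels:
            electrode, side, _ = parse_channel_label(lab)
            rows.append(
                {
                    "label": lab,
                    "electrode": f"{electrode}{side}",
                    "hemisphere": side,
                    "focal": side == self.focal_side,
                    "resected": lab in resected,
                }
            )
        meta = pd.DataFrame(rows)
        bad = meta.loc[meta["resected"] & ~meta["focal"], "label"].tolist()
        if bad:
            warnings.warn(f"resected channels outside the focal hemisphere: {bad}")
        return meta


def default_hub_spec(
    channel_labels,
    hub_label: str = "HiR01",
    target_labels: tuple = ("HiR02", "HiR03", "HiR04", "AmR01", "AmR02"),
    coupling_strength: float = 1.0,
) -> NonlinearHubSpec:
    """Star-shaped nonlinear hub on the focal hippocampus.

    The hub sits on the first contact of the focal hippocampal electrode and
    drives nearby focal-hemisphere contacts, emulating the concentration of
    nonlinear excess interrelations on later-resected tissue.
    """
    index = {lab: i for i, lab in enumerate(channel_labels)}
    return NonlinearHubSpec(
        hub_channels=frozenset({index[hub_label]}),
        target_channels=frozenset(index[t] for t in target_labels),
        coupling_strength=coupling_strength,
    )


def desk_scale_config(
    n_contacts: int = 4,
    sampling_rate: float = 128.0,
    epoch_duration: float = 40.0,
    with_hub: bool = True,
    seed: int = 0,
) -> SimulationConfig:
    """Reduced study geometry for desk-scale runs: 16 channels, short epochs.

    Same block structure and hub design as the full default, scaled down so a
    complete multi-epoch analysis runs in minutes on one CPU.
    """
    labels = default_labels(n_contacts)
    cfg = SimulationConfig(
        n_channels=len(labels),
        channel_labels=labels,
        sampling_rate=sampling_rate,
        epoch_duration=epoch_duration,
        seed=seed,
    )
    if with_hub:
        cfg.hub_spec = default_hub_spec(labels)
    return cfg


def nearest_correlation_psd(target: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD one, re-unitizing the diagonal.

    Negative eigenvalues are clipped at zero; if the projected matrix still
    fails PSD (pathological input), raise with the offending eigenvalues.
    """
    w, v = np.linalg.eigh((target + target.T) / 2.0)
    if w.min() >= -tol:
        return target
    warnings.warn(
        f"target correlation not PSD (min eigenvalue {w.min():.3g}); projecting"
    )
    w_clipped = np.clip(w, 0.0, None)
    proj = (v * w_clipped) @ v.T
    d = np.sqrt(np.diag(proj))
    if np.any(d <= 0):
        raise ValueError(
            "PSD projection produced a zero-variance channel; eigenvalues: "
            f"{np.sort(w)[:5]}"
        )
    proj = proj / np.outer(d, d)
    np.fill_diagonal(proj, 1.0)
    w2 = np.linalg.eigvalsh(proj)
    if w2.min() < -1e-8:
        raise ValueError(f"projection failed; residual eigenvalues {np.sort(w2)[:5]}")
    return proj


def make_target_correlation(config: SimulationConfig) -> np.ndarray:
    """Block-structured target correlation from the montage geometry.

    Same electrode: ``within_electrode_level * exp(-decay * (d - 1))`` for
    contact distance d; same hemisphere, different electrode:
    ``within_hemisphere_level``; opposite hemispheres:
    ``between_hemisphere_level``.
    """
    if config.target_correlation is not None:
        return nearest_correlation_psd(np.asarray(config.target_correlation, float))
    parsed = [parse_channel_label(lab) for lab in config.channel_labels]
    n = config.n_channels
    corr = np.empty((n, n))
    for i in range(n):
        ei, si, ci = parsed[i]
        for j in range(n):
            ej, sj, cj = parsed[j]
            if i == j:
                corr[i, j] = 1.0
            elif ei == ej and si == sj:
                d = abs(ci - cj)
                corr[i, j] = config.within_electrode_level * np.exp(
                    -config.within_electrode_decay * (d - 1)
                )
            elif si == sj:
                corr[i, j] = config.within_hemisphere_level
            else:
                corr[i, j] = config.between_hemisphere_level
    return nearest_correlation_psd(corr)


def _ar_spectral_radius(coeffs) -> float:
    # roots of z^p - a1 z^{p-1} - ... - ap; stable iff all inside the unit circle
    poly = np.concatenate([[1.0], -np.asarray(coeffs, float)])
    roots = np.roots(poly)
    return float(np.max(np.abs(roots))) if roots.size else 0.0


def generate_epoch(config: SimulationConfig, seed: int | None = None) -> EpochRecording:
    """Generate one synthetic epoch.

    Base process: independent AR-filtered Gaussian noise per channel,
    standardized, then mixed through the Cholesky factor of the (PSD-projected)
    target correlation.  If a hub is configured, each target channel gains
    ``beta * g(hub signal)`` with g the centered, variance-normalized
    transform.  Deterministic given the seed.
    """
    if _ar_spectral_radius(config.ar_coefficients) >= 1.0:
        raise ValueError(
            f"unstable AR coefficients {config.ar_coefficients}: spectral radius >= 1"
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_samples
    burn = 512
    noise = rng.standard_normal((config.n_channels, n + burn))
    a = np.concatenate([[1.0], -np.asarray(config.ar_coefficients, float)])
    base = sps.lfilter([1.0], a, noise, axis=1)[:, burn:]
    base -= base.mean(axis=1, keepdims=True)
    base /= base.std(axis=1, keepdims=True)

    target = make_target_correlation(config)
    # eigenvector square root: robust also for exactly singular projected targets
    w, v = np.linalg.eigh(target)
    L = v * np.sqrt(np.clip(w, 0.0, None))
    x = L @ base

    hub = config.hub_spec
    if hub is not None and hub.coupling_strength > 0 and hub.target_channels:
        g_fn = HUB_TRANSFORMS[hub.transform]
        beta = hub.coupling_strength / max(len(hub.hub_channels), 1)
        for h_idx in sorted(hub.hub_channels):
            g = g_fn(x[h_idx])
            g = g - g.mean()
            sd = g.std()
            if sd == 0:
                raise ValueError("hub transform produced a constant signal")
            g /= sd
            for t_idx in sorted(hub.target_channels):
                x[t_idx] = x[t_idx] + beta * g

    return EpochRecording(
        signals=x,
        sampling_rate=config.sampling_rate,
        metadata=config.channel_metadata(),
        provenance={
            "generator": "preictalnet.simulate",
            "seed": int(config.seed if seed is None else seed),
            "tag": "preictal-synthetic",
        },
    )


def generate_cohort(config: SimulationConfig, n_epochs: int, seed: int | None = None):
    """Independent epochs sharing one configuration (seeds spawned from one root)."""
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    out = []
    for i, child in enumerate(root.spawn(n_epochs)):
        ep_seed = int(child.generate_state(1)[0] % (2**31))
        ep = generate_epoch(replace(config, seed=ep_seed))
        ep.provenance["epoch_index"] = i
        out.append(ep)
    return out
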