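"""End-to-end analysis driver: epochs -> matrices -> metrics -> statistics.

`run_pipeline` ties the stages together for a set of recorded or simulated
epochs and writes every artifact (window matrices as HDF5, per-channel
metrics as CSV, statistics and a reproducibility summary as JSON) together
with a manifest recording versions, seeds and parameters, so any artifact
can be regenerated from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .contrasts import RegionLabels, contrast_epochs
from .interrelation import (
    CorrectionConfig,
    InterrelationMatrix,
    WindowingConfig,
    epoch_average,
    epoch_matrices,
)
from .io import EpochRecording, read_epoch, write_epoch_hdf5
from .network import matrix_metrics
from .reproducibility import laterality_match, mantel_test, pca_components
from .simulate import SimulationConfig, generate_cohort

__all__ = [
    "AnalysisConfig",
    "run_pipeline",
    "write_matrices_hdf5",
    "read_matrices_hdf5",
    "analyze_epoch",
]


@dataclass
class AnalysisConfig:
    """Everything one pipeline run depends on."""

    windowing: WindowingConfig = field(default_factory=WindowingConfig)
    correction: CorrectionConfig = field(default_factory=CorrectionConfig)
    simulation: SimulationConfig | None = None
    n_epochs: int = 2
    epoch_paths: tuple = ()
    metadata_path: str | None = None
    alpha: float = 0.01
    seed: int = 0
    mantel_permutations: int = 10_000
    out_dir: str = "results/pipeline"


def write_matrices_hdf5(matrices, path) -> None:
    """Store a list of same-kind window matrices as one HDF5 container."""
    matrices = list(matrices)
    kinds = {m.kind for m in matrices}
    if len(kinds) != 1:
        raise ValueError("matrices must share one kind")
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=np.stack([m.values for m in matrices]))
        f.create_dataset("window_index", data=[m.window_index for m in matrices])
        f.attrs["kind"] = matrices[0].kind
        labels = matrices[0].channel_labels
        if labels:
            f.create_dataset(
                "labels", data=list(labels), dtype=h5py.string_dtype("utf-8")
            )


def read_matrices_hdf5(path) -> list[InterrelationMatrix]:
    with h5py.File(path, "r") as f:
        values = f["values"][()]
        kind = f.attrs["kind"]
        widx = f["window_index"][()]
        labels = None
        if "labels" in f:
            labels = [s.decode() if isinstance(s, bytes) else s for s in f["labels"][()]]
    return [
        InterrelationMatrix(values[k], kind, int(widx[k]), labels)
        for k in range(values.shape[0])
    ]


def analyze_epoch(epoch: EpochRecording, config: AnalysisConfig, seed: int):
    """Window matrices, epoch averages and network metrics for one epoch."""
    per_window = epoch_matrices(
        epoch, config.windowing, config.correction, seed=seed
    )
    averages = {fam: epoch_average(mats) for fam, mats in per_window.items()}
    metrics = {fam: matrix_metrics(avg) for fam, avg in averages.items()}
    window_assort = {}
    for fam, mats in per_window.items():
        vals = []
        for m in mats:
            try:
                vals.append(matrix_metrics(m).assortativity)
            except ValueError:
                vals.append(float("nan"))
        window_assort[fam] = np.asarray(vals)
    return {
        "per_window": per_window,
        "averages": averages,
        "metrics": metrics,
        "window_assortativity": window_assort,
    }


def _metrics_table(epoch, result) -> pd.DataFrame:
    rows = []
    for fam, met in result["metrics"].items():
        for i, lab in enumerate(epoch.labels):
            rows.append(
                {
                    "family": fam,
                    "channel": lab,
                    "node_strength": met.node_strength[i],
                    "core": i in met.core_set,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full analysis; returns the report bundle and writes artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_root = np.random.SeedSequence(config.seed)

    if config.epoch_paths:
        epochs = [read_epoch(p, config.metadata_path) for p in config.epoch_paths]
    elif config.simulation is not None:
        epochs = generate_cohort(config.simulation, config.n_epochs, seed=config.seed)
        for i, ep in enumerate(epochs):
            write_epoch_hdf5(ep, out / f"epoch_{i:02d}.h5")
    else:
        raise ValueError("config provides neither epoch paths nor a simulation")

    epoch_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in rng_root.spawn(len(epochs))
    ]
    results = []
    for i, (ep, es) in enumerate(zip(epochs, epoch_seeds)):
        res = analyze_epoch(ep, config, seed=es)
        for fam, mats in res["per_window"].items():
            write_matrices_hdf5(mats, out / f"epoch_{i:02d}_{fam}.h5")
            avg = res["averages"][fam]
            pd.DataFrame(
                avg.values, index=ep.labels, columns=ep.labels
            ).to_csv(out / f"epoch_{i:02d}_{fam}_average.csv")
        _metrics_table(ep, res).to_csv(out / f"epoch_{i:02d}_metrics.csv", index=False)
        results.append(res)

    families = list(config.correction.families)
    labels_per_epoch = [RegionLabels.from_metadata(ep.metadata) for ep in epochs]
    statistics = {}
    for fam in families:
        averages = [r["averages"][fam] for r in results]
        fam_stats = {}
        for scheme in ("hemisphere", "resection"):
            if scheme == "resection" and not any(
                l.resected.any() for l in labels_per_epoch
            ):
                continue
            c = contrast_epochs(averages, labels_per_epoch, scheme, config.alpha)
            fam_stats[scheme] = {
                "groups": list(c.group_names),
                "factors": c.factors.tolist(),
                "omnibus": c.omnibus,
                "pairwise": {f"{a}|{b}": v for (a, b), v in c.pairwise.items()},
                "sign_tests": c.sign_tests,
                "corrected_alpha": c.corrected_alpha,
            }
        statistics[fam] = fam_stats

    reproducibility = {}
    mantel_seed = int(rng_root.spawn(1)[0].generate_state(1)[0] % (2**31))
    if len(epochs) >= 2:
        for fam in families:
            matched = [
                laterality_match(r["averages"][fam], ep.metadata)[0]
                for r, ep in zip(results, epochs)
            ]
            try:
                pca = pca_components(matched)
                reproducibility[fam] = {
                    "explained_variance": pca.explained_variance[:3].tolist(),
                    "collectivity": pca.collectivity.tolist(),
                    "symmetry": pca.symmetry.tolist(),
                }
            except ValueError as exc:
                reproducibility[fam] = {"error": str(exc)}
    if len(families) >= 2:
        pairs = []
        for i, r in enumerate(results):
            a, b = families[0], families[1]
            try:
                r_m, p_m = mantel_test(
                    r["averages"][a], r["averages"][b],
                    n_perm=config.mantel_permutations, seed=mantel_seed + i,
                )
                pairs.append({"epoch": i, "r": r_m, "p": p_m})
            except ValueError as exc:
                pairs.append({"epoch": i, "error": str(exc)})
        reproducibility[f"mantel_{families[0]}_vs_{families[1]}"] = pairs

    manifest = {
        "package": "preictalnet",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "epoch_seeds": epoch_seeds,
        "n_epochs": len(epochs),
        "n_windows_per_epoch": [
            len(next(iter(r["per_window"].values()))) for r in results
        ],
        "windowing": dataclasses.asdict(config.windowing),
        "correction": dataclasses.asdict(config.correction),
        "families": families,
        "alpha": config.alpha,
        "surrogate_iterations": {
            fam: "regenerated per window" for fam in families
        },
    }
    report = {
        "manifest": manifest,
        "statistics": statistics,
        "reproducibility": reproducibility,
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    with open(out / "report.json", "w") as f:
        json.dump(report, f, indent=2, default=float)
    return report
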