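# preictalnet

Surrogate-corrected linear and nonlinear-excess interrelation networks from
preictal multichannel intracranial EEG (iEEG).

## The problem

Before a focal epileptic seizure, how is the brain's functional network
organized, and does the tissue that surgeons later resect stand out in it?
One productive way to ask this quantitatively: compute channel-by-channel
interrelation matrices in sliding windows over the preictal epoch, keep only
the elements that beat a surrogate-data null, and characterize the resulting
networks with graph measures.  `preictalnet` implements that pipeline for
anyone working with multichannel electrophysiology who needs
surrogate-calibrated connectivity:

* **Linear networks** — Pearson zero-lag cross-correlation `C_ij`, tested
  against univariate IAAFT surrogates (same amplitude distribution and power
  spectrum per channel, no cross-channel relations).  Significant elements
  are rescaled to `sign(C_ij)·(|C_ij| − q_ij)/(1 − q_ij) ∈ [−1, 1]`, with
  `q_ij` the (1 − α) null quantile.
* **Nonlinear-excess networks** — mutual information `MI_ij` (plug-in,
  equiquantal B×B bins, in bits), tested against *multivariate* IAAFT
  surrogates that conserve the Pearson matrix, so only interaction beyond
  the linear part survives: `(MI_ij − q_ij)/(log₂B − q_ij) ∈ [0, 1]`.
* **Shift-corrected MI** — the same MI against circular-shift surrogates
  (autocorrelation kept, cross-correlation destroyed); a control family
  that responds to linear and nonlinear coupling alike.

Downstream, the package computes node strength (mean |M_ij| per channel),
degree assortativity (Pearson correlation of endpoint degrees over edges:
negative for star-like hubs, positive for uniformly integrated networks),
data-driven core/periphery splits from the largest gap in sorted node
strengths, uniform-expectation normalized shares (factor > 1 ⇒ a channel
group carries more interrelation than its size predicts), nonparametric
region contrasts (Kruskal–Wallis, Mann–Whitney U, sign tests, Bonferroni),
laterality-matched uncentered PCA across epochs (explained variance,
collectivity, symmetry), and Mantel permutation tests between matrices.

Patient iEEG of this kind is not shareable, so the package ships a
synthetic generator producing ground-truthed epochs: AR(2) colored noise
with block-structured linear coupling (strong within an electrode, decaying
with contact distance, weak across hemispheres) plus a nonlinear hub —
target channels gain `β·g(hub)` with `g` a centered square, which is
invisible to Pearson correlation but carries mutual information.  See
`docs/methods.md` for every modeling choice and its rationale.

## Worked example

```python
import numpy as np
from preictalnet import (desk_scale_config, generate_epoch, epoch_matrices,
                         WindowingConfig, CorrectionConfig, epoch_average,
                         matrix_metrics, node_strength, normalized_share)

cfg = desk_scale_config(seed=0)          # 16 ch, 40 s @ 128 Hz, hub on HiR01
epoch = generate_epoch(cfg)
mats = epoch_matrices(
    epoch,
    WindowingConfig(window_length=4, step=4, epoch_length=40),
    CorrectionConfig(n_surrogates=99, pointwise_alpha=0.01,
                     families=("linear", "nonlinear_excess"), max_iter=20),
    seed=1,
)
non = epoch_average(mats["nonlinear_excess"])
met = matrix_metrics(non)
resected = np.where(epoch.metadata["resected"])[0]
print(met.assortativity, [epoch.labels[i] for i in sorted(met.core_set)],
      normalized_share(node_strength(non), resected))
```

On the synthetic cohort (`python analysis/01_simulate_cohort.py` …
`05_reproducibility.py`) this prints, per family across 10 hub epochs:

```
linear:           mean assortativity +0.164, core = hub in 0% of epochs,   median resected factor 1.27
mi_shift:         mean assortativity +0.211, core = hub in 0% of epochs,   median resected factor 1.65
nonlinear_excess: mean assortativity -0.674, core = hub in 100% of epochs, median resected factor 3.19
```

i.e. the linear networks are mildly assortative with no core–periphery
structure, while the nonlinear-excess networks are strongly disassortative
star networks whose single automatically detected core node is the planted
hub, and the "resected" channel group carries ≈ 3× the node strength a
uniform distribution would give it.  The region contrasts and the
reproducibility stage print, for the same cohort:

```
nonlinear_excess_hemisphere: median factors {'within_focal': 4.24, 'within_nonfocal': 0.03, 'between': 0.01}
nonlinear_excess_resection:  median factors {'within_resected': 3.02, 'within_nonresected': 0.16, 'bridging': 0.57}
PCA linear:            EV1=1.00, collectivity=1.00, symmetry=0.76
PCA nonlinear_excess:  EV1=1.00, collectivity=1.00, symmetry=-0.04
Mantel shift-vs-linear max p = 0.0001; nonlinear-vs-linear median p = 0.421
```

The share bookkeeping itself is exercised on published channel counts by
`python analysis/06_worked_arithmetic.py`:

```
patient 1 (48 ch, 7 resected):
  expected share 14.6%  nonlinear factor 1.7  linear factor 0.6
  hippocampal contacts only: expected 8.3%, factor 2.0
Bonferroni: alpha/18 = 5.5e-04, alpha/6 = 0.0017
```

## Command line

`preictalnet simulate | connectivity | metrics | contrast | reproducibility |
run-all` wrap the same library calls; epochs travel as HDF5 (`/signals`,
`/fs`, per-channel metadata) or EDF.

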