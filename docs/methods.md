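# Methods

`preictalnet` implements a surrogate-based functional-connectivity analysis
for multichannel intracranial EEG epochs, together with a synthetic signal
generator that provides ground-truthed inputs.  This note describes the
models, the parameters that matter, the numerical choices, and what the
synthetic validation does and does not establish.

## Interrelation matrices

Signals are analyzed in sliding windows (default 8 s, stepped by 1 s over a
180 s epoch, i.e. 173 windows; the epoch is cut half-open and left-aligned).
Per window, three symmetric channel-by-channel matrices are available:

**Linear.**  The zero-lag Pearson matrix `C` is compared element-wise against
univariate IAAFT surrogates — random series sharing each channel's amplitude
distribution exactly and its power spectrum approximately, with all
cross-channel relations destroyed.  With `q_ij` the empirical (1 − α)
quantile of |C_ij| over N surrogates, the corrected element is

    sign(C_ij) · (|C_ij| − q_ij) / (1 − q_ij)   if |C_ij| > q_ij, else 0,

which lies in [−1, 1] and is zero unless the observed correlation exceeds
what uncorrelated signals of identical spectra can produce.

**Nonlinear excess.**  Mutual information (MI) per pair, compared against
multivariate IAAFT surrogates whose null *conserves* the Pearson matrix: at
each frequency the source channels' relative Fourier phases are restored up
to one common random rotation, so the cross-spectrum — and with it the
zero-lag correlation — survives while everything not captured by second
moments is destroyed.  Surviving MI is mapped onto
`(MI − q) / (log2 B − q) ∈ [0, 1]`.  Because the null absorbs the linear
part, only interaction *beyond* linear survives.

**Shift-corrected MI.**  The same MI statistic against circular-shift
surrogates, which keep each channel's full (linear and nonlinear)
autocorrelation but destroy cross-channel alignment.  This family responds
to linear and nonlinear interaction alike; on linearly coupled data it
reproduces the linear matrices (verified by Mantel tests), which is why the
multivariate-IAAFT family is the informative nonlinear readout.

### Significance rule and scaling

The correction is a one-sided rank test at pointwise α (default 0.01) with
N = 99 surrogates per family, regenerated independently per window.  The
quantile is the order statistic `ceil((1 − α)(N + 1))`, i.e. the surrogate
maximum at the defaults, giving an exact 1/(N + 1) exceedance probability
under exchangeability; `(N + 1)·α ≥ 1` is enforced.  The residual-range
rescaling formulas above are chosen to satisfy the published ranges
([−1, 1] linear, [0, 1] nonlinear); the original methodology's exact
rescaling is not restated in the literature we follow, so these forms are a
declared convention of this package.

### Mutual information estimator

Plug-in MI in bits from a B × B equiquantal contingency table: marginal
bins are rank-based (ties split in order of appearance, no jitter), hence
near-uniform by construction.  Default B = round(√(n/5)) capped at 16
(≈ 5 samples per cell); we require n ≥ 4 B².  The plug-in estimator's
O((B−1)²/(2n ln 2)) positive bias cancels in the surrogate comparison
because observed and null estimates share n and B; the first-order bias
formula is verified directly in the tests.

### IAAFT iterations

Each IAAFT iteration imposes the source amplitude spectrum keeping current
phases, then rank-remaps onto the source amplitudes, so the amplitude
distribution is exact and the spectrum approximate; iteration stops when the
rank order is unchanged or after `max_iter` (default 100).  Univariate
surrogates of AR(2) signals typically converge in ~40 iterations.  The
multivariate variant rarely reaches exact rank-order fixation, but its
defining conservation property saturates quickly: the maximum Pearson
deviation from the source is ≈ 3·10⁻³ after 5 iterations and ≈ 10⁻⁴ after
20.  The analysis drivers therefore cap the multivariate iteration at 20;
the cap is configurable.

Shift surrogates draw per-channel offsets uniformly from
[⌈f·n⌉, n − ⌈f·n⌉] with f = 0.05, avoiding near-identity shifts.

## Graph measures

*Node strength* NS_i is the mean |M_ij| over j ≠ i.  *Degree assortativity*
is the Pearson correlation of endpoint degrees over the directed edge list
of the binarized (nonzero-after-correction) matrix; it is −1 for a star,
+1 for disjoint regular cliques, and undefined (flagged) when all endpoint
degrees coincide.  Binary degrees are the default because the surrogate
correction already sparsifies the matrix and makes sign claims
transform-invariant; a weighted variant is available.  *Core nodes* are
found by sorting node strengths and locating the largest adjacent gap on
the linear and the logarithmic scale (zeros always peripheral); a scale is
accepted only if its largest gap exceeds 2× that scale's median gap, the
more prominent scale wins, and if neither qualifies the core set is empty —
the expected outcome for linear networks, which carry no core–periphery
structure.

*Normalized shares*: the node-strength share of a channel subset divided by
its channel-count share; 1 under a uniform distribution of interrelation
strength.  Factors over a partition, weighted by expected shares, average
to exactly 1.  Percentages are rendered by rounding half away from zero to
one decimal.

## Region contrasts

Channel pairs are grouped by hemisphere (within-focal / within-nonfocal /
between) or by resection (within-resected / within nonresected ipsilateral
tissue / bridging).  Per epoch, group means of |M_ij| are divided by the
grand mean over all grouped pairs, so the pair-count-weighted factor mean
is 1.  The epoch is the statistical unit.  Inference: Kruskal–Wallis
omnibus, Mann–Whitney U post hoc, exact binomial sign tests against factor
1, all two-sided at α = 0.01 with Bonferroni correction over the declared
comparison count.  Mann–Whitney uses exact enumeration up to group size 8
(without straddling ties) and the tie-corrected normal approximation above;
Kruskal–Wallis uses the chi-square approximation throughout, adequate at
the cohort sizes (≥ 18 epochs) this battery targets.  Corrected thresholds
are rendered at two significant figures by truncation for reporting;
comparisons always use full precision.

## Reproducibility analysis

Matrices are *laterality matched* into a fixed slot order (amygdala then
hippocampus of the focal hemisphere, then the nonfocal mirror, up to 8
contacts each); missing contacts are masked and excluded pairwise.  The
cross-epoch PCA is **uncentered** (no mean-pattern subtraction) on the
vectorized upper triangles restricted to elements observed in every epoch,
so the dominant component *is* the common pattern.  Explained variance
fractions are squared singular values; *collectivity* of a component is
|Σ scores| / Σ|scores| (1 iff every epoch contributes with one sign);
*symmetry* is the Pearson correlation between a component pattern and its
hemisphere-swapped counterpart.  These operational formulas stand in for
definitions in prior literature that the source methodology does not
restate; centering and the exact collectivity formula were genuinely open
choices, decided as above.

Matrix similarity uses a one-sided Mantel test: Pearson r over
upper-triangle elements, null from random joint row/column permutations,
p = (1 + #{r_perm ≥ r}) / (1 + n_perm), default n_perm = 10,000 (the
desk-scale experiments use 999, resolving p ≥ 10⁻³).

## Synthetic generator

Real preictal iEEG is not distributable, so validation runs on a generator
that emulates the *statistical structure the analysis assumes*, not the
physiology: no seizure dynamics, no artifacts, no nonstationarity.  All
generator choices are stand-ins and labeled as such.

* **Geometry**: 32 channels, 4 electrodes (AmR/HiR/AmL/HiL) × 8 contacts,
  180 s epochs.  The sampling rate is set to 256 Hz — a generator choice
  keeping an 8 s window at 2048 samples; the montage's native rate is not a
  modeled quantity.
* **Base process**: per-channel AR(2) with coefficients (1.3, −0.4)
  (spectral radius 0.8), giving a 1/f-like autocorrelated background so the
  IAAFT correction is exercised on colored, non-white signals.  Stability
  (spectral radius < 1) is enforced.
* **Linear structure**: a block target correlation — within an electrode
  0.8·exp(−0.4·(d−1)) for contact distance d, 0.2 across electrodes within
  a hemisphere, 0.05 between hemispheres — mixed via an eigenvalue square
  root after projection to the nearest PSD correlation (negative
  eigenvalues clipped, diagonal renormalized; the default construction is
  PSD without projection).  With no hub the population correlation equals
  the target exactly.
* **Nonlinear hub**: designated target channels gain β·g(h) where h is the
  hub channel's signal and g its centered, variance-normalized square
  (alternatives: symmetric threshold, Hermite cubic).  For symmetric
  drivers cov(h, g(h)) = 0, so the coupling is invisible to Pearson but
  carries mutual information — exactly the "nonlinear excess" the pipeline
  must recover.  Default: hub HiR01 driving HiR02–04 and AmR01–02 at β = 1,
  placing the star on the later-"resected" focal hippocampus.  Targets
  share the hub's injected component, so weak target–target dependence
  beyond their conserved correlation exists; at the default β and target
  layout it stays below the correction threshold and the recovered network
  is a star (verified in the recovery experiment).
* **Labels**: hemisphere from the channel name, focal side configurable
  (default R), resected = HiR01–04 (25% of channels, matching the reported
  mean resection fraction of ~22%).

### Desk-scale problem sizes

The validation experiments run a reduced geometry chosen as the package's
standard desk-scale configuration: 16 channels (4 contacts per electrode),
40 s epochs at 128 Hz, 4 s windows stepped by 4 s (10 windows per epoch),
N = 99 surrogates at α = 0.01.  Calibration uses 20 independent white-noise
channels × 50 windows (9,500 pointwise tests per family); recovery uses 10
hub epochs; the linearity comparison 6 hub-free epochs.  A full-scale run
(32 channels, 173 windows, three families) is a matter of hours, not of
method.

### What passing tests show — and what they do not

The synthetic suite establishes internal validity: exact conservation laws
of the surrogate families, pointwise false-positive rates at the nominal α,
recovery of planted block-linear and star-nonlinear structure, and the
redundancy of shift-corrected MI with the linear matrices on linear data.
It cannot establish that real preictal iEEG carries hub-like nonlinear
excess concentrated on epileptogenic tissue — that is an empirical claim
about patients, not about the estimator — nor that the AR(2)/static-hub
model spans the nonstationarities, artifacts and volume-conduction effects
of clinical recordings.

## Degenerate inputs and tie-breaks

Constant channels are rejected by every surrogate family (named in the
error).  A null quantile at the range ceiling (q = 1 for correlation,
q = log2 B for MI) zeroes the element with a warning.  Assortativity of an
edgeless matrix is an error; equal-degree graphs return an undefined flag
rather than a value.  Core detection requires ≥ 3 channels.  Equiquantal
ties are split deterministically in order of appearance.  All randomness
flows from explicit seeds (NumPy `SeedSequence` spawning); reruns are
byte-identical.

## Known limitations

* The multivariate IAAFT null conserves the *full cross-spectrum*, which is
  stricter than conserving the zero-lag Pearson matrix alone; excess MI is
  therefore measured against a conservative linear null.
* Windows are processed independently; overlapping windows share data, so
  window-level quantities are not independent draws (the pipeline only ever
  averages them per epoch before inference, as intended).
* The equiquantal MI estimator is insensitive to any strictly monotone
  per-channel transform — a feature for robustness, but it discards
  amplitude information by design.
* EDF support is read-oriented (via MNE); the built-in writer emits minimal
  plain EDF (16-bit, 1 s records) sufficient for round-tripping synthetic
  epochs, not annotated clinical EDF+.
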