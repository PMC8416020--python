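# Methods

This note documents the models, defaults and numerical choices behind
aquaprobe, and what the synthetic generators do and do not emulate.

## Spectral deconvolution and the hydration parameter

**Model.** A hydroxycoumarin probe excited at 320 nm populates its neutral
excited state; excited-state proton transfer in a wet microenvironment
shifts emission weight to the anionic and tautomer species.  The
normalized emission spectrum over the 340–600 nm window is modelled as a
sum of exactly three peak functions plus an optional constant baseline.
Three bands (not a configurable count) keep the hydration parameter
well-defined: H is the fractional band area of the anionic plus tautomer
species, so H ∈ [0, 1] by construction and is comparable across spectra of
different absolute intensity.  A raw-area variant would not be, which is
why fractional areas are the default reading of "summed contribution".

**Peak function.** Gaussian in wavelength with peak-height amplitude
(`amplitude` is the band's intensity at its center), width = Gaussian
sigma in nm.  Coumarin emission bands are also commonly fitted with
lognormal shapes; `shape="lognormal"` switches all bands to
A·exp(−ln²(λ/c)/2σ²) with σ = w/c, keeping the peak-height convention.
Band areas are analytic in both families (Gaussian: A·w·√(2π); lognormal:
A·c·σ·√(2π)·e^{σ²/2}), so fractional areas carry no quadrature error.

**Fitting.** Bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective) on the spectrum
normalized to unit peak.  Default initial centers 380/450/510 nm and
widths 30 nm span the recorded window; they are starting values only.
Center boxes ([window start, 420], [420, 480], [480, window end]) enforce
the ordering neutral < anionic < tautomer and prevent label swapping —
the one identifiability hazard of a three-Gaussian mixture.  Widths are
bounded to [5, 120] nm, amplitudes to [0, 2·peak].  Ten multi-starts
(start 1 at the defaults, the rest jittered by 10% of each box, seeded)
guard against local minima; the best-cost solution wins, with an early
exit once a start reaches machine-precision cost (noiseless data).
Convergence tolerances are 1e-10 on cost, step and gradient.  The baseline
is fixed at 0 for normalized spectra by default; `fit_baseline=True` adds
a constant offset.  R² = 1 − SS_res/SS_tot on the un-normalized data.
Degenerate inputs (all-zero spectrum, non-convergence across all starts)
raise instead of returning garbage.

**Replicates and statistics.** H is estimated per replicate spectrum —
never on pooled spectra — and summarised as mean ± SD (three replicates is
the conventional design).  Conditions are compared by one-way ANOVA plus
Dunnett's many-to-one test against a reference condition (apo by
convention), reporting multiplicity-adjusted p-values
(`scipy.stats.dunnett`).  The Dunnett family is the set of
condition-vs-reference contrasts; its family-wise error under a simulated
global null is verified to sit at the nominal α in the test suite.

## Occupancy grids and probe hydration

**Semantics.** Space is discretised into cubic voxels of 1.0 Å (default)
covering the padded (3.0 Å) bounding box of the selected atoms over all
frames, or explicit bounds when two states must share geometry for
differencing.  A voxel is occupied in a frame iff at least one selected
atom *center* lies in its half-open cube [o + i·Δ, o + (i+1)·Δ); its value
is occupied-frame count / n_frames.  Center counting (rather than
van-der-Waals smearing) makes the computation exactly reproducible by
exhaustive counting, which the tests exploit: grids are compared to a
brute-force per-voxel oracle for equality, not approximate agreement.
All values are exact multiples of 1/n_frames; iso-volume at threshold p
(0.3 by convention for hydration surfaces) is non-increasing in p.

**Reference frame.** Frames are rigid-body superposed (Kabsch, proper
rotation enforced) on the receptor Cα atoms onto frame 1 before gridding,
so maps live in the receptor frame.  Trajectories are assumed pre-imaged
(solute whole, waters wrapped); **no minimum-image correction is applied**
in grids or distances — feed imaged trajectories.

**Water selection.** Atoms named OW/OH2 in residues HOH/TIP3/SOL/WAT;
any predicate can replace it.

**Probe hydration.** Per frame, waters within 3.5 Å (first hydration
shell) of any side-chain heavy atom of the probe residue are counted,
falling back to Cα for side-chain-less residues.  `contact_fraction` is
the fraction of frames with ≥ 1 such water.  Between two states, delta =
fraction(active) − fraction(inactive) is called an increase/decrease when
|delta| ≥ 0.1; the threshold is a package choice (direction, not
magnitude, is the scientifically interpreted quantity) and is exposed as a
parameter.  Contact fractions are non-decreasing in the cutoff.

**I/O.** Grids are read/written as OpenDX scalar fields through
GridDataFormats; the DX format carries no frame count, so a re-read grid
defaults to n_frames = 1 (probabilities preserved, occupancy multiples
not recoverable).  A completeness pre-check rejects truncated data
sections before parsing.

## Curated ensemble PCA

**Curation.** Given per-structure Cα coordinates mapped to alignment
columns (gaps and absent rows = missing), two rules are applied in a
single pass over the initial set: (1) delete every structure that is the
sole one missing some column — those columns are kept; (2) delete every
column missing in ≥ 2 structures of the initial set.  The result is
provably fully observed.  Single-pass evaluation (both rules counted on
the initial set, no iteration) reproduces the reference arithmetic in
which columns with exactly one offender survive via structure deletion;
an `iterate=True` flag repeats the pass to a fixed point for users who
want the stricter variant.  Curation is verified against a brute-force
restatement of the rules on randomized missing patterns.

**Superposition.** Iterative mean fitting over all retained columns: each
structure is Kabsch-superposed onto the running mean, the mean is
recomputed, and the loop stops when the mean shifts < 1e-6 Å (max 100
iterations).  No invariant-core detection is attempted — simpler, fully
testable, and adequate for ensembles that share most of their fold.

**PCA.** Covariance PCA (ddof = 1) of the flattened superposed
coordinates via SVD of the centered matrix: eigenvalues descending,
eigenvectors orthonormal, explained fractions summing to 1 over the full
rank (trace identity holds to 1e-9).  Coordinates enter in raw Å
(covariance, not correlation — standard for Cα ensembles where all
variables share units).  Sign convention: the largest-magnitude loading
of each component is made positive, so projections are reproducible
across runs and platforms.  All-identical rows are a rank-0 input and
raise.  Projection of external conformers optionally superposes each
conformer onto the model mean first; the ensemble mean projects to the
origin, and full-rank reconstruction round-trips to 1e-8.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (parameters, seed) using
`numpy.random.default_rng`; identical seeds give identical outputs.

* **Spectra** — band model at known fractional areas plus additive
  Gaussian noise (SD as a fraction of peak intensity, default conditions
  for recovery studies: truth H = 0.60, noise 1%).  Real spectra add
  instrument response, baseline drift and correlated noise; passing
  recovery tests bounds estimator error under the assumed noise model
  only.
* **Two-state trajectories** — a rigid idealized helical scaffold with
  CB-bearing probe residues; each probe site owns one water placed in a
  2.5 Å sphere around the site anchor with a per-state Bernoulli
  probability per frame, otherwise in bulk; bulk waters are
  rejection-sampled outside 6 Å exclusion spheres so they cannot
  contaminate site statistics.  The default site pattern encodes the
  two-state hydration contrast (site "5.58": 0.1 → 0.9 presence on
  activation; site "6.44": 0.9 → 0.1; a 0.5/0.5 control).  The study
  condition for direction-call tests is 400 frames per state: a contact
  fraction then has standard error ≤ 0.025, making the ±0.1 call
  threshold a ≥ 3σ decision at the control site (chosen by this power
  analysis, before any test was run).  No claim of structural realism —
  water kinetics, exchange and correlation are absent; only the
  site-wise presence statistics matter for validating the analysis code.
* **Structure ensembles** — a helical base chain; the active-like
  cluster rigidly displaces the terminal third of the chain by the hinge
  magnitude (default 10 Å, mimicking outward TM-helix spreading);
  isotropic Gaussian coordinate noise (default 0.5 Å); missing flags
  injected at stated (structure, column) pairs.  Note that rigid
  superposition absorbs part of a terminal-segment displacement into the
  fitted frame: with 10 Å hinge and 0.5 Å noise PC1 separates the
  clusters perfectly but carries ~75% of the variance; its share exceeds
  90% once the hinge dwarfs the noise by ≳ 40× per coordinate.
* **Replicate H tables** — truth H plus Gaussian noise clipped to
  [0, 1], default three replicates.

## Problem sizes and defaults used in the verification suite

Recovery and calibration runs use 100 seeded spectra (261-point grid),
200 randomized grid/curation instances, 100 trajectory seed pairs at 400
frames per state with 10 bulk waters, 30-structure/40-column ensembles,
and 2000 null repetitions (4 groups, n = 3) for the Dunnett family-wise
error; these sizes give binomial/CLT margins comfortably tighter than the
asserted bounds.  The full suite and the acceptance script each run in
about a minute on one core.

## Known limitations

* No instrument/baseline correction, quantum-yield or lifetime analysis;
  H is a relative hydration index, not an absolute water count.
* Occupancy maps ignore periodic images and atom radii; anisotropic
  voxels are not supported.
* Curation assumes a trusted alignment; computing the alignment and
  cleaning the structures (removing partners, extra chains) are upstream
  responsibilities.
* `scipy.stats.dunnett` evaluates the multivariate-t integral
  numerically; adjusted p-values carry ~1e-4 integration noise (seeded
  here for determinism).
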