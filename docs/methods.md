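# Methods

`fretkin` analyses camera-based single-molecule FRET (smFRET) trajectories
of a reversible bimolecular nucleic-acid contact — the binding and release
of a short exon-mimic strand by a hairpin carrying the complementary
binding site — and the structural side of the same question, the sugar
pseudorotation dynamics at the binding interface. This note records the
models, the defaults and why they were chosen, the numerical choices, and
what the synthetic-data generator does and does not emulate.

## Kinetic model

Binding is modelled as a continuous-time Markov chain over a small set of
kinetic states. Two schemes are built in:

* **Two-state**: `0` (unbound, zero FRET) ⇌ `1` (bound, high FRET ≈ 0.75),
  with pseudo-first-order association rate k′_on = k₀₁ and dissociation
  rate k_off = k₁₀. This describes contact formation under purely
  monovalent salt.
* **Sequential three-state with a degenerate bound level**:
  `0 ⇌ 1 ⇌ 2`, with `0 ⇌ 2` forbidden. States 1 and 2 share one FRET
  emission level: state 2 represents the bound contact additionally locked
  by site-bound divalent ions, a change invisible to the dye pair but
  visible in the exit kinetics (multi-exponential bound-state dwell
  decays — "kinetic heterogeneity"). The rate matrix is

      K = [ -k01            k01              0    ]
          [  k10           -(k10 + k12)      k12  ]
          [  0              k21             -k21  ]

  The (3,2) entry carries the back-exchange rate k₂₁ (distinct from k₁₂),
  so that the generator has proper reversible structure; a transcription
  that reuses k₁₂ in that position is a known variant and is deliberately
  not followed.

Degenerate states make the likelihood invariant under relabelling within
a fully connected bound pair; the sequential topology canonicalizes the
labels (state 1 is the bound state with a direct path to unbound).

## Synthetic-data generator

The generator replaces the microscope and defines the study conditions
used throughout the tests and the acceptance script:

1. **State paths** are sampled exactly (Gillespie): dwell in state *i* is
   Exponential(−K_ii), the successor is drawn proportionally to k_ij.
   Paths are continuous-time first and only then binned — transitions are
   not per-frame Bernoulli events.
2. **Camera binning** integrates the emission level over frames of width
   dt (occupancy-weighted average), so a transition mid-frame produces an
   intermediate FRET value, as a real camera does. The dominant state per
   frame is kept as ground truth for benchmarking discretizers.
3. **Emission**: ideal intensities I_A = E·I_tot, I_D = (1−E)·I_tot with
   an anti-correlated Gaussian perturbation of the two channels, so the
   recomputed apparent FRET has exactly the requested standard deviation
   σ_FRET. Background counts, donor→acceptor bleedthrough and an optional
   exponential photobleaching time are then applied; the corrections in
   `trace_processing` are their exact algebraic inverse at zero noise
   (tested to machine precision).

Default study conditions: frame rate 5 Hz (dt = 0.2 s), observation
window 400 s, high-FRET level 0.75, zero-FRET level 0.0, σ_FRET = 0.10,
ligand concentrations 35 nM (RNA exon) / 50 nM (DNA exon). The noise
level and emission intensities are package defaults chosen to look like
typical EMCCD smFRET data; they are not measured values.

Not emulated: photon-counting (Poisson) statistics, dye blinking and
other photophysics, spot-detection and colocalization errors, baseline
drift. Passing recovery tests therefore demonstrates correctness of the
estimators under idealized Gaussian noise, not robustness to every
real-world artefact.

Reproducibility: one master seed; per-trace generators derived via
`numpy.random.SeedSequence(seed).spawn(n)`. Identical (model, emission,
seed) gives byte-identical ensembles.

## Trace processing and dwell analysis

FRET is the proximity ratio E = I_A/(I_A+I_D) on corrected intensities
(no γ correction). Corrections: background subtraction per channel, then
bleedthrough removal using the background-corrected donor
(I_A − bg_A − α·(I_D − bg_D)).

Molecules are classified by transition count of the thresholded trace:
static zero / static high / one transition / dynamic (≥ 2 transitions);
only dynamic molecules enter kinetic analyses.

Discretization uses a threshold criterion (default 0.375, the midpoint of
the two emission levels; configurable, with an optional minimum-dwell
filter). First and last dwells of every trace are truncated by the
observation window and are excluded from fits by default (a toggle exists
for sensitivity analysis). Dwells shorter than two frames are treated as
unobservable; survival fits condition on t ≥ 2·dt.

Per-trace statistics: mean dwell times ⟨t_zero⟩, ⟨t_high⟩, within-trace
ranges Δt, and the per-molecule dissociation constant
K_d,n = c·⟨t_zero⟩/⟨t_high⟩. The cumulative K_d,n distribution is fitted
with the normalized logistic function P(K_d,n) = 1/(1 + (K_d/K_d,n)^p);
the transition point K_d (P = 1/2) summarizes contact stability. The
(⟨t_zero⟩, ⟨t_high⟩) cloud is summarized by k-means centers (k = 1 by
default — the single-cluster center).

Survival (complementary cumulative dwell-time) curves are fitted with a
biexponential S(t) = w·e^(−k₁t) + (1−w)·e^(−k₂t) (k₁ ≥ k₂ by convention)
or a stretched exponential S(t) = exp(−(t/τ)^β), β ∈ (0,1]. **Objective:**
the default is maximum likelihood on the dwell sample with left
truncation at the t ≥ 2·dt cut. Least squares on the empirical survival
curve with uniform weights is available (`objective="ls"`) but is not the
default: in direct comparison it shows a systematic ≈ −30% bias on the
slow rate of a 96:4 mixture at n = 2000 (the long-time tail, carried by a
handful of dwells, dominates the uniform-weight residual), while the MLE
recovers both rates within sampling error. A biexponential fit whose
improvement over the single-exponential MLE fails a likelihood-ratio test
(2ΔlogL < 5.99) or whose rates collapse within 5% is reported with model
tag `single`.

Bootstrap errors (default 100 replicates) resample molecules, not frames,
because frames within a trace are strongly correlated.

The Mg²⁺ binding isotherm (bound fraction vs [Mg²⁺]) is fitted with a
Hill form f(c) = sat·cⁿ/(cⁿ + midⁿ) with free exponent — the minimal form
exposing a midpoint and a sub-unity saturation plateau.

## Global hidden Markov model

Hidden states emit Gaussian FRET values; degenerate states share one
component. The workflow:

1. **Emission fixing**: two-component Gaussian mixtures are fitted per
   trace; the medians of the component means/widths across traces are
   frozen as the emission model (the median resists the traces dominated
   by a single state).
2. **Global fit**: one shared start vector and transition matrix are
   optimized over the whole dynamic ensemble by Baum–Welch EM. The scaled
   (normalized) forward–backward recursions are vectorized across traces
   of equal length, so 300 × 2000-frame ensembles fit in seconds to tens
   of seconds. Structural zeros in the transition matrix (forbidden
   links) are preserved exactly by the M-step.
3. **Model selection**: candidate topologies are ranked by
   BIC = −2·logL + p·ln(n), with p = free transition entries + free start
   entries (emissions fixed and therefore not counted) and n = total
   frames. The parameter counting is fixed across candidates so ΔBIC is
   meaningful.
4. **Rates**: per-frame probabilities convert to rate coefficients by
   k = A_ij/dt (first-order approximation; a warning fires when any
   A_ij > 0.1 per frame) with a matrix-logarithm alternative for faster
   kinetics. Populations come from the stationary distribution of A
   (Viterbi-occupancy populations are also available);
   K_d = S_unbound·c/S_bound with degenerate bound states aggregated.
5. **Errors**: profile-likelihood (likelihood-ratio) bounds — one
   transition entry is clamped along a bracket while all other parameters
   are re-optimized by constrained EM; the bound sits where 2·ΔlogL
   crosses the χ²(1) quantile (1σ by default). Sides that never cross
   within (0, 1) are flagged one-sided.

Numerical choices: convergence when the log-likelihood gain per frame
drops below 1e−8 (the degenerate-exchange direction of the likelihood is
a flat ridge; looser thresholds leave a visible bias in k₁₂/k₂₁), at most
2000 iterations, three restarts. Initialization is a dwell-count point
estimate of the transition matrix at the component level; within a
degenerate group the exchange probability starts small (0.02/frame) so
the self-transition stays dominant — a large initial exchange seed leads
EM into a fast-exchange local optimum. Restarts jitter the off-diagonal
entries log-normally (σ = 0.5). Emission widths are floored at 1e−4 and
emission densities at 1e−300 to keep noiseless traces finite. Viterbi
ties break toward the lower state index.

Validation: the forward likelihood is tested against brute-force
enumeration over all hidden paths on short traces (and against an
independent HMM library's scorer); parameter recovery on ensembles
simulated from the published rate models is within 15% at 200–300 traces
× 400 s (the acceptance script reports the recovered values).

## Thermodynamics

ΔG_bind = RT·ln K_d (K_d in M, 1 M reference state) and the
transition-state barrier ΔG‡ = −RT·ln(k_on·h/(κ·k_B·T)) with κ = 1 and
T = 298 K by default. T is configurable; 298 K reproduces the published
derived energies to their printed decimal in all but one rounding-edge
cell (−27.14 vs −27.2 kJ/mol for the weakest contact). ΔG‡ applies the
formula to the numeric value of a second-order rate coefficient in
M⁻¹s⁻¹; the argument of the logarithm is then not strictly dimensionless.
This convention is preserved deliberately for comparability and flagged
here. Note the algebra: a smaller transmission coefficient κ *lowers* the
computed barrier (same observed rate, less efficient crossing).

Two-site Mg²⁺ occupancy: Θ = (K₁c + K₂c + K₁K₂c²)/(1 + K₁c + K₂c +
K₁K₂c²), the occupied-over-total partition-function ratio; site
association constants can be given directly (M⁻¹) or as dissociation
midpoints in mM (defaults 1.78 and 0.87 mM from NMR titrations).

## Sugar pseudorotation

Ring conformation is parameterized by the pseudorotation phase P and
amplitude. Two definitions are computed and cross-checked (agreement
within 2° on the test grid):

* torsion-based (Altona–Sundaralingam):
  tan P = (ν₄+ν₁−ν₃−ν₀)/(2ν₂(sin 36° + sin 72°)), amplitude
  ν_max = hypot(ν₂, (ν₄+ν₁−ν₃−ν₀)/(2(sin 36°+sin 72°))) — the hypot form
  equals ν₂/cos P but stays finite at P ≈ 90°/270°;
* Cartesian (Cremer–Pople-style) from the out-of-plane displacements,
  reported with a −90° phase offset to align its convention with the
  torsion-based P.

Phases are classified into ten 36°-wide modes with C3′-endo covering
[0°, 36°) so the canonical P = 18° is bin-centred; the bin offset is
configurable. Rings with amplitude < 1° are reported phase-undefined
(planar). Mirror reflection negates all torsions and hence shifts P by
180° (endo ↔ exo swap) — useful as a chirality check.

The build/measure oracle constructs a ring as a regular pentagon with
out-of-plane displacements z_j ∝ q·cos(φ + 4πj/5) and calibrates (q, φ)
numerically so the measured torsion-based (P, amplitude) matches the
request; round trips on the full 36°-grid recover P and amplitude within
1°. PDB input (multi-MODEL aware, via biotite) extracts the five ring
atoms per nucleotide, skipping residues that lack them with a warning;
deoxyribose is flagged by the absence of O2′.

Repuckering kinetics reduce the phase series to a North/South indicator
(N: P ∈ [270°, 360°) ∪ [0°, 90°)) and report mean dwell per side, N⇌S
rates and the exponential decay time of the indicator autocorrelation
(computed by FFT; for a two-state telegraph process this equals
1/(k_NS + k_SN)). The autocorrelation route is the default because it is
more robust to brief threshold-crossing noise than transition counting;
both numbers are reported.

## File formats and pipeline

Traces travel as plain CSV (one row per frame: trace id, frame index,
time, donor, acceptor, optional FRET and ground-truth state); unknown
columns survive a round trip. Results are JSON plus CSV tables; the run
log records every seed so any stochastic output is reproducible from the
results directory alone. The `fretkin` CLI exposes simulate / classify /
dwell / hmm / thermo / pucker / run as thin wrappers over the library.

## Problem sizes

The test suite simulates ensembles of 20–80 traces × 400 s for module
tests and 200 traces × 400 s for the acceptance-grade recovery tests; the
acceptance script uses 300 traces × 400 s at 5 Hz, the upper end of the
published ensemble sizes. These sizes put stochastic recovery errors
comfortably inside the 15% band while keeping a full run on a single CPU
in the minutes range.

## Known limitations

* Rate conversion k = A_ij/dt under-resolves kinetics approaching the
  frame rate (dwells of a few frames); the matrix-logarithm route helps
  only while A remains embeddable. Dissociation rates ≳ 1/s at 5 Hz (the
  weakest published condition) are at the edge of what the discretization
  supports.
* No missed-event correction beyond the t ≥ 2·dt cut.
* The HMM assumes shared kinetics across the ensemble (that is the point
  of the global fit); true molecule-to-molecule rate dispersion would be
  absorbed into the degenerate-state exchange.
* Bayesian/variational HMMs, photon-level likelihoods and dye-photophysics
  corrections are out of scope.
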