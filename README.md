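# fretkin

Kinetic analysis of single-molecule FRET trajectories with
degenerate-state hidden Markov models.

`fretkin` is for biophysicists who study reversible biomolecular
interactions — here, an RNA hairpin binding short RNA or DNA target
strands — one molecule at a time. Camera-based smFRET reports binding as
jumps between a zero-FRET (unbound) and a high-FRET (~0.75, bound) level.
Metal ions that lock the bound contact often change the FRET level not at
all: a single FRET state then hides several kinetic states that differ
only in their exit rates ("kinetic heterogeneity"). The package provides
the full chain needed to dissect such data, plus a trace simulator that
stands in for the microscope:

* **`synthetic_traces`** — exact (Gillespie) continuous-time Markov
  simulation from a rate matrix, camera-frame binning, Gaussian
  channel noise, background, bleedthrough, photobleaching;
* **`trace_processing`** — intensity corrections, FRET = I_A/(I_A+I_D),
  molecule classification (static zero / static high / one transition /
  dynamic), Gaussian-mixture FRET histograms, Hill binding isotherms;
* **`dwell_analysis`** — threshold discretization, dwell extraction,
  per-molecule K_d,n = c·⟨t_zero⟩/⟨t_high⟩ with a logistic fit
  P(K_d,n) = 1/(1+(K_d/K_d,n)^p) of its cumulative distribution,
  biexponential / stretched-exponential survival fits;
* **`hmm_kinetics`** — a global Baum–Welch HMM with *degenerate* Gaussian
  emissions (several hidden states sharing one FRET level), BIC model
  selection across kinetic networks, conversion to rate coefficients,
  state populations, K_d = S_unbound·c/S_bound, and profile-likelihood
  error bounds;
* **`thermo`** — ΔG_bind = RT·ln K_d, Eyring barrier
  ΔG‡ = −RT·ln(k_on·h/(κ·k_B·T)), two-site Mg²⁺ occupancy Θ;
* **`pucker_analysis`** — sugar pseudorotation phase/amplitude
  (Altona–Sundaralingam and a Cartesian definition, cross-checked),
  ten-mode classification, circular histograms, N⇌S repuckering
  correlation times, PDB input;
* **`io` / `fretkin` CLI** — plain-text trace files, JSON results, and an
  end-to-end pipeline (`simulate`, `classify`, `dwell`, `hmm`, `thermo`,
  `pucker`, `run`).

## Worked example

Simulate a two-state ensemble at a slow binding condition
(k′_on = 0.0296 s⁻¹, k_off = 0.051 s⁻¹, 35 nM ligand), then run the full
pipeline:

```bash
fretkin simulate --rates 0.0296,0.051 --n-traces 40 --duration 400 \
    --frame-rate 5 --seed 1 --out traces.csv
fretkin run --trace-file traces.csv --out-dir results --ligand-conc 35
```

The final pipeline stage prints the derived kinetics (from one run):

```json
{
  "k_on_pseudo_per_s": 0.02924040311911502,
  "k_on_per_M_s": 835440.089117572,
  "k_off_per_s": 0.050338637911558674,
  "kd_nM_population": 60.254036845093516,
  "kd_nM_from_rates": 60.25403684509385,
  "delta_g_bind_kj_mol": -41.188881975267755,
  "delta_g_barrier_kj_mol": 39.19855204466158
}
```

Reading: the global HMM recovered the generating rates within ~2%
(0.0292 vs 0.0296 s⁻¹; 0.0503 vs 0.051 s⁻¹). The dissociation constant
from the fitted state populations, K_d = S_unbound·c/S_bound ≈ 60 nM,
agrees with the rate-ratio estimate k_off/k_on. Converting to free
energies at 298 K gives a binding free energy of −41.2 kJ/mol and, with
transmission coefficient κ = 1, an association barrier of 39.2 kJ/mol.
`results/` additionally holds the per-molecule class table, dwell
summaries, survival-curve fits, the BIC ranking of the candidate kinetic
networks (the two-state model wins on this dataset, as it should), and a
run log with every seed.

The same pipeline applied to a three-state simulation
(`--rates 0.0214,0.146,0.331,0.0256`) selects the sequential three-state
network with a twofold-degenerate bound level and resolves the two bound
states' exchange kinetics — states that are indistinguishable by FRET
level alone.

## Layout

```
src/fretkin/        library modules (see above)
tests/              pytest suite (unit, property, acceptance)
scripts/acceptance.py
docs/methods.md     models, defaults, numerical choices, limitations
```
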