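# navgate

Markov voltage-clamp simulation and electrophysiology analysis of Nav-channel
fast inactivation with a conductive ("leaky") inactivated state, plus a
HOLE-style pore-radius profiler for channel structures.

The package has three layers:

1. **Simulation** — `gating_model` defines labelled-state Markov schemes with
   voltage-dependent rates (`k(V) = k0·exp(z_eff·F·V/RT)`), per-transition
   gating charge and per-state Na⁺/K⁺ permeabilities (GHK flux), and
   propagates them exactly (per-epoch matrix exponentials) under
   piecewise-constant protocols.  `synthetic_data` turns ten reference
   constructs (WT, single/double/quadruple alanine mutants, IQM variants)
   into realistic cut-open-oocyte recordings: capacitive transients
   (τ = 75 µs), band-limited Gaussian noise, and exact P/N leak subtraction
   (P/−4 from −130 mV for ionic, P/4 from +20 mV for gating currents).
   `protocols` ships the standard families (I-V, availability,
   charge-immobilization, instantaneous I-V, variable-duration tails).
2. **Analysis** — `trace_analysis` (peak/steady-state ratios, 1–2 exponential
   fits with F-test model selection, weighted tail time constants),
   `gating_charge` (off-gating decomposition, immobilized-charge fraction,
   Q-V curves), `voltage_dependence` (h∞, I-V with linear-interpolated
   reversal potentials, G-V curves, two-state Boltzmann fits) and
   `selectivity` (instantaneous I-V → V_rev(t) → bionic GHK inversion →
   P_Na/P_K time course).
3. **Structure** — `pore_profile` traces the maximal-inscribed-sphere radius
   along a pore axis, detects two-tier constrictions, reports the lining
   residues, and maps residue positions across isoforms by global alignment.

Traces are plain TSV files (`time_ms`, `v_mV`, `i_uA`) with a JSON sidecar;
schemes and fixtures are versioned JSON under `src/navgate/schemes/`.

## CLI

```bash
navgate fixtures                          # catalog with tuning targets
navgate simulate --fixture DIIIAA --protocol instantaneous_iv \
    --na-out 57.5 --k-in 120 --na-in 0 --seed 7 --out rec/
navgate kinetics --in rec/tdep_5ms --n auto --json kin.json
navgate selectivity --in rec --na-out 57.5 --k-in 120 --na-in 0 --latency 0.2
navgate voltage-dep --in iv_dir --curve gv --source steady
navgate gating --in gating_dir --family immobilization --mode integral
navgate pore --pdb 6a95.cif --seed-point auto --json pore.json
```

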