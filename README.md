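# bekinet

Chemical-kinetic modelling of cytosine base-editor selectivity.

A base editor operating on a window with one target and one bystander
cytidine is modelled as a 15-state continuous-time Markov chain with four
absorbing outcomes: CTC (no edit), CTT (target only), TTC (bystander
only) and TTT (both).  The toolkit provides:

- **Closed-form outcome probabilities** (`bekinet.closed_form`): the
  first-passage probabilities of all four outcomes, the overall target /
  bystander editing probabilities `P_t` / `P_b`, and the diagnostic odds
  ratios `r1` (target-first vs bystander-first edit) and `r2`
  (stop-at-CTT vs continue-to-TTT).
- **An explicit network engine** (`bekinet.network`): the labelled
  15-state chain, exact splitting probabilities by linear solve, and a
  vectorized Gillespie simulator — two independent oracles for the
  closed forms.
- **Parameter handling** (`bekinet.params`): the six dimensionless model
  parameters (`gamma1`, `gamma2`, `gamma3`, `m`, `ddE0`, `ddEm`; energies
  in units of k_B·T), the Boltzmann energy→rate mapping, and inference of
  site kinetics from Michaelis–Menten constants (`Kd`, `KM`, `kcat`).
- **Calibration** (`bekinet.fitting`): deterministic multi-start
  least-squares fitting of `gamma1` / `gamma3` (optionally `m`) to
  observed per-variant editing fractions, plus objective-surface
  profiling.
- **Design screening** (`bekinet.screen`): selectivity landscapes
  `S(ddEm) = P_t − P_b`, refined peak and design-window identification,
  ranked candidate-mutation screening, and one-at-a-time sensitivity
  scans.
- **Synthetic data** (`bekinet.synth`): seeded multinomial per-variant
  outcome counts for fixture generation and parameter-recovery studies.

## CLI

The `bekinet` command exposes the workflow as subcommands; model
parameters come from flags or a JSON/YAML config (keys `gamma1`,
`gamma2`, `gamma3`, `m`, `ddE0_kBT`, `ddEm_kBT`, or an
`enzyme_kinetics: {Kd_uM, KM_uM, kcat_per_s}` block instead of
`gamma2`).

```sh
# outcome probabilities + diagnostic ratios
bekinet solve --gamma1 2.1 --gamma2 11.4 --gamma3 2.9e-5 --dde0 6

# selectivity curve with peak/window report
bekinet scan --gamma1 2.1 --gamma2 11.4 --gamma3 2.9e-5 --dde0 6 \
    --grid-min -2 --grid-max 12 --grid-step 0.05 --out scan.tsv

# calibrate gamma1/gamma3 against a variant table
bekinet fit --gamma2 11.4 --dde0 6 --variants variants.csv --out fit.json

# rank candidate mutations by predicted selectivity
bekinet screen --gamma1 2.1 --gamma2 11.4 --gamma3 2.9e-5 --dde0 6 \
    --candidates candidates.csv --out screen.tsv

# stochastic simulation / synthetic fixture generation
bekinet simulate --gamma1 2.1 --gamma2 11.4 --gamma3 2.9e-5 --dde0 6 --n-traj 100000 --seed 1
bekinet synth --gamma1 2.1 --gamma2 11.4 --gamma3 2.9e-5 --dde0 6 \
    --ddem-values 0,2.1,2.4,3.5,4.5 --n-cells 10000 --seed 1 --out fixture.csv

# network export (GraphViz DOT or edge TSV)
bekinet export-network --gamma1 2.1 --gamma2 11.4 --gamma3 2.9e-5 --dde0 6
```

Variant tables are CSV/TSV with case-insensitive columns
`variant_id, ddEm_kBT, pt_obs, pb_obs` (optional `ddEm_sem, locus,
n_reps`); candidate tables use `name, ddEm_kBT[, ddEm_sem]`.  Every file
output is accompanied by a provenance record (config hash, seed,
package version).

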