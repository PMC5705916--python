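# syntrosim

Kinetic simulator of an obligate, bidirectional cross-feeding mutualism
between a fermenter (*E. coli*-like; converts glucose into excreted organic
acids) and a phototrophic N2 fixer (*R. palustris*-like; consumes those
acids and excretes NH4+).  Because the producer can also re-acquire
extracellular NH4+, the partners *compete* for the cross-fed nutrient.  The
package simulates batch, serial-transfer and pulsed fed-batch cultures and
maps the consequences of that competition for coexistence — in particular
the phase behaviour in which stable coexistence requires the *recipient* to
hold the competitive advantage for a nutrient that is generated
intracellularly by the producer.

## Model

Eight state variables (fermenter and fixer densities in cells/ml; glucose,
extracellular NH4+, pooled consumable organic acids, formate, ethanol and
cumulative H2 in mM) evolve under Monod kinetics with a shared Hill-type
acid-inhibition factor.  Two variants:

- **default** (partial privatization): the fixer grows on N2 directly,
  bypassing the dissolved NH4+ pool, plus a small growth-rate boost when it
  takes up extracellular NH4+; NH4+ excretion is proportional to
  N2-route growth (parameter `R_A`, fmol per new cell).
- **communal**: all fixed nitrogen transits the extracellular pool before
  either species can assimilate it (fixation decoupled from growth).

Parameters carry provenance flags: a few are printed values
(`K_A = K_AR = 0.01 mM`, `mu_R_max2 = 0.0152 1/h`, `R_A = 0.15` or `0.5`
fmol/cell); the rest are a shipped calibration chosen to reproduce the
documented macroscopic behaviour (growth-rate ratio 4.6, ~10:1 stationary
composition, full glucose consumption within a batch, serial-transfer
collapse threshold at affinity ratio ~1.5).  Every run writes its fully
resolved parameter set, with provenance, next to the results.

## CLI

```sh
syntrosim simulate  --set duration=300 --out results/            # one batch
syntrosim transfer  --set n_transfers=8 --set K_A=0.015 --out results/
syntrosim fedbatch  --set init.Ec=2.7e6 --set init.Rp=2.7e6 --set init.C=20 --out results/
syntrosim scan      --set kind=affinity --out results/           # or excretion | inoculum
syntrosim critical-ratio --set criterion=transfer_stability --set "bounds=[1.0, 3.0]" --out results/
```

Flags: `--config run.yaml` (flat YAML/JSON; unknown keys rejected),
repeatable `--set key=value` overrides (dotted keys reach nested sections;
parameter names like `K_A` work verbatim), `--variant default|communal`,
`--out DIR`, `--verbose`.  Outputs are RFC-4180 CSV tables with units in
the header plus a JSON sidecar (resolved config, provenance, integrator
diagnostics).  The model is deterministic: there is no `--seed` flag, and
passing one is an error.  Exit codes: 0 ok, 2 configuration error,
3 integration failure.

## Layout

- `src/syntrosim/params.py` — parameter set, units, provenance, validation
- `src/syntrosim/model.py` — state space and the two RHS variants
- `src/syntrosim/simulate.py` — batch / serial-transfer / fed-batch drivers
- `src/syntrosim/experiments.py` — scans, outcome classification, critical-
  ratio bisection, yields, competitive index
- `src/syntrosim/config.py`, `cli.py`, `io.py` — configuration, CLI, CSV/JSON
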