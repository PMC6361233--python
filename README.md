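# skempi2

Tools for working with SKEMPI-2.0-style tables of protein–protein binding
energetics upon mutation: parsing and validating the curated CSV format,
inter-converting thermodynamic and kinetic observables, building and
classifying double (and higher-order) mutant cycles, quantifying
duplicate-measurement concordance, cleaning PDB complexes and classifying
residue burial at interfaces, and clustering homologous interactions.
A synthetic-data generator with full ground truth makes every analysis
testable without downloading anything.

## Who this is for

People developing or benchmarking predictors of binding-affinity changes
(ΔΔG), binding kinetics or hot-spot residues, and anyone analysing curated
mutation-energetics tables: the package gives them a validated record
grammar, the standard unit conventions, and the derived quantities
(coupling energies, burial classes, homology clusters) used to partition
and interpret such datasets.

## The quantities at the core

For a complex with dissociation constant *K*<sub>D</sub> (molar) at
temperature *T*:

- ΔG = RT ln *K*<sub>D</sub> (kcal·mol⁻¹, negative = favourable), with
  R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹; *K*<sub>D</sub> = 1/*K*<sub>A</sub> =
  k<sub>off</sub>/k<sub>on</sub>; ΔG = ΔH − TΔS.
- ΔΔG = ΔG(mutant) − ΔG(wild type); positive values destabilize the
  complex.
- For mutations A and B in a shared background,
  ΔΔG<sub>int</sub> = ΔΔG(AB) − ΔΔG(A) − ΔΔG(B) is the residue coupling
  (double-mutant-cycle interaction) energy. |ΔΔG<sub>int</sub>| < 0.5
  kcal·mol⁻¹ counts as additive; ΔΔG<sub>int</sub> < 0 is positive
  epistasis (double mutant tighter than the additive expectation),
  ΔΔG<sub>int</sub> > 0 negative epistasis; sub-classes and sign
  epistasis follow the 0.2/0.2/0.4 kcal·mol⁻¹ rules (see
  `docs/methods.md`). Triple-mutant cubes and 16-vertex fourth-order
  cycles give higher-order couplings via inclusion–exclusion.
- Residue burial: rASA = SASA / residue-type maximum, computed in the
  unbound monomer and in the complex; interface residues (any heavy atom
  within 10 Å of the partner) are support / core / rim by burial before
  and after binding, others interior / surface.
- Interactions are homologous when they share a partner (or a homologous
  one: global alignment score > 50 and identity ≥ 30%) and ≥ 70% of the
  corresponding interface residues.

## Worked example

```python
from skempi2.cycles import aggregate_ddg, enumerate_double_cycles, cycle_report
from skempi2.synthetic import (GeneratorConfig, PlantedCycleSpec,
                               PLANTABLE_LABELS, generate_table)

cfg = GeneratorConfig(seed=17, n_interactions=10,
                      planted_cycles=tuple(PlantedCycleSpec(l)
                                           for l in PLANTABLE_LABELS))
entries, truth = generate_table(cfg)
report = cycle_report(enumerate_double_cycles(aggregate_ddg(entries)))
```

Running `python examples/03_mutant_cycles.py` (the same computation)
prints:

```
11 cycles (11 direct, 0 in a third-mutation background), 11 quantified
additive 1, positive 5, negative 5, sign epistasis 4 (reciprocal 2)
planted 'reciprocal_destabilizing_to_stabilizing': singles +0.91/+0.66, double -0.80, ΔΔG_int -2.38 → positive/antagonistic, sign epistasis: reciprocal_destabilizing_to_stabilizing
```

One planted cycle of every epistasis class was generated; replicates are
averaged to one ΔΔG per mutant state, all complete 4-vertex cycles are
enumerated, and each quantified cycle is classified. The last line shows
a cycle planted as reciprocal sign epistasis — two individually
destabilizing mutations (+0.91, +0.66 kcal·mol⁻¹) whose double mutant
stabilizes (−0.80) — recovered exactly.

The other scripts in `examples/` demonstrate parsing/validation,
thermodynamic completion (including ΔΔG bounds from non-binding entries
with a detection limit), duplicate-measurement concordance against its
closed form, interface burial classification on a geometry-forced toy
complex, and homology clustering of planted families.

A thin command-line layer exposes the same operations
(`skempi2 validate|summary|ddg|cycles|concordance|clean-pdb|annotate|simulate`).

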