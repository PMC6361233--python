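"""Convert between KD, rates, calorimetry and binding free energies.

ΔG = RT ln KD links the dissociation constant to the binding free energy;
KD = koff/kon links it to kinetics; ΔG = ΔH − TΔS to calorimetry.  The
per-entry completion fills in whatever is derivable and flags
inconsistencies between independently reported routes.
"""

import skempi2 as sk
from skempi2.io import AffinityMeasurement, Qualifier, SkempiEntry
from skempi2.thermo import complete_entry, ddg, dg_from_kd, kd_from_rates

print(f"ΔG(1 nM, 298 K)  = {dg_from_kd(1e-9, 298.0):+.3f} kcal/mol")
print(f"ΔG(1 µM, 298 K)  = {dg_from_kd(1e-6, 298.0):+.3f} kcal/mol")
print(f"ΔΔG(1 nM → 1 µM) = {ddg(1e-9, 1e-6, 298.0):+.3f} kcal/mol "
      "(positive: the mutation destabilizes binding)")
print(f"KD from kon=1e6, koff=1e-3: {kd_from_rates(1e6, 1e-3):.1e} M")

entry = SkempiEntry(
    pdb_id="1CSE", side1=("E",), side2=("I",),
    mutations=tuple(sk.parse_mutation_string("LI38G")),
    wt_affinity=AffinityMeasurement(1.1e-12, Qualifier.EXACT),
    mut_affinity=AffinityMeasurement(None, Qualifier.NON_BINDING,
                                     detection_limit=1e-5),
    temperature=294.0)
record = complete_entry(entry)
(bound,) = record.ddg_bounds
print(f"non-binding mutant with a 10 µM detection limit: "
      f"ΔΔG {bound.direction} than {bound.value:+.2f} kcal/mol")
# a mutation that abolishes detectable binding has no exact ΔΔG, but the
# detection limit still yields a lower bound on the destabilization
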