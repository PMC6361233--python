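"""Synthetic SKEMPI-like tables, toy complexes and homolog families.

The generator emits tables that are valid under the parser's invariants
and carry full ground truth, so that parsing, thermodynamics, replicate
aggregation, concordance, cycle classification, structure annotation and
homology clustering can all be exercised without any external data.

Default distributions emulate the curated dataset's gross statistics:
ΔΔG ~ N(1.5, 2.0) kcal·mol⁻¹ (most values inside [−3, 7]), replicate
noise 0.25 kcal·mol⁻¹ (the typical reported experimental error),
wild-type KD log-uniform between 10 pM and 100 nM, ~72% single-point
mutations of which ~55% are to alanine, kinetics on ~26% of entries and
calorimetric ΔH/ΔS on ~6%, a few percent inequality and non-binding
entries, everything at 298 K.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .io import (AA_ALPHABET, AffinityMeasurement, MutationSpec, Qualifier,
                 SkempiEntry)
from .thermo import R_KCAL
from .cycles import (DoubleMutantCycle, EpistasisCall, EpistasisThresholds,
                     classify_epistasis, interaction_id)

__all__ = [
    "GeneratorConfig",
    "PlantedCycleSpec",
    "PlantedCycleTruth",
    "GroundTruth",
    "PLANTABLE_LABELS",
    "plant_cycle",
    "generate_table",
    "generate_toy_complex",
    "generate_homolog_families",
]


@dataclass(frozen=True)
class PlantedCycleSpec:
    """Request for one double mutant cycle of a known epistasis class."""

    label: str
    margin: float = 0.1      # kcal·mol⁻¹ beyond every classification threshold
    background: bool = False  # plant in the background of a third mutation


#: labels accepted by :func:`plant_cycle`
PLANTABLE_LABELS = (
    "additive",
    "positive_synergistic", "positive_antagonistic", "positive_mixed",
    "negative_synergistic", "negative_antagonistic", "negative_mixed",
    "sign_stabilizing", "sign_destabilizing",
    "reciprocal_stabilizing_to_destabilizing",
    "reciprocal_destabilizing_to_stabilizing",
)


@dataclass
class GeneratorConfig:
    seed: int = 17
    n_interactions: int = 20
    mutations_per_interaction: int = 10
    ddg_mean: float = 1.5            # kcal·mol⁻¹
    ddg_sd: float = 2.0
    ddg_clip: float = 9.0            # keep mutant KD physically sane
    replicate_noise_sd: float = 0.25  # kcal·mol⁻¹ per measurement
    replicate_count_probs: dict = field(
        default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1})
    #: probability that an independent laboratory (different reference and
    #: method) re-measures a mutation, creating a concordance pair
    duplicate_pair_fraction: float = 0.15
    inequality_fraction: float = 0.03
    non_binding_fraction: float = 0.03
    kinetics_probability: float = 0.26
    thermo_probability: float = 0.06
    temperature: float = 298.0
    kd_wt_log10_range: tuple[float, float] = (-11.0, -7.0)
    single_point_fraction: float = 0.72
    alanine_fraction: float = 0.55
    planted_cycles: tuple[PlantedCycleSpec, ...] = ()
    thresholds: EpistasisThresholds = field(default_factory=EpistasisThresholds)

    def validate(self) -> None:
        for name in ("duplicate_pair_fraction", "inequality_fraction",
                     "non_binding_fraction", "kinetics_probability",
                     "thermo_probability", "single_point_fraction",
                     "alanine_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.inequality_fraction + self.non_binding_fraction > 0.999 \
                and self.planted_cycles:
            raise ValueError(
                "cannot plant quantified cycles when essentially every entry "
                "is an inequality or non-binding")
        if abs(sum(self.replicate_count_probs.values()) - 1.0) > 1e-9:
            raise ValueError("replicate_count_probs must sum to 1")
        for spec in self.planted_cycles:
            if spec.label not in PLANTABLE_LABELS:
                raise ValueError(f"unknown planted label {spec.label!r}")


@dataclass(frozen=True)
class PlantedCycleTruth:
    interaction: tuple
    background: frozenset
    mut_a: MutationSpec
    mut_b: MutationSpec
    label: str
    call: EpistasisCall


@dataclass
class GroundTruth:
    """Per-entry and per-state truth for one generated table."""

    entry_true_ddg: list[Optional[float]]
    entry_qualifier: list[str]  # "exact" | "inequality" | "non_binding"
    true_ddg: dict  # (interaction, frozenset[MutationSpec]) -> float
    planted_cycles: list[PlantedCycleTruth]


def _expected_call(label: str) -> EpistasisCall:
    table = {
        "additive": ("additive", "none", "none"),
        "positive_synergistic": ("positive", "synergistic", "none"),
        "positive_antagonistic": ("positive", "antagonistic", "none"),
        "positive_mixed": ("positive", "mixed", "none"),
        "negative_synergistic": ("negative", "synergistic", "none"),
        "negative_antagonistic": ("negative", "antagonistic", "none"),
        "negative_mixed": ("negative", "mixed", "none"),
        "sign_stabilizing": ("positive", "mixed", "stabilizing"),
        "sign_destabilizing": ("negative", "mixed", "destabilizing"),
        "reciprocal_stabilizing_to_destabilizing":
            ("negative", "antagonistic",
             "reciprocal_stabilizing_to_destabilizing"),
        "reciprocal_destabilizing_to_stabilizing":
            ("positive", "antagonistic",
             "reciprocal_destabilizing_to_stabilizing"),
    }
    return EpistasisCall(*table[label])


def plant_cycle(
    label: str,
    margin: float,
    rng: np.random.Generator,
    thresholds: EpistasisThresholds = EpistasisThresholds(),
) -> tuple[float, float, float, EpistasisCall]:
    """Draw (ΔΔG_A, ΔΔG_B, ΔΔG_AB) realizing ``label`` with ``margin``.

    Every classification inequality holds with at least ``margin``
    kcal·mol⁻¹ to spare, so noise below the margin cannot change the
    class.  The planted triple is verified against
    :func:`~skempi2.cycles.classify_epistasis` before being returned.
    """
    t = thresholds
    if label == "additive":
        cap = min(t.additive, t.flip)
    elif label in ("positive_mixed", "negative_mixed",
                   "sign_stabilizing", "sign_destabilizing"):
        cap = t.single  # these need a non-empty near-neutral band
    else:
        cap = 1.0
    if margin < 0 or margin >= cap:
        raise ValueError(f"margin {margin} unsatisfiable for {label} under {t}")
    s = t.single + margin
    add = t.additive + margin
    u = rng.uniform

    def triple(a, b, gint):
        return a, b, a + b + gint

    neutral_hw = max(t.single - margin, 0.0)
    if label == "additive":
        cap = min(t.additive, t.flip) - margin
        a, b = u(-1.5, 1.5), u(-1.5, 1.5)
        a, b, ab = triple(a, b, u(-cap, cap))
    elif label == "positive_synergistic":
        a, b = u(-2.0, -s), u(-2.0, -s)
        a, b, ab = triple(a, b, u(-2.0, -add))
    elif label == "positive_antagonistic":
        gint = u(-1.5, -add)
        a = u(s - gint + 0.05, s - gint + 1.5)
        b = u(s - gint + 0.05, s - gint + 1.5)
        a, b, ab = triple(a, b, gint)
    elif label == "positive_mixed":
        a = u(-2.5, -s)
        b = u(-neutral_hw, neutral_hw)
        a, b, ab = triple(a, b, u(-1.5, -add))
    elif label == "negative_synergistic":
        a, b = u(s, 2.0), u(s, 2.0)
        a, b, ab = triple(a, b, u(add, 2.0))
    elif label == "negative_antagonistic":
        gint = u(add, 1.5)
        a = u(-gint - s - 1.5, -gint - s - 0.05)
        b = u(-gint - s - 1.5, -gint - s - 0.05)
        a, b, ab = triple(a, b, gint)
    elif label == "negative_mixed":
        a = u(s, 2.5)
        b = u(-neutral_hw, neutral_hw)
        a, b, ab = triple(a, b, u(add, 1.5))
    elif label == "sign_stabilizing":
        # A destabilizes alone, stabilizes in B's background; B near-neutral
        a = u(s, s + 1.0)
        a_in_b = u(-s - 1.0, -s - margin)
        b = u(-neutral_hw, neutral_hw)
        gint = a_in_b - a
        a, b, ab = triple(a, b, gint)
    elif label == "sign_destabilizing":
        a = u(-s - 1.0, -s)
        a_in_b = u(s + margin, s + 1.0)
        b = u(-neutral_hw, neutral_hw)
        gint = a_in_b - a
        a, b, ab = triple(a, b, gint)
    elif label == "reciprocal_stabilizing_to_destabilizing":
        a, b = u(-1.5, -s), u(-1.5, -s)
        ab = u(s, 1.5)
    elif label == "reciprocal_destabilizing_to_stabilizing":
        a, b = u(s, 1.5), u(s, 1.5)
        ab = u(-1.5, -s)
    else:
        raise ValueError(f"unknown label {label!r}")

    expected = _expected_call(label)
    check = DoubleMutantCycle(
        interaction=("PLNT", ()), background=frozenset(),
        mut_a=MutationSpec("A", "A", 1, "", "G"),
        mut_b=MutationSpec("A", "A", 2, "", "G"),
        ddg_a=a, ddg_b=b, ddg_ab=ab, quantified=True,
        same_reference=True, mixed_temperature=False,
    )
    got = classify_epistasis(check, thresholds)
    if got != expected:
        raise AssertionError(
            f"planted cycle for {label} classified as {got}, expected {expected}")
    return a, b, ab, expected


def _random_mutation(rng: np.random.Generator, chain: str, resnum: int,
                     to_alanine: bool) -> MutationSpec:
    wt = AA_ALPHABET[rng.integers(len(AA_ALPHABET))]
    if to_alanine and wt != "A":
        mut = "A"
    else:
        choices = [c for c in AA_ALPHABET if c != wt]
        mut = choices[rng.integers(len(choices))]
    return MutationSpec(wt, chain, resnum, "", mut)


def generate_table(config: GeneratorConfig) -> tuple[list[SkempiEntry], GroundTruth]:
    """Generate a full synthetic entry table with ground truth.

    Mutant KD is KD_wt·exp(ΔΔG/RT) with measurement noise applied in
    energy space; kinetic and calorimetric observables, when emitted, are
    exactly consistent with the entry's (noisy) KD values.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    T = config.temperature
    RT = R_KCAL * T
    entries: list[SkempiEntry] = []
    truth = GroundTruth([], [], {}, [])

    rep_counts = sorted(config.replicate_count_probs)
    rep_probs = [config.replicate_count_probs[k] for k in rep_counts]

    def emit(pdb_id, mutations, true_ddg, kd_wt, reference, method,
             qualifier="exact"):
        measured_ddg = true_ddg + (
            rng.normal(0.0, config.replicate_noise_sd)
            if config.replicate_noise_sd > 0 else 0.0)
        kd_mut = kd_wt * math.exp(measured_ddg / RT)
        wt_aff = AffinityMeasurement(kd_wt, Qualifier.EXACT)
        if qualifier == "exact":
            mut_aff = AffinityMeasurement(kd_mut, Qualifier.EXACT)
        elif qualifier == "inequality":
            mut_aff = AffinityMeasurement(kd_mut, Qualifier.GREATER_THAN)
        else:  # non-binding, with the detection-limit KD retained
            mut_aff = AffinityMeasurement(
                None, Qualifier.NON_BINDING, detection_limit=1e-4)
        kwargs = {}
        if rng.random() < config.kinetics_probability:
            kon_wt = 10.0 ** rng.uniform(4.0, 7.0)
            kon_mut = 10.0 ** rng.uniform(4.0, 7.0)
            kwargs.update(
                kon_wt=kon_wt, koff_wt=kon_wt * kd_wt,
                kon_mut=kon_mut,
                koff_mut=kon_mut * kd_mut if qualifier == "exact" else None,
            )
            if qualifier != "exact":
                kwargs["kon_mut"] = None
        if rng.random() < config.thermo_probability and qualifier == "exact":
            ds_wt = rng.normal(-20.0, 15.0)
            ds_mut = rng.normal(-20.0, 15.0)
            kwargs.update(
                ds_wt=ds_wt, dh_wt=RT * math.log(kd_wt) / 1.0 + T * ds_wt / 1000.0,
                ds_mut=ds_mut,
                dh_mut=RT * math.log(kd_mut) + T * ds_mut / 1000.0,
            )
        entry = SkempiEntry(
            pdb_id=pdb_id, side1=("A",), side2=("B",),
            mutations=tuple(mutations),
            wt_affinity=wt_aff, mut_affinity=mut_aff,
            temperature=T, method=method, reference=reference, **kwargs,
        )
        entries.append(entry)
        truth.entry_true_ddg.append(true_ddg if qualifier == "exact" else None)
        truth.entry_qualifier.append(
            "exact" if qualifier == "exact"
            else "inequality" if qualifier == "inequality" else "non_binding")
        return entry

    for i in range(config.n_interactions):
        pdb_id = f"S{i:03d}"
        kd_wt = 10.0 ** rng.uniform(*config.kd_wt_log10_range)
        reference = f"Ref{i:03d}"
        resnums = rng.permutation(np.arange(1, 400))[:2 * config.mutations_per_interaction]
        cursor = 0
        for j in range(config.mutations_per_interaction):
            if rng.random() < config.single_point_fraction:
                n_point = 1
            else:
                n_point = 2
            mutations = []
            for _ in range(n_point):
                chain = "A" if rng.random() < 0.5 else "B"
                to_ala = rng.random() < config.alanine_fraction
                mutations.append(_random_mutation(
                    rng, chain, int(resnums[cursor]), to_ala))
                cursor += 1
            true_ddg = float(np.clip(
                rng.normal(config.ddg_mean, config.ddg_sd),
                -config.ddg_clip, config.ddg_clip))
            r = rng.random()
            if r < config.non_binding_fraction:
                qualifier = "non_binding"
            elif r < config.non_binding_fraction + config.inequality_fraction:
                qualifier = "inequality"
            else:
                qualifier = "exact"
            entry0 = emit(pdb_id, mutations, true_ddg, kd_wt, reference,
                          "SPR", qualifier)
            truth.true_ddg[(interaction_id(entry0),
                            frozenset(entry0.mutations))] = true_ddg
            n_rep = int(rng.choice(rep_counts, p=rep_probs))
            if qualifier != "non_binding":  # n.b. replicates are contentless
                for _ in range(n_rep - 1):
                    emit(pdb_id, mutations, true_ddg, kd_wt, reference, "SPR",
                         qualifier)
            if qualifier == "exact" and rng.random() < config.duplicate_pair_fraction:
                emit(pdb_id, mutations, true_ddg, kd_wt,
                     f"Ref{i:03d}dup", "ITC", qualifier)

    for p_idx, spec in enumerate(config.planted_cycles):
        pdb_id = f"P{p_idx:03d}"
        kd_wt = 10.0 ** rng.uniform(*config.kd_wt_log10_range)
        reference = f"RefP{p_idx:03d}"
        a, b, ab, call = plant_cycle(spec.label, spec.margin, rng,
                                     config.thresholds)
        mut_a = _random_mutation(rng, "A", 10, False)
        mut_b = _random_mutation(rng, "A", 20, False)
        states: dict[frozenset, float] = {}
        if spec.background:
            mut_c = _random_mutation(rng, "B", 30, False)
            c0 = float(rng.normal(0.0, 1.0))
            bg = frozenset({mut_c})
            states[bg] = c0
            states[frozenset({mut_c, mut_a})] = c0 + a
            states[frozenset({mut_c, mut_b})] = c0 + b
            states[frozenset({mut_c, mut_a, mut_b})] = c0 + ab
        else:
            bg = frozenset()
            states[frozenset({mut_a})] = a
            states[frozenset({mut_b})] = b
            states[frozenset({mut_a, mut_b})] = ab
        saved_noise = config.replicate_noise_sd
        config.replicate_noise_sd = 0.0  # planted vertices are exact
        try:
            for muts, ddg_value in states.items():
                entry0 = emit(pdb_id, sorted(muts), ddg_value, kd_wt,
                              reference, "SPR")
                truth.true_ddg[(interaction_id(entry0), frozenset(muts))] = \
                    ddg_value
        finally:
            config.replicate_noise_sd = saved_noise
        truth.planted_cycles.append(PlantedCycleTruth(
            interaction=interaction_id(entry0), background=bg,
            mut_a=mut_a, mut_b=mut_b, label=spec.label, call=call))

    return entries, truth


# ---------------------------------------------------------------------------
# toy structures

_RES_OFFSETS = {  # planar 5-atom alanine-like residue, offsets in Å
    "N": (-1.3, 0.3), "CA": (0.0, 0.0), "C": (1.3, 0.3),
    "O": (0.6, -1.1), "CB": (-0.6, -1.1),
}


def generate_toy_complex(
    n: int = 5,
    gap: float = 4.0,
    spacing: float = 5.6,
    sink: float = 2.0,
    seed: int = 17,
) -> tuple[str, dict]:
    """Two flat pseudo-protein slabs with geometry-forced burial classes.

    Chain A is an ``n × n`` four-layer block of planar alanine residues
    (lattice constant ``spacing``); its top layer faces chain B, a 3×3
    two-layer block, across a plane-to-plane ``gap``.  The centre residue
    of A's top layer is recessed by ``sink`` Å: its lattice neighbours
    shade most of it in the unbound chain (mostly buried), and chain B's
    facing residue blocks its remaining upward exposure on binding — a
    support residue.  Interior residues sit two layers down; the bottom
    layer faces away from the interface (surface).  One water sits 3 Å
    from chain A (retained by the 5 Å cleaning rule), another far outside
    it.

    Returns the PDB text and a ground-truth dict with per-residue labels
    (only residues whose class is forced by the geometry are listed) and
    the expected interface content.

    Requires ``n`` ≥ 5 (odd) so that interior residues exist.
    """
    if n < 5 or n % 2 == 0:
        raise ValueError("n must be odd and at least 5")
    if sink <= 0:
        raise ValueError("sink must be positive")
    rng = np.random.default_rng(seed)  # reserved for future jitter; unused
    del rng
    centre = n // 2
    # the partner can shade chain A's facing residues only if its atoms come
    # within one atom-plus-probe diameter (≈ 6.2 Å with carbon radii)
    contact = gap < 6.2 and gap + sink < 6.2
    from Bio.PDB.StructureBuilder import StructureBuilder
    from Bio.PDB import PDBIO

    builder = StructureBuilder()
    builder.init_structure("toy")
    builder.init_model(0)

    serial = [1]

    def add_residue(chain, resnum, x, y, z):
        builder.init_seg("")
        builder.init_residue("ALA", " ", resnum, " ")
        for name, (dx, dy) in _RES_OFFSETS.items():
            element = name[0]
            builder.init_atom(name, np.array([x + dx, y + dy, z], dtype="f"),
                              0.0, 1.0, " ", name, serial[0], element)
            serial[0] += 1

    labels: dict[tuple[str, int, str], str] = {}
    top_z = 3 * spacing

    builder.init_chain("A")
    resnum = 0
    for layer in range(4):
        z = layer * spacing
        for ix in range(n):
            for iy in range(n):
                cheb = max(abs(ix - centre), abs(iy - centre))
                sunken = layer == 3 and cheb == 0
                resnum += 1
                add_residue("A", resnum, ix * spacing, iy * spacing,
                            z - (sink if sunken else 0.0))
                rid = ("A", resnum, "")
                if layer == 0:
                    labels[rid] = "SUR"
                elif layer == 1:
                    if cheb <= 1:
                        labels[rid] = "INT"
                elif layer == 3:
                    if not contact:
                        # partner too distant to shade anything: the facing
                        # layer is plain surface, the recess plain interior
                        if sunken:
                            labels[rid] = "INT"
                        elif cheb <= 2 and (cheb < 2 or ix == centre
                                            or iy == centre):
                            labels[rid] = "SUR"
                    elif sunken:
                        labels[rid] = "SUP"
                    elif cheb <= 1:
                        labels[rid] = "COR"
                    elif cheb == 2 and (ix == centre or iy == centre):
                        # edge-centre residues: shaded by chain B's rim but
                        # keep their outward lateral face
                        labels[rid] = "RIM"

    # body-centred filler residues plug the interstitial voids between
    # layers so that interior residues are genuinely probe-inaccessible;
    # they carry no ground-truth label
    for layer in range(3):
        z = (layer + 0.5) * spacing
        for ix in range(n - 1):
            for iy in range(n - 1):
                resnum += 1
                add_residue("A", resnum, (ix + 0.5) * spacing,
                            (iy + 0.5) * spacing, z)

    builder.init_chain("B")
    resnum = 0
    for layer, z in ((0, top_z + gap), (1, top_z + gap + spacing)):
        for ix in range(centre - 1, centre + 2):
            for iy in range(centre - 1, centre + 2):
                resnum += 1
                add_residue("B", resnum, ix * spacing, iy * spacing, z)

    # waters: one 3 Å above a corner atom of A (kept), one 30 Å away (dropped)
    builder.init_chain("W")
    builder.init_seg("")
    builder.init_residue("HOH", "W", 1, " ")
    builder.init_atom("O", np.array([0.0, 0.0, -3.0], dtype="f"),
                      0.0, 1.0, " ", "O", serial[0], "O")
    serial[0] += 1
    builder.init_residue("HOH", "W", 2, " ")
    builder.init_atom("O", np.array([-30.0, -30.0, -30.0], dtype="f"),
                      0.0, 1.0, " ", "O", serial[0], "O")

    io = PDBIO()
    io.set_structure(builder.get_structure())
    buf = _io.StringIO()
    io.save(buf)
    ground_truth = {
        "labels": labels,
        "side1": ("A",),
        "side2": ("B",),
        "gap": gap,
        "water_kept": ("W", 1),
        "water_dropped": ("W", 2),
    }
    return buf.getvalue(), ground_truth


# ---------------------------------------------------------------------------
# homolog families

def generate_homolog_families(
    n_families: int = 3,
    members_per_family: int = 3,
    seq_len: int = 120,
    within_mutation_rate: float = 0.15,
    interface_size: int = 24,
    interface_overlap: float = 0.8,
    seed: int = 17,
) -> tuple[dict, dict, dict]:
    """Planted interaction families for homology-clustering tests.

    Each family shares a mutated copy of one ancestral receptor sequence
    (pairwise identity ≈ 1 − ``within_mutation_rate``) carrying
    ``interface_overlap`` of the ancestral interface positions; ligands
    and cross-family receptors are independent random sequences.  Returns
    ``(sequences, interfaces, family_of)`` in the shape expected by
    :func:`~skempi2.homology.cluster_interactions`.
    """
    rng = np.random.default_rng(seed)
    aas = list(AA_ALPHABET)

    def random_seq():
        return "".join(aas[k] for k in rng.integers(0, 20, seq_len))

    def mutate(seq, rate):
        out = list(seq)
        for i in range(len(out)):
            if rng.random() < rate:
                out[i] = aas[rng.integers(0, 20)]
        return "".join(out)

    sequences: dict = {}
    interfaces: dict = {}
    family_of: dict = {}
    for f in range(n_families):
        ancestor = random_seq()
        base_iface = set(
            int(i) for i in rng.choice(seq_len, interface_size, replace=False))
        for m in range(members_per_family):
            iid = f"fam{f}_m{m}"
            receptor = mutate(ancestor, within_mutation_rate)
            keep = int(round(interface_overlap * interface_size))
            # the kept positions are common to the family so that pairwise
            # interface overlap equals the requested fraction
            kept = set(sorted(base_iface)[:keep])
            pool = sorted(set(range(seq_len)) - base_iface)
            fresh = set(
                int(i) for i in rng.choice(pool, interface_size - keep,
                                           replace=False))
            sequences[iid] = {"R": receptor, "L": random_seq()}
            interfaces[iid] = {"R": kept | fresh,
                               "L": set(range(10))}
            family_of[iid] = f
    return sequences, interfaces, family_of
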