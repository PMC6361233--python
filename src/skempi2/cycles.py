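"""Mutant-cycle construction and epistasis classification.

A double mutant cycle compares the binding free-energy changes of two
single mutations A and B and their double mutant AB, all relative to a
common background (the wild type, or a third mutation C).  The coupling
energy

    ΔΔG_int = ΔΔG(AB) − ΔΔG(A) − ΔΔG(B)

measures the interaction between the two substitutions: cycles with small
|ΔΔG_int| are additive; negative coupling means the double mutant binds
tighter than the additive expectation (positive epistasis), positive
coupling the reverse (negative epistasis).  Sign epistasis — one
mutation's effect changing sign depending on the presence of the other —
is detected per mutation; when both flip, the cycle exhibits reciprocal
sign epistasis.  Third- and fourth-order coupling terms come from triple
mutant cubes (8 vertices) and quadruple cycles (16 vertices) via the
inclusion–exclusion alternating sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

from .io import MutationSpec, SkempiEntry, Qualifier
from .thermo import EnergyRecord, complete_entry

__all__ = [
    "MutationKey",
    "AggregatedDDG",
    "DoubleMutantCycle",
    "EpistasisThresholds",
    "EpistasisCall",
    "HigherOrderCycle",
    "aggregate_ddg",
    "enumerate_double_cycles",
    "classify_epistasis",
    "enumerate_triple_cubes",
    "enumerate_quad_cycles",
    "interaction_energy",
    "cycle_report",
]


def interaction_id(entry: SkempiEntry) -> tuple:
    sides = tuple(sorted((tuple(sorted(entry.side1)), tuple(sorted(entry.side2)))))
    return (entry.pdb_id.upper(), sides)


@dataclass(frozen=True)
class MutationKey:
    """Order-independent identity of a mutant state of one interaction."""

    interaction: tuple
    mutations: frozenset[MutationSpec]

    def __post_init__(self) -> None:
        if not self.mutations:
            raise ValueError("mutation set must be non-empty")

    @property
    def canonical(self) -> tuple[MutationSpec, ...]:
        return tuple(sorted(self.mutations))


@dataclass
class AggregatedDDG:
    """Replicate-averaged ΔΔG for one mutant state.

    ``ddg`` is the mean over exact-affinity replicates (equivalently the
    geometric-mean KD ratio); it is absent when no exact replicate exists,
    in which case the state is non-quantified.
    """

    ddg: Optional[float]
    quantified: bool
    n_replicates: int
    references: frozenset[str]
    qualifiers: frozenset[Qualifier]
    temperatures: frozenset[float]


def aggregate_ddg(
    entries: Sequence[SkempiEntry],
    records: Optional[Sequence[EnergyRecord]] = None,
) -> dict[MutationKey, AggregatedDDG]:
    """Collapse replicate measurements to one ΔΔG per mutant state.

    A state is quantified if at least one replicate has exact wild-type
    and mutant affinities; non-quantified states (inequality or
    non-binding only) are kept with ``ddg=None`` so that cycles involving
    them can still be enumerated and counted.
    """
    if records is None:
        records = [complete_entry(e) for e in entries]
    groups: dict[MutationKey, list[tuple[SkempiEntry, EnergyRecord]]] = {}
    for entry, record in zip(entries, records):
        key = MutationKey(interaction_id(entry), frozenset(entry.mutations))
        groups.setdefault(key, []).append((entry, record))
    out: dict[MutationKey, AggregatedDDG] = {}
    for key, members in groups.items():
        exact = [r.ddg for _, r in members if r.ddg is not None]
        out[key] = AggregatedDDG(
            ddg=sum(exact) / len(exact) if exact else None,
            quantified=bool(exact),
            n_replicates=len(members),
            references=frozenset(e.reference for e, _ in members),
            qualifiers=frozenset(
                q for e, _ in members
                for q in (e.wt_affinity.qualifier, e.mut_affinity.qualifier)
            ),
            temperatures=frozenset(e.temperature for e, _ in members),
        )
    return out


@dataclass
class DoubleMutantCycle:
    interaction: tuple
    background: frozenset[MutationSpec]
    mut_a: MutationSpec
    mut_b: MutationSpec
    ddg_a: Optional[float]      # ΔΔG ab→Ab (relative to background)
    ddg_b: Optional[float]      # ΔΔG ab→aB
    ddg_ab: Optional[float]     # ΔΔG ab→AB
    quantified: bool
    same_reference: bool
    mixed_temperature: bool
    references: frozenset[str] = field(default_factory=frozenset)

    @property
    def ddg_a_in_b(self) -> Optional[float]:
        """ΔΔG aB→AB: effect of A in the presence of B."""
        if self.ddg_ab is None or self.ddg_b is None:
            return None
        return self.ddg_ab - self.ddg_b

    @property
    def ddg_b_in_a(self) -> Optional[float]:
        """ΔΔG Ab→AB: effect of B in the presence of A."""
        if self.ddg_ab is None or self.ddg_a is None:
            return None
        return self.ddg_ab - self.ddg_a

    @property
    def ddg_int(self) -> Optional[float]:
        """Coupling energy; both §-defining paths are algebraically equal."""
        if None in (self.ddg_a, self.ddg_b, self.ddg_ab):
            return None
        return self.ddg_ab - self.ddg_a - self.ddg_b

    @property
    def is_direct(self) -> bool:
        return not self.background


def _vertex(
    ddg_map: Mapping[MutationKey, AggregatedDDG],
    interaction: tuple,
    mutations: frozenset[MutationSpec],
) -> Optional[AggregatedDDG]:
    if not mutations:
        return AggregatedDDG(0.0, True, 0, frozenset(), frozenset(), frozenset())
    return ddg_map.get(MutationKey(interaction, mutations))


def enumerate_double_cycles(
    ddg_map: Mapping[MutationKey, AggregatedDDG],
    max_background: int = 1,
) -> list[DoubleMutantCycle]:
    """All double mutant cycles constructible from an aggregated ΔΔG map.

    For every interaction, background set S (|S| ≤ ``max_background``) and
    unordered pair of distinct single mutations {A, B}, a cycle is emitted
    when the states S (if non-empty), S∪{A}, S∪{B} and S∪{A,B} all exist.
    Vertex energies are re-referenced to the background.  |S| = 0 cycles
    are "direct"; |S| = 1 corresponds to a cycle in the background of a
    third mutation.
    """
    by_interaction: dict[tuple, dict[frozenset, AggregatedDDG]] = {}
    for key, agg in ddg_map.items():
        by_interaction.setdefault(key.interaction, {})[key.mutations] = agg

    cycles: list[DoubleMutantCycle] = []
    for interaction, states in by_interaction.items():
        # candidate backgrounds: empty set plus any existing state small enough
        backgrounds = [frozenset()] + [
            s for s in states if len(s) <= max_background
        ]
        singles = sorted({m for s in states for m in s})
        for bg in backgrounds:
            bg_agg = _vertex(ddg_map, interaction, bg)
            if bg_agg is None:
                continue
            candidates = sorted(set(singles) - bg)
            for mut_a, mut_b in combinations(candidates, 2):
                sa = bg | {mut_a}
                sb = bg | {mut_b}
                sab = bg | {mut_a, mut_b}
                va, vb, vab = states.get(sa), states.get(sb), states.get(sab)
                if va is None or vb is None or vab is None:
                    continue
                vertices = [v for v in (bg_agg, va, vb, vab) if v.n_replicates]
                quantified = all(
                    v.quantified for v in (bg_agg, va, vb, vab))
                refsets = [v.references for v in vertices]
                common = frozenset.intersection(*refsets) if refsets else frozenset()
                temps = set().union(*(v.temperatures for v in vertices))
                def rel(v: AggregatedDDG):
                    if v.ddg is None or bg_agg.ddg is None:
                        return None
                    return v.ddg - bg_agg.ddg
                cycles.append(DoubleMutantCycle(
                    interaction=interaction, background=bg,
                    mut_a=mut_a, mut_b=mut_b,
                    ddg_a=rel(va), ddg_b=rel(vb), ddg_ab=rel(vab),
                    quantified=quantified,
                    same_reference=bool(common),
                    mixed_temperature=len(temps) > 1,
                    references=frozenset().union(*refsets) if refsets else frozenset(),
                ))
    return cycles


@dataclass(frozen=True)
class EpistasisThresholds:
    """Classification thresholds in kcal·mol⁻¹."""

    additive: float = 0.5       # |ΔΔG_int| below this → additive
    single: float = 0.2         # |single ΔΔG| above this → stabilizing/destabilizing
    flip: float = 0.4           # |ΔΔG with − without background| for a sign flip


@dataclass(frozen=True)
class EpistasisCall:
    additivity: str             # "additive" | "positive" | "negative"
    subclass: str               # "synergistic" | "antagonistic" | "mixed" | "none"
    sign_epistasis: str         # "none" | "stabilizing" | "destabilizing" |
                                # "reciprocal_stabilizing_to_destabilizing" |
                                # "reciprocal_destabilizing_to_stabilizing"

    @property
    def is_additive(self) -> bool:
        return self.additivity == "additive"


def _flip(without_bg: float, with_bg: float, t: EpistasisThresholds) -> Optional[str]:
    """Sign-flip type for one mutation, or None.

    "destabilizing": destabilizes with the background present, stabilizes
    without it; "stabilizing": the reverse.
    """
    if (abs(without_bg) > t.single and abs(with_bg) > t.single
            and abs(without_bg - with_bg) > t.flip
            and without_bg * with_bg < 0):
        return "destabilizing" if with_bg > 0 else "stabilizing"
    return None


def classify_epistasis(
    cycle: DoubleMutantCycle,
    thresholds: EpistasisThresholds = EpistasisThresholds(),
) -> EpistasisCall:
    """Classify one quantified double mutant cycle."""
    if not cycle.quantified or cycle.ddg_int is None:
        raise ValueError(
            "cycle is not quantified; inequality-bearing cycles cannot be "
            "classified — inspect their bounds instead"
        )
    t = thresholds
    a, b, ab, gint = cycle.ddg_a, cycle.ddg_b, cycle.ddg_ab, cycle.ddg_int

    if abs(gint) < t.additive:
        additivity, subclass = "additive", "none"
    else:
        additivity = "positive" if gint < 0 else "negative"
        both_stab = a < -t.single and b < -t.single
        both_destab = a > t.single and b > t.single
        if additivity == "positive":
            subclass = ("synergistic" if both_stab
                        else "antagonistic" if both_destab else "mixed")
        else:
            subclass = ("synergistic" if both_destab
                        else "antagonistic" if both_stab else "mixed")

    flip_a = _flip(a, cycle.ddg_a_in_b, t)
    flip_b = _flip(b, cycle.ddg_b_in_a, t)
    if flip_a and flip_b:
        # both flips necessarily share a direction (see docs)
        sign = ("reciprocal_stabilizing_to_destabilizing"
                if flip_a == "destabilizing"
                else "reciprocal_destabilizing_to_stabilizing")
    elif flip_a or flip_b:
        sign = flip_a or flip_b
    else:
        sign = "none"
    return EpistasisCall(additivity, subclass, sign)


@dataclass
class HigherOrderCycle:
    """A complete 2^n-vertex mutant hypercube (n = 3 or 4)."""

    interaction: tuple
    mutations: tuple[MutationSpec, ...]
    vertex_ddg: dict  # frozenset(subset) -> Optional[float]; ∅ -> 0.0
    quantified: bool
    same_reference: bool

    @property
    def order(self) -> int:
        return len(self.mutations)

    @property
    def interaction_energy(self) -> Optional[float]:
        if not self.quantified:
            return None
        return interaction_energy(self.vertex_ddg, self.mutations)


def interaction_energy(
    vertex_ddg: Mapping[frozenset, Optional[float]],
    mutations: Sequence[MutationSpec],
) -> float:
    """n-th order coupling: Σ_T (−1)^(n−|T|) ΔΔG(T) over subsets T.

    Equals the recursive definition (difference of (n−1)-order terms
    across the n-th mutation's background) and is permutation-symmetric.
    """
    n = len(mutations)
    total = 0.0
    for r in range(n + 1):
        for subset in combinations(mutations, r):
            v = vertex_ddg.get(frozenset(subset), 0.0 if r == 0 else None)
            if v is None:
                raise ValueError(f"missing vertex {subset}")
            total += (-1) ** (n - r) * v
    return total


def _enumerate_hypercubes(
    ddg_map: Mapping[MutationKey, AggregatedDDG], order: int
) -> list[HigherOrderCycle]:
    by_interaction: dict[tuple, dict[frozenset, AggregatedDDG]] = {}
    for key, agg in ddg_map.items():
        by_interaction.setdefault(key.interaction, {})[key.mutations] = agg
    out: list[HigherOrderCycle] = []
    for interaction, states in by_interaction.items():
        singles = sorted({m for s in states if len(s) == 1 for m in s})
        for muts in combinations(singles, order):
            subsets = [frozenset(c) for r in range(1, order + 1)
                       for c in combinations(muts, r)]
            if not all(s in states for s in subsets):
                continue
            vertices = {s: states[s] for s in subsets}
            quantified = all(v.quantified for v in vertices.values())
            refsets = [v.references for v in vertices.values()]
            common = frozenset.intersection(*refsets)
            vertex_ddg = {frozenset(): 0.0}
            vertex_ddg.update({s: v.ddg for s, v in vertices.items()})
            out.append(HigherOrderCycle(
                interaction=interaction, mutations=tuple(muts),
                vertex_ddg=vertex_ddg, quantified=quantified,
                same_reference=bool(common),
            ))
    return out


def enumerate_triple_cubes(
    ddg_map: Mapping[MutationKey, AggregatedDDG],
) -> list[HigherOrderCycle]:
    """All complete 8-vertex triple mutant cubes."""
    return _enumerate_hypercubes(ddg_map, 3)


def enumerate_quad_cycles(
    ddg_map: Mapping[MutationKey, AggregatedDDG],
) -> list[HigherOrderCycle]:
    """All complete 16-vertex fourth-order mutant cycles."""
    return _enumerate_hypercubes(ddg_map, 4)


def cycle_report(
    cycles: Sequence[DoubleMutantCycle],
    thresholds: EpistasisThresholds = EpistasisThresholds(),
) -> dict:
    """Summary counts over a list of double mutant cycles."""
    direct = [c for c in cycles if c.is_direct]
    background = [c for c in cycles if not c.is_direct]
    quantified = [c for c in cycles if c.quantified]
    calls = {id(c): classify_epistasis(c, thresholds) for c in quantified}

    def count(pred):
        return sum(1 for c in quantified if pred(calls[id(c)]))

    ddg_int_values = sorted(c.ddg_int for c in quantified)
    report = {
        "n_cycles": len(cycles),
        "n_direct": len(direct),
        "n_background": len(background),
        "n_quantified": len(quantified),
        "n_direct_non_quantified": sum(1 for c in direct if not c.quantified),
        "n_background_quantified": sum(1 for c in background if c.quantified),
        "n_direct_same_reference": sum(1 for c in direct if c.same_reference),
        "n_background_same_reference": sum(
            1 for c in background if c.same_reference),
        "n_additive": count(lambda k: k.additivity == "additive"),
        "n_positive": count(lambda k: k.additivity == "positive"),
        "n_negative": count(lambda k: k.additivity == "negative"),
        "n_positive_synergistic": count(
            lambda k: k.additivity == "positive" and k.subclass == "synergistic"),
        "n_positive_antagonistic": count(
            lambda k: k.additivity == "positive" and k.subclass == "antagonistic"),
        "n_positive_mixed": count(
            lambda k: k.additivity == "positive" and k.subclass == "mixed"),
        "n_negative_synergistic": count(
            lambda k: k.additivity == "negative" and k.subclass == "synergistic"),
        "n_negative_antagonistic": count(
            lambda k: k.additivity == "negative" and k.subclass == "antagonistic"),
        "n_negative_mixed": count(
            lambda k: k.additivity == "negative" and k.subclass == "mixed"),
        "n_sign_epistasis": count(lambda k: k.sign_epistasis != "none"),
        "n_sign_stabilizing": count(lambda k: k.sign_epistasis == "stabilizing"),
        "n_sign_destabilizing": count(
            lambda k: k.sign_epistasis == "destabilizing"),
        "n_reciprocal": count(lambda k: k.sign_epistasis.startswith("reciprocal")),
        "n_reciprocal_stab_to_destab": count(
            lambda k: k.sign_epistasis == "reciprocal_stabilizing_to_destabilizing"),
        "n_reciprocal_destab_to_stab": count(
            lambda k: k.sign_epistasis == "reciprocal_destabilizing_to_stabilizing"),
        "ddg_int_min": ddg_int_values[0] if ddg_int_values else None,
        "ddg_int_max": ddg_int_values[-1] if ddg_int_values else None,
    }
    return report
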