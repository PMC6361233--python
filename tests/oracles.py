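"""Independent oracles and tiny entry builders shared by the test suite
and the acceptance script.

Everything here is deliberately written from the definitions — literal
rule tables, exhaustive enumeration, recursive formulations, all-pairs
scans — and stays independent of the code paths it checks.
"""

import math

import numpy as np
from itertools import combinations

from Bio.Align import substitution_matrices
from scipy.spatial.distance import cdist

import skempi2 as sk
from skempi2.cycles import DoubleMutantCycle, EpistasisCall, EpistasisThresholds
from skempi2.io import AffinityMeasurement, Qualifier, SkempiEntry
from skempi2.thermo import R_KCAL

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def mut(chain, num, target="A", wt="K"):
    return sk.MutationSpec(wt if target != wt else "T", chain, num, "", target)


def make_entry(pdb, mutations, ddg_value, reference="R1", kd_wt=1e-9,
               qualifier=Qualifier.EXACT, temperature=298.0, method="SPR"):
    kd_mut = kd_wt * np.exp(ddg_value / (R_KCAL * temperature))
    if qualifier is Qualifier.NON_BINDING:
        mut_aff = AffinityMeasurement(None, qualifier)
    else:
        mut_aff = AffinityMeasurement(kd_mut, qualifier)
    return SkempiEntry(
        pdb_id=pdb, side1=("A",), side2=("B",), mutations=tuple(mutations),
        wt_affinity=AffinityMeasurement(kd_wt, Qualifier.EXACT),
        mut_affinity=mut_aff, temperature=temperature, method=method,
        reference=reference)


def cycle(a, b, ab, quantified=True):
    return DoubleMutantCycle(
        interaction=("1ABC", ()), background=frozenset(),
        mut_a=mut("A", 1), mut_b=mut("A", 2),
        ddg_a=a, ddg_b=b, ddg_ab=ab, quantified=quantified,
        same_reference=True, mixed_temperature=False)


def oracle_classify(a, b, ab, t=EpistasisThresholds()):
    """Literal transcription of the epistasis taxonomy, kept independent of
    the implementation: additivity from the coupling energy, sub-class from
    the single-mutation signs, sign epistasis from the per-mutation
    0.2/0.2/0.4 flip rule."""
    gint = ab - a - b
    if abs(gint) < t.additive:
        add, sub = "additive", "none"
    elif gint < 0:
        add = "positive"
        sub = ("synergistic" if (a < -t.single and b < -t.single) else
               "antagonistic" if (a > t.single and b > t.single) else "mixed")
    else:
        add = "negative"
        sub = ("synergistic" if (a > t.single and b > t.single) else
               "antagonistic" if (a < -t.single and b < -t.single) else "mixed")

    def flips(x, x_bg):
        return (abs(x) > t.single and abs(x_bg) > t.single
                and abs(x - x_bg) > t.flip and (x > 0) != (x_bg > 0))

    fa, fb = flips(a, ab - b), flips(b, ab - a)
    if fa and fb:
        sign = ("reciprocal_stabilizing_to_destabilizing" if a < 0
                else "reciprocal_destabilizing_to_stabilizing")
    elif fa:
        sign = "destabilizing" if ab - b > 0 else "stabilizing"
    elif fb:
        sign = "destabilizing" if ab - a > 0 else "stabilizing"
    else:
        sign = "none"
    return EpistasisCall(add, sub, sign)


def recursive_interaction_energy(vertex, mutations):
    """Independent oracle: order-n coupling defined recursively as the
    difference of order-(n−1) couplings across the last mutation."""
    mutations = list(mutations)
    if len(mutations) == 1:
        return vertex[frozenset(mutations)] - vertex[frozenset()]
    last = mutations[-1]
    rest = mutations[:-1]
    with_bg = {
        frozenset(s): vertex[frozenset(s) | {last}]
        for r in range(len(rest) + 1) for s in combinations(rest, r)}
    without = {
        frozenset(s): vertex[frozenset(s)]
        for r in range(len(rest) + 1) for s in combinations(rest, r)}
    return (recursive_interaction_energy(with_bg, rest)
            - recursive_interaction_energy(without, rest))


def brute_force_best_score(a, b, open_=-10.0, ext=-0.5):
    """Exhaustive enumeration over all global alignments (affine gaps).

    Recursion over all monotone edit paths, carrying the running score and
    the previous move so gap openings and extensions are charged exactly;
    independent of any dynamic-programming shortcut.
    """
    best = -math.inf

    def rec(i, j, score, prev):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + BLOSUM62[a[i], b[j]], "M")
        if i < len(a):
            rec(i + 1, j, score + (ext if prev == "gb" else open_), "gb")
        if j < len(b):
            rec(i, j + 1, score + (ext if prev == "ga" else open_), "ga")

    rec(0, 0, 0.0, None)
    return best


def brute_force_interface(structure, side1, side2, cutoff=10.0):
    """O(n²) all-pairs heavy-atom distance oracle for interface residues."""
    model = next(iter(structure))

    def atoms(side):
        return [((c.id, r.id[1], r.id[2].strip()), a.coord)
                for c in model if c.id in set(side)
                for r in c if r.id[0] == " "
                for a in r if a.element != "H"]

    a1, a2 = atoms(side1), atoms(side2)
    if not a1 or not a2:
        return set(), set()
    d = cdist(np.array([x for _, x in a1]), np.array([x for _, x in a2]))
    hit = d <= cutoff
    s1 = {rid for k, (rid, _) in enumerate(a1) if hit[k, :].any()}
    s2 = {rid for k, (rid, _) in enumerate(a2) if hit[:, k].any()}
    return s1, s2
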