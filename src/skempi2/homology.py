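"""Pairwise protein homology and shared-binding-site clustering.

Two proteins are homologous when their global alignment score exceeds a
threshold and their percent identity (over aligned non-gap columns) is at
least 30%.  Two interactions are homologous when they have a shared or
homologous binding partner and at least 70% of the corresponding
interface residues are common to both; the transitive closure of this
relation partitions the dataset into clusters.

The alignment engine is Needleman–Wunsch with affine gap penalties
(BLOSUM62, gap open 10, extension 0.5).  The score threshold is
configuration: raw alignment scores are not portable across scoring
schemes, so the default of 50 is a calibration under these parameters
(identical sequences of realistic length exceed it by orders of
magnitude, unrelated random sequences fall far below).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Hashable, Mapping, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentResult",
    "InteractionCluster",
    "global_align",
    "are_homologous",
    "shared_binding_site",
    "cluster_interactions",
    "SCORE_THRESHOLD",
    "IDENTITY_THRESHOLD",
    "SHARED_SITE_THRESHOLD",
]

SCORE_THRESHOLD = 50.0
IDENTITY_THRESHOLD = 30.0       # percent
SHARED_SITE_THRESHOLD = 0.70

_VALID = set("ACDEFGHIKLMNPQRSTVWYBZX")


def _aligner(open_gap: float = 10.0, extend_gap: float = 0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -extend_gap
    return aligner


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    percent_identity: float
    #: monotone list of aligned (index_in_a, index_in_b) pairs
    position_map: tuple[tuple[int, int], ...]


def global_align(
    seq_a: str,
    seq_b: str,
    open_gap: float = 10.0,
    extend_gap: float = 0.5,
) -> AlignmentResult:
    """Optimal global alignment of two amino-acid sequences.

    Ties between co-optimal alignments break deterministically (the
    engine's first reported alignment).
    """
    for seq in (seq_a, seq_b):
        if not seq:
            raise ValueError("sequences must be non-empty")
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"invalid sequence characters: {sorted(bad)}")
    aligner = _aligner(open_gap, extend_gap)
    alignment = aligner.align(seq_a, seq_b)[0]
    a_row, b_row = str(alignment[0]), str(alignment[1])
    pairs = []
    ia = ib = 0
    matches = 0
    aligned_cols = 0
    for ca, cb in zip(a_row, b_row):
        if ca != "-" and cb != "-":
            pairs.append((ia, ib))
            aligned_cols += 1
            matches += ca == cb
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    identity = 100.0 * matches / aligned_cols if aligned_cols else 0.0
    return AlignmentResult(a_row, b_row, float(alignment.score), identity,
                           tuple(pairs))


def are_homologous(
    seq_a: str,
    seq_b: str,
    score_threshold: float = SCORE_THRESHOLD,
    identity_threshold: float = IDENTITY_THRESHOLD,
) -> bool:
    """Score > threshold AND percent identity ≥ threshold."""
    result = global_align(seq_a, seq_b)
    return (result.score > score_threshold
            and result.percent_identity >= identity_threshold)


def shared_binding_site(
    interface_a: set[int],
    interface_b: set[int],
    position_map: Sequence[tuple[int, int]],
) -> Optional[float]:
    """Fraction of corresponding interface residues common to both.

    ``interface_a``/``interface_b`` are 0-based sequence positions of the
    interface residues on the shared (or homologous) partner of each
    interaction; ``position_map`` aligns partner A positions to partner B
    positions.  The denominator is the smaller interface set; returns
    ``None`` when either set is empty.
    """
    if not interface_a or not interface_b:
        return None
    mapped = {j for i, j in position_map if i in interface_a}
    common = mapped & interface_b
    return len(common) / min(len(interface_a), len(interface_b))


@dataclass
class InteractionCluster:
    members: tuple[Hashable, ...]
    label: Optional[str] = None  # carried from manual assignment, never computed


def _interactions_homologous(
    sides_a: Mapping[str, str],
    sides_b: Mapping[str, str],
    ifaces_a: Mapping[str, set[int]],
    ifaces_b: Mapping[str, set[int]],
    score_threshold: float,
    identity_threshold: float,
    site_threshold: float,
) -> bool:
    for ka, seq_a in sides_a.items():
        for kb, seq_b in sides_b.items():
            if seq_a == seq_b:
                result = None
                homolog = True
            else:
                result = global_align(seq_a, seq_b)
                homolog = (result.score > score_threshold
                           and result.percent_identity >= identity_threshold)
            if not homolog:
                continue
            pmap = (result.position_map if result is not None
                    else tuple((i, i) for i in range(len(seq_a))))
            frac = shared_binding_site(
                ifaces_a.get(ka, set()), ifaces_b.get(kb, set()), pmap)
            if frac is not None and frac >= site_threshold:
                return True
    return False


def cluster_interactions(
    sequences: Mapping[Hashable, Mapping[str, str]],
    interfaces: Mapping[Hashable, Mapping[str, set[int]]],
    score_threshold: float = SCORE_THRESHOLD,
    identity_threshold: float = IDENTITY_THRESHOLD,
    site_threshold: float = SHARED_SITE_THRESHOLD,
    labels: Optional[Mapping[Hashable, str]] = None,
) -> list[InteractionCluster]:
    """Single-linkage clustering of homologous interactions.

    ``sequences[iid]`` maps each side of interaction ``iid`` (any side
    key, e.g. a chain-group name) to its amino-acid sequence;
    ``interfaces[iid]`` maps the same side keys to 0-based interface
    residue positions on that side's sequence.  The pairwise relation
    (shared/homologous partner with ≥ ``site_threshold`` common
    corresponding interface residues) is closed transitively; the result
    is a partition, independent of input order.  Optional ``labels``
    (manual category names) are carried onto clusters when all labelled
    members agree.
    """
    ids = sorted(sequences, key=repr)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry, key=repr)] = min(rx, ry, key=repr)

    for a, b in combinations(ids, 2):
        if _interactions_homologous(
            sequences[a], sequences[b], interfaces.get(a, {}),
            interfaces.get(b, {}), score_threshold, identity_threshold,
            site_threshold,
        ):
            union(a, b)

    groups: dict[Hashable, list[Hashable]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    clusters = []
    for root in sorted(groups, key=repr):
        members = tuple(groups[root])
        label = None
        if labels:
            seen = {labels[m] for m in members if m in labels}
            if len(seen) == 1:
                label = next(iter(seen))
        clusters.append(InteractionCluster(members, label))
    return clusters
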