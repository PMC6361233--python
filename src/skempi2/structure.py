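"""Structure cleaning and residue-burial classification.

A complex is split into two chain groups (the interacting sides).
Cleaned structures keep only the chains of interest, renumbered from 1,
plus waters/heteroatoms with a heavy atom within a retention radius of a
chain of interest.  Interface residues are those with a heavy atom within
10 Å of the partner side.  Each residue is classified from its relative
solvent accessibility (rASA = SASA / residue-type maximum) computed in
the unbound monomer and in the complex:

    ΔrASA = 0:  interior (INT) if buried in the monomer, else surface (SUR)
    ΔrASA > 0:  support (SUP) if mostly buried when unbound,
                core (COR) if exposed when unbound but buried on binding,
                rim (RIM) otherwise

SASA uses the Shrake–Rupley method (probe 1.4 Å, 960 sphere points per
atom, heavy atoms only).
"""

from __future__ import annotations

import copy
import io as _io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

from Bio.PDB import PDBParser, PDBIO, NeighborSearch, Select
from Bio.PDB.SASA import ShrakeRupley
from Bio.PDB.Polypeptide import is_aa
from Bio.Data.PDBData import protein_letters_3to1

from .io import SkempiEntry, ValidationIssue

__all__ = [
    "MAX_ASA",
    "BURIAL_THRESHOLD",
    "ResidueLocation",
    "CleanedStructure",
    "load_structure",
    "clean_structure",
    "interface_residues",
    "relative_sasa",
    "location_label",
    "classify_locations",
    "annotate_entries",
    "chain_sequences",
]

#: theoretical maximum accessible surface area per residue (Å²),
#: Gly-X-Gly reference conformation (Tien et al. 2013, theoretical set)
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
_GENERIC_MAX_ASA = sum(MAX_ASA.values()) / len(MAX_ASA)

#: rASA below which a residue counts as buried in the five-class scheme
BURIAL_THRESHOLD = 0.25

#: ΔrASA above which a residue counts as losing area upon binding
_DRASA_EPS = 1e-6

_SASA_N_POINTS = 960
_SASA_PROBE = 1.4

ResidueId = tuple[str, int, str]  # (chain, resnum, icode)


@dataclass(frozen=True)
class ResidueLocation:
    residue: ResidueId
    resname: str
    rasa_monomer: float
    rasa_complex: float
    label: str  # INT | SUR | SUP | COR | RIM
    flagged: bool = False  # unknown residue type or missing atoms


@dataclass
class CleanedStructure:
    structure: object  # Bio.PDB Structure (cleaned)
    pdb_text: str
    #: original (chain, resnum, icode) -> new (chain, index)
    forward_map: dict[ResidueId, tuple[str, int]]
    #: new (chain, index) -> original (chain, resnum, icode)
    backward_map: dict[tuple[str, int], ResidueId]


def load_structure(source: str | Path, name: str = "complex"):
    """Parse PDB-format text or a file path into a Bio.PDB structure."""
    parser = PDBParser(QUIET=True)
    if isinstance(source, str) and "\n" in source:
        return parser.get_structure(name, _io.StringIO(source))
    return parser.get_structure(name, str(source))


def _model(structure):
    return next(iter(structure))


def _heavy_atoms(residue):
    return [a for a in residue.get_atoms() if a.element != "H"]


def _res_id(chain_id: str, residue) -> ResidueId:
    _, resnum, icode = residue.id
    return (chain_id, resnum, icode.strip())


def clean_structure(
    pdb_source: str | Path,
    side1: Sequence[str],
    side2: Sequence[str],
    retain_radius: float = 5.0,
) -> CleanedStructure:
    """Produce a cleaned structure for one interaction.

    Keeps the polymer residues of ``side1`` and ``side2`` (renumbered
    consecutively from 1 per chain, insertion codes removed) and any
    water or heteroatom residue anywhere in the file with a heavy atom
    within ``retain_radius`` Å of a chain-of-interest heavy atom; the
    retained heteroatoms continue the numbering of the chain they follow.
    Alternate locations collapse to the highest-occupancy conformer.
    """
    structure = load_structure(pdb_source)
    model = _model(structure)
    chains = set(side1) | set(side2)
    missing = chains - {c.id for c in model}
    if missing:
        raise ValueError(f"chains missing from structure: {sorted(missing)}")

    polymer_atoms = [
        a
        for chain in model if chain.id in chains
        for res in chain if res.id[0] == " "
        for a in _heavy_atoms(res)
    ]
    search = NeighborSearch(polymer_atoms)

    def keep_het(res) -> bool:
        return any(
            search.search(a.coord, retain_radius, level="A")
            for a in _heavy_atoms(res)
        )

    from Bio.PDB.StructureBuilder import StructureBuilder

    builder = StructureBuilder()
    builder.init_structure("cleaned")
    builder.init_model(0)
    forward: dict[ResidueId, tuple[str, int]] = {}
    backward: dict[tuple[str, int], ResidueId] = {}

    def copy_residue(res, new_id):
        new_res = res.copy()
        # collapse disorder: residue.copy() keeps DisorderedAtom wrappers;
        # replace each with its highest-occupancy conformer
        for atom in list(new_res):
            if atom.is_disordered():
                best = max(atom.disordered_get_list(), key=lambda a: a.occupancy)
                best = best.copy()
                best.disordered_flag = 0
                best.set_altloc(" ")
                new_res.detach_child(atom.id)
                new_res.add(best)
        new_res.id = new_id
        new_res.segid = ""
        return new_res

    for chain in model:
        if chain.id not in chains:
            continue
        new_chain_residues = []
        index = 0
        for res in chain:
            if res.id[0] != " ":
                continue
            index += 1
            orig = _res_id(chain.id, res)
            forward[orig] = (chain.id, index)
            backward[(chain.id, index)] = orig
            new_chain_residues.append(copy_residue(res, (" ", index, " ")))
        for res in chain:
            if res.id[0] == " " or not keep_het(res):
                continue
            index += 1
            new_chain_residues.append(copy_residue(res, (res.id[0], index, " ")))
        if new_chain_residues:
            builder.init_chain(chain.id)
            for r in new_chain_residues:
                builder.chain.add(r)
    # heteroatoms on chains outside the selection that pass the radius rule
    extra = []
    for chain in model:
        if chain.id in chains:
            continue
        for res in chain:
            if res.id[0] != " " and keep_het(res):
                extra.append((chain.id, res))
    if extra:
        for chain_id in sorted({c for c, _ in extra}):
            builder.init_chain(chain_id)
            index = 0
            for c, res in extra:
                if c != chain_id:
                    continue
                index += 1
                builder.chain.add(copy_residue(res, (res.id[0], index, " ")))

    cleaned = builder.get_structure()
    io = PDBIO()
    io.set_structure(cleaned)
    buf = _io.StringIO()
    io.save(buf)
    return CleanedStructure(cleaned, buf.getvalue(), forward, backward)


def interface_residues(
    structure,
    side1: Sequence[str],
    side2: Sequence[str],
    cutoff: float = 10.0,
) -> tuple[set[ResidueId], set[ResidueId]]:
    """Residues with a heavy atom within ``cutoff`` Å of the partner side."""
    if isinstance(structure, (str, Path)):
        structure = load_structure(structure)
    model = _model(structure)

    def side_atoms(side):
        return [
            (chain.id, res, a)
            for chain in model if chain.id in set(side)
            for res in chain if res.id[0] == " "
            for a in _heavy_atoms(res)
        ]

    atoms1, atoms2 = side_atoms(side1), side_atoms(side2)
    out1: set[ResidueId] = set()
    out2: set[ResidueId] = set()
    if not atoms1 or not atoms2:
        return out1, out2
    search2 = NeighborSearch([a for _, _, a in atoms2])
    for chain_id, res, atom in atoms1:
        if search2.search(atom.coord, cutoff, level="A"):
            out1.add(_res_id(chain_id, res))
    search1 = NeighborSearch([a for _, _, a in atoms1])
    for chain_id, res, atom in atoms2:
        if search1.search(atom.coord, cutoff, level="A"):
            out2.add(_res_id(chain_id, res))
    return out1, out2


def _context_copy(structure, chains: Optional[set[str]]):
    """Deep copy restricted to polymer heavy atoms of selected chains."""
    model = copy.deepcopy(_model(structure))
    for chain in list(model):
        if chains is not None and chain.id not in chains:
            model.detach_child(chain.id)
            continue
        for res in list(chain):
            if res.id[0] != " ":
                chain.detach_child(res.id)
                continue
            for atom in list(res):
                if atom.element == "H":
                    res.detach_child(atom.id)
        if len(chain) == 0:
            model.detach_child(chain.id)
    return model


def relative_sasa(
    structure,
    chains: Optional[Sequence[str]] = None,
    n_points: int = _SASA_N_POINTS,
    probe_radius: float = _SASA_PROBE,
) -> dict[ResidueId, tuple[float, float, bool]]:
    """Per-residue (SASA Å², rASA, flagged) in the given chain context.

    ``chains=None`` uses the whole assembly.  rASA divides by the
    residue-type maximum; unknown residue types use a generic maximum and
    are flagged.
    """
    if isinstance(structure, (str, Path)):
        structure = load_structure(structure)
    model = _context_copy(structure, set(chains) if chains is not None else None)
    sr = ShrakeRupley(probe_radius=probe_radius, n_points=n_points)
    sr.compute(model, level="R")
    out: dict[ResidueId, tuple[float, float, bool]] = {}
    for chain in model:
        for res in chain:
            flagged = res.resname not in MAX_ASA
            max_asa = MAX_ASA.get(res.resname, _GENERIC_MAX_ASA)
            out[_res_id(chain.id, res)] = (res.sasa, res.sasa / max_asa, flagged)
    return out


def location_label(
    rasa_monomer: float,
    rasa_complex: float,
    burial_threshold: float = BURIAL_THRESHOLD,
) -> str:
    """Five-class burial label from monomer/complex rASA (see module doc)."""
    drasa = rasa_monomer - rasa_complex
    if drasa <= _DRASA_EPS:
        return "INT" if rasa_monomer < burial_threshold else "SUR"
    if rasa_monomer < burial_threshold:
        return "SUP"
    if rasa_complex < burial_threshold:
        return "COR"
    return "RIM"


def classify_locations(
    structure,
    side1: Sequence[str],
    side2: Sequence[str],
    burial_threshold: float = BURIAL_THRESHOLD,
) -> list[ResidueLocation]:
    """Five-class burial location for every polymer residue.

    Monomer rASA is computed for each side alone; complex rASA for the
    assembled pair.  See the module docstring for the labelling rule.
    """
    if isinstance(structure, (str, Path)):
        structure = load_structure(structure)
    mono: dict[ResidueId, tuple[float, float, bool]] = {}
    mono.update(relative_sasa(structure, side1))
    mono.update(relative_sasa(structure, side2))
    comp = relative_sasa(structure, tuple(side1) + tuple(side2))

    model = _model(structure)
    out: list[ResidueLocation] = []
    for chain in model:
        if chain.id not in set(side1) | set(side2):
            continue
        for res in chain:
            if res.id[0] != " ":
                continue
            rid = _res_id(chain.id, res)
            _, r_mono, flagged = mono[rid]
            _, r_comp, _ = comp[rid]
            out.append(ResidueLocation(
                rid, res.resname, r_mono, r_comp,
                location_label(r_mono, r_comp, burial_threshold), flagged))
    return out


def annotate_entries(
    entries: Sequence[SkempiEntry],
    pdb_dir: str | Path,
    burial_threshold: float = BURIAL_THRESHOLD,
) -> tuple[list[SkempiEntry], list[ValidationIssue], dict]:
    """Attach per-mutation location labels from structures in a directory.

    Expects ``<pdb_id>.pdb`` files (case-insensitive).  Entries whose
    structure or residue cannot be found are passed through unlabelled
    with a reported issue.  Returns the annotated entries, the issues,
    and a tabulation of single- and double-mutation location
    combinations.
    """
    pdb_dir = Path(pdb_dir)
    cache: dict[tuple, Optional[dict[ResidueId, str]]] = {}
    annotated: list[SkempiEntry] = []
    issues: list[ValidationIssue] = []
    singles: dict[str, int] = {}
    doubles: dict[tuple[str, str], int] = {}

    for i, entry in enumerate(entries):
        key = (entry.pdb_id.upper(), entry.side1, entry.side2)
        if key not in cache:
            path = None
            for cand in (f"{entry.pdb_id}.pdb", f"{entry.pdb_id.upper()}.pdb",
                         f"{entry.pdb_id.lower()}.pdb"):
                if (pdb_dir / cand).exists():
                    path = pdb_dir / cand
                    break
            if path is None:
                cache[key] = None
            else:
                locs = classify_locations(path, entry.side1, entry.side2,
                                          burial_threshold)
                cache[key] = {l.residue: l.label for l in locs}
        labels_by_res = cache[key]
        if labels_by_res is None:
            issues.append(ValidationIssue(
                i, "#Pdb", "missing_structure", "warning",
                f"no PDB file for {entry.pdb_id} in {pdb_dir}"))
            annotated.append(entry)
            continue
        labels = []
        ok = True
        for m in entry.mutations:
            label = labels_by_res.get((m.chain, m.resnum, m.icode))
            if label is None:
                issues.append(ValidationIssue(
                    i, "Mutation(s)_PDB", "residue_not_in_structure", "warning",
                    f"residue {m.chain}{m.resnum}{m.icode} absent from "
                    f"{entry.pdb_id}"))
                ok = False
                break
            labels.append(label)
        if not ok:
            annotated.append(entry)
            continue
        annotated.append(replace(entry, location_labels=tuple(labels)))
        if len(labels) == 1:
            singles[labels[0]] = singles.get(labels[0], 0) + 1
        elif len(labels) == 2:
            combo = tuple(sorted(labels))
            doubles[combo] = doubles.get(combo, 0) + 1

    summary = {
        "single_mutation_locations": dict(sorted(singles.items())),
        "double_mutation_locations": {
            "/".join(k): v for k, v in sorted(doubles.items())
        },
        "n_labelled": sum(1 for e in annotated if e.location_labels),
        "n_skipped": len(entries) - sum(
            1 for e in annotated if e.location_labels),
    }
    return annotated, issues, summary


def chain_sequences(structure) -> dict[str, str]:
    """One-letter sequence of each polymer chain (unknown residues → X)."""
    if isinstance(structure, (str, Path)):
        structure = load_structure(structure)
    out: dict[str, str] = {}
    for chain in _model(structure):
        seq = "".join(
            protein_letters_3to1.get(res.resname, "X")
            for res in chain if res.id[0] == " " and is_aa(res, standard=False)
        )
        if seq:
            out[chain.id] = seq
    return out
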