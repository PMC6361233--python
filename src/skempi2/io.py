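"""Reading, validation and writing of SKEMPI-2.0-format mutation tables.

A table has one row per curated measurement: the PDB complex and its two
interacting chain groups, the mutation list, wild-type and mutant
dissociation constants (molar), the temperature, the experimental method,
and optional kinetic (kon, koff) and thermodynamic (dH, dS) observables.
The first column combines structure and chain partition as
``<pdb>_<side1>_<side2>`` (e.g. ``1CSE_E_I``); mutations are encoded as
``<wtAA><chain><resnum><icode?><mutAA>`` tokens joined by commas
(e.g. ``KI15A,TI17R``).  Affinities may carry a leading ``>`` or ``<``
when only a limit could be measured, or a non-binding marker (``n.b.``)
when the mutation abolishes detectable binding.
"""

from __future__ import annotations

import csv
import io as _io
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "AA_ALPHABET",
    "Qualifier",
    "AffinityMeasurement",
    "MutationSpec",
    "SkempiEntry",
    "ValidationIssue",
    "ParseResult",
    "parse_affinity_field",
    "parse_mutation_string",
    "parse_skempi_table",
    "write_skempi_table",
    "summarize_composition",
    "entry_key",
    "MutationParseError",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: markers accepted (case-insensitively) for "binding not detectable"
NON_BINDING_TOKENS = ("n.b.", "n.b", "nb", "no binding", "non-binding")

DEFAULT_TEMPERATURE = 298.0


class Qualifier(str, Enum):
    EXACT = "exact"
    GREATER_THAN = "greater_than"
    LESS_THAN = "less_than"
    NON_BINDING = "non_binding"
    UNPARSEABLE = "unparseable"


@dataclass(frozen=True)
class AffinityMeasurement:
    """A dissociation constant with its qualifier.

    ``kd`` is in molar and present exactly when the qualifier is not
    ``non_binding``/``unparseable``.  A non-binding entry may carry a
    ``detection_limit`` (molar) usable as a lower bound on the mutant KD.
    """

    kd: Optional[float]
    qualifier: Qualifier
    detection_limit: Optional[float] = None
    raw_text: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.qualifier in (Qualifier.NON_BINDING, Qualifier.UNPARSEABLE):
            if self.kd is not None:
                raise ValueError(f"kd must be absent for {self.qualifier} affinity")
        else:
            if self.kd is None or not self.kd > 0:
                raise ValueError("kd must be a positive number")

    @property
    def is_exact(self) -> bool:
        return self.qualifier is Qualifier.EXACT


_MUTATION_RE = re.compile(
    rf"^([{AA_ALPHABET}])([A-Za-z0-9])(-?\d+)([a-z]?)([{AA_ALPHABET}])$"
)


class MutationParseError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class MutationSpec:
    """One point substitution: wild-type residue, chain, PDB residue number,
    optional insertion code and target residue."""

    wt_aa: str
    chain: str
    resnum: int
    icode: str
    mut_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa not in AA_ALPHABET or self.mut_aa not in AA_ALPHABET:
            raise MutationParseError(
                f"amino acids must be one of {AA_ALPHABET}: {self.wt_aa}/{self.mut_aa}"
            )
        if self.wt_aa == self.mut_aa:
            raise MutationParseError(
                f"wild-type and mutant residue identical: {self}"
            )
        if len(self.chain) != 1:
            raise MutationParseError(f"chain must be one character: {self.chain!r}")

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.chain}{self.resnum}{self.icode}{self.mut_aa}"


def parse_mutation_string(text: str) -> list[MutationSpec]:
    """Parse a comma-separated mutation list, order preserved."""
    if not text or not text.strip():
        raise MutationParseError("empty mutation string")
    specs = []
    for token in text.split(","):
        token = token.strip()
        m = _MUTATION_RE.match(token)
        if m is None:
            raise MutationParseError(f"unrecognized mutation token {token!r}")
        wt, chain, resnum, icode, mut = m.groups()
        specs.append(MutationSpec(wt, chain, int(resnum), icode, mut))
    return specs


_FLOAT_RE = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")


def parse_affinity_field(text: str) -> AffinityMeasurement:
    """Parse one affinity cell into an :class:`AffinityMeasurement`.

    Accepts plain/scientific notation, a leading ``>`` or ``<`` for a
    limit, and non-binding markers; ``n.b. (2E-5)`` keeps the detection
    limit. Unrecognized text yields the ``unparseable`` qualifier rather
    than raising, so callers can report the row.
    """
    raw = text
    s = text.strip()
    if not s:
        return AffinityMeasurement(None, Qualifier.UNPARSEABLE, raw_text=raw)
    low = s.lower()
    for token in NON_BINDING_TOKENS:
        if low.startswith(token):
            rest = s[len(token):]
            m = _FLOAT_RE.search(rest)
            limit = float(m.group()) if m else None
            if limit is not None and limit <= 0:
                limit = None
            return AffinityMeasurement(
                None, Qualifier.NON_BINDING, detection_limit=limit, raw_text=raw
            )
    qualifier = Qualifier.EXACT
    if s[0] == ">":
        qualifier = Qualifier.GREATER_THAN
        s = s[1:].strip()
    elif s[0] == "<":
        qualifier = Qualifier.LESS_THAN
        s = s[1:].strip()
    try:
        kd = float(s)
    except ValueError:
        return AffinityMeasurement(None, Qualifier.UNPARSEABLE, raw_text=raw)
    if kd <= 0:
        return AffinityMeasurement(None, Qualifier.UNPARSEABLE, raw_text=raw)
    return AffinityMeasurement(kd, qualifier, raw_text=raw)


@dataclass
class SkempiEntry:
    """One curated measurement row."""

    pdb_id: str
    side1: tuple[str, ...]
    side2: tuple[str, ...]
    mutations: tuple[MutationSpec, ...]
    wt_affinity: AffinityMeasurement
    mut_affinity: AffinityMeasurement
    temperature: float = DEFAULT_TEMPERATURE
    method: str = ""
    reference: str = ""
    mutations_cleaned: Optional[tuple[MutationSpec, ...]] = None
    kon_wt: Optional[float] = None
    kon_mut: Optional[float] = None
    koff_wt: Optional[float] = None
    koff_mut: Optional[float] = None
    dh_wt: Optional[float] = None
    dh_mut: Optional[float] = None
    ds_wt: Optional[float] = None
    ds_mut: Optional[float] = None
    notes: str = ""
    location_labels: Optional[tuple[str, ...]] = None
    cluster_id: Optional[str] = None
    temperature_text: Optional[str] = field(default=None, compare=False)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if set(self.side1) & set(self.side2):
            raise ValueError("side1 and side2 must be disjoint")
        if not self.mutations:
            raise ValueError("at least one mutation required")
        chains = set(self.side1) | set(self.side2)
        for mspec in self.mutations:
            if mspec.chain not in chains:
                raise ValueError(
                    f"mutation {mspec} names chain {mspec.chain!r} outside "
                    f"sides {self.side1}/{self.side2}"
                )

    @property
    def is_single_point(self) -> bool:
        return len(self.mutations) == 1

    @property
    def has_kinetics(self) -> bool:
        return None not in (self.kon_wt, self.kon_mut, self.koff_wt, self.koff_mut)

    @property
    def has_thermodynamics(self) -> bool:
        return None not in (self.dh_wt, self.dh_mut, self.ds_wt, self.ds_mut)

    @property
    def is_qualified(self) -> bool:
        """True if either affinity is an inequality or non-binding."""
        return not (self.wt_affinity.is_exact and self.mut_affinity.is_exact)


def entry_key(entry: SkempiEntry) -> tuple:
    """Uniqueness key: (pdb, unordered side partition, canonical mutation set)."""
    sides = tuple(sorted((tuple(sorted(entry.side1)), tuple(sorted(entry.side2)))))
    muts = tuple(sorted(entry.mutations))
    return (entry.pdb_id.upper(), sides, muts)


@dataclass(frozen=True)
class ValidationIssue:
    row: int  # 0-based data-row index; -1 for table-level issues
    column: str
    code: str
    severity: str  # "warning" | "error" | "fatal"
    message: str


@dataclass
class ParseResult:
    entries: list[SkempiEntry]
    issues: list[ValidationIssue]
    delimiter: str = ";"

    @property
    def n_dropped(self) -> int:
        return sum(1 for i in self.issues if i.severity == "error")


# canonical column set; aliases are matched after lower-casing and stripping
_COLUMNS = [
    "#Pdb",
    "Mutation(s)_PDB",
    "Mutation(s)_cleaned",
    "Affinity_mut (M)",
    "Affinity_wt (M)",
    "Reference",
    "Temperature",
    "kon_mut (M^(-1)s^(-1))",
    "kon_wt (M^(-1)s^(-1))",
    "koff_mut (s^(-1))",
    "koff_wt (s^(-1))",
    "dH_mut (kcal mol^(-1))",
    "dH_wt (kcal mol^(-1))",
    "dS_mut (cal mol^(-1) K^(-1))",
    "dS_wt (cal mol^(-1) K^(-1))",
    "Method",
    "Notes",
    "Location(s)",
    "Cluster",
]

_MANDATORY = {"#Pdb", "Mutation(s)_PDB", "Affinity_mut (M)", "Affinity_wt (M)"}


def _canon_col(name: str) -> str:
    return re.sub(r"[^a-z0-9#]+", "", name.lower())


_ALIASES = {_canon_col(c): c for c in _COLUMNS}
# a few tolerated spellings
_ALIASES.update(
    {
        "#pdb": "#Pdb",
        "pdb": "#Pdb",
        "mutationspdb": "Mutation(s)_PDB",
        "mutationscleaned": "Mutation(s)_cleaned",
        "affinitymutm": "Affinity_mut (M)",
        "affinitywtm": "Affinity_wt (M)",
        "temperaturek": "Temperature",
        "locations": "Location(s)",
    }
)


def _sniff_delimiter(header_line: str) -> str:
    return ";" if header_line.count(";") >= header_line.count(",") else ","


def _opt_float(
    cell: str, row: int, col: str, issues: list[ValidationIssue]
) -> Optional[float]:
    cell = (cell or "").strip()
    if not cell:
        return None
    try:
        value = float(cell)
    except ValueError:
        issues.append(
            ValidationIssue(row, col, "malformed_numeric", "warning",
                            f"cannot parse {cell!r} as a number; treated as missing")
        )
        return None
    return value


def _parse_temperature(
    cell: str, row: int, issues: list[ValidationIssue]
) -> tuple[float, Optional[str]]:
    raw = (cell or "").strip()
    if not raw:
        issues.append(
            ValidationIssue(row, "Temperature", "missing_temperature", "warning",
                            f"missing temperature; defaulting to {DEFAULT_TEMPERATURE} K")
        )
        return DEFAULT_TEMPERATURE, None
    m = _FLOAT_RE.search(raw)
    if m is None or float(m.group()) <= 0:
        issues.append(
            ValidationIssue(row, "Temperature", "malformed_numeric", "warning",
                            f"cannot parse temperature {raw!r}; defaulting to "
                            f"{DEFAULT_TEMPERATURE} K")
        )
        return DEFAULT_TEMPERATURE, raw
    return float(m.group()), (raw if m.group() != raw else None)


def parse_skempi_table(source: str | Path | _io.TextIOBase) -> ParseResult:
    """Parse a SKEMPI-format delimited table.

    ``source`` may be a path, a block of text containing at least one
    newline, or an open text stream.  The delimiter (comma or semicolon)
    is sniffed from the header row.  Rows whose mandatory fields cannot be
    parsed are reported as ``error`` issues and excluded from ``entries``;
    recoverable anomalies become ``warning`` issues.  Row order is
    preserved.

    Raises
    ------
    ValueError
        If a mandatory column is missing from the header (fatal
        configuration error).
    """
    if isinstance(source, _io.TextIOBase):
        text = source.read()
    else:
        if isinstance(source, str) and "\n" in source:
            text = source
        else:
            text = Path(source).read_text()
    lines = text.splitlines()
    if not lines:
        raise ValueError("empty table: no header row")
    delimiter = _sniff_delimiter(lines[0])
    reader = csv.reader(_io.StringIO(text), delimiter=delimiter)
    header = next(reader)
    colmap: dict[int, str] = {}
    known = set()
    for i, name in enumerate(header):
        canon = _ALIASES.get(_canon_col(name))
        if canon is not None and canon not in known:
            colmap[i] = canon
            known.add(canon)
        else:
            colmap[i] = name  # passthrough column, kept verbatim
    missing = _MANDATORY - known
    if missing:
        raise ValueError(f"mandatory columns missing from header: {sorted(missing)}")

    entries: list[SkempiEntry] = []
    issues: list[ValidationIssue] = []
    for row_idx, row in enumerate(reader):
        if not any(cell.strip() for cell in row):
            continue
        cells = {colmap[i]: row[i] for i in range(min(len(row), len(header)))}
        entry = _parse_row(cells, row_idx, issues)
        if entry is not None:
            entries.append(entry)

    _check_duplicates(entries, issues)
    return ParseResult(entries, issues, delimiter)


def _parse_row(
    cells: dict[str, str], row: int, issues: list[ValidationIssue]
) -> Optional[SkempiEntry]:
    pdb_field = (cells.get("#Pdb") or "").strip()
    parts = pdb_field.split("_")
    if len(parts) != 3 or len(parts[0]) != 4 or not parts[1] or not parts[2]:
        issues.append(
            ValidationIssue(row, "#Pdb", "unparseable_field", "error",
                            f"cannot parse complex identifier {pdb_field!r} "
                            "(expected <pdb>_<side1>_<side2>)")
        )
        return None
    pdb_id, side1, side2 = parts[0], tuple(parts[1]), tuple(parts[2])

    try:
        mutations = tuple(parse_mutation_string(cells.get("Mutation(s)_PDB", "")))
    except MutationParseError as exc:
        issues.append(
            ValidationIssue(row, "Mutation(s)_PDB", "unparseable_field", "error",
                            str(exc))
        )
        return None
    cleaned_text = (cells.get("Mutation(s)_cleaned") or "").strip()
    mutations_cleaned: Optional[tuple[MutationSpec, ...]] = None
    if cleaned_text:
        try:
            mutations_cleaned = tuple(parse_mutation_string(cleaned_text))
        except MutationParseError as exc:
            issues.append(
                ValidationIssue(row, "Mutation(s)_cleaned", "unparseable_field",
                                "warning", str(exc))
            )

    wt_aff = parse_affinity_field(cells.get("Affinity_wt (M)", ""))
    mut_aff = parse_affinity_field(cells.get("Affinity_mut (M)", ""))
    for col, aff in (("Affinity_wt (M)", wt_aff), ("Affinity_mut (M)", mut_aff)):
        if aff.qualifier is Qualifier.UNPARSEABLE:
            issues.append(
                ValidationIssue(row, col, "unparseable_field", "error",
                                f"cannot parse affinity {aff.raw_text!r}")
            )
    if (wt_aff.qualifier is Qualifier.UNPARSEABLE
            or mut_aff.qualifier is Qualifier.UNPARSEABLE):
        return None

    temperature, temp_text = _parse_temperature(cells.get("Temperature", ""), row, issues)

    kwargs = {}
    for col, attr in (
        ("kon_mut (M^(-1)s^(-1))", "kon_mut"),
        ("kon_wt (M^(-1)s^(-1))", "kon_wt"),
        ("koff_mut (s^(-1))", "koff_mut"),
        ("koff_wt (s^(-1))", "koff_wt"),
        ("dH_mut (kcal mol^(-1))", "dh_mut"),
        ("dH_wt (kcal mol^(-1))", "dh_wt"),
        ("dS_mut (cal mol^(-1) K^(-1))", "ds_mut"),
        ("dS_wt (cal mol^(-1) K^(-1))", "ds_wt"),
    ):
        kwargs[attr] = _opt_float(cells.get(col, ""), row, col, issues)
    for rate in ("kon_mut", "kon_wt", "koff_mut", "koff_wt"):
        if kwargs[rate] is not None and kwargs[rate] <= 0:
            issues.append(
                ValidationIssue(row, rate, "unit_anomaly", "warning",
                                f"non-positive rate {kwargs[rate]}; treated as missing")
            )
            kwargs[rate] = None

    loc_text = (cells.get("Location(s)") or "").strip()
    location_labels = tuple(t.strip() for t in loc_text.split(",")) if loc_text else None
    cluster = (cells.get("Cluster") or "").strip() or None
    extra = {
        k: v for k, v in cells.items() if k not in _COLUMNS and (v or "").strip()
    }

    try:
        entry = SkempiEntry(
            pdb_id=pdb_id, side1=side1, side2=side2, mutations=mutations,
            wt_affinity=wt_aff, mut_affinity=mut_aff, temperature=temperature,
            method=(cells.get("Method") or "").strip(),
            reference=(cells.get("Reference") or "").strip(),
            mutations_cleaned=mutations_cleaned,
            notes=(cells.get("Notes") or "").strip(),
            location_labels=location_labels, cluster_id=cluster,
            temperature_text=temp_text, extra=extra, **kwargs,
        )
    except ValueError as exc:
        issues.append(
            ValidationIssue(row, "#Pdb", "invariant_violation", "error", str(exc))
        )
        return None

    if entry.wt_affinity.kd is not None and not (0 < entry.wt_affinity.kd < 10):
        issues.append(
            ValidationIssue(row, "Affinity_wt (M)", "unit_anomaly", "warning",
                            f"wild-type KD {entry.wt_affinity.kd} M outside the "
                            "(0, 10) M sanity range")
        )
    return entry


def _check_duplicates(entries: Sequence[SkempiEntry],
                      issues: list[ValidationIssue]) -> None:
    # replicate measurements legitimately share mutation/reference/method;
    # only a row repeating the same measured affinities as well is suspect
    seen: dict[tuple, int] = {}
    for i, e in enumerate(entries):
        key = entry_key(e) + (
            e.reference, e.method,
            e.wt_affinity.kd, e.wt_affinity.qualifier,
            e.mut_affinity.kd, e.mut_affinity.qualifier,
        )
        if key in seen:
            issues.append(
                ValidationIssue(i, "#Pdb", "duplicate_key", "warning",
                                f"same mutation, source and affinities as row "
                                f"{seen[key]}")
            )
        else:
            seen[key] = i


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _affinity_text(aff: AffinityMeasurement) -> str:
    if aff.qualifier is Qualifier.NON_BINDING:
        if aff.detection_limit is not None:
            return f"n.b. ({_fmt(aff.detection_limit)})"
        return "n.b."
    prefix = {Qualifier.GREATER_THAN: ">", Qualifier.LESS_THAN: "<"}.get(
        aff.qualifier, "")
    return prefix + _fmt(aff.kd)


def write_skempi_table(
    entries: Iterable[SkempiEntry],
    path: Optional[str | Path] = None,
    delimiter: str = ";",
) -> str:
    """Write entries as a SKEMPI-format table; returns the text.

    Round-trips: ``parse_skempi_table(write_skempi_table(E)).entries == E``
    for valid entry lists (floats are written in shortest exact form).
    """
    entries = list(entries)
    extra_cols: list[str] = []
    for e in entries:
        for k in e.extra:
            if k not in extra_cols:
                extra_cols.append(k)
    header = _COLUMNS + extra_cols
    buf = _io.StringIO()
    writer = csv.writer(buf, delimiter=delimiter, lineterminator="\n")
    writer.writerow(header)
    for e in entries:
        row = {
            "#Pdb": f"{e.pdb_id}_{''.join(e.side1)}_{''.join(e.side2)}",
            "Mutation(s)_PDB": ",".join(str(m) for m in e.mutations),
            "Mutation(s)_cleaned": ",".join(str(m) for m in e.mutations_cleaned)
            if e.mutations_cleaned else "",
            "Affinity_mut (M)": _affinity_text(e.mut_affinity),
            "Affinity_wt (M)": _affinity_text(e.wt_affinity),
            "Reference": e.reference,
            "Temperature": e.temperature_text or _fmt(e.temperature),
            "kon_mut (M^(-1)s^(-1))": _fmt(e.kon_mut),
            "kon_wt (M^(-1)s^(-1))": _fmt(e.kon_wt),
            "koff_mut (s^(-1))": _fmt(e.koff_mut),
            "koff_wt (s^(-1))": _fmt(e.koff_wt),
            "dH_mut (kcal mol^(-1))": _fmt(e.dh_mut),
            "dH_wt (kcal mol^(-1))": _fmt(e.dh_wt),
            "dS_mut (cal mol^(-1) K^(-1))": _fmt(e.ds_mut),
            "dS_wt (cal mol^(-1) K^(-1))": _fmt(e.ds_wt),
            "Method": e.method,
            "Notes": e.notes,
            "Location(s)": ",".join(e.location_labels) if e.location_labels else "",
            "Cluster": e.cluster_id or "",
        }
        for k in extra_cols:
            row[k] = e.extra.get(k, "")
        writer.writerow([row[c] for c in header])
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def summarize_composition(entries: Sequence[SkempiEntry]) -> dict:
    """Dataset composition statistics.

    Returns a dict with total/unique entry counts, kinetics- and
    thermodynamics-bearing counts, inequality/non-binding counts, distinct
    PDB codes, the single/multi point split and per-method counts.
    """
    unique = {entry_key(e) for e in entries}
    methods: dict[str, int] = {}
    for e in entries:
        methods[e.method] = methods.get(e.method, 0) + 1
    n_qualified = sum(1 for e in entries if e.is_qualified)
    return {
        "total_entries": len(entries),
        "unique_entries": len(unique),
        "with_kinetics": sum(1 for e in entries if e.has_kinetics),
        "with_thermodynamics": sum(1 for e in entries if e.has_thermodynamics),
        "inequality_or_non_binding": n_qualified,
        "quantified": len(entries) - n_qualified,
        "distinct_pdb": len({e.pdb_id.upper() for e in entries}),
        "single_point": sum(1 for e in entries if e.is_single_point),
        "multi_point": sum(1 for e in entries if not e.is_single_point),
        "per_method": dict(sorted(methods.items())),
    }
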