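"""Binding thermodynamics and kinetics inter-conversion.

Conventions: ΔG = RT·ln(KD) in kcal·mol⁻¹ (negative = favorable binding),
ΔΔG = ΔG(mutant) − ΔG(wild-type) (positive = destabilizing), KD = koff/kon,
ΔG = ΔH − TΔS with ΔH in kcal·mol⁻¹ and ΔS in cal·mol⁻¹·K⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .io import AffinityMeasurement, Qualifier, SkempiEntry

__all__ = [
    "R_KCAL",
    "DEFAULT_CONSISTENCY_TOL",
    "Bound",
    "EnergyRecord",
    "dg_from_kd",
    "ddg",
    "kd_from_rates",
    "dg_from_enthalpy_entropy",
    "delta_log10_rate",
    "complete_entry",
]

#: gas constant, kcal·mol⁻¹·K⁻¹
R_KCAL = 1.9872e-3

#: tolerance (kcal·mol⁻¹) for reported-vs-derived consistency checks;
#: of the order of the typical reported experimental error
DEFAULT_CONSISTENCY_TOL = 0.2


def dg_from_kd(kd: float, temperature: float) -> float:
    """Binding free energy RT·ln(KD), kcal·mol⁻¹."""
    if kd <= 0:
        raise ValueError("KD must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return R_KCAL * temperature * math.log(kd)


def ddg(kd_wt: float, kd_mut: float, temperature: float) -> float:
    """ΔΔG = RT·ln(KD_mut/KD_wt); positive when the mutation destabilizes."""
    if kd_wt <= 0 or kd_mut <= 0:
        raise ValueError("dissociation constants must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return R_KCAL * temperature * math.log(kd_mut / kd_wt)


def kd_from_rates(kon: float, koff: float) -> float:
    """KD = koff/kon (molar)."""
    if kon <= 0 or koff <= 0:
        raise ValueError("rates must be positive")
    return koff / kon


def dg_from_enthalpy_entropy(dh: float, ds: float, temperature: float) -> float:
    """ΔG = ΔH − TΔS; ΔH kcal·mol⁻¹, ΔS cal·mol⁻¹·K⁻¹."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return dh - temperature * ds / 1000.0


def delta_log10_rate(rate_wt: float, rate_mut: float) -> float:
    """log10(rate_mut) − log10(rate_wt)."""
    if rate_wt <= 0 or rate_mut <= 0:
        raise ValueError("rates must be positive")
    return math.log10(rate_mut) - math.log10(rate_wt)


@dataclass(frozen=True)
class Bound:
    """An inequality bound on a derived quantity."""

    value: float
    direction: str  # "greater" | "less"


@dataclass
class EnergyRecord:
    """Derived energetics of one entry.

    ``ddg`` is present exactly when both affinities are exact; otherwise
    any finite inequality bounds derivable from the qualified affinities
    are listed in ``ddg_bounds``.  ``derived_fields`` names every quantity
    that was computed rather than reported.
    """

    temperature: float
    dg_wt: Optional[float] = None
    dg_mut: Optional[float] = None
    ddg: Optional[float] = None
    ddg_bounds: tuple[Bound, ...] = ()
    dlog10_kon: Optional[float] = None
    dlog10_koff: Optional[float] = None
    ddh: Optional[float] = None
    dds: Optional[float] = None
    kd_wt: Optional[float] = None
    kd_mut: Optional[float] = None
    derived_fields: frozenset[str] = frozenset()
    consistency_issues: tuple[str, ...] = ()


def _kd_interval(aff: AffinityMeasurement) -> tuple[float, float]:
    """KD interval (lo, hi) implied by a measurement; inf/0 when open."""
    if aff.qualifier is Qualifier.EXACT:
        return aff.kd, aff.kd
    if aff.qualifier is Qualifier.GREATER_THAN:
        return aff.kd, math.inf
    if aff.qualifier is Qualifier.LESS_THAN:
        return 0.0, aff.kd
    if aff.qualifier is Qualifier.NON_BINDING:
        lo = aff.detection_limit if aff.detection_limit is not None else 0.0
        return lo, math.inf
    return 0.0, math.inf  # unparseable: no information


def complete_entry(
    entry: SkempiEntry, consistency_tol: float = DEFAULT_CONSISTENCY_TOL
) -> EnergyRecord:
    """Fill every derivable energetic quantity for one entry.

    KD is taken from the affinity column when exact, else derived from
    koff/kon when both rates are reported; reported values are never
    overwritten — if both routes exist and disagree by more than
    ``consistency_tol`` (on the ΔG scale), the discrepancy is flagged and
    the reported KD kept.
    """
    T = entry.temperature
    derived: set[str] = set()
    issues: list[str] = []

    def effective_kd(aff: AffinityMeasurement, kon, koff, label: str):
        kd_rates = koff / kon if (kon and koff) else None
        if aff.qualifier is Qualifier.EXACT:
            if kd_rates is not None:
                gap = abs(dg_from_kd(kd_rates, T) - dg_from_kd(aff.kd, T))
                if gap > consistency_tol:
                    issues.append(
                        f"{label}: KD from koff/kon ({kd_rates:.3g} M) disagrees "
                        f"with reported KD ({aff.kd:.3g} M) by {gap:.2f} kcal/mol"
                    )
            return aff.kd
        if kd_rates is not None:
            derived.add(f"kd_{label}")
            return kd_rates
        return None

    kd_wt = effective_kd(entry.wt_affinity, entry.kon_wt, entry.koff_wt, "wt")
    kd_mut = effective_kd(entry.mut_affinity, entry.kon_mut, entry.koff_mut, "mut")

    dg_wt = dg_mut = ddg_val = None
    bounds: list[Bound] = []
    if kd_wt is not None:
        dg_wt = dg_from_kd(kd_wt, T)
        derived.add("dg_wt")
    if kd_mut is not None:
        dg_mut = dg_from_kd(kd_mut, T)
        derived.add("dg_mut")
    if kd_wt is not None and kd_mut is not None:
        ddg_val = ddg(kd_wt, kd_mut, T)
        derived.add("ddg")
    else:
        wt_lo, wt_hi = (kd_wt, kd_wt) if kd_wt is not None \
            else _kd_interval(entry.wt_affinity)
        mut_lo, mut_hi = (kd_mut, kd_mut) if kd_mut is not None \
            else _kd_interval(entry.mut_affinity)
        if mut_lo > 0 and wt_hi not in (0.0, math.inf) and math.isfinite(mut_lo):
            bounds.append(Bound(ddg(wt_hi, mut_lo, T), "greater"))
        if math.isfinite(mut_hi) and wt_lo > 0 and mut_hi > 0:
            bounds.append(Bound(ddg(wt_lo, mut_hi, T), "less"))

    dlog_kon = dlog_koff = None
    if entry.kon_wt and entry.kon_mut:
        dlog_kon = delta_log10_rate(entry.kon_wt, entry.kon_mut)
        derived.add("dlog10_kon")
    if entry.koff_wt and entry.koff_mut:
        dlog_koff = delta_log10_rate(entry.koff_wt, entry.koff_mut)
        derived.add("dlog10_koff")

    ddh = dds = None
    if entry.dh_wt is not None and entry.dh_mut is not None:
        ddh = entry.dh_mut - entry.dh_wt
        derived.add("ddh")
    if entry.ds_wt is not None and entry.ds_mut is not None:
        dds = entry.ds_mut - entry.ds_wt
        derived.add("dds")

    # thermodynamic consistency: ΔH − TΔS should match RT ln KD
    for label, dh, ds, kd in (
        ("wt", entry.dh_wt, entry.ds_wt, kd_wt),
        ("mut", entry.dh_mut, entry.ds_mut, kd_mut),
    ):
        if dh is not None and ds is not None and kd is not None:
            gap = abs(dg_from_enthalpy_entropy(dh, ds, T) - dg_from_kd(kd, T))
            if gap > consistency_tol:
                issues.append(
                    f"{label}: ΔH−TΔS disagrees with RT ln KD by {gap:.2f} kcal/mol"
                )

    return EnergyRecord(
        temperature=T, dg_wt=dg_wt, dg_mut=dg_mut, ddg=ddg_val,
        ddg_bounds=tuple(bounds), dlog10_kon=dlog_kon, dlog10_koff=dlog_koff,
        ddh=ddh, dds=dds, kd_wt=kd_wt, kd_mut=kd_mut,
        derived_fields=frozenset(derived), consistency_issues=tuple(issues),
    )
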