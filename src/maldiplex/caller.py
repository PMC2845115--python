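"""Allele quantification and mutation calling from peak assignments.

Allele fractions are area ratios over the extension products of one assay:
``fraction(base) = area(base) / sum(extension areas)``; the UEP fraction
(``UEP / (UEP + extensions)``) is a per-assay quality metric.  An assay is
called mutant when a mutant extension product carries at least the minimum
allele fraction with adequate signal-to-noise.  Thresholds are explicit,
declared surrogates for the manual review a genotyping analyst performs;
fraction comparisons are made at the two-decimal precision the fractions
are reported at.

Complex codons (several sub-assays interrogating different nucleotide
positions of one codon) are resolved by substituting the called mutant base
into the reference codon and translating with the standard genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from Bio.Seq import Seq

from .errors import ComplexGroupError, NoSignalError
from .panel import Assay, Panel
from .signal import PeakAssignment, process_spectrum
from .simulate import Spectrum

#: decimal places at which allele fractions are reported and thresholded
FRACTION_DECIMALS = 2


@dataclass(frozen=True)
class CallThresholds:
    """Decision thresholds for mutation calling.

    ``min_fraction`` (default 0.05) is the demonstrated detection limit of
    the chemistry: mutant peaks at 5% of the extension area are real and
    reportable.  ``min_snr`` rejects peaks indistinguishable from noise;
    ``max_uep`` fails assays whose extension reaction barely ran.
    """

    min_fraction: float = 0.05
    min_snr: float = 3.0
    max_uep: float = 0.90

    def __post_init__(self) -> None:
        if not (self.min_fraction > 0 and self.min_snr > 0 and self.max_uep > 0):
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class AssayCall:
    """Outcome of one assay on one sample."""

    sample_id: str
    assay_id: str
    status: str  # wildtype | mutant | fail
    mut_base: Optional[str] = None
    aa_change: Optional[str] = None
    fail_reason: Optional[str] = None
    allele_fractions: Mapping[str, float] = field(default_factory=dict)
    uep_fraction: float = 0.0
    snr: Mapping[str, float] = field(default_factory=dict)
    qc_flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class MutationRecord:
    """One reported mutation: sample, gene, amino-acid change, fraction."""

    sample_id: str
    gene: str
    aa_change: str
    fraction: float
    aa_alias: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("mutant allele fraction must be in (0, 1]")

    @property
    def label(self) -> str:
        return f"{self.gene}-{self.aa_change}"


def allele_fractions(
    assignment: PeakAssignment,
) -> tuple[dict[str, float], float]:
    """Per-base allele fractions and UEP fraction from one assay's peaks.

    Unmatched analytes contribute zero area; adduct and background peaks are
    excluded.  With no extension signal but a UEP present, returns an empty
    fraction map and UEP fraction 1.0 (an extension-failure signal for the
    caller).  Raises :class:`NoSignalError` when every analyte is absent.
    """
    uep_area = 0.0
    ext_areas: dict[str, float] = {}
    any_matched = False
    for a in assignment.analytes:
        p = assignment.matched.get(a)
        area = p.area if p is not None else 0.0
        any_matched = any_matched or p is not None
        if a.role == "unextended":
            uep_area += area
        else:
            ext_areas[a.label] = ext_areas.get(a.label, 0.0) + area
    if not any_matched:
        raise NoSignalError("no analyte peak matched for this assay")
    total_ext = sum(ext_areas.values())
    if total_ext <= 0:
        return {}, 1.0
    fractions = {b: area / total_ext for b, area in ext_areas.items()}
    uep_fraction = uep_area / (uep_area + total_ext)
    return fractions, uep_fraction


def call_assay(
    sample_id: str,
    assay: Assay,
    fractions: Mapping[str, float],
    uep_fraction: float,
    snr: Mapping[str, float] | None = None,
    thresholds: CallThresholds = CallThresholds(),
) -> AssayCall:
    """Threshold allele fractions into a wildtype/mutant/fail call.

    Mutant iff some mutant base reaches ``min_fraction`` (compared at the
    two-decimal reporting precision) with peak SNR >= ``min_snr``; among
    several qualifying bases the highest fraction wins and a ``multi-mutant``
    QC flag is raised.  Failures (no extension product, or UEP fraction
    above ``max_uep``) are statuses, not exceptions.
    """
    snr = dict(snr or {})
    if not fractions:
        return AssayCall(
            sample_id, assay.assay_id, "fail", fail_reason="no-extension",
            uep_fraction=uep_fraction,
        )
    if uep_fraction > thresholds.max_uep:
        return AssayCall(
            sample_id, assay.assay_id, "fail", fail_reason="insufficient-extension",
            allele_fractions=dict(fractions), uep_fraction=uep_fraction,
        )
    candidates = [
        b
        for b in assay.mut_alleles
        if round(fractions.get(b, 0.0), FRACTION_DECIMALS) >= thresholds.min_fraction
        and snr.get(b, float("inf")) >= thresholds.min_snr
    ]
    flags: list[str] = []
    if len(candidates) > 1:
        flags.append("multi-mutant")
    if candidates:
        best = max(candidates, key=lambda b: (fractions.get(b, 0.0), b))
        return AssayCall(
            sample_id, assay.assay_id, "mutant",
            mut_base=best, aa_change=assay.mut_alleles[best],
            allele_fractions=dict(fractions), uep_fraction=uep_fraction,
            snr=snr, qc_flags=tuple(flags),
        )
    return AssayCall(
        sample_id, assay.assay_id, "wildtype",
        allele_fractions=dict(fractions), uep_fraction=uep_fraction,
        snr=snr, qc_flags=tuple(flags),
    )


@dataclass(frozen=True)
class CodonResolution:
    status: str  # wildtype | mutant | flagged
    aa_change: Optional[str] = None
    fraction: Optional[float] = None
    flag: Optional[str] = None


def resolve_complex(
    calls: Sequence[AssayCall],
    assays: Mapping[str, Assay],
    codon_ref: str,
) -> CodonResolution:
    """Combine the sub-assay calls of one complex codon into one label.

    The mutant base of the (single) mutant sub-assay is substituted into its
    interrogated codon position and the codon translated with the standard
    genetic code, yielding a ``X<pos><Y>`` amino-acid-change label.  Two
    simultaneously mutant sub-assays are chemically possible but biologically
    exceptional, so they are flagged ``multi-hit-codon`` for manual review
    rather than silently resolved.
    """
    if len(codon_ref) != 3:
        raise ComplexGroupError("codon_ref must have length 3")
    members = [assays[c.assay_id] for c in calls]
    groups = {a.complex_group for a in members}
    if len(groups) != 1 or None in groups:
        raise ComplexGroupError("calls do not share a single complex group")
    positions = {a.codon_pos for a in members}
    if None in positions:
        raise ComplexGroupError("complex sub-assays must declare codon_pos")

    mutant_calls = [c for c in calls if c.status == "mutant"]
    if not mutant_calls:
        return CodonResolution("wildtype")
    if len(mutant_calls) > 1:
        return CodonResolution("flagged", flag="multi-hit-codon")

    call = mutant_calls[0]
    assay = assays[call.assay_id]
    pos = assay.codon_pos
    codon = list(codon_ref)
    codon[pos - 1] = call.mut_base
    wt_aa = str(Seq(codon_ref).translate())
    mut_aa = str(Seq("".join(codon)).translate())
    aa_pos = "".join(ch for ch in assay.aa_label if ch.isdigit())
    label = f"{wt_aa}{aa_pos}{mut_aa}"
    fraction = call.allele_fractions.get(call.mut_base)
    return CodonResolution("mutant", aa_change=label, fraction=fraction)


def sample_report(
    calls: Sequence[AssayCall], panel: Panel
) -> list[MutationRecord]:
    """Collapse one sample's assay calls into its mutation report.

    Simple mutant calls yield one record each; complex groups are resolved
    to a single codon-level record.  Records are ordered by gene then
    amino-acid change.  Short-isoform labels carry any long-isoform alias
    recorded on the assay (e.g. MET juxtamembrane numbering).
    """
    records: list[MutationRecord] = []
    sample_ids = {c.sample_id for c in calls}
    if len(sample_ids) > 1:
        raise ValueError(f"calls span multiple samples: {sorted(sample_ids)}")
    sample_id = calls[0].sample_id if calls else ""

    by_group: dict[str, list[AssayCall]] = {}
    for c in calls:
        assay = panel.assays[c.assay_id]
        if assay.complex_group is not None:
            by_group.setdefault(assay.complex_group, []).append(c)
        elif c.status == "mutant":
            records.append(
                MutationRecord(
                    sample_id, assay.gene, c.aa_change,
                    c.allele_fractions.get(c.mut_base, 0.0),
                    aa_alias=assay.aa_aliases.get(c.aa_change),
                )
            )
    for gname, group_calls in sorted(by_group.items()):
        assay0 = panel.assays[group_calls[0].assay_id]
        res = resolve_complex(group_calls, panel.assays, assay0.codon_ref)
        if res.status == "mutant":
            records.append(
                MutationRecord(
                    sample_id, assay0.gene, res.aa_change, res.fraction or 0.0,
                    aa_alias=assay0.aa_aliases.get(res.aa_change),
                )
            )
        # flagged multi-hit codons are deliberately absent from the report;
        # they surface through the assay calls' QC flags
    return sorted(records, key=lambda r: (r.gene, r.aa_change))


def call_sample(
    spectra: Mapping[str, Spectrum],
    panel: Panel,
    thresholds: CallThresholds = CallThresholds(),
    baseline_window: float = 90.0,
    snr_min: float = 3.0,
    peak_width_sd: float = 1.5,
    tol: float = 1.0,
) -> list[AssayCall]:
    """Process every pool spectrum of one sample into assay calls."""
    calls: list[AssayCall] = []
    sample_ids = {s.sample_id for s in spectra.values()}
    if len(sample_ids) != 1:
        raise ValueError("spectra must belong to a single sample")
    sample_id = sample_ids.pop()
    for pool_id, spectrum in sorted(spectra.items()):
        assays = panel.pool_assays(pool_id)
        assignment = process_spectrum(
            spectrum, assays, panel.mass_table,
            baseline_window=baseline_window, snr_min=snr_min,
            peak_width_sd=peak_width_sd, tol=tol,
        )
        for assay in assays:
            sub = assignment.for_assay(assay.assay_id)
            try:
                fractions, uep = allele_fractions(sub)
            except NoSignalError:
                calls.append(
                    AssayCall(sample_id, assay.assay_id, "fail", fail_reason="no-signal")
                )
                continue
            snr = {
                a.label: p.snr
                for a, p in sub.matched.items()
                if a.role != "unextended"
            }
            calls.append(
                call_assay(sample_id, assay, fractions, uep, snr, thresholds)
            )
    return calls


def calls_to_rows(calls: Sequence[AssayCall]) -> list[dict]:
    rows = []
    for c in calls:
        mut_frac = (
            c.allele_fractions.get(c.mut_base, 0.0) if c.mut_base else 0.0
        )
        rows.append(
            {
                "sample_id": c.sample_id,
                "assay_id": c.assay_id,
                "status": c.status,
                "mutant_base": c.mut_base or "",
                "aa_change": c.aa_change or "",
                "mutant_fraction": round(mut_frac, FRACTION_DECIMALS),
                "uep_fraction": round(c.uep_fraction, FRACTION_DECIMALS),
                "qc_flags": ";".join(c.qc_flags) or (c.fail_reason or ""),
            }
        )
    return rows
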