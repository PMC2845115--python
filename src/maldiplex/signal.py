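"""Spectrum processing: baseline, peak detection, integration, assignment.

The processing chain automates what an analyst does on a genotyping
spectrum: estimate a slowly varying baseline, pick local maxima that stand
out from the noise, integrate the background-subtracted area under each
peak, and assign peaks to the expected analyte masses of the pooled assays
— flagging salt-adduct satellites and background peaks so they are excluded
from allele quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from .errors import AmbiguousPanelError, SpectrumError
from .panel import Analyte, Assay, MassTable, analytes_for
from .simulate import Spectrum

#: default peak-to-analyte match tolerance (Da); generous against the
#: >= 8 Da terminator gaps yet tight against 22/38 Da adduct shifts
DEFAULT_TOL = 1.0


@dataclass(frozen=True)
class Peak:
    """A detected spectral peak."""

    apex_mass: float
    area: float
    snr: float

    def __post_init__(self) -> None:
        if self.area < 0 or self.snr < 0:
            raise ValueError("peak area and snr must be nonnegative")


@dataclass
class PeakAssignment:
    """Mapping of detected peaks onto the expected analytes of a pool.

    Each analyte is matched by at most one peak and each peak assigned to at
    most one analyte.  Peaks that match no analyte are flagged either
    ``adduct-of(<assay>:<label>)`` (within tolerance of an analyte mass plus
    a known cation shift) or ``background``.
    """

    analytes: list[Analyte]
    matched: dict[Analyte, Peak]
    unassigned: list[tuple[Peak, str]] = field(default_factory=list)

    def for_assay(self, assay_id: str) -> "PeakAssignment":
        sub = [a for a in self.analytes if a.assay_id == assay_id]
        return PeakAssignment(
            analytes=sub,
            matched={a: p for a, p in self.matched.items() if a.assay_id == assay_id},
            unassigned=list(self.unassigned),
        )


def estimate_baseline(spectrum: Spectrum, window: float = 90.0) -> np.ndarray:
    """Rolling-median baseline over a mass window (Da)."""
    if not window > 0:
        raise ValueError("window must be > 0")
    if spectrum.masses.size == 0:
        raise SpectrumError("empty spectrum")
    spacing = float(np.median(np.diff(spectrum.masses))) if spectrum.masses.size > 1 else 1.0
    size = max(3, int(round(window / spacing)) | 1)  # odd window
    return median_filter(spectrum.intensities, size=size, mode="nearest")


def _noise_scale(residual: np.ndarray) -> float:
    """Robust noise level: scaled median absolute deviation of residuals."""
    mad = float(np.median(np.abs(residual - np.median(residual))))
    return 1.4826 * mad


def detect_peaks(
    spectrum: Spectrum,
    baseline: np.ndarray,
    snr_min: float = 3.0,
    peak_width_sd: float = 1.5,
) -> list[Peak]:
    """Local maxima above baseline with SNR >= ``snr_min``, area-integrated.

    SNR is (apex - baseline) / noise-scale with the noise scale the scaled
    MAD of the baseline residuals.  Each peak's area is the trapezoidal
    integral of the background-subtracted trace over apex +/- 4 peak-width
    standard deviations, truncated at the minima separating neighboring
    detected peaks.  Peaks are returned sorted by mass.
    """
    if not snr_min > 0:
        raise ValueError("snr_min must be > 0")
    residual = spectrum.intensities - baseline
    noise = _noise_scale(residual)
    height = snr_min * noise if noise > 0 else np.finfo(float).tiny
    spacing = (
        float(np.median(np.diff(spectrum.masses))) if spectrum.masses.size > 1 else 1.0
    )
    # suppress satellite maxima closer than the integration half-width, so a
    # noise blip on a peak's flank cannot truncate that peak's support
    distance = max(1, int(round(4.0 * peak_width_sd / spacing)))
    idx, _ = find_peaks(residual, height=height, distance=distance)
    if idx.size == 0:
        return []

    masses = spectrum.masses
    half_width = 4.0 * peak_width_sd
    peaks: list[Peak] = []
    for k, i in enumerate(idx):
        lo = int(np.searchsorted(masses, masses[i] - half_width, side="left"))
        hi = int(np.searchsorted(masses, masses[i] + half_width, side="right")) - 1
        # truncate support at the minimum between this and the adjacent peak
        if k > 0 and idx[k - 1] > lo:
            sep = idx[k - 1] + int(np.argmin(residual[idx[k - 1]: i + 1]))
            lo = max(lo, sep)
        if k + 1 < idx.size and idx[k + 1] < hi:
            sep = i + int(np.argmin(residual[i: idx[k + 1] + 1]))
            hi = min(hi, sep)
        area = float(np.trapezoid(residual[lo: hi + 1], masses[lo: hi + 1]))
        snr = float(residual[i] / noise) if noise > 0 else float("inf")
        peaks.append(Peak(float(masses[i]), max(area, 0.0), max(snr, 0.0)))
    return sorted(peaks, key=lambda p: p.apex_mass)


def assign_peaks(
    peaks: Sequence[Peak],
    analytes: Sequence[Analyte],
    tol: float = DEFAULT_TOL,
    adduct_shifts: Sequence[tuple[str, float]] = (),
) -> PeakAssignment:
    """Greedy nearest-mass matching of peaks to expected analytes.

    Candidate (peak, analyte) pairs within ``tol`` Da are matched smallest
    mass difference first (ties broken toward the lower-mass analyte), each
    peak and analyte used at most once.  Leftover peaks within ``tol`` of an
    analyte mass plus a cation adduct shift are flagged as that analyte's
    adduct; everything else is flagged background.
    """
    if not tol > 0:
        raise ValueError("tol must be > 0")
    srt = sorted(analytes, key=lambda a: a.mass)
    for a, b in zip(srt, srt[1:]):
        if b.mass - a.mass < tol:
            raise AmbiguousPanelError(
                f"analytes {a.assay_id}:{a.label} and {b.assay_id}:{b.label} "
                f"are {b.mass - a.mass:.2f} Da apart (< tol {tol})"
            )

    order = sorted(peaks, key=lambda p: p.apex_mass)
    candidates = []
    for p in order:
        for a in srt:
            d = abs(p.apex_mass - a.mass)
            if d <= tol:
                candidates.append((d, a.mass, p, a))
    candidates.sort(key=lambda t: (t[0], t[1]))

    matched: dict[Analyte, Peak] = {}
    used: set[int] = set()
    for d, _, p, a in candidates:
        if a in matched or id(p) in used:
            continue
        matched[a] = p
        used.add(id(p))

    unassigned: list[tuple[Peak, str]] = []
    for p in order:
        if id(p) in used:
            continue
        flag = "background"
        best = tol + 1.0
        for a in srt:
            for label, shift in adduct_shifts:
                d = abs(p.apex_mass - (a.mass + shift))
                if d <= tol and d < best:
                    best = d
                    flag = f"adduct-of({a.assay_id}:{a.label}+{label})"
        unassigned.append((p, flag))
    return PeakAssignment(analytes=list(srt), matched=matched, unassigned=unassigned)


def process_spectrum(
    spectrum: Spectrum,
    assays: Sequence[Assay],
    mass_table: MassTable,
    baseline_window: float = 90.0,
    snr_min: float = 3.0,
    peak_width_sd: float = 1.5,
    tol: float = DEFAULT_TOL,
) -> PeakAssignment:
    """Baseline -> detect -> assign for one pooled spectrum."""
    analytes = []
    for a in assays:
        analytes.extend(analytes_for(a, mass_table))
    baseline = estimate_baseline(spectrum, baseline_window)
    peaks = detect_peaks(spectrum, baseline, snr_min=snr_min, peak_width_sd=peak_width_sd)
    return assign_peaks(peaks, analytes, tol=tol, adduct_shifts=mass_table.adduct_shifts)


def assignment_rows(sample_id: str, assignment: PeakAssignment) -> list[dict]:
    """Flat rows (one per analyte or flagged peak) for TSV export."""
    rows = []
    for a in assignment.analytes:
        p = assignment.matched.get(a)
        rows.append(
            {
                "sample_id": sample_id,
                "assay_id": a.assay_id,
                "analyte": a.label,
                "expected_mass": round(a.mass, 2),
                "matched_mass": round(p.apex_mass, 2) if p else "",
                "area": round(p.area, 3) if p else 0.0,
                "snr": round(p.snr, 2) if p else 0.0,
                "flag": "" if p else "absent",
            }
        )
    for p, flag in assignment.unassigned:
        rows.append(
            {
                "sample_id": sample_id,
                "assay_id": "",
                "analyte": "",
                "expected_mass": "",
                "matched_mass": round(p.apex_mass, 2),
                "area": round(p.area, 3),
                "snr": round(p.snr, 2),
                "flag": flag,
            }
        )
    return rows
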