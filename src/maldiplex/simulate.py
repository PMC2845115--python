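"""Synthetic-data generation: cohort genotype truths and rendered spectra.

The generative model mirrors the physics the downstream analysis assumes.
For one assay with unextended-primer (UEP) fraction ``u``, per-assay primer
scale ``T``, purity-adjusted mutant allele fractions ``f_b`` (one per mutant
base, ``F = sum f_b``), the expected peak areas are::

    UEP        u * T
    wild type  (1 - u) * T * (1 - F)
    mutant b   (1 - u) * T * f_b

so allele fractions are recoverable as area ratios over the extension
products.  The UEP fraction is a step function of PCR input DNA: about 0.09
below 3 ng of input and about 0.07 at 3 ng and above.  Peaks are rendered as
Gaussians of fixed width (Da) on a regular mass grid, with multiplicative
area noise, additive baseline noise, mass-calibration error, stochastic
sodium/potassium adduct satellites, and spurious salt/background peaks.

Randomness: every public operation takes a single integer seed and expands
it into per-sample substreams via ``numpy`` ``SeedSequence`` keys
``[seed, counter]``, so cohorts are reproducible piecewise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SpectrumError
from .panel import Analyte, Assay, MassTable, Panel, analytes_for


@dataclass(frozen=True)
class SampleTruth:
    """Ground-truth genotype of one simulated sample.

    ``mutations`` maps ``"GENE-AAchange"`` labels (e.g. ``"KRAS-G12D"``) to
    *allele-level* mutant fractions in [0, 1].  A missing label means wild
    type.  Fractions above 0.5 model mutant-allele amplification.  Tumor
    purity multiplies every fraction at rendering time (normal-cell DNA
    dilutes the mutant allele).
    """

    sample_id: str
    mutations: Mapping[str, float]
    purity: float = 1.0
    input_dna_ng: float = 14.0

    def __post_init__(self) -> None:
        for label, f in self.mutations.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{self.sample_id}: fraction for {label} outside [0,1]")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"{self.sample_id}: purity must be in (0,1]")
        if not self.input_dna_ng > 0:
            raise ValueError(f"{self.sample_id}: input_dna_ng must be > 0")

    def mutated_genes(self) -> set[str]:
        return {label.split("-", 1)[0] for label in self.mutations}


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic components of spectrum rendering; all defaults documented.

    ``uep_fraction_low``/``uep_fraction_high`` are the unextended-primer area
    shares below / at-or-above the 3 ng input-DNA boundary.  ``area_cv`` is
    the relative standard deviation of each rendered peak area (within-
    spectrum area ratios on this chemistry are reproducible to a few
    percent).  ``background_peak_rate`` is the expected number of spurious
    salt/background peaks per spectrum.
    """

    uep_fraction_low: float = 0.09
    uep_fraction_high: float = 0.07
    input_dna_boundary_ng: float = 3.0
    peak_width_sd: float = 1.5
    area_cv: float = 0.02
    baseline_level: float = 5.0
    baseline_sd: float = 0.3
    adduct_prob: Mapping[str, float] = field(
        default_factory=lambda: {"Na": 0.1, "K": 0.1}
    )
    adduct_rel_area: float = 0.15
    mass_error_sd: float = 0.2
    background_peak_rate: float = 2.0
    background_area_mean: float = 20.0
    total_area: float = 1000.0

    def __post_init__(self) -> None:
        for name in (
            "peak_width_sd", "area_cv", "baseline_level", "baseline_sd",
            "adduct_rel_area", "mass_error_sd", "background_peak_rate",
            "background_area_mean",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("uep_fraction_low", "uep_fraction_high"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if not self.total_area > 0 or not self.peak_width_sd > 0:
            raise ValueError("total_area and peak_width_sd must be positive")

    def uep_fraction(self, input_dna_ng: float) -> float:
        if input_dna_ng < self.input_dna_boundary_ng:
            return self.uep_fraction_low
        return self.uep_fraction_high

    def zeroed(self) -> "NoiseModel":
        """Copy with all stochastic components off (UEP split retained)."""
        return replace(
            self,
            area_cv=0.0,
            baseline_level=0.0,
            baseline_sd=0.0,
            adduct_prob={},
            mass_error_sd=0.0,
            background_peak_rate=0.0,
        )


@dataclass(frozen=True)
class Spectrum:
    """A rendered mass spectrum trace (regular or irregular mass grid)."""

    sample_id: str
    pool_id: str
    masses: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.masses, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "masses", m)
        object.__setattr__(self, "intensities", i)
        if m.ndim != 1 or m.shape != i.shape:
            raise SpectrumError("masses and intensities must be equal-length 1-D")
        if m.size == 0:
            raise SpectrumError("empty spectrum")
        if np.any(np.diff(m) <= 0):
            raise SpectrumError("masses must be strictly ascending")
        if np.any(i < 0):
            raise SpectrumError("intensities must be nonnegative")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"mass_da": self.masses, "intensity": self.intensities}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path, sample_id: str = "", pool_id: str = "") -> "Spectrum":
        df = pd.read_csv(path, sep="\t")
        return cls(sample_id, pool_id, df["mass_da"].to_numpy(), df["intensity"].to_numpy())


def _rng(seed: int, *counters: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *map(int, counters)])


# categories of PCR input DNA (ng) and their cohort weights, emulating the
# observed input distribution (most FFPE extractions yielded >= 14 ng)
_INPUT_NG = np.array([2.0, 6.0, 11.0, 14.0])
_INPUT_WEIGHTS = np.array([4.0, 9.0, 13.0, 210.0])

#: genes whose mutant allele may be amplified: gene -> (probability, (lo, hi))
AMPLIFIED_GENES: dict[str, tuple[float, tuple[float, float]]] = {
    "MET": (0.5, (0.58, 0.70))
}


def simulate_cohort_truth(
    mutation_freqs: pd.DataFrame | Sequence[tuple[str, str, float]],
    n_samples: int,
    cooccurrence_mode: str = "independent",
    enrichment_factor: float = 1.0,
    purity_mean: float = 0.75,
    purity_sd: float = 0.12,
    purity_min: float = 0.3,
    het_fraction: float = 0.5,
    amplified_genes: Mapping[str, tuple[float, tuple[float, float]]] | None = None,
    seed: int = 0,
) -> list[SampleTruth]:
    """Draw a cohort of ground-truth genotypes from per-mutation frequencies.

    ``mutation_freqs`` rows are ``(gene, aa_change, frequency)`` with
    frequency the per-sample probability of carrying that mutation.  Under
    ``independent`` mode every mutation is an independent Bernoulli draw; in
    ``enriched`` mode, conditional on a sample carrying at least one
    mutation, every other mutation's probability is multiplied by
    ``enrichment_factor`` (capped at 1), modelling co-occurrence excess.

    Mutant allele fractions default to ``het_fraction`` (0.5: heterozygous
    in every tumor cell); genes in ``amplified_genes`` instead draw, with the
    stated probability, an amplified fraction from the given range.  Purity
    is truncated-normal.  Deterministic given ``seed``.
    """
    if isinstance(mutation_freqs, pd.DataFrame):
        rows = list(
            mutation_freqs[["gene", "aa_change", "frequency"]].itertuples(index=False)
        )
    else:
        rows = list(mutation_freqs)
    for gene, aa, f in rows:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"frequency for {gene}-{aa} outside [0,1]: {f}")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if cooccurrence_mode not in ("independent", "enriched"):
        raise ValueError("cooccurrence_mode must be 'independent' or 'enriched'")
    if amplified_genes is None:
        amplified_genes = AMPLIFIED_GENES

    truths = []
    for k in range(n_samples):
        rng = _rng(seed, k)
        hits: dict[str, float] = {}
        draws = rng.random(len(rows))
        carried = [d < f for d, (_, _, f) in zip(draws, rows)]
        if cooccurrence_mode == "enriched" and any(carried) and enrichment_factor > 1:
            extra = rng.random(len(rows))
            for i, ((_, _, f), c) in enumerate(zip(rows, carried)):
                if not c and extra[i] < min(1.0, (enrichment_factor - 1.0) * f):
                    carried[i] = True
        for (gene, aa, _), c in zip(rows, carried):
            if not c:
                continue
            frac = het_fraction
            if gene in amplified_genes:
                p_amp, (lo, hi) = amplified_genes[gene]
                if rng.random() < p_amp:
                    frac = rng.uniform(lo, hi)
            hits[f"{gene}-{aa}"] = frac
        purity = float(
            np.clip(rng.normal(purity_mean, purity_sd), purity_min, 1.0)
        )
        input_ng = float(rng.choice(_INPUT_NG, p=_INPUT_WEIGHTS / _INPUT_WEIGHTS.sum()))
        truths.append(
            SampleTruth(f"S{k:04d}", hits, purity=purity, input_dna_ng=input_ng)
        )
    return truths


def _assay_mut_fractions(truth: SampleTruth, assay: Assay) -> dict[str, float]:
    """Purity-adjusted mutant fraction per extension base for one assay."""
    out: dict[str, float] = {}
    for base, label in assay.mut_alleles.items():
        f = truth.mutations.get(f"{assay.gene}-{label}")
        if f:
            out[base] = out.get(base, 0.0) + f * truth.purity
    return out


def render_spectrum(
    truth: SampleTruth,
    assays: Sequence[Assay],
    mass_table: MassTable,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    pool_id: str = "pool",
    grid_step: float = 0.25,
    margin: float = 60.0,
    stream: int = 0,
) -> Spectrum:
    """Render one multiplexed spectrum for a sample over a pool of assays."""
    rng = _rng(seed, stream)
    u = noise.uep_fraction(truth.input_dna_ng)
    T = noise.total_area

    centers: list[float] = []
    areas: list[float] = []
    expected: list[Analyte] = []
    for assay in assays:
        analytes = analytes_for(assay, mass_table)
        expected.extend(analytes)
        muts = _assay_mut_fractions(truth, assay)
        F = min(sum(muts.values()), 1.0)
        for an in analytes:
            if an.role == "unextended":
                area = u * T
            elif an.role == "wt_extension":
                area = (1.0 - u) * T * (1.0 - F)
            else:
                area = (1.0 - u) * T * muts.get(an.label, 0.0)
            if noise.area_cv > 0:
                area *= max(0.0, 1.0 + rng.normal(0.0, noise.area_cv))
            if area <= 0:
                continue
            center = an.mass + (
                rng.normal(0.0, noise.mass_error_sd) if noise.mass_error_sd > 0 else 0.0
            )
            centers.append(center)
            areas.append(area)
            for adduct_label, shift in mass_table.adduct_shifts:
                p = noise.adduct_prob.get(adduct_label, 0.0)
                if p > 0 and rng.random() < p:
                    centers.append(center + shift)
                    areas.append(area * noise.adduct_rel_area)

    lo = min(an.mass for an in expected) - margin
    hi = max(an.mass for an in expected) + margin

    n_bg = rng.poisson(noise.background_peak_rate) if noise.background_peak_rate > 0 else 0
    for _ in range(n_bg):
        centers.append(rng.uniform(lo, hi))
        areas.append(rng.exponential(noise.background_area_mean))

    grid = np.arange(lo, hi + grid_step, grid_step)
    inten = np.full(grid.shape, noise.baseline_level, dtype=float)
    if noise.baseline_sd > 0:
        inten += rng.normal(0.0, noise.baseline_sd, grid.shape)
    sd = noise.peak_width_sd
    norm = 1.0 / (sd * np.sqrt(2.0 * np.pi))
    for c, a in zip(centers, areas):
        span = (grid > c - 6 * sd) & (grid < c + 6 * sd)
        inten[span] += a * norm * np.exp(-0.5 * ((grid[span] - c) / sd) ** 2)
    return Spectrum(truth.sample_id, pool_id, grid, np.clip(inten, 0.0, None))


def render_sample(
    truth: SampleTruth,
    panel: Panel,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    grid_step: float = 0.25,
) -> dict[str, Spectrum]:
    """Render every pool of a panel for one sample: pool_id -> Spectrum."""
    out = {}
    for i, pool_id in enumerate(sorted(panel.pools)):
        out[pool_id] = render_spectrum(
            truth,
            panel.pool_assays(pool_id),
            panel.mass_table,
            noise,
            seed=seed,
            pool_id=pool_id,
            grid_step=grid_step,
            stream=i,
        )
    return out


def simulate_mixing_series(
    mutant_line_fractions: Sequence[float],
    heterozygous: bool,
    assay: Assay,
    mass_table: MassTable,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> list[tuple[SampleTruth, Spectrum]]:
    """Cell-line mixing series: a mutant line diluted into a wild-type line.

    The allele fraction of each spectrum is cell fraction x 0.5 when the
    mutant line is heterozygous (10% cells -> 5% mutant alleles).  The first
    (alphabetically lowest) mutant base of the assay carries the mutation.
    """
    base = sorted(assay.mut_alleles)[0]
    label = f"{assay.gene}-{assay.mut_alleles[base]}"
    out = []
    for i, cell_frac in enumerate(mutant_line_fractions):
        if not 0.0 <= cell_frac <= 1.0:
            raise ValueError(f"mixing fraction outside [0,1]: {cell_frac}")
        allele_frac = cell_frac * (0.5 if heterozygous else 1.0)
        truth = SampleTruth(
            f"mix{i:02d}",
            {label: allele_frac} if allele_frac > 0 else {},
            purity=1.0,
        )
        spec = render_spectrum(
            truth, [assay], mass_table, noise, seed=seed + i, pool_id="mix"
        )
        out.append((truth, spec))
    return out


def simulate_node_pairs(
    primaries: Sequence[SampleTruth],
    dropout_prob: float = 4.0 / 26.0,
    fraction_drift_sd: float = 0.05,
    seed: int = 0,
) -> list[tuple[SampleTruth, SampleTruth]]:
    """Paired metastatic lymph-node genotypes derived from primary tumors.

    Each primary mutation is inherited by the node independently with
    probability ``1 - dropout_prob``; retained fractions are perturbed by a
    truncated-normal drift.  Nodes never gain mutations absent from their
    primary (metastases are clonal descendants of the primary in this
    model), so any discordance is primary-only.
    """
    if not 0.0 <= dropout_prob <= 1.0:
        raise ValueError("dropout_prob must be in [0,1]")
    pairs = []
    for k, primary in enumerate(primaries):
        rng = _rng(seed, k, 1)
        node_muts: dict[str, float] = {}
        for label, f in primary.mutations.items():
            if rng.random() < dropout_prob:
                continue
            drifted = f + rng.normal(0.0, fraction_drift_sd) if fraction_drift_sd > 0 else f
            node_muts[label] = float(np.clip(drifted, 0.01, 1.0))
        node = SampleTruth(
            f"{primary.sample_id}-LN",
            node_muts,
            purity=primary.purity,
            input_dna_ng=primary.input_dna_ng,
        )
        pairs.append((primary, node))
    return pairs


def truths_to_tsv(truths: Sequence[SampleTruth], path: str | Path) -> None:
    rows = []
    for t in truths:
        if not t.mutations:
            rows.append(
                {"sample_id": t.sample_id, "mutation": "", "true_fraction": 0.0,
                 "purity": t.purity, "input_ng": t.input_dna_ng}
            )
        for label, f in sorted(t.mutations.items()):
            rows.append(
                {"sample_id": t.sample_id, "mutation": label, "true_fraction": f,
                 "purity": t.purity, "input_ng": t.input_dna_ng}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
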