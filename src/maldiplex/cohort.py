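"""Cohort-level mutation analysis.

Given per-sample mutation reports this module computes the summaries a
mutation-profiling study reports: per-mutation and per-gene frequency
tables, double-mutation (co-occurrence) frequencies against the
independence expectation (the product of the single-gene frequencies),
mutant-allele-fraction ratios between co-occurring mutations, concordance
between primary tumors and their metastatic lymph nodes, chi-square tests
of association with histology, and frequency-threshold selection of assays
worth keeping in a smaller panel.

Internal computation keeps full precision; display rounding (percent with
1-2 decimals, ratios with 2) is applied only in the exported tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .caller import MutationRecord
from .panel import Panel


@dataclass(frozen=True)
class FrequencyTable:
    """Per-mutation and per-gene mutation frequencies for one cohort.

    ``per_gene`` carries both the sum of the gene's per-mutation counts and
    the distinct-mutated-sample count; the two coincide exactly when no
    sample carries two mutations within one gene.  ``frequency`` columns are
    fractions of ``n_samples``; ``multiple_mutation_pct`` is the percentage
    of a gene's mutant samples that carry at least one other mutation
    (in any gene, or a second one in the same gene).
    """

    n_samples: int
    per_mutation: pd.DataFrame
    per_gene: pd.DataFrame
    overall_pct: float  # percent of samples with >= 1 mutation

    def gene_frequency(self, gene: str) -> float:
        sub = self.per_gene[self.per_gene["gene"] == gene]
        return float(sub["frequency"].iloc[0]) if len(sub) else 0.0

    def mutation_frequency(self, gene: str, aa_change: str) -> float:
        sub = self.per_mutation[
            (self.per_mutation["gene"] == gene)
            & (self.per_mutation["aa_change"] == aa_change)
        ]
        return float(sub["frequency"].iloc[0]) if len(sub) else 0.0


def frequency_table(
    records: Sequence[MutationRecord], n_samples: int
) -> FrequencyTable:
    """Tally mutation records into a cohort frequency table."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    samples = {r.sample_id for r in records}
    if len(samples) > n_samples:
        raise ValueError(
            f"{len(samples)} distinct mutated samples exceed cohort size {n_samples}"
        )

    mut_samples: dict[tuple[str, str], set[str]] = {}
    gene_samples: dict[str, set[str]] = {}
    per_sample_counts: dict[str, int] = {}
    for r in records:
        mut_samples.setdefault((r.gene, r.aa_change), set()).add(r.sample_id)
        gene_samples.setdefault(r.gene, set()).add(r.sample_id)
        per_sample_counts[r.sample_id] = per_sample_counts.get(r.sample_id, 0) + 1

    per_mutation = pd.DataFrame(
        [
            {
                "gene": g,
                "aa_change": aa,
                "count": len(s),
                "frequency": len(s) / n_samples,
            }
            for (g, aa), s in sorted(mut_samples.items())
        ],
        columns=["gene", "aa_change", "count", "frequency"],
    )

    gene_rows = []
    for gene in sorted(gene_samples):
        count_sum = int(
            per_mutation.loc[per_mutation["gene"] == gene, "count"].sum()
        )
        distinct = gene_samples[gene]
        n_multi = sum(1 for s in distinct if per_sample_counts[s] >= 2)
        gene_rows.append(
            {
                "gene": gene,
                "count_sum": count_sum,
                "count_distinct": len(distinct),
                "frequency": len(distinct) / n_samples,
                "multiple_mutation_pct": 100.0 * n_multi / len(distinct),
            }
        )
    per_gene = pd.DataFrame(
        gene_rows,
        columns=["gene", "count_sum", "count_distinct", "frequency",
                 "multiple_mutation_pct"],
    )
    overall_pct = 100.0 * len(samples) / n_samples
    return FrequencyTable(n_samples, per_mutation, per_gene, overall_pct)


def records_from_counts(
    counts: pd.DataFrame, prefix: str = "S"
) -> list[MutationRecord]:
    """Expand per-mutation sample counts into synthetic mutation records.

    Each gene's mutations are assigned to distinct samples (no sample gets
    two mutations of the same gene), so per-gene distinct-sample counts
    equal the sum of the per-mutation counts — the regime a published
    frequency table with additive gene totals implies.  Cross-gene overlap
    is not reconstructed; use only for frequency computations.
    """
    records = []
    for gene, sub in counts.groupby("gene", sort=True):
        i = 0
        for _, row in sub.iterrows():
            for _ in range(int(row["count"])):
                records.append(
                    MutationRecord(f"{prefix}{gene}-{i:04d}", gene,
                                   row["aa_change"], 0.5)
                )
                i += 1
    return records


def records_from_truths(truths: Sequence) -> list[MutationRecord]:
    """Mutation records straight from simulated ground truths (no spectra)."""
    records = []
    for t in truths:
        for label, f in sorted(t.mutations.items()):
            gene, aa = label.split("-", 1)
            records.append(MutationRecord(t.sample_id, gene, aa, f))
    return records


def expected_double_frequency(freq_a: float, freq_b: float) -> float:
    """Independence expectation for a double mutation: the product rule."""
    return freq_a * freq_b


@dataclass(frozen=True)
class CooccurrenceTable:
    """Actual vs independence-expected double-mutation frequencies."""

    n_samples: int
    table: pd.DataFrame  # gene_a, gene_b, actual, expected (fractions)

    def pair(self, gene_a: str, gene_b: str) -> tuple[float, float]:
        a, b = sorted((gene_a, gene_b))
        sub = self.table[(self.table["gene_a"] == a) & (self.table["gene_b"] == b)]
        if not len(sub):
            raise KeyError(f"no pair {a} x {b}")
        return float(sub["actual"].iloc[0]), float(sub["expected"].iloc[0])


def cooccurrence(
    records: Sequence[MutationRecord], n_samples: int
) -> CooccurrenceTable:
    """Pairwise double-mutation frequencies across genes.

    ``actual`` is the fraction of samples mutated in both genes; ``expected``
    is the product of the two gene-level single frequencies computed from the
    same records.
    """
    ft = frequency_table(records, n_samples)
    gene_samples: dict[str, set[str]] = {}
    for r in records:
        gene_samples.setdefault(r.gene, set()).add(r.sample_id)
    genes = sorted(gene_samples)
    rows = []
    for a, b in itertools.combinations(genes, 2):
        both = len(gene_samples[a] & gene_samples[b])
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "actual": both / n_samples,
                "expected": ft.gene_frequency(a) * ft.gene_frequency(b),
            }
        )
    return CooccurrenceTable(
        n_samples, pd.DataFrame(rows, columns=["gene_a", "gene_b", "actual", "expected"])
    )


def mutation_ratio(
    record_m1: MutationRecord, record_m2: MutationRecord
) -> Optional[float]:
    """Ratio of two co-occurring mutations' allele fractions (M1/M2).

    Returns ``None`` (undefined) when M2's fraction is zero — e.g. a node in
    which the second mutation dropped out.  Both records must come from the
    same sample.
    """
    if record_m1.sample_id != record_m2.sample_id:
        raise ValueError("mutation_ratio compares mutations within one sample")
    if record_m2.fraction == 0:
        return None
    return record_m1.fraction / record_m2.fraction


@dataclass(frozen=True)
class RatioSummary:
    n: int
    n_above: int  # ratios above the dominance threshold
    pct_above: float
    band_counts: Mapping[str, int]
    mean: float
    median: float


def ratio_summary(
    ratios: Sequence[float],
    threshold: float = 1.25,
    balanced_low: float = 0.9,
) -> RatioSummary:
    """Band and summarize a set of M1/M2 allele-fraction ratios.

    Bands: ``m1_dominant`` (ratio > threshold), ``balanced``
    (balanced_low <= ratio <= threshold), ``m2_dominant`` (< balanced_low).
    """
    arr = np.asarray(list(ratios), dtype=float)
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError("ratios must be finite; drop undefined ratios first")
    n_above = int(np.sum(arr > threshold))
    bands = {
        "m1_dominant": n_above,
        "balanced": int(np.sum((arr >= balanced_low) & (arr <= threshold))),
        "m2_dominant": int(np.sum(arr < balanced_low)),
    }
    return RatioSummary(
        n=int(arr.size),
        n_above=n_above,
        pct_above=100.0 * n_above / arr.size if arr.size else 0.0,
        band_counts=bands,
        mean=float(arr.mean()) if arr.size else float("nan"),
        median=float(np.median(arr)) if arr.size else float("nan"),
    )


@dataclass(frozen=True)
class ConcordanceReport:
    """Primary-tumor vs lymph-node mutation-profile concordance."""

    n_pairs: int
    n_identical: int
    percent_concordant: float
    primary_only: tuple[tuple[str, str], ...]  # (sample_id, mutation label)
    node_only: tuple[tuple[str, str], ...]
    #: per double-mutant pair: sample_id -> (primary M1/M2, node M1/M2 or None)
    double_mutant_ratios: Mapping[str, tuple[Optional[float], Optional[float]]] = field(
        default_factory=dict
    )


def concordance(
    primary_reports: Mapping[str, Iterable[MutationRecord]],
    node_reports: Mapping[str, Iterable[MutationRecord]],
) -> ConcordanceReport:
    """Compare paired primary/node mutation reports keyed by sample id.

    A pair is concordant iff the two mutation sets (gene + amino-acid
    change) are identical; the percentage is identical pairs / pairs x 100.
    For primaries with exactly two mutations, the M1/M2 allele-fraction
    ratio (mutations ordered by descending primary fraction) is reported
    for both members of the pair.
    """
    if set(primary_reports) != set(node_reports):
        missing = set(primary_reports) ^ set(node_reports)
        raise ValueError(f"unpaired sample ids: {sorted(missing)}")
    n_pairs = len(primary_reports)
    n_identical = 0
    primary_only: list[tuple[str, str]] = []
    node_only: list[tuple[str, str]] = []
    ratios: dict[str, tuple[Optional[float], Optional[float]]] = {}
    for sid in sorted(primary_reports):
        prim = list(primary_reports[sid])
        node = list(node_reports[sid])
        pset = {(r.gene, r.aa_change) for r in prim}
        nset = {(r.gene, r.aa_change) for r in node}
        if pset == nset:
            n_identical += 1
        primary_only.extend((sid, f"{g}-{aa}") for g, aa in sorted(pset - nset))
        node_only.extend((sid, f"{g}-{aa}") for g, aa in sorted(nset - pset))
        if len(prim) == 2:
            m1, m2 = sorted(prim, key=lambda r: -r.fraction)
            prim_ratio = mutation_ratio(m1, m2)
            node_by_label = {(r.gene, r.aa_change): r for r in node}
            n1 = node_by_label.get((m1.gene, m1.aa_change))
            n2 = node_by_label.get((m2.gene, m2.aa_change))
            node_ratio = mutation_ratio(n1, n2) if n1 and n2 else None
            ratios[sid] = (prim_ratio, node_ratio)
    return ConcordanceReport(
        n_pairs=n_pairs,
        n_identical=n_identical,
        percent_concordant=100.0 * n_identical / n_pairs if n_pairs else 0.0,
        primary_only=tuple(primary_only),
        node_only=tuple(node_only),
        double_mutant_ratios=ratios,
    )


def chisq_association(
    table: Sequence[Sequence[float]], yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square test of association on a 2x2 count table.

    No continuity correction by default (1 degree of freedom); the corrected
    variant is available behind ``yates``.  Raises on a zero marginal.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("all row and column marginals must be > 0")
    res = chi2_contingency(arr, correction=yates)
    return float(res.statistic), float(res.pvalue)


def select_assays(
    freq_table: FrequencyTable,
    panel: Panel,
    level: str = "gene",
    threshold: float = 0.01,
) -> list[str]:
    """Assays whose interrogated mutations clear a cohort-frequency bar.

    At ``gene`` level, every assay of a gene whose total mutation frequency
    reaches ``threshold`` is kept; at ``assay`` level an assay is kept iff
    one of the specific amino-acid changes it reports reaches ``threshold``.
    Output order is deterministic (gene, then assay id).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if level not in ("gene", "assay"):
        raise ValueError("level must be 'gene' or 'assay'")
    selected = []
    for assay in panel.assays.values():
        if level == "gene":
            keep = freq_table.gene_frequency(assay.gene) >= threshold
        else:
            keep = any(
                freq_table.mutation_frequency(assay.gene, label) >= threshold
                for label in assay.mut_alleles.values()
            )
        if keep:
            selected.append(assay.assay_id)
    return sorted(selected, key=lambda aid: (panel.assays[aid].gene, aid))
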