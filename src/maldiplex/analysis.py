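"""End-to-end study analyses: reference-table summaries and simulation benchmarks.

Each function recomputes one headline quantity of a mutation-profiling study
from scratch by running the package: tallying the shipped reference cohort
tables, or generating synthetic spectra/cohorts and pushing them through the
full detect -> assign -> call -> report chain.  The functions are consumed
by the acceptance script and the test suite; problem sizes are parameters
with defaults matching the study conditions.
"""

from __future__ import annotations


import numpy as np

from .caller import CallThresholds, MutationRecord, allele_fractions, call_assay
from .cohort import (
    concordance,
    cooccurrence,
    expected_double_frequency,
    frequency_table,
    mutation_ratio,
    ratio_summary,
    records_from_counts,
    records_from_truths,
)
from .panel import Panel, default_panel, pool_conflicts
from .reference import CohortReference, load_reference
from .replex import replex, replex_optimal
from .signal import process_spectrum
from .simulate import (
    NoiseModel,
    SampleTruth,
    render_spectrum,
    simulate_cohort_truth,
    simulate_mixing_series,
)


# ---------------------------------------------------------------- reference


def reference_gene_frequencies(ref: CohortReference | None = None) -> dict[str, float]:
    """Gene-level and headline per-mutation frequencies (percent) from the
    shipped per-mutation counts."""
    ref = ref or load_reference()
    ft = frequency_table(
        records_from_counts(ref.mutation_counts), ref.n_samples
    )
    out = {
        gene: 100.0 * ft.gene_frequency(gene)
        for gene in ft.per_gene["gene"]
    }
    out["KRAS-G12D"] = 100.0 * ft.mutation_frequency("KRAS", "G12D")
    out["n_mutated_genes"] = float(len(ft.per_gene))
    return out


def reference_expected_doubles(ref: CohortReference | None = None) -> dict[str, float]:
    """Independence-expected double-mutation frequencies (percent) from the
    reference gene-level single frequencies."""
    ref = ref or load_reference()
    singles = {g: f / 100.0 for g, f in ref.gene_single_freq_pct.items()}
    return {
        "METxKRAS": 100.0 * expected_double_frequency(singles["MET"], singles["KRAS"]),
        "NRASxKRAS": 100.0 * expected_double_frequency(singles["NRAS"], singles["KRAS"]),
        "KRASxPIK3CA": 100.0
        * expected_double_frequency(singles["KRAS"], singles["PIK3CA"]),
    }


def reference_concordance(ref: CohortReference | None = None):
    """Primary/node concordance recomputed from the paired-cohort summary.

    The 39 pairs are reconstructed from the shipped summary: the listed
    primary-only mutations each discord one pair; the remaining pairs share
    identical profiles (mutant or wild type).
    """
    ref = ref or load_reference()
    np_ = ref.node_pairs
    primary: dict[str, list[MutationRecord]] = {}
    node: dict[str, list[MutationRecord]] = {}
    k = 0
    for gene, aa in np_["primary_only_mutations"]:
        sid = f"pair{k:02d}"
        primary[sid] = [MutationRecord(sid, gene, aa, 0.3)]
        node[sid] = []
        k += 1
    n_shared_mut = np_["n_node_mutations"]
    for i in range(np_["n_pairs"] - k):
        sid = f"pair{k + i:02d}"
        if i < n_shared_mut:
            primary[sid] = [MutationRecord(sid, "KRAS", "G12D", 0.4)]
            node[sid] = [MutationRecord(sid, "KRAS", "G12D", 0.4)]
        else:
            primary[sid] = []
            node[sid] = []
    return concordance(primary, node)


def reference_ratio_dominance(ref: CohortReference | None = None, seed: int = 0):
    """Share of double-mutant samples whose first mutation dominates.

    Individual ratios are not published, only their bands; ratios are drawn
    uniformly within each published band (the dominance count depends only
    on the band memberships).
    """
    ref = ref or load_reference()
    rng = np.random.default_rng([seed, 5])
    ratios: list[float] = []
    for band in ref.kras_pik3ca_ratio_bands:
        ratios.extend(rng.uniform(band["low"], band["high"], band["n"]).tolist())
    return ratio_summary(ratios, threshold=1.25)


def reference_paired_ratios(ref: CohortReference | None = None) -> dict[str, float]:
    """M1/M2 allele-fraction ratios for the published double-mutant pairs."""
    ref = ref or load_reference()
    out: dict[str, float] = {}
    for entry in ref.paired_double_mutants:
        sid = entry["sample"]
        for tissue in ("primary", "node"):
            f1, f2 = entry[tissue]
            if f1 <= 0:
                continue
            m1 = MutationRecord(sid, *entry["m1"], f1)
            m2 = MutationRecord(sid, *entry["m2"], f2) if f2 > 0 else None
            ratio = mutation_ratio(m1, m2) if m2 else None
            if ratio is not None:
                out[f"{sid}:{tissue}"] = ratio
    return out


# -------------------------------------------------------------- simulation


def _estimate_fraction(
    assay, panel: Panel, truth: SampleTruth, noise: NoiseModel, seed: int
) -> tuple[float, dict[str, float], float]:
    """Render the assay's full multiplexed pool and recover its mutant fraction."""
    pool_id = panel.pool_of(assay.assay_id)
    pool = panel.pool_assays(pool_id)
    spec = render_spectrum(
        truth, pool, panel.mass_table, noise, seed=seed, pool_id=pool_id
    )
    assignment = process_spectrum(spec, pool, panel.mass_table)
    fractions, uep = allele_fractions(assignment.for_assay(assay.assay_id))
    mut_bases = list(assay.mut_alleles)
    est = sum(fractions.get(b, 0.0) for b in mut_bases)
    return est, fractions, uep


def fraction_recovery(
    seed: int = 0,
    n_per_point: int = 100,
    fractions_grid: tuple[float, ...] = (0.05, 0.1, 0.25, 0.5),
    assay_id: str = "PIK3CA_6",
    panel: Panel | None = None,
) -> dict[float, float]:
    """Mean |estimated - true| mutant fraction per grid point, end to end."""
    panel = panel or default_panel()
    assay = panel.assays[assay_id]
    label = f"{assay.gene}-{sorted(assay.mut_alleles.values())[0]}"
    noise = NoiseModel()
    out = {}
    for f in fractions_grid:
        errs = []
        for i in range(n_per_point):
            truth = SampleTruth("s", {label: f} if f > 0 else {}, purity=1.0)
            est, _, _ = _estimate_fraction(assay, panel, truth, noise, seed * 1009 + i)
            errs.append(abs(est - f))
        out[f] = float(np.mean(errs))
    return out


def sensitivity_specificity(
    seed: int = 0,
    n_mutant: int = 200,
    n_wildtype: int = 500,
    fraction: float = 0.05,
    panel: Panel | None = None,
    thresholds: CallThresholds = CallThresholds(),
) -> dict[str, float]:
    """Mutant-detection rate at the detection limit and wild-type call rate.

    Mutant spectra carry one mutation at ``fraction``; wild-type assay calls
    come from fully multiplexed wild-type pool spectra (adducts, background
    peaks and all), counting any mutant call as a false positive.
    """
    panel = panel or default_panel()
    noise = NoiseModel()
    assay = panel.assays["KRAS_4"]
    label = "KRAS-G13D"
    mut_pool_id = panel.pool_of(assay.assay_id)
    mut_pool = panel.pool_assays(mut_pool_id)
    detected = 0
    for i in range(n_mutant):
        truth = SampleTruth("s", {label: fraction}, purity=1.0)
        spec = render_spectrum(
            truth, mut_pool, panel.mass_table, noise,
            seed=seed * 2003 + i, pool_id=mut_pool_id,
        )
        assignment = process_spectrum(spec, mut_pool, panel.mass_table)
        sub = assignment.for_assay(assay.assay_id)
        fr, uep = allele_fractions(sub)
        snr = {
            a.label: p.snr for a, p in sub.matched.items()
            if a.role != "unextended"
        }
        call = call_assay("s", assay, fr, uep, snr, thresholds)
        detected += call.status == "mutant"

    pool_id = "W2"
    pool = panel.pool_assays(pool_id)
    n_calls = 0
    false_pos = 0
    i = 0
    while n_calls < n_wildtype:
        truth = SampleTruth("wt", {}, purity=1.0)
        spec = render_spectrum(
            truth, pool, panel.mass_table, noise, seed=seed * 3001 + i, pool_id=pool_id
        )
        assignment = process_spectrum(spec, pool, panel.mass_table)
        for a in pool:
            if n_calls >= n_wildtype:
                break
            sub = assignment.for_assay(a.assay_id)
            fr, uep = allele_fractions(sub)
            snr = {
                an.label: p.snr for an, p in sub.matched.items()
                if an.role != "unextended"
            }
            call = call_assay("wt", a, fr, uep, snr, thresholds)
            if call.status == "mutant":
                false_pos += 1
            n_calls += 1
        i += 1
    return {
        "sensitivity_pct": 100.0 * detected / n_mutant,
        "false_positive_pct": 100.0 * false_pos / n_wildtype,
        "n_mutant": n_mutant,
        "n_wildtype": n_wildtype,
    }


def mixing_series_estimates(
    seed: int = 0,
    n_seeds: int = 50,
    cell_fractions: tuple[float, ...] = (0.0, 0.05, 0.1, 0.25, 0.5, 1.0),
    assay_id: str = "PIK3CA_6",
    panel: Panel | None = None,
) -> dict[float, float]:
    """Mean recovered allele fraction per mixing fraction (heterozygous line)."""
    panel = panel or default_panel()
    assay = panel.assays[assay_id]
    sums = {c: 0.0 for c in cell_fractions}
    for rep in range(n_seeds):
        series = simulate_mixing_series(
            cell_fractions, True, assay, panel.mass_table,
            NoiseModel(), seed=seed * 4001 + rep * 101,
        )
        for (truth, spec), c in zip(series, cell_fractions):
            assignment = process_spectrum(spec, [assay], panel.mass_table)
            fr, _ = allele_fractions(assignment.for_assay(assay.assay_id))
            sums[c] += sum(fr.get(b, 0.0) for b in assay.mut_alleles)
    return {c: s / n_seeds for c, s in sums.items()}


def independence_check(
    seed: int = 0, n_samples: int = 5000, ref: CohortReference | None = None
) -> dict[str, dict[str, float]]:
    """Actual vs expected co-occurrence on an independently simulated cohort.

    Returns, per gene pair, the actual and expected double-mutant fractions
    and the deviation in units of the binomial standard error.
    """
    ref = ref or load_reference()
    truths = simulate_cohort_truth(ref.mutation_freqs, n_samples, seed=seed)
    records = records_from_truths(truths)
    table = cooccurrence(records, n_samples)
    out = {}
    for _, row in table.table.iterrows():
        e, a = row["expected"], row["actual"]
        se = np.sqrt(max(e * (1 - e), 1e-12) / n_samples)
        out[f"{row['gene_a']}x{row['gene_b']}"] = {
            "actual": a, "expected": e, "z": (a - e) / se,
        }
    return out


def replex_panel_summary(panel: Panel | None = None) -> dict[str, float]:
    """Replex the shipped panel's assays from scratch; count pools/conflicts."""
    panel = panel or default_panel()
    new = replex(
        list(panel.assays.values()), panel.mass_table, max_plex=9, min_gap=16.0
    )
    n_conflicts = sum(
        len(pool_conflicts(new.pool_assays(pid), panel.mass_table, 16.0))
        for pid in new.pools
    )
    return {
        "n_assays": len(panel.assays),
        "n_pools": len(new.pools),
        "n_conflicts": n_conflicts,
    }


def greedy_vs_optimal(
    mass_table, seed: int = 0, n_instances: int = 200
) -> dict[str, float]:
    """Greedy pool counts vs provably minimal counts on random instances."""
    from .panel import Assay

    rng = np.random.default_rng([seed, 8])
    bases = np.array(list("ACGT"))
    n_ok = 0
    gaps = []
    for _ in range(n_instances):
        n = int(rng.integers(3, 11))
        assays = []
        for i in range(n):
            length = int(rng.integers(15, 19))
            seq = "".join(rng.choice(bases, size=length))
            assays.append(
                Assay(
                    assay_id=f"r{i:02d}", gene="G", aa_label="X1",
                    primer_seq=seq, wt_base="A", mut_alleles={"T": "X1Y"},
                )
            )
        max_plex = int(rng.integers(2, 6))
        g = len(replex(assays, mass_table, max_plex=max_plex).pools)
        o = len(replex_optimal(assays, mass_table, max_plex=max_plex).pools)
        n_ok += g >= o
        gaps.append(g - o)
    return {
        "n_instances": n_instances,
        "greedy_ge_optimal_share": n_ok / n_instances,
        "mean_pool_gap": float(np.mean(gaps)),
    }
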