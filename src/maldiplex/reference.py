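"""Shipped reference statistics for a 239-tumor colon cancer cohort.

These are the observed per-mutation sample counts, gene-level single-mutation
frequencies, paired primary/lymph-node summaries and double-mutant allele
fractions from a stage II/III colon cancer cohort profiled with multiplexed
single-base-extension MALDI-TOF genotyping.  They serve two purposes: as
default generating frequencies for the cohort simulator, and as the worked
inputs for the cohort-analysis examples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd


@dataclass(frozen=True)
class CohortReference:
    n_samples: int
    #: per-mutation distinct-sample counts: columns gene, aa_change, count
    mutation_counts: pd.DataFrame
    #: gene-level single-mutation frequencies (percent) used for
    #: co-occurrence expectations
    gene_single_freq_pct: dict[str, float]
    node_pairs: dict
    kras_pik3ca_ratio_bands: list[dict]
    paired_double_mutants: list[dict]

    @property
    def mutation_freqs(self) -> pd.DataFrame:
        """Counts with a per-mutation frequency column (count / n_samples)."""
        df = self.mutation_counts.copy()
        df["frequency"] = df["count"] / self.n_samples
        return df


def load_reference() -> CohortReference:
    text = (
        resources.files("maldiplex.data")
        .joinpath("colon_cohort_reference.json")
        .read_text()
    )
    raw = json.loads(text)
    counts = pd.DataFrame(
        raw["mutation_counts"], columns=["gene", "aa_change", "count"]
    )
    return CohortReference(
        n_samples=int(raw["n_samples"]),
        mutation_counts=counts,
        gene_single_freq_pct=dict(raw["gene_single_freq_pct"]),
        node_pairs=dict(raw["node_pairs"]),
        kras_pik3ca_ratio_bands=list(raw["kras_pik3ca_ratio_bands"]),
        paired_double_mutants=list(raw["paired_double_mutants"]),
    )
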