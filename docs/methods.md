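# Methods

## Assay and mass model

A single-base-extension (SBE) assay is modeled by its extension primer
sequence, the interrogated wild-type base, and up to three mutant extension
bases, each labeled with the amino-acid change it reports. The expected
mass-spectral species ("analytes") of an assay are the unextended primer
(UEP) and one extension product per base; an extension product's mass is
the UEP mass plus the terminator mass of the incorporated base, so the UEP
is always the lightest analyte of its assay.

Masses are **average masses**: linear MALDI-TOF of 4.5–9 kDa
oligonucleotides resolves the averaged isotope envelope, not monoisotopic
peaks. All masses come from a single swappable `MassTable`:

| quantity | default (Da) | rationale |
|---|---|---|
| residue masses A/C/G/T | 313.21 / 289.18 / 329.21 / 304.20 | standard average internal dNMP residue masses |
| terminal adjustment | 18.02 | water for a 5'-OH/3'-OH oligo |
| terminator masses A/C/G/T | 271.17 / 247.15 / 287.17 / 327.19 | mass-modified terminators; pairwise gaps ≥ 16 Da so any two alleles of one assay are resolvable |
| adduct shifts | Na +21.98, K +37.95 | sodium/potassium salt adducts |

The published assay chemistry does not print analyte masses or primer
sequences (they are proprietary), so the shipped 25-assay colon hotspot
panel uses **synthetic primer sequences**, generated deterministically
(`scripts/make_panel.py`, seed 20100316) on a 150 Da UEP-mass ladder from
4800 Da. Pool assignment strides the ladder (assay *i* → pool *i* mod 6),
which makes every shipped pool conflict-free at a 16 Da minimum gap with
adducts included, while the full 25-assay conflict graph remains nontrivial
(each assay conflicts with its immediate mass neighbors), so re-pooling the
panel is a meaningful optimization instance.

Complex codons (e.g. KRAS codon 12, interrogated at two nucleotide
positions by two sub-assays) carry a reference codon and per-sub-assay codon
position; calls are resolved by substituting the mutant base into the codon
and translating with the standard genetic code. MET mutations are labeled
in short-isoform numbering (R970C, T992I) with the long-isoform synonyms
(R988C, T1010I) carried as aliases. The panel mirrors a published
reduced-panel listing of 25 assays; the source text counts them
inconsistently (24 in one place, 25 in another), and one assay (HRAS_6)
interrogates a mutation never observed in the reference cohort — it is
included and is exactly the assay a 1% frequency filter removes.

## Generative spectrum model

For one assay with UEP fraction `u`, per-assay primer scale `T` (default
1000 intensity·Da), and purity-adjusted mutant fractions `f_b`
(`F = Σ f_b`), expected areas are

```
UEP:        u·T
wild type:  (1−u)·T·(1−F)
mutant b:   (1−u)·T·f_b
```

so total area per assay is conserved at `T` and allele fractions are
recoverable as area ratios. `u` is a step function of PCR input DNA
(0.09 below 3 ng, 0.07 at or above), reflecting the observed dependence of
unextended-primer share on input; smoother input–efficiency models are
deliberately omitted. Truth fractions are allele-level; tumor purity
multiplies them at render time; fractions above 0.5 model mutant-allele
amplification (the generator draws amplified fractions from U(0.58, 0.70)
for half of MET-mutant samples, mirroring the observed 58–70% MET fractions).

Peaks are Gaussians of constant width (sd 1.5 Da) on a 0.25 Da grid —
the simplest shape with a closed-form area, adequate for area-recovery
testing. Stochastic components, all per-spectrum and seeded:

| parameter | default | meaning |
|---|---|---|
| `area_cv` | 0.02 | relative sd of each peak area |
| `baseline_level`, `baseline_sd` | 5.0, 0.3 | additive baseline and its noise |
| `mass_error_sd` | 0.2 Da | per-peak calibration error |
| `adduct_prob`, `adduct_rel_area` | 0.1 per cation, 0.15 | salt-satellite generation |
| `background_peak_rate`, `background_area_mean` | 2 per spectrum, 20 | spurious salt/background peaks, exponential areas |

`area_cv` and `baseline_sd` were set so that the allele-fraction
measurement error at the 5% detection limit is ≈0.3 percentage points and
peak SNR at a 5% fraction is ≈20. This is the self-consistency the
chemistry demands: a platform whose 5% mutant peaks are "small but clear"
and whose UEP fractions are quantified to two decimals cannot have
within-spectrum ratio noise much above 2–3%. Values much larger would
contradict the demonstrated detection limit; much smaller would make the
simulation trivially easy.

Cohort truths are drawn per-mutation Bernoulli (independent mode) from a
frequency table; an enriched mode multiplies the conditional probability of
additional mutations by a factor. Purity is truncated-normal
(mean 0.75, sd 0.12, floor 0.3) — plausible for macrodissected FFPE tumor
tissue; input DNA follows the observed input distribution (mostly 14 ng,
occasional 1–13 ng extractions). Lymph-node pairs inherit each primary
mutation with probability `1 − dropout` (default 4/26) plus truncated-normal
fraction drift; nodes never gain mutations absent from the primary,
matching the observed regime where all discordance was primary-only.
Randomness expands from one integer seed into per-sample substreams via
`SeedSequence` keys `[seed, sample_index]`, so cohorts are reproducible
piecewise.

## Signal processing and calling

Baseline is a rolling median over a 90 Da window. The window must be large
against the widest co-elevated peak cluster: a wild-type/mutant pair can sit
16 Da apart and each peak is visibly elevated over ~10 Da, so a 30 Da
median rides up on the cluster and clips ~3% of the area, while 90 Da
recovers noiseless areas to <0.1%. Peaks are local maxima of the
baseline-subtracted trace with SNR ≥ 3, where the noise scale is the scaled
median absolute deviation of the residuals (robust to the sparse peaks).
A minimum peak separation of 4 peak-widths is enforced so a noise blip on a
flank cannot become a separate "peak" that truncates the real peak's
integration support. Areas are trapezoidal integrals over apex ± 4
peak-width sd, truncated at the minimum separating adjacent detected peaks.

Assignment is greedy nearest-mass within ±1.0 Da (generous against ≥16 Da
analyte gaps, tight against 22/38 Da adduct shifts), smallest mass
difference first, ties toward the lower-mass analyte; each peak and analyte
is used at most once. Unmatched peaks within tolerance of an analyte mass
plus an adduct shift are flagged as that analyte's adduct; the rest are
background. **Adduct and background areas are excluded from allele
quantification** — they are artifacts to reject, not signal to merge.

Calls: an assay fails when no extension product is found or the UEP
fraction exceeds 0.90 (extension failure); otherwise it is mutant iff some
mutant base's fraction reaches `min_fraction` (default 0.05, the
demonstrated detection limit) at SNR ≥ 3. Fraction comparisons are made at
the two-decimal reporting precision — an estimate of 0.048 at a true 5%
fraction is a detection, not a miss; with an unbiased estimator a strict
threshold exactly at the detection limit would reject half of all
true-limit mutants by construction. Thresholds are declared surrogates for
the manual multi-investigator review the assay chemistry traditionally
receives; none are published. A doubly-mutant complex codon is flagged
`multi-hit-codon` for review rather than silently resolved.

## Cohort analysis

Frequency tables report per-mutation distinct-sample counts and per-gene
totals both as the sum of per-mutation counts and as distinct mutated
samples (these coincide when no sample is doubly mutant within one gene, as
the reference cohort's published totals imply). The "multiple mutations"
share counts a gene's mutant samples carrying ≥1 other mutation in any gene
including a second in the same gene (the source is ambiguous on this
point). Overall mutation burden is the share of samples with ≥1 mutation
across all profiled genes — the source prints slightly different values
(64%, 60.2%, 60.3%) for differently-scoped gene sets; the implementation
computes the one well-defined quantity.

Double-mutation expectations use the product rule on gene-level single
frequencies. One published expected value (NRAS×PIK3CA 0.40%) does not
match the product rule that reproduces the other cells; the implementation
uses the product rule throughout. Chi-square association is Pearson's test
without continuity correction (the corrected variant is behind a flag); no
multiple-testing correction is applied, matching the source analysis.
Concordance compares mutation sets (gene + amino-acid change) of paired
primary/node reports; per-pair M1/M2 allele-fraction ratios are reported
for double mutants, with the ratio undefined (not zero) when M2 dropped
out of the node.

Replexing selects assays by cohort frequency (gene- or assay-level,
default ≥1%) and re-pools them by greedy first-fit-decreasing over the
conflict graph (descending conflict degree, ties by assay id); pool count
is the only objective — fewest pools is the stated economic goal — with
fill-first as the implicit size tie-break. An exhaustive branch-and-bound
solver (≤12 assays) provides provably minimal counts as the oracle; on 200
random instances greedy never beat it and matched it on all but ~0.5%.

## What the simulation does and does not show

The generator reproduces the statistical structure the analysis assumes:
allele-proportional areas, UEP behavior, salt artifacts, purity dilution,
independence or enrichment of co-occurring mutations, primary-only node
discordance. Passing tests therefore demonstrate that the pipeline
recovers known truth *under this model*. Real FFPE spectra additionally
have mass-dependent peak widths and resolution, PCR amplification bias,
isotope envelope overlap at low mass separation, detector saturation, and
formalin-induced artifactual mutations (C>T deamination) — none are
modeled, so real-data performance claims require real calibration data.
Assay selection and pooling ignore PCR-level primer interactions (the
conflict predicate is pluggable).

## Problem sizes and numerics

Acceptance-scale runs use the study's sizes: a 239-sample reference cohort,
39 node pairs, 100 spectra per fraction grid point, 200/500 spectra for
sensitivity/specificity, 50 replicates per mixing fraction, a 5000-sample
cohort for independence convergence, and 200 random ≤10-assay replex
instances; the whole acceptance script runs in a few seconds. Degenerate
inputs are defined errors: empty spectra, zero marginals in chi-square,
unpaired concordance ids, frequencies outside [0,1], analyte masses closer
than the match tolerance (ambiguous panel). Fractions are kept at full
precision internally and rounded (2 decimals; percent with 1–2) only for
reporting and threshold comparison.
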