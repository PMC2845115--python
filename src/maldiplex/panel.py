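"""Assay panel model: mass tables, assays, analytes, pools.

A single-base-extension (SBE) genotyping assay consists of an extension
primer that anneals immediately 3' of an interrogated base and is extended by
exactly one chain-terminating nucleotide.  Each assay therefore produces up
to ``2 + n_mutant`` mass-spectral species ("analytes"): the unextended primer
(UEP), the wild-type extension product, and one extension product per
interrogated mutant allele.  Assays are pooled into multiplexes; within a
pool every analyte mass must be separated far enough from every other
assay's analytes to be resolvable as a distinct peak.

Masses are average (not monoisotopic) masses: linear MALDI-TOF of
oligonucleotides in the 4.5-9 kDa range resolves the averaged isotope
envelope.  All masses come from a swappable :class:`MassTable`; the shipped
default table uses standard average DNA residue masses and mass-modified
terminators with pairwise gaps >= 16 Da.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .errors import (
    ComplexGroupError,
    DuplicateAssayError,
    InvalidSequenceError,
    MassTableError,
    PanelValidationError,
    PoolSizeError,
    UnknownBaseError,
)

BASES = ("A", "C", "G", "T")

#: default maximum number of assays per multiplex pool
DEFAULT_MAX_PLEX = 9

#: default minimum pairwise gap (Da) required between terminator masses
MIN_TERMINATOR_GAP = 8.0


def _check_bases(mapping: Mapping[str, float], what: str) -> None:
    if set(mapping) != set(BASES):
        raise MassTableError(f"{what} must define exactly the bases {BASES}")
    for base, m in mapping.items():
        if not m > 0:
            raise MassTableError(f"{what}[{base}] must be strictly positive, got {m}")


@dataclass(frozen=True)
class MassTable:
    """Masses used to compute oligonucleotide analyte masses.

    Parameters
    ----------
    residue_mass
        Average mass (Da) contributed by each internal deoxynucleotide
        residue within an oligo.
    terminator_mass
        Mass (Da) added by the chain-terminating nucleotide incorporated
        during single-base extension.  The four values must be pairwise
        distinct with gaps of at least ``min_terminator_gap`` so the four
        possible extension products of one primer are resolvable.
    terminal_adjustment
        Constant (Da) added once per oligo for the end groups (water for a
        5'-OH / 3'-OH oligo).
    adduct_shifts
        Cation adduct shifts as ``(label, Da)`` pairs, e.g. sodium and
        potassium; salt adduct peaks appear at analyte mass + shift.
    """

    residue_mass: Mapping[str, float]
    terminator_mass: Mapping[str, float]
    terminal_adjustment: float
    adduct_shifts: Sequence[tuple[str, float]] = ()
    min_terminator_gap: float = MIN_TERMINATOR_GAP

    def __post_init__(self) -> None:
        _check_bases(self.residue_mass, "residue_mass")
        _check_bases(self.terminator_mass, "terminator_mass")
        if not self.terminal_adjustment > 0:
            raise MassTableError("terminal_adjustment must be strictly positive")
        masses = sorted(self.terminator_mass.values())
        gaps = [b - a for a, b in zip(masses, masses[1:])]
        if gaps and min(gaps) < self.min_terminator_gap:
            raise MassTableError(
                f"terminator masses must be pairwise separated by >= "
                f"{self.min_terminator_gap} Da; smallest gap is {min(gaps):.2f}"
            )
        for label, shift in self.adduct_shifts:
            if not shift > 0:
                raise MassTableError(f"adduct shift {label!r} must be positive")

    @classmethod
    def from_dict(cls, d: Mapping) -> "MassTable":
        return cls(
            residue_mass=dict(d["residue_mass"]),
            terminator_mass=dict(d["terminator_mass"]),
            terminal_adjustment=float(d["terminal_adjustment"]),
            adduct_shifts=[(str(l), float(s)) for l, s in d.get("adduct_shifts", [])],
            min_terminator_gap=float(d.get("min_terminator_gap", MIN_TERMINATOR_GAP)),
        )

    def to_dict(self) -> dict:
        return {
            "residue_mass": dict(self.residue_mass),
            "terminator_mass": dict(self.terminator_mass),
            "terminal_adjustment": self.terminal_adjustment,
            "adduct_shifts": [list(p) for p in self.adduct_shifts],
            "min_terminator_gap": self.min_terminator_gap,
        }

    @classmethod
    def default(cls) -> "MassTable":
        """The shipped default table (``data/mass_table.json``)."""
        text = resources.files("maldiplex.data").joinpath("mass_table.json").read_text()
        return cls.from_dict(json.loads(text))


def oligo_mass(sequence: str, mass_table: MassTable) -> float:
    """Average mass (Da) of a DNA oligo: terminal adjustment + residue sum.

    Raises :class:`InvalidSequenceError` naming the first offending position
    if the sequence contains a symbol outside A, C, G, T.
    """
    total = mass_table.terminal_adjustment
    for i, base in enumerate(sequence):
        if base not in mass_table.residue_mass:
            raise InvalidSequenceError(sequence, i)
        total += mass_table.residue_mass[base]
    return total


@dataclass(frozen=True)
class Assay:
    """One SBE assay interrogating a single nucleotide position.

    ``mut_alleles`` maps each interrogated mutant extension base to the
    amino-acid-change label it reports (e.g. ``{"A": "G12D"}``).  A *complex*
    assay is one of a group of sub-assays (linked by ``complex_group``) that
    interrogate different nucleotide positions of the same codon and must be
    combined to name the amino-acid change; for those, ``codon_ref`` holds
    the wild-type codon (read on the coding strand) and ``codon_pos`` the
    1-based position within it that this sub-assay reads.
    """

    assay_id: str
    gene: str
    aa_label: str
    primer_seq: str
    wt_base: str
    mut_alleles: Mapping[str, str]
    kind: str = "simple"
    complex_group: Optional[str] = None
    codon_ref: Optional[str] = None
    codon_pos: Optional[int] = None
    aa_aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, b in enumerate(self.primer_seq):
            if b not in BASES:
                raise InvalidSequenceError(self.primer_seq, i)
        if len(self.primer_seq) < 15:
            raise PanelValidationError(
                f"{self.assay_id}: primer length must be >= 15, got {len(self.primer_seq)}"
            )
        if self.wt_base not in BASES:
            raise UnknownBaseError(f"{self.assay_id}: unknown wt base {self.wt_base!r}")
        if not self.mut_alleles or len(self.mut_alleles) > 3:
            raise PanelValidationError(
                f"{self.assay_id}: mut_alleles must have 1-3 entries"
            )
        for b in self.mut_alleles:
            if b not in BASES:
                raise UnknownBaseError(f"{self.assay_id}: unknown mutant base {b!r}")
        if self.wt_base in self.mut_alleles:
            raise PanelValidationError(
                f"{self.assay_id}: wt base {self.wt_base} cannot also be a mutant allele"
            )
        if self.kind not in ("simple", "complex"):
            raise PanelValidationError(f"{self.assay_id}: kind must be simple|complex")
        if self.kind == "complex" and self.complex_group is None:
            raise ComplexGroupError(f"{self.assay_id}: complex assay needs a group")
        if self.codon_ref is not None:
            if len(self.codon_ref) != 3:
                raise PanelValidationError(f"{self.assay_id}: codon_ref must be length 3")
            for i, b in enumerate(self.codon_ref):
                if b not in BASES:
                    raise InvalidSequenceError(self.codon_ref, i)
        if self.codon_pos is not None and self.codon_pos not in (1, 2, 3):
            raise PanelValidationError(f"{self.assay_id}: codon_pos must be 1, 2 or 3")

    def to_dict(self) -> dict:
        d = {
            "assay_id": self.assay_id,
            "gene": self.gene,
            "aa_label": self.aa_label,
            "primer_seq": self.primer_seq,
            "wt_base": self.wt_base,
            "mut_alleles": dict(self.mut_alleles),
            "kind": self.kind,
        }
        if self.complex_group is not None:
            d["complex_group"] = self.complex_group
        if self.codon_ref is not None:
            d["codon_ref"] = self.codon_ref
        if self.codon_pos is not None:
            d["codon_pos"] = self.codon_pos
        if self.aa_aliases:
            d["aa_aliases"] = dict(self.aa_aliases)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "Assay":
        return cls(
            assay_id=d["assay_id"],
            gene=d["gene"],
            aa_label=d["aa_label"],
            primer_seq=d["primer_seq"],
            wt_base=d["wt_base"],
            mut_alleles=dict(d["mut_alleles"]),
            kind=d.get("kind", "simple"),
            complex_group=d.get("complex_group"),
            codon_ref=d.get("codon_ref"),
            codon_pos=d.get("codon_pos"),
            aa_aliases=dict(d.get("aa_aliases", {})),
        )


@dataclass(frozen=True)
class Analyte:
    """One expected mass-spectral species of an assay."""

    assay_id: str
    label: str  # "UEP" or the extension base
    mass: float
    role: str  # unextended | wt_extension | mut_extension


def analytes_for(assay: Assay, mass_table: MassTable) -> list[Analyte]:
    """Expected analytes of an assay: UEP, wild-type and mutant extensions.

    Extension-product mass is UEP mass + terminator mass of the incorporated
    base, so the UEP is always the lightest analyte of its assay.
    """
    uep = oligo_mass(assay.primer_seq, mass_table)
    out = [Analyte(assay.assay_id, "UEP", uep, "unextended")]
    out.append(
        Analyte(
            assay.assay_id,
            assay.wt_base,
            uep + mass_table.terminator_mass[assay.wt_base],
            "wt_extension",
        )
    )
    for base in sorted(assay.mut_alleles):
        out.append(
            Analyte(
                assay.assay_id,
                base,
                uep + mass_table.terminator_mass[base],
                "mut_extension",
            )
        )
    return out


@dataclass
class Panel:
    """A named collection of assays partitioned into multiplex pools."""

    name: str
    assays: dict[str, Assay]
    pools: dict[str, list[str]]
    mass_table: MassTable
    max_plex: int = DEFAULT_MAX_PLEX

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for pool_id, ids in self.pools.items():
            if not 1 <= len(ids) <= self.max_plex:
                raise PoolSizeError(
                    f"pool {pool_id}: size {len(ids)} outside [1, {self.max_plex}]"
                )
            for aid in ids:
                if aid not in self.assays:
                    raise PanelValidationError(
                        f"pool {pool_id} references unknown assay {aid!r}"
                    )
                if aid in seen:
                    raise DuplicateAssayError(
                        f"assay {aid!r} appears in more than one pool"
                    )
                seen.add(aid)
        missing = set(self.assays) - seen
        if missing:
            raise PanelValidationError(
                f"assays not assigned to any pool: {sorted(missing)}"
            )
        # complex groups must have >= 2 members agreeing on gene and codon
        groups: dict[str, list[Assay]] = {}
        for a in self.assays.values():
            if a.complex_group is not None:
                groups.setdefault(a.complex_group, []).append(a)
        for gname, members in groups.items():
            if len(members) < 2:
                raise ComplexGroupError(
                    f"complex group {gname!r} has a single member "
                    f"({members[0].assay_id}); a partner assay is missing"
                )
            codons = {a.codon_ref for a in members}
            genes = {a.gene for a in members}
            if len(codons) != 1 or len(genes) != 1:
                raise ComplexGroupError(
                    f"complex group {gname!r} members disagree on gene/codon"
                )

    def pool_of(self, assay_id: str) -> str:
        for pool_id, ids in self.pools.items():
            if assay_id in ids:
                return pool_id
        raise KeyError(assay_id)

    def pool_assays(self, pool_id: str) -> list[Assay]:
        return [self.assays[aid] for aid in self.pools[pool_id]]

    def analytes(self, pool_id: Optional[str] = None) -> list[Analyte]:
        assays: Iterable[Assay]
        if pool_id is None:
            assays = self.assays.values()
        else:
            assays = self.pool_assays(pool_id)
        out: list[Analyte] = []
        for a in assays:
            out.extend(analytes_for(a, self.mass_table))
        return out

    def assay_for_mutation(self, gene: str, aa_change: str) -> tuple[Assay, str]:
        """Find the (assay, mutant base) interrogating a gene/aa-change pair."""
        for a in self.assays.values():
            if a.gene != gene:
                continue
            for base, label in a.mut_alleles.items():
                if label == aa_change:
                    return a, base
        raise KeyError(f"{gene}-{aa_change} is not interrogated by panel {self.name}")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "max_plex": self.max_plex,
            "mass_table": self.mass_table.to_dict(),
            "pools": {
                pid: [self.assays[aid].to_dict() for aid in ids]
                for pid, ids in self.pools.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Panel":
        assays: dict[str, Assay] = {}
        pools: dict[str, list[str]] = {}
        for pid, entries in d["pools"].items():
            ids = []
            for entry in entries:
                a = Assay.from_dict(entry)
                if a.assay_id in assays:
                    raise DuplicateAssayError(f"duplicate assay_id {a.assay_id!r}")
                assays[a.assay_id] = a
                ids.append(a.assay_id)
            pools[pid] = ids
        return cls(
            name=d["name"],
            assays=assays,
            pools=pools,
            mass_table=MassTable.from_dict(d["mass_table"]),
            max_plex=int(d.get("max_plex", DEFAULT_MAX_PLEX)),
        )


def load_panel(path: str | Path) -> Panel:
    """Load and validate a panel definition from its JSON file."""
    with open(path) as fh:
        return Panel.from_dict(json.load(fh))


def write_panel(panel: Panel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(panel.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def panel_to_tsv(panel: Panel) -> str:
    """One row per assay, for human review."""
    import io

    import pandas as pd

    rows = []
    for pid, ids in panel.pools.items():
        for aid in ids:
            a = panel.assays[aid]
            rows.append(
                {
                    "pool": pid,
                    "assay_id": a.assay_id,
                    "gene": a.gene,
                    "aa_label": a.aa_label,
                    "kind": a.kind,
                    "complex_group": a.complex_group or "",
                    "primer_seq": a.primer_seq,
                    "uep_mass_da": round(oligo_mass(a.primer_seq, panel.mass_table), 2),
                    "wt_base": a.wt_base,
                    "mut_alleles": ",".join(
                        f"{b}:{l}" for b, l in sorted(a.mut_alleles.items())
                    ),
                }
            )
    buf = io.StringIO()
    pd.DataFrame(rows).to_csv(buf, sep="\t", index=False)
    return buf.getvalue()


def default_panel() -> Panel:
    """The shipped colon hotspot panel fixture (synthetic primer sequences)."""
    text = resources.files("maldiplex.data").joinpath("colon_panel.json").read_text()
    return Panel.from_dict(json.loads(text))


def pool_conflicts(
    assays: Sequence[Assay],
    mass_table: MassTable,
    min_gap: float = 16.0,
    include_adducts: bool = False,
) -> list[tuple[Analyte, Analyte, float]]:
    """Cross-assay analyte pairs closer than ``min_gap`` Da.

    Pairs within one assay are not reported: their gaps are fixed by the
    terminator chemistry and validated by the mass table, not by pooling.
    With ``include_adducts``, each analyte's salt-adduct satellites are also
    compared against other assays' analytes (an adduct that lands on another
    assay's expected mass is as confounding as the analyte itself).
    """
    if not min_gap > 0:
        raise ValueError("min_gap must be > 0")
    per_assay = [analytes_for(a, mass_table) for a in assays]
    conflicts: list[tuple[Analyte, Analyte, float]] = []
    for i in range(len(per_assay)):
        for j in range(i + 1, len(per_assay)):
            for a in per_assay[i]:
                for b in per_assay[j]:
                    d = abs(a.mass - b.mass)
                    if d < min_gap:
                        conflicts.append((a, b, d))
                    elif include_adducts and any(
                        abs(a.mass + s - b.mass) < min_gap
                        or abs(b.mass + s - a.mass) < min_gap
                        for _, s in mass_table.adduct_shifts
                    ):
                        conflicts.append((a, b, d))
    return conflicts
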