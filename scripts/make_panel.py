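"""Generate the shipped colon hotspot panel fixture with synthetic primers.

Primer sequences are synthetic (the vendor's sequences are proprietary and
unpublished); they are constructed so UEP masses sit on a 150 Da ladder from
4800 Da, with pool assignment striding the ladder so every pool is
mass-resolvable with adducts included.
"""
import json
import sys

sys.path.insert(0, "src")  # allow running from a source checkout
import numpy as np

from maldiplex.panel import BASES, MassTable, Panel, Assay, oligo_mass, pool_conflicts

MT = MassTable.default()

# assay_id, gene, aa_label, wt, muts, kind, group, codon_ref, codon_pos, aliases
ASSAYS = [
    ("BRAF_15", "BRAF", "V600", "T", {"A": "V600E"}, "complex", "BRAF_V600", "GTG", 2, {}),
    ("BRAF_16", "BRAF", "V600", "G", {"A": "V600K", "C": "V600L", "T": "V600L"}, "complex", "BRAF_V600", "GTG", 1, {}),
    ("BRAF_9", "BRAF", "D594", "A", {"T": "D594V", "G": "D594G"}, "simple", None, "GAT", 2, {}),
    ("HRAS_6", "HRAS", "Q61", "A", {"T": "Q61L"}, "simple", None, "CAG", 2, {}),
    ("KRAS_1", "KRAS", "G12", "G", {"T": "G12C", "A": "G12S", "C": "G12R"}, "complex", "KRAS_G12", "GGT", 1, {}),
    ("KRAS_2", "KRAS", "G12", "G", {"T": "G12V", "A": "G12D", "C": "G12A"}, "complex", "KRAS_G12", "GGT", 2, {}),
    ("KRAS_4", "KRAS", "G13", "G", {"A": "G13D"}, "simple", None, "GGC", 2, {}),
    ("KRAS_5", "KRAS", "A59", "G", {"A": "A59T"}, "simple", None, "GCA", 1, {}),
    ("KRAS_7", "KRAS", "Q61", "A", {"T": "Q61L", "G": "Q61R"}, "simple", None, "CAA", 2, {}),
    ("KRAS_8", "KRAS", "Q61", "A", {"C": "Q61H", "T": "Q61H"}, "simple", None, "CAA", 3, {}),
    ("MET_1", "MET", "R970", "C", {"T": "R970C"}, "simple", None, "CGC", 1, {"R970C": "R988C"}),
    ("MET_2", "MET", "T992", "C", {"T": "T992I"}, "simple", None, "ACA", 2, {"T992I": "T1010I"}),
    ("NRAS_1", "NRAS", "G12", "G", {"T": "G12V", "C": "G12A", "A": "G12D"}, "complex", "NRAS_G12", "GGT", 2, {}),
    ("NRAS_2", "NRAS", "G12", "G", {"T": "G12C", "C": "G12R", "A": "G12S"}, "complex", "NRAS_G12", "GGT", 1, {}),
    ("NRAS_3", "NRAS", "G13", "G", {"T": "G13V", "C": "G13A", "A": "G13D"}, "complex", "NRAS_G13", "GGT", 2, {}),
    ("NRAS_4", "NRAS", "G13", "G", {"T": "G13C", "C": "G13R", "A": "G13S"}, "complex", "NRAS_G13", "GGT", 1, {}),
    ("NRAS_7", "NRAS", "Q61", "A", {"C": "Q61H", "T": "Q61H"}, "simple", None, "CAA", 3, {}),
    ("NRAS_8", "NRAS", "Q61", "C", {"G": "Q61E", "A": "Q61K"}, "simple", None, "CAA", 1, {}),
    ("PIK3CA_1", "PIK3CA", "R88", "G", {"A": "R88Q"}, "simple", None, "CGA", 2, {}),
    ("PIK3CA_3", "PIK3CA", "C420", "T", {"C": "C420R"}, "simple", None, "TGT", 1, {}),
    ("PIK3CA_5", "PIK3CA", "E542", "G", {"A": "E542K"}, "simple", None, "GAA", 1, {}),
    ("PIK3CA_6", "PIK3CA", "E545", "G", {"A": "E545K"}, "simple", None, "GAG", 1, {}),
    ("PIK3CA_7", "PIK3CA", "Q546", "C", {"A": "Q546K"}, "simple", None, "CAG", 1, {}),
    ("PIK3CA_8", "PIK3CA", "H701", "A", {"C": "H701P"}, "simple", None, "CAT", 2, {}),
    ("PIK3CA_9", "PIK3CA", "H1047", "A", {"G": "H1047R", "T": "H1047L"}, "simple", None, "CAT", 2, {}),
]


def seq_for_mass(target, rng, tol=12.0):
    L = max(15, round((target - MT.terminal_adjustment) / 309.0))
    seq = list(rng.choice(list(BASES), size=L))

    def mass(s):
        return oligo_mass("".join(s), MT)

    for _ in range(1000):
        err = mass(seq) - target
        if abs(err) <= tol:
            break
        i = int(rng.integers(0, L))
        seq[i] = min(BASES, key=lambda b: abs(mass(seq[:i] + [b] + seq[i + 1:]) - target))
    return "".join(seq)


rng = np.random.default_rng(20100316)
assays = {}
pools = {f"W{k}": [] for k in range(1, 7)}
for slot, row in enumerate(ASSAYS):
    aid, gene, aa, wt, muts, kind, group, codon, pos, aliases = row
    target = 4800.0 + 150.0 * slot
    a = Assay(
        assay_id=aid, gene=gene, aa_label=aa,
        primer_seq=seq_for_mass(target, rng),
        wt_base=wt, mut_alleles=muts, kind=kind, complex_group=group,
        codon_ref=codon, codon_pos=pos, aa_aliases=aliases,
    )
    assays[aid] = a
    pools[f"W{slot % 6 + 1}"].append(aid)

panel = Panel(name="colon-hotspot-v1", assays=assays, pools=pools,
              mass_table=MT, max_plex=9)

for pid, ids in panel.pools.items():
    c = pool_conflicts([assays[i] for i in ids], MT, min_gap=16.0, include_adducts=True)
    print(pid, len(ids), "conflicts:", len(c))
    assert not c

with open("src/maldiplex/data/colon_panel.json", "w") as fh:
    json.dump(panel.to_dict(), fh, indent=1, sort_keys=True)
    fh.write("\n")
print("UEP masses:", [round(oligo_mass(a.primer_seq, MT), 1) for a in assays.values()])
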